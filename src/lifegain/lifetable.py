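"""Exposure-group period life tables from partitioned mortality rates.

Three estimates combine into group-specific life tables over ages 50-100:
(1) national central death rates by single year of age, (2) adjusted
hazard ratios of each exposure group vs the reference, and (3) the
population prevalence of the groups by 5-year age band.  At each age x the
reference-group hazard solves

    m_ref(x) = m_total(x) / sum_g p_g(x) * HR_g,

and each group's hazard is HR_g * m_ref(x), so that the prevalence-weighted
mean of group hazards reproduces the national rate exactly (the partition
identity).  Hazard ratios act on the hazard (m) scale; death probabilities
follow as q = 1 - exp(-m) for one-year intervals.

Life-table conventions (configurable): radix 100,000 at age 50, deaths at
mid-interval (L_x = l_x - 0.5 d_x), and a constant-hazard closure of the
open terminal age (L_100 = l_100 / m_100).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exposure import CAUSES, GROUP_LABELS

logger = logging.getLogger(__name__)

DEFAULT_AGE_RANGE = (50, 100)
DEFAULT_RADIX = 100_000.0


def expand_prevalence(prevalence: pd.DataFrame, ages: np.ndarray) -> np.ndarray:
    """Map 5-year-band prevalences to single-year ages (constant within a
    band; the oldest band is carried forward).  Returns (n_ages, n_groups)."""
    bands = prevalence.index.to_numpy(float)
    cols = [g for g in GROUP_LABELS if g in prevalence.columns]
    if len(cols) != 5:
        raise ValueError("prevalence table must carry all five group columns")
    P = prevalence[cols].to_numpy(float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("prevalence rows must sum to 1")
    idx = np.searchsorted(bands, ages, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("prevalence bands do not reach the requested ages")
    idx = np.clip(idx, 0, len(bands) - 1)
    return P[idx]


def partition_rates(
    rate_table,
    hazard_estimates,
    prevalence: pd.DataFrame,
    age_range=DEFAULT_AGE_RANGE,
    reference: str = "none",
    negative_other_tol: float = 0.5,
) -> dict:
    """Partition national rates into per-exposure-group hazard schedules.

    Parameters
    ----------
    rate_table : RateTable
        Single-group (no sex/race keys) rates covering ``age_range``.
    hazard_estimates : DataFrame
        Long table (group, cause, beta or hr); the all-cause rows drive the
        total partition, cause rows (cvd, cancer) the cause-specific one.
    prevalence : DataFrame
        Band-indexed group prevalences (see :func:`expand_prevalence`).
    negative_other_tol : float
        A group's residual other-cause hazard more negative than this
        fraction of its total hazard raises an error; smaller negatives are
        floored at zero with a logged warning.

    Returns
    -------
    dict mapping group -> DataFrame with columns age, m, m_cvd, m_cancer,
    m_other, satisfying sum_g p_g(x) m_g(x) = m_total(x) to 1e-12.
    """
    ages = np.arange(age_range[0], age_range[1] + 1)
    m_all, m_cvd, m_cancer = rate_table.arrays(*age_range)
    P = expand_prevalence(prevalence, ages)

    hr = _hr_vector(hazard_estimates, "all", reference)
    denom = P @ hr
    if np.any(denom <= 0):
        raise ValueError("prevalence-weighted mean HR is nonpositive at some age")
    m_ref = m_all / denom
    M = np.outer(hr, m_ref)  # (group, age)

    causes_avail = {
        c for c in ("cvd", "cancer")
        if (hazard_estimates["cause"] == c).any()
    }
    Mc = {}
    for cause, m_c in (("cvd", m_cvd), ("cancer", m_cancer)):
        hr_c = _hr_vector(hazard_estimates, cause, reference) if cause in causes_avail \
            else hr
        denom_c = P @ hr_c
        Mc[cause] = np.outer(hr_c, m_c / denom_c)

    out = {}
    for gi, g in enumerate(GROUP_LABELS):
        other = M[gi] - Mc["cvd"][gi] - Mc["cancer"][gi]
        neg = other < 0
        if np.any(other < -negative_other_tol * M[gi]):
            raise ValueError(
                f"group {g!r}: residual other-cause hazard is negative beyond "
                f"tolerance (cause HRs inconsistent with the all-cause HR)"
            )
        if np.any(neg):
            logger.warning(
                "group %r: residual other-cause hazard negative at ages %s; floored at 0",
                g, list(ages[neg]),
            )
            other = np.where(neg, 0.0, other)
        out[g] = pd.DataFrame(
            {
                "age": ages,
                "m": M[gi],
                "m_cvd": Mc["cvd"][gi],
                "m_cancer": Mc["cancer"][gi],
                "m_other": other,
            }
        )
    return out


def _hr_vector(hazard_estimates, cause, reference) -> np.ndarray:
    he = pd.DataFrame(hazard_estimates)
    sub = he[he["cause"] == cause].set_index("group")
    hr = np.empty(5)
    for gi, g in enumerate(GROUP_LABELS):
        if g == reference and g not in sub.index:
            hr[gi] = 1.0
        elif g in sub.index:
            row = sub.loc[g]
            hr[gi] = float(row["hr"]) if "hr" in sub.columns else float(np.exp(row["beta"]))
        else:
            raise ValueError(f"no {cause!r} hazard ratio for group {g!r}")
        if not np.isfinite(hr[gi]) or hr[gi] <= 0:
            raise ValueError(f"invalid hazard ratio for group {g!r}, cause {cause!r}")
    return hr


# -- life-table arithmetic (vectorized core) ----------------------------


def life_table_arrays(M: np.ndarray, radix: float = DEFAULT_RADIX):
    """Life-table columns from hazard schedules.

    ``M`` has shape (..., n_ages): the last axis is age.  Returns a dict of
    arrays (q, l, d, L, T, e) of the same shape.  q = 1 - exp(-m) for the
    one-year intervals, the terminal interval is closed with L = l / m
    (constant hazard beyond the last age) and q = 1.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("hazards must be strictly positive at every age")
    q = 1.0 - np.exp(-M)
    q[..., -1] = 1.0
    surv = np.cumprod(1.0 - q[..., :-1], axis=-1)
    l = np.concatenate(
        [np.full(M.shape[:-1] + (1,), radix), radix * surv], axis=-1
    )
    d = l * q
    L = l - 0.5 * d
    L[..., -1] = l[..., -1] / M[..., -1]
    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = T / l  # NaN only where l has fully vanished (q == 1 upstream)
    return {"q": q, "l": l, "d": d, "L": L, "T": T, "e": e}


def build_life_table(
    schedule,
    radix: float = DEFAULT_RADIX,
    age_range=DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Period life table for one hazard schedule.

    ``schedule`` is either a DataFrame with columns ``age``, ``m`` (and
    optionally ``m_cvd``/``m_cancer``/``m_other``) as produced by
    :func:`partition_rates`, or a bare array of hazards over ``age_range``.
    Returns the full table: age, m, q, l, d, L, T, e (+ cause columns).
    """
    if isinstance(schedule, pd.DataFrame):
        ages = schedule["age"].to_numpy(int)
        m = schedule["m"].to_numpy(float)
        extra = {
            c: schedule[c].to_numpy(float)
            for c in ("m_cvd", "m_cancer", "m_other")
            if c in schedule.columns
        }
        if extra and len(extra) == 3:
            tot = extra["m_cvd"] + extra["m_cancer"] + extra["m_other"]
            if not np.allclose(tot, m, rtol=0, atol=1e-12 * max(1.0, m.max())):
                raise ValueError("cause-specific hazards must sum to the total")
    else:
        m = np.asarray(schedule, dtype=float)
        ages = np.arange(age_range[0], age_range[0] + len(m))
        extra = {}
    cols = life_table_arrays(m, radix=radix)
    out = pd.DataFrame({"age": ages, "m": m, **extra})
    for k in ("q", "l", "d", "L", "T", "e"):
        out[k] = cols[k]
    return out


def e50(table: pd.DataFrame) -> float:
    """Remaining life expectancy at the table's first age."""
    return float(table["e"].iloc[0])


def life_gain(tables: dict, reference: str = "none") -> pd.DataFrame:
    """Life-expectancy difference at age 50 of each group vs the reference."""
    if reference not in tables:
        raise ValueError(f"reference group {reference!r} missing from tables")
    ref_e = e50(tables[reference])
    rows = [
        {"group": g, "e50": e50(t), "gain_years": e50(t) - ref_e}
        for g, t in tables.items()
    ]
    return pd.DataFrame(rows)
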