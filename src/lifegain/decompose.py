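"""Arriaga decomposition of a life-expectancy difference by age and cause.

The difference in life expectancy at age 50 between two life tables is
decomposed exactly into single-year-of-age contributions (direct +
indirect/interaction terms), which are then allocated to causes of death in
proportion to the cause-specific differences in central death rates at each
age.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CAUSE_COLS = ("m_cvd", "m_cancer", "m_other")

#: Total-rate differences below this are treated as degenerate for the
#: cause allocation (the age's contribution is left unallocated).
DEGENERATE_RATE_TOL = 1e-15


def arriaga_by_age(lt_ref: pd.DataFrame, lt_cmp: pd.DataFrame) -> pd.Series:
    """Per-age contributions to e50(comparison) - e50(reference).

    With superscript 1 = reference and 2 = comparison, for non-terminal x

        D_x = (l1_x / l1_50) (L2_x / l2_x - L1_x / l1_x)
            + (T2_{x+1} / l1_50) (l1_x / l2_x - l1_{x+1} / l2_{x+1})

    and for the open terminal age

        D_term = (l1_term / l1_50) (T2_term / l2_term - T1_term / l1_term).

    The contributions sum exactly to the life-expectancy difference.
    """
    if not np.array_equal(lt_ref["age"].to_numpy(), lt_cmp["age"].to_numpy()):
        raise ValueError("life tables must share the same age grid")
    if not np.isclose(lt_ref["l"].iloc[0], lt_cmp["l"].iloc[0]):
        raise ValueError("life tables must share the same radix")
    l1, L1, T1 = (lt_ref[c].to_numpy(float) for c in ("l", "L", "T"))
    l2, L2, T2 = (lt_cmp[c].to_numpy(float) for c in ("l", "L", "T"))
    r = l1[0]
    d = np.empty(len(l1))
    d[:-1] = (l1[:-1] / r) * (L2[:-1] / l2[:-1] - L1[:-1] / l1[:-1]) + (
        T2[1:] / r
    ) * (l1[:-1] / l2[:-1] - l1[1:] / l2[1:])
    d[-1] = (l1[-1] / r) * (T2[-1] / l2[-1] - T1[-1] / l1[-1])
    return pd.Series(d, index=lt_ref["age"].to_numpy(int), name="contribution")


def split_by_cause(
    delta_x: pd.Series,
    m_ref_causes: pd.DataFrame,
    m_cmp_causes: pd.DataFrame,
    m_ref_total: np.ndarray,
    m_cmp_total: np.ndarray,
) -> pd.DataFrame:
    """Allocate per-age contributions to causes of death.

    Each age's contribution is split in proportion to the cause-specific
    rate differences: D_{x,c} = D_x (m1_{x,c} - m2_{x,c}) / (m1_x - m2_x).
    At ages where the total rates coincide (|m1 - m2| below
    :data:`DEGENERATE_RATE_TOL`) the allocation is undefined; those ages get
    zero cause contributions and are flagged ``degenerate`` (so cause sums
    conserve D_x only at non-degenerate ages).
    """
    m1 = np.asarray(m_ref_total, float)
    m2 = np.asarray(m_cmp_total, float)
    c1 = m_ref_causes[list(CAUSE_COLS)].to_numpy(float)
    c2 = m_cmp_causes[list(CAUSE_COLS)].to_numpy(float)
    for label, tot, causes in (("reference", m1, c1), ("comparison", m2, c2)):
        if not np.allclose(causes.sum(axis=1), tot, rtol=0, atol=1e-9 * max(1, tot.max())):
            raise ValueError(f"{label} cause-specific rates do not partition the total")
    dx = delta_x.to_numpy(float)
    diff = m1 - m2
    degenerate = np.abs(diff) < DEGENERATE_RATE_TOL
    if degenerate.any():
        logger.warning(
            "equal total rates at ages %s: cause allocation undefined there",
            list(delta_x.index[degenerate]),
        )
    safe = np.where(degenerate, 1.0, diff)
    shares = (c1 - c2) / safe[:, None]
    shares[degenerate] = 0.0
    out = pd.DataFrame(
        dx[:, None] * shares,
        index=delta_x.index,
        columns=["cvd", "cancer", "other"],
    )
    out.insert(0, "total", dx)
    out["degenerate"] = degenerate
    return out


def cause_summary(decomposition: pd.DataFrame) -> pd.DataFrame:
    """Cause totals (years) and percentage shares of the overall difference."""
    total = decomposition["total"].sum()
    rows = []
    for cause in ("cvd", "cancer", "other"):
        yrs = decomposition[cause].sum()
        rows.append(
            {
                "cause": cause,
                "years": yrs,
                "percent": 100.0 * yrs / total if total != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def decompose_gain(lt_ref: pd.DataFrame, lt_cmp: pd.DataFrame) -> pd.DataFrame:
    """Full age-by-cause decomposition table for two life tables that carry
    cause-specific hazard columns (m_cvd, m_cancer, m_other)."""
    delta = arriaga_by_age(lt_ref, lt_cmp)
    return split_by_cause(
        delta,
        lt_ref,
        lt_cmp,
        lt_ref["m"].to_numpy(float),
        lt_cmp["m"].to_numpy(float),
    )
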