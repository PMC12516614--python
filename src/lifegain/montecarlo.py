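"""Monte Carlo confidence intervals for life expectancy and life gain.

Sampling uncertainty in the fitted log hazard ratios is propagated through
the rate partition and life-table construction: each run draws every
group's log hazard ratio from Normal(beta, se^2) independently, rebuilds
the partitioned life tables, and records e50 per group and each group's
gain vs the reference.  Intervals are the 2.5th/97.5th percentiles across
runs (percentile CIs; baseline rates and prevalences are held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import GROUP_LABELS
from .lifetable import DEFAULT_AGE_RANGE, DEFAULT_RADIX, expand_prevalence, life_table_arrays


@dataclass
class MCInterval:
    """Percentile Monte Carlo interval for one scalar quantity.

    ``lo <= point <= hi`` is deliberately not enforced: a percentile CI can
    exclude the plug-in point estimate in finite samples.
    """

    point: float
    lo: float
    hi: float
    n_runs: int
    seed: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("interval bounds out of order")

    def to_dict(self) -> dict:
        return {
            "point": float(self.point),
            "lo": float(self.lo),
            "hi": float(self.hi),
            "n_runs": self.n_runs,
            "seed": self.seed,
        }


def _e50_for_hr_draws(HR: np.ndarray, m_all: np.ndarray, P: np.ndarray, radix: float):
    """e50 per group for a batch of HR vectors, shape (runs, 5) -> (runs, 5)."""
    denom = P @ HR.T  # (ages, runs)
    m_ref = m_all[:, None] / denom  # (ages, runs)
    M = HR[:, :, None] * m_ref.T[:, None, :]  # (runs, groups, ages)
    return life_table_arrays(M, radix=radix)["e"][..., 0]  # (runs, groups)


def monte_carlo_ci(
    hazard_estimates,
    rate_table,
    prevalence: pd.DataFrame,
    n_runs: int = 1000,
    seed: int = 0,
    reference: str = "none",
    age_range=DEFAULT_AGE_RANGE,
    radix: float = DEFAULT_RADIX,
    return_draws: bool = False,
):
    """Monte Carlo CIs for each group's e50 and for each gain vs reference.

    ``hazard_estimates`` must carry all-cause rows (group, beta, se); only
    the all-cause hazard ratios are resampled (they alone determine e50).

    Returns a dict with ``e50`` and ``gain`` sub-dicts of
    :class:`MCInterval` per group (and optionally the raw e50 draws).
    """
    if n_runs < 2:
        raise ValueError("need at least 2 Monte Carlo runs")
    he = pd.DataFrame(hazard_estimates)
    sub = he[he["cause"] == "all"].set_index("group")
    beta = np.zeros(5)
    se = np.zeros(5)
    for gi, g in enumerate(GROUP_LABELS):
        if g == reference and g not in sub.index:
            continue
        row = sub.loc[g]
        beta[gi] = float(row["beta"])
        se[gi] = float(row["se"])
        if se[gi] < 0 or not np.isfinite(se[gi]):
            raise ValueError(f"invalid standard error for group {g!r}")

    ages = np.arange(age_range[0], age_range[1] + 1)
    m_all, _, _ = rate_table.arrays(*age_range)
    P = expand_prevalence(prevalence, ages)

    rng = np.random.default_rng(seed)
    draws = rng.normal(beta, se, size=(n_runs, 5))
    HR = np.exp(draws)
    e_draws = _e50_for_hr_draws(HR, m_all, P, radix)  # (runs, 5)
    e_point = _e50_for_hr_draws(np.exp(beta)[None, :], m_all, P, radix)[0]

    ref_idx = GROUP_LABELS.index(reference)
    gain_draws = e_draws - e_draws[:, [ref_idx]]
    gain_point = e_point - e_point[ref_idx]

    lo_e, hi_e = np.percentile(e_draws, [2.5, 97.5], axis=0)
    lo_g, hi_g = np.percentile(gain_draws, [2.5, 97.5], axis=0)
    out = {
        "e50": {
            g: MCInterval(e_point[gi], lo_e[gi], hi_e[gi], n_runs, seed)
            for gi, g in enumerate(GROUP_LABELS)
        },
        "gain": {
            g: MCInterval(gain_point[gi], lo_g[gi], hi_g[gi], n_runs, seed)
            for gi, g in enumerate(GROUP_LABELS)
        },
    }
    if return_draws:
        out["e50_draws"] = e_draws
    return out
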