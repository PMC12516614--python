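"""Model/Results facade for the life-expectancy analysis.

:class:`LifeExpectancyModel` bundles the three estimates the method needs
(national rates, group hazard ratios, group prevalences); ``fit()`` builds
the partitioned life tables, life gains, Monte Carlo intervals and the
age-by-cause decomposition, returned as a :class:`LifeExpectancyResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cox import DEFAULT_COVARIATES, WeightedCoxModel
from .decompose import cause_summary, decompose_gain
from .exposure import GROUP_LABELS
from .lifetable import (
    DEFAULT_AGE_RANGE,
    DEFAULT_RADIX,
    build_life_table,
    life_gain,
    partition_rates,
)
from .montecarlo import monte_carlo_ci
from .simulate import tabulate_prevalence


class LifeExpectancyModel:
    """Life expectancy by exposure group from rates, hazard ratios and
    prevalences.

    Parameters
    ----------
    rate_table : RateTable
        National single-year-age rates covering ``age_range`` (single
        sex/race group).
    hazard_estimates : DataFrame
        Long table (group, cause, beta, se, hr) with all-cause rows for
        every non-reference group; cvd/cancer rows optional (they refine
        the cause-specific partition used by the decomposition).
    prevalence : DataFrame
        Exposure-group prevalence by 5-year age band
        (:func:`~lifegain.simulate.tabulate_prevalence` layout).
    """

    def __init__(
        self,
        rate_table,
        hazard_estimates,
        prevalence: pd.DataFrame,
        reference: str = "none",
        age_range=DEFAULT_AGE_RANGE,
        radix: float = DEFAULT_RADIX,
    ):
        self.rate_table = rate_table
        self.hazard_estimates = pd.DataFrame(hazard_estimates)
        self.prevalence = prevalence
        self.reference = reference
        self.age_range = age_range
        self.radix = radix

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        rate_table,
        covariates=DEFAULT_COVARIATES,
        causes=("all", "cvd", "cancer"),
        reference: str = "none",
        **kwargs,
    ) -> "LifeExpectancyModel":
        """Fit the weighted Cox models on a cohort (with derived exposure
        columns) and tabulate its prevalences, then assemble the model."""
        estimates = []
        for cause in causes:
            res = WeightedCoxModel(
                cohort, cause=cause, covariates=covariates, reference=reference
            ).fit()
            estimates.append(res.hazard_estimates)
        hazards = pd.concat(estimates, ignore_index=True)
        prevalence = tabulate_prevalence(cohort)
        return cls(rate_table, hazards, prevalence, reference=reference, **kwargs)

    def fit(self, n_runs: int = 1000, seed: int = 0) -> "LifeExpectancyResults":
        schedules = partition_rates(
            self.rate_table,
            self.hazard_estimates,
            self.prevalence,
            age_range=self.age_range,
            reference=self.reference,
        )
        tables = {
            g: build_life_table(s, radix=self.radix, age_range=self.age_range)
            for g, s in schedules.items()
        }
        gains = life_gain(tables, reference=self.reference)
        intervals = monte_carlo_ci(
            self.hazard_estimates,
            self.rate_table,
            self.prevalence,
            n_runs=n_runs,
            seed=seed,
            reference=self.reference,
            age_range=self.age_range,
            radix=self.radix,
        )
        return LifeExpectancyResults(self, tables, gains, intervals)


class LifeExpectancyResults:
    """Fitted life tables, life gains with Monte Carlo CIs, and
    decompositions of each group's gain vs the reference."""

    def __init__(self, model, life_tables, gains, intervals):
        self.model = model
        self.life_tables = life_tables
        self._gains = gains
        self.intervals = intervals

    @property
    def e50(self) -> pd.Series:
        return pd.Series(
            {g: float(t["e"].iloc[0]) for g, t in self.life_tables.items()},
            name="e50",
        )

    @property
    def gains(self) -> pd.DataFrame:
        """Per-group e50 and gain vs reference, with percentile CIs."""
        out = self._gains.copy()
        for col, key in (("e50", "e50"), ("gain", "gain")):
            ivs = self.intervals[key]
            out[f"{col}_lo"] = [ivs[g].lo for g in out["group"]]
            out[f"{col}_hi"] = [ivs[g].hi for g in out["group"]]
        return out.rename(columns={"gain_years": "gain"})[
            ["group", "e50", "e50_lo", "e50_hi", "gain", "gain_lo", "gain_hi"]
        ]

    def decompose(self, comparison: str, reference: str | None = None) -> pd.DataFrame:
        """Arriaga age-by-cause decomposition of comparison-vs-reference."""
        ref = reference if reference is not None else self.model.reference
        return decompose_gain(self.life_tables[ref], self.life_tables[comparison])

    def decomposition_summary(self, comparison: str) -> pd.DataFrame:
        return cause_summary(self.decompose(comparison))

    def summary(self) -> str:
        lines = [
            "Life expectancy at age 50 by exposure group",
            "=" * 60,
            f"reference: {self.model.reference}    ages "
            f"{self.model.age_range[0]}-{self.model.age_range[1]}    "
            f"radix {self.model.radix:g}",
            "-" * 60,
            f"{'group':<12}{'e50':>8}{'95% CI':>18}{'gain':>8}{'95% CI':>16}",
        ]
        for _, r in self.gains.iterrows():
            ci_e = f"({r['e50_lo']:.2f}, {r['e50_hi']:.2f})"
            ci_g = f"({r['gain_lo']:.2f}, {r['gain_hi']:.2f})"
            lines.append(
                f"{r['group']:<12}{r['e50']:>8.2f}{ci_e:>18}"
                f"{r['gain']:>8.2f}{ci_g:>16}"
            )
        lines.append("-" * 60)
        for g in GROUP_LABELS:
            if g == self.model.reference or g not in self.life_tables:
                continue
            cs = self.decomposition_summary(g)
            parts = ", ".join(
                f"{r['cause']} {r['years']:+.2f}y ({r['percent']:.1f}%)"
                for _, r in cs.iterrows()
                if np.isfinite(r["percent"])
            )
            lines.append(f"gain {g} vs {self.model.reference}: {parts}")
        return "\n".join(lines)
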