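"""National mortality rate tables and old-age extrapolation.

A :class:`RateTable` holds central death rates per person-year by single
year of age (optionally by sex and/or race): all-cause ``m_all`` and the
cause-specific ``m_cvd`` and ``m_cancer``; the residual "other" cause is
implied.  Cause-specific national data often stop before age 100 (CVD rates
end at 84); :func:`extrapolate_cause_rates` projects them to older ages with
a Poisson regression on age and age squared on the log-rate scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

RATE_COLUMNS = ("m_all", "m_cvd", "m_cancer")
KEY_COLUMNS = ("sex", "race")


class RateTable:
    """Single-year-age central death rates, all-cause and cause-specific.

    Wraps a DataFrame with columns ``age``, optional ``sex``/``race`` keys,
    and ``m_all``, ``m_cvd``, ``m_cancer``.  Cause columns may be NaN at old
    ages pending extrapolation; wherever both causes are present the
    invariant ``m_all >= m_cvd + m_cancer >= 0`` must hold, and ages must be
    contiguous within each key group.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in ("age", *RATE_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"rate table lacks columns: {missing}")
        self.df = df
        self.keys = [k for k in KEY_COLUMNS if k in df.columns]
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["age", *self.keys])
        if dup.any():
            raise ValueError(
                f"duplicate (age{',' if self.keys else ''}{','.join(self.keys)}) keys "
                f"at rows {list(df.index[dup])}"
            )
        if (df["m_all"] <= 0).any():
            raise ValueError("m_all must be strictly positive at every age")
        for c in ("m_cvd", "m_cancer"):
            bad = df[c].notna() & (df[c] < 0)
            if bad.any():
                raise ValueError(f"negative {c} at rows {list(df.index[bad])}")
        both = df["m_cvd"].notna() & df["m_cancer"].notna()
        excess = both & (df["m_cvd"] + df["m_cancer"] > df["m_all"] * (1 + 1e-12))
        if excess.any():
            rows = list(df.index[excess])
            raise ValueError(
                f"m_cvd + m_cancer exceeds m_all at rows {rows} "
                f"(ages {list(df.loc[excess, 'age'])})"
            )
        for _, grp in self._groups():
            ages = np.sort(grp["age"].to_numpy())
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError("ages must be contiguous within each sex/race group")

    def _groups(self):
        if self.keys:
            return self.df.groupby(self.keys, sort=True)
        return [((), self.df)]

    def select(self, sex=None, race=None) -> "RateTable":
        """Sub-table for one sex and/or race key, keys dropped."""
        df = self.df
        for key, val in (("sex", sex), ("race", race)):
            if val is not None:
                if key not in df.columns:
                    raise KeyError(f"rate table has no {key} column")
                df = df[df[key] == val]
                if df.empty:
                    raise KeyError(f"no rows with {key}={val!r}")
        return RateTable(df.drop(columns=[k for k in self.keys]), validate=False)

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.df["age"].unique())

    def m_other(self) -> pd.Series:
        return self.df["m_all"] - self.df["m_cvd"] - self.df["m_cancer"]

    def arrays(self, age_lo: int, age_hi: int):
        """(m_all, m_cvd, m_cancer) arrays over a contiguous age span."""
        if self.keys:
            raise ValueError("select a single sex/race group before extracting arrays")
        df = self.df.set_index("age").sort_index()
        ages = np.arange(age_lo, age_hi + 1)
        if not set(ages) <= set(df.index):
            raise ValueError(f"rate table does not cover ages {age_lo}..{age_hi}")
        sub = df.loc[ages]
        return (
            sub["m_all"].to_numpy(float),
            sub["m_cvd"].to_numpy(float),
            sub["m_cancer"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        span = f"{self.df['age'].min()}-{self.df['age'].max()}"
        return f"RateTable(ages {span}, n={len(self.df)}, keys={self.keys})"


def read_rate_table(path) -> RateTable:
    """Read and validate a rate-table CSV (columns: age, [sex], [race],
    m_all, m_cvd, m_cancer)."""
    df = pd.read_csv(path, comment="#")
    return RateTable(df)


@dataclass
class RateProjectionModel:
    """Fitted log-quadratic rate projection for one cause.

    log m(age) = b0 + b1*age + b2*age^2, fitted by Poisson regression on the
    observed rates (unit-exposure offset); projected rates are exp of the
    quadratic and therefore strictly positive by construction.
    """

    cause: str
    coefficients: np.ndarray  # (intercept, age, age^2)
    fitted_range: tuple
    projected_range: tuple
    deviance: float
    condition_number: float

    def predict(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        X = np.column_stack([np.ones_like(ages), ages, ages**2])
        return np.exp(X @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "coefficients": [float(c) for c in self.coefficients],
            "fitted_range": [int(a) for a in self.fitted_range],
            "projected_range": [int(a) for a in self.projected_range],
            "deviance": float(self.deviance),
            "condition_number": float(self.condition_number),
        }


def _fit_log_quadratic(ages, rates, cause):
    if np.any(rates <= 0):
        raise ValueError(f"nonpositive {cause} rate in the fitting range")
    X = np.column_stack([np.ones_like(ages, dtype=float), ages, ages**2.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(rates, X, family=sm.families.Poisson()).fit(
            maxiter=500, tol=1e-12
        )
    cond = float(np.linalg.cond(X))
    logger.info(
        "log-quadratic projection for %s: coef=%s deviance=%.3g cond=%.3g",
        cause, fit.params, fit.deviance, cond,
    )
    return np.asarray(fit.params, float), float(fit.deviance), cond


def extrapolate_cause_rates(
    rate_table: RateTable,
    last_observed_age: int = 84,
    target_max_age: int = 100,
    causes=("cvd",),
) -> tuple[RateTable, list[RateProjectionModel]]:
    """Project cause-specific rates beyond the last observed age.

    For each requested cause, a Poisson regression of the observed rates on
    age and age squared (log link) is fitted over the contiguous observed
    ages up to ``last_observed_age``; ages ``last_observed_age + 1`` to
    ``target_max_age`` are filled with the fitted curve.  Observed ages are
    left untouched, and all-cause rates at projected ages are raised to
    ``m_cvd + m_cancer`` (with a logged warning) wherever the projection
    would otherwise break the cause-partition invariant.

    Returns the completed :class:`RateTable` and the per-cause
    :class:`RateProjectionModel` diagnostics.
    """
    if rate_table.keys:
        raise ValueError("extrapolate one sex/race group at a time (use .select)")
    df = rate_table.df.set_index("age").sort_index()
    obs_ages = df.index[df.index <= last_observed_age].to_numpy()
    if len(obs_ages) < 10:
        raise ValueError("need at least 10 observed ages to fit the projection")
    if not np.array_equal(obs_ages, np.arange(obs_ages[0], obs_ages[-1] + 1)):
        raise ValueError("observed ages must be contiguous up to the last observed age")
    proj_ages = np.arange(last_observed_age + 1, target_max_age + 1)
    if not set(proj_ages) <= set(df.index):
        raise ValueError(
            f"rate table must carry all-cause rows up to age {target_max_age}"
        )

    models = []
    for cause in causes:
        col = f"m_{cause}"
        if col not in df.columns:
            raise ValueError(f"unknown cause column {col!r}")
        rates = df.loc[obs_ages, col].to_numpy(float)
        coef, deviance, cond = _fit_log_quadratic(obs_ages.astype(float), rates, cause)
        model = RateProjectionModel(
            cause=cause,
            coefficients=coef,
            fitted_range=(int(obs_ages[0]), int(obs_ages[-1])),
            projected_range=(int(proj_ages[0]), int(proj_ages[-1])),
            deviance=deviance,
            condition_number=cond,
        )
        df.loc[proj_ages, col] = model.predict(proj_ages)
        models.append(model)

    # Cause-partition guard on the projected ages only.
    both = df.loc[proj_ages, "m_cvd"].notna() & df.loc[proj_ages, "m_cancer"].notna()
    sum_c = df.loc[proj_ages, "m_cvd"] + df.loc[proj_ages, "m_cancer"]
    raise_rows = both & (sum_c > df.loc[proj_ages, "m_all"])
    if raise_rows.any():
        ages_raised = list(proj_ages[raise_rows.to_numpy()])
        logger.warning(
            "projected cause rates exceed m_all at ages %s; raising m_all to the cause sum",
            ages_raised,
        )
        df.loc[proj_ages[raise_rows.to_numpy()], "m_all"] = sum_c[raise_rows]

    return RateTable(df.reset_index()), models
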