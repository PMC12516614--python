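"""Coffee-exposure derivation and covariate coding for 24-hour dietary recalls.

The exposure is daily coffee intake in standard 8-oz cups, averaged over the
available recall days, and grouped into five ordered categories (none, low,
moderate, high, very high).  Subtype flags (caffeinated / instant / with
sugar) are derived from the attributes of the consumed items.  Covariate
coding (income-to-poverty category, physical-activity sufficiency) and the
sequential eligibility cascade live here as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Volume of one standard cup of coffee (8 oz) in millilitres.
ML_PER_CUP = 236.56

#: Ordered exposure-group labels; ordinal codes are the positions 0..4.
GROUP_LABELS = ("none", "low", "moderate", "high", "very_high")

#: Upper cup bounds of the first four groups; intervals are left-open,
#: right-closed ((1, 2] is "1 to <= 2 cups"), the last group is > 3 cups.
GROUP_UPPER_BOUNDS = (0.0, 1.0, 2.0, 3.0)

#: Death-cause labels used throughout (competing causes of death).
CAUSES = ("cvd", "cancer", "other")

#: Eligibility cascade: (step name, boolean flag column), applied in order.
EXCLUSION_STEPS = (
    ("pregnant", "pregnant"),
    ("missing_mortality", "missing_mortality"),
    ("missing_smoking", "missing_smoking"),
    ("missing_education", "missing_education"),
    ("missing_marital", "missing_marital"),
    ("missing_activity", "missing_activity"),
)


def cups_from_volume(volume_ml):
    """Convert a consumed coffee volume (mL) to standard 8-oz cups."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v < 0):
        raise ValueError("coffee volume must be nonnegative")
    out = v / ML_PER_CUP
    return float(out) if np.isscalar(volume_ml) else out


def average_recalls(day1, day2=None):
    """Average coffee cups over the available recall days.

    Single-day participants are used as documented; two-day participants are
    averaged.  ``day2`` may be None/NaN (scalar) or contain NaN (array), which
    marks a missing second recall.
    """
    d1 = np.asarray(day1, dtype=float)
    if np.any(d1 < 0):
        raise ValueError("recall cups must be nonnegative")
    if day2 is None:
        return float(d1) if np.isscalar(day1) else d1.copy()
    d2 = np.asarray(day2, dtype=float)
    if np.any(d2[~np.isnan(d2)] < 0):
        raise ValueError("recall cups must be nonnegative")
    out = np.where(np.isnan(d2), d1, 0.5 * (d1 + d2))
    return float(out) if out.ndim == 0 else out


def categorize(cups):
    """Map daily cups to the five-level exposure group.

    Boundaries are left-open, right-closed: 0 -> none, (0, 1] -> low,
    (1, 2] -> moderate, (2, 3] -> high, (3, inf) -> very_high.
    """
    c = np.asarray(cups, dtype=float)
    if np.any(c < 0):
        raise ValueError("cups must be nonnegative")
    code = np.searchsorted(GROUP_UPPER_BOUNDS, c, side="left")
    if np.isscalar(cups) or c.ndim == 0:
        return GROUP_LABELS[int(code)]
    return pd.Categorical.from_codes(code, categories=list(GROUP_LABELS), ordered=True)


def ordinal_code(group):
    """Ordinal code 0..4 of an exposure-group label (or array of labels)."""
    if isinstance(group, str):
        return GROUP_LABELS.index(group)
    return pd.Categorical(group, categories=list(GROUP_LABELS), ordered=True).codes


def subtype_flags(items, mixed_rule="any"):
    """Derive (caffeinated, instant, with_sugar) flags from consumed items.

    Parameters
    ----------
    items : DataFrame or list of dict
        One row per consumed coffee item with boolean ``caffeinated`` and
        ``instant`` attributes, ``added_sugar_g`` grams, and (for the
        majority rule) ``volume_ml``.
    mixed_rule : {"any", "majority"}
        How mixed consumers (e.g. both caffeinated and decaf items in a day)
        are classified: ``any`` sets a flag if any item has the attribute;
        ``majority`` classifies by the larger share of consumed volume.

    ``with_sugar`` is True when total added sugar across items exceeds 0 g.
    """
    df = pd.DataFrame(items)
    if df.empty:
        raise ValueError("empty item list: flags are undefined without consumed items")
    with_sugar = bool(df["added_sugar_g"].sum() > 0)
    if mixed_rule == "any":
        caffeinated = bool(df["caffeinated"].any())
        instant = bool(df["instant"].any())
    elif mixed_rule == "majority":
        vol = df["volume_ml"].astype(float)
        total = vol.sum()
        if total <= 0:
            raise ValueError("majority rule requires positive total volume")
        caffeinated = bool(vol[df["caffeinated"].astype(bool)].sum() > 0.5 * total)
        instant = bool(vol[df["instant"].astype(bool)].sum() > 0.5 * total)
    else:
        raise ValueError(f"unknown mixed_rule {mixed_rule!r}")
    return caffeinated, instant, with_sugar


def apply_exclusions(cohort: pd.DataFrame):
    """Apply the sequential eligibility cascade and return (eligible, log).

    Records are removed in the fixed step order of :data:`EXCLUSION_STEPS`;
    a record failing several flags is removed (and counted) at the first
    applicable step only.  The log reports the count removed at each step and
    the initial/final sizes.
    """
    missing = [col for _, col in EXCLUSION_STEPS if col not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks exclusion flag columns: {missing}")
    keep = cohort
    log = {"n_initial": int(len(cohort)), "steps": []}
    for step, col in EXCLUSION_STEPS:
        drop = keep[col].astype(bool)
        log["steps"].append({"step": step, "n_removed": int(drop.sum())})
        keep = keep.loc[~drop]
    log["n_eligible"] = int(len(keep))
    return keep.copy(), log


def code_income(ratio):
    """Income-to-poverty ratio -> category: low (<=1.30), moderate
    (1.31-3.50), high (>3.50); missing ratios form their own category."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r[~np.isnan(r)] < 0):
        raise ValueError("income-to-poverty ratio must be nonnegative")
    cats = np.select(
        [np.isnan(r), r <= 1.30, r <= 3.50], ["missing", "low", "moderate"], "high"
    )
    if np.isscalar(ratio) or (isinstance(ratio, float) or r.ndim == 0):
        return str(cats) if r.ndim == 0 else cats
    return cats


def code_activity(moderate_min, vigorous_min):
    """Sufficient physical activity: >=150 min/week moderate, or >=75 min
    vigorous, or an equivalent combination (1 vigorous min == 2 moderate)."""
    m = np.asarray(moderate_min, dtype=float)
    v = np.asarray(vigorous_min, dtype=float)
    out = (m + 2.0 * v) >= 150.0
    return bool(out) if out.ndim == 0 else out


def weighted_correlation(x, y, w):
    """Weighted Pearson correlation between ``x`` and ``y`` with weights ``w``.

    Invariant to rescaling all weights by a positive constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mx = np.dot(w, x) / wsum
    my = np.dot(w, y) / wsum
    cov = np.dot(w, (x - mx) * (y - my)) / wsum
    vx = np.dot(w, (x - mx) ** 2) / wsum
    vy = np.dot(w, (y - my) ** 2) / wsum
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance: correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def derive_exposure(cohort: pd.DataFrame, source: str = "recalls") -> pd.DataFrame:
    """Append derived exposure columns ``cups``, ``group`` and ``income_cat``.

    ``source='recalls'`` averages the recall columns (the measurement the
    survey provides); ``source='true'`` copies the generator's latent group
    and true cups, bypassing recall measurement error (useful for estimator
    checks on synthetic data).
    """
    out = cohort.copy()
    if source == "recalls":
        out["cups"] = average_recalls(
            out["recall1_cups"].to_numpy(), out["recall2_cups"].to_numpy()
        )
        out["group"] = categorize(out["cups"].to_numpy())
    elif source == "true":
        if "true_cups" not in out.columns or "group_true" not in out.columns:
            raise ValueError("source='true' requires generator columns")
        out["cups"] = out["true_cups"]
        out["group"] = pd.Categorical(
            out["group_true"], categories=list(GROUP_LABELS), ordered=True
        )
    else:
        raise ValueError(f"unknown exposure source {source!r}")
    if "income_ratio" in out.columns:
        out["income_cat"] = code_income(out["income_ratio"].to_numpy())
    if {"activity_moderate_min", "activity_vigorous_min"} <= set(out.columns):
        out["activity_sufficient"] = code_activity(
            out["activity_moderate_min"].to_numpy(),
            out["activity_vigorous_min"].to_numpy(),
        )
    return out
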