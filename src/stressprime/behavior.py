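"""Behavioral preprocessing and the composite depression-like outcome score.

Derived measures (sucrose preference, novelty-suppressed-feeding latency
ratio), single-pass per-group outlier exclusion at 2 SD, and a composite
score: the percent of available behavioral tests on which a mouse crosses
a depression/anxiety-like criterion defined from the standard-control
group's mean ± 1 SD (or a fixed cutoff, e.g. sucrose preference < 50%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("Std-Ctl", "Std-Stress", "ELS-Ctl", "ELS-Stress")


@dataclass(frozen=True)
class CriterionRule:
    """One measure's depression-like criterion.

    ``direction`` is 'above' or 'below'; the threshold is either the
    reference group's mean ± ``sd_multiplier`` SD (when ``fixed`` is None)
    or the fixed constant.
    """

    direction: str
    fixed: float | None = None
    sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")


@dataclass(frozen=True)
class CompositeCriteria:
    """Per-measure rules plus the reference group the mean±SD rules use."""

    rules: Mapping[str, CriterionRule] = field(
        default_factory=lambda: dict(DEFAULT_RULES)
    )
    reference_group: str = "Std-Ctl"


#: the four default tests: NSF latency ratio above mean+1SD, forced-swim
#: latency to immobility below mean−1SD, sucrose preference below a fixed
#: 50%, splash-test grooming duration below mean−1SD
DEFAULT_RULES: dict[str, CriterionRule] = {
    "nsf_ratio": CriterionRule("above"),
    "fst_latency_to_immobility": CriterionRule("below"),
    "sucrose_preference_pct": CriterionRule("below", fixed=50.0),
    "grooming_duration_s": CriterionRule("below"),
}


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Percent sucrose preference: 100 × sucrose / (sucrose + water)."""
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumption must be >= 0")
    total = sucrose_g + water_g
    if total <= 0:
        raise ValueError("zero total consumption")
    return 100.0 * sucrose_g / total


def nsf_ratio(novel_latency_s: float, home_latency_s: float) -> float:
    """Latency to eat in the novel arena over home-cage latency."""
    if home_latency_s <= 0:
        raise ValueError("home-cage latency must be > 0")
    if novel_latency_s < 0:
        raise ValueError("latency must be >= 0")
    return novel_latency_s / home_latency_s


def exclude_outliers(
    values: pd.Series, groups: pd.Series, k: float = 2.0
) -> pd.Series:
    """Single-pass per-group outlier mask (True = keep).

    A value is excluded iff |value − group mean| > k × group SD, with the
    group statistics computed including the candidate.  Groups with fewer
    than 3 non-missing values are left untouched with a warning.  Missing
    values are kept (they are simply unavailable downstream).
    """
    keep = pd.Series(True, index=values.index)
    for g, idx in values.groupby(groups).groups.items():
        v = values.loc[idx]
        obs = v.dropna()
        if len(obs) < 3:
            warnings.warn(f"group {g!r}: n={len(obs)} < 3, no outlier exclusion")
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            continue
        keep.loc[idx] = ~((v - mu).abs() > k * sd).fillna(False)
    return keep


def composite_score(
    table: pd.DataFrame,
    criteria: CompositeCriteria | None = None,
    exclude: bool = True,
    outlier_k: float = 2.0,
) -> pd.DataFrame:
    """Composite behavior outcome score per mouse.

    ``table`` holds one row per mouse with a ``group`` column and one
    column per measure.  Outliers are removed per measure per group first
    (single pass), then each remaining measure is scored against its rule;
    the composite is 100 × criteria met / tests available.  Measures
    missing for a mouse reduce the denominator (a cohort may omit a test
    entirely).
    """
    criteria = criteria or CompositeCriteria()
    if "group" not in table.columns:
        raise ValueError("table needs a 'group' column")
    if criteria.reference_group not in set(table["group"]):
        raise ValueError(f"reference group {criteria.reference_group!r} absent")
    measures = [m for m in criteria.rules if m in table.columns]
    if not measures:
        raise ValueError("no criterion measure present in table")

    work = table.copy()
    if exclude:
        for m in measures:
            keep = exclude_outliers(work[m], work["group"], k=outlier_k)
            work.loc[~keep, m] = np.nan

    ref = work[work["group"] == criteria.reference_group]
    met = pd.DataFrame(index=work.index)
    for m in measures:
        rule = criteria.rules[m]
        if rule.fixed is not None:
            threshold = rule.fixed
        else:
            ref_vals = ref[m].dropna()
            if len(ref_vals) < 2:
                raise ValueError(
                    f"reference group too small for mean±SD rule on {m!r}"
                )
            mu, sd = ref_vals.mean(), ref_vals.std(ddof=1)
            threshold = mu + rule.sd_multiplier * sd if rule.direction == "above" \
                else mu - rule.sd_multiplier * sd
        v = work[m]
        flag = v > threshold if rule.direction == "above" else v < threshold
        met[m] = flag.where(v.notna())

    available = met.notna().sum(axis=1)
    if (available == 0).any():
        raise ValueError("mouse with no available test")
    n_met = met.eq(True).sum(axis=1)
    out = work[["group"]].copy()
    for m in measures:
        out[f"met_{m}"] = met[m]
    out["criteria_met"] = n_met.astype(int)
    out["tests_available"] = available.astype(int)
    out["composite_pct"] = 100.0 * n_met / available
    return out
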