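"""Primed-gene detection in the two-hit stress design.

A gene is *primed* when its expression change appears only with both hits:
in the two-hit (ELS + adult stress) group it is significantly different
from standard-control with a fold-change cutoff, and also significantly
different from each single-stress group (ELS alone, adult stress alone) in
either direction without a fold-change cutoff.  The three inputs are the
contrasts (two-hit vs Std-Ctl), (two-hit vs ELS-Ctl) and (two-hit vs
Stress-Ctl) over a shared gene universe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DETable


@dataclass(frozen=True)
class PrimedCriteria:
    """Thresholds of the three-contrast priming filter.

    The vs-standard-control leg requires both significance and fold-change
    (default |LFC| > 0.3785; 0.3875 is selectable); the two single-stress
    legs require significance only, direction-free.
    """

    p_max_vs_std: float = 0.05
    lfc_min_abs_vs_std: float = 0.3785
    p_max_vs_single: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.p_max_vs_std, self.p_max_vs_single):
            if not 0.0 < p < 1.0:
                raise ValueError(f"p threshold must be in (0,1), got {p}")
        if self.lfc_min_abs_vs_std < 0:
            raise ValueError("lfc_min_abs_vs_std must be >= 0")


PRIMED_COLUMNS = [
    "gene_id",
    "direction",
    "lfc_vs_std",
    "lfc_vs_els",
    "lfc_vs_stress",
    "p_vs_std",
    "p_vs_els",
    "p_vs_stress",
    "base_mean",
]


@dataclass
class PrimedGeneSet:
    """Genes passing the priming filter for one sex × region."""

    label: str
    members: pd.DataFrame  # PRIMED_COLUMNS; unique gene_ids

    def __post_init__(self) -> None:
        if self.members["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in primed set")

    def __len__(self) -> int:
        return len(self.members)

    def direction_map(self) -> dict[str, str]:
        return dict(zip(self.members["gene_id"], self.members["direction"]))

    def to_tsv(self, path) -> None:
        self.members.to_csv(path, sep="\t", index=False)


def _check_universe(*tables: DETable) -> None:
    universes = [set(t.gene_ids) for t in tables]
    base = universes[0]
    for t, u in zip(tables[1:], universes[1:]):
        if u != base:
            diff = sorted(base.symmetric_difference(u))
            raise ValueError(
                f"gene universes differ between {tables[0].contrast!r} and "
                f"{t.contrast!r}; symmetric difference (first 10): {diff[:10]}"
            )


def detect_primed(
    vs_std: DETable,
    vs_els: DETable,
    vs_stress: DETable,
    criteria: PrimedCriteria | None = None,
    label: str = "primed",
) -> PrimedGeneSet:
    """Apply the three-contrast priming filter.

    Primed iff p_vs_std < p_max_vs_std AND |lfc_vs_std| > lfc_min_abs_vs_std
    AND p_vs_els < p_max_vs_single AND p_vs_stress < p_max_vs_single.
    Direction is the sign of the LFC versus standard-control.
    """
    criteria = criteria or PrimedCriteria()
    _check_universe(vs_std, vs_els, vs_stress)
    std = vs_std.data.set_index("gene_id")
    els = vs_els.data.set_index("gene_id").reindex(std.index)
    stress = vs_stress.data.set_index("gene_id").reindex(std.index)

    primed = (
        (std["p_value"] < criteria.p_max_vs_std)
        & (std["lfc"].abs() > criteria.lfc_min_abs_vs_std)
        & (els["p_value"] < criteria.p_max_vs_single)
        & (stress["p_value"] < criteria.p_max_vs_single)
    )
    out = pd.DataFrame(
        {
            "gene_id": std.index[primed],
            "direction": np.where(std.loc[primed, "lfc"] > 0, "up", "down"),
            "lfc_vs_std": std.loc[primed, "lfc"].to_numpy(),
            "lfc_vs_els": els.loc[primed, "lfc"].to_numpy(),
            "lfc_vs_stress": stress.loc[primed, "lfc"].to_numpy(),
            "p_vs_std": std.loc[primed, "p_value"].to_numpy(),
            "p_vs_els": els.loc[primed, "p_value"].to_numpy(),
            "p_vs_stress": stress.loc[primed, "p_value"].to_numpy(),
            "base_mean": std.loc[primed, "base_mean"].to_numpy(),
        }
    ).sort_values("gene_id", ignore_index=True)
    return PrimedGeneSet(label=label, members=out)


def intersect_primed(sets: list[PrimedGeneSet]) -> pd.DataFrame:
    """Venn regions across primed-gene sets with direction concordance.

    Returns one row per gene per exclusive Venn region with the region
    label (``&``-joined set labels) and, for genes shared by ≥2 sets, a
    concordance flag: 'same' when the vs-standard-control direction agrees
    in every containing set, else 'opposite'.
    """
    if len(sets) < 2:
        raise ValueError("need at least two primed sets")
    dirmaps = {s.label: s.direction_map() for s in sets}
    labels = [s.label for s in sets]
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(set(dirmaps[l]) for l in combo))
            rest = [l for l in labels if l not in combo]
            outside = set().union(*(set(dirmaps[l]) for l in rest)) if rest else set()
            for g in sorted(inside - outside):
                dirs = {dirmaps[l][g] for l in combo}
                rows.append(
                    {
                        "region": "&".join(combo),
                        "n_sets": r,
                        "gene_id": g,
                        "concordance": ("same" if len(dirs) == 1 else "opposite")
                        if r >= 2
                        else "",
                    }
                )
    return pd.DataFrame(rows, columns=["region", "n_sets", "gene_id", "concordance"])


def primed_bubble_table(primed: PrimedGeneSet) -> pd.DataFrame:
    """Plot-ready table for the primed-gene bubble chart.

    Per gene: LFC vs standard-control, LFC vs ELS-control, −log10 of the
    vs-standard p-value, and log10 base mean (bubble size).  Genes with a
    zero base mean are flagged and get no size value.
    """
    m = primed.members
    zero = m["base_mean"] == 0
    return pd.DataFrame(
        {
            "gene_id": m["gene_id"],
            "lfc_vs_std": m["lfc_vs_std"],
            "lfc_vs_els": m["lfc_vs_els"],
            "neg_log10_p_vs_std": -np.log10(m["p_vs_std"]),
            "log10_base_mean": np.where(zero, np.nan, np.log10(m["base_mean"].where(~zero, 1.0))),
            "zero_base_mean": zero,
        }
    )
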