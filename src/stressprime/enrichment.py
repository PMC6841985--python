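"""Cell-type marker derivation and DEG/marker overlap enrichment.

Markers are derived from a cell-type × gene mean-expression matrix with the
stringent rule that a marker's expression in its cell type exceeds
``ratio_min`` (default 10×) times the mean background expression of the
remaining cell types.  DEG lists are then tested for marker enrichment by
the odds ratio of list overlap with a Fisher exact test, one-tailed
"greater" by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class MarkerCriteria:
    ratio_min: float = 10.0

    def __post_init__(self) -> None:
        if self.ratio_min <= 1:
            raise ValueError("ratio_min must be > 1")


@dataclass
class MarkerSet:
    cell_type: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in marker set")


@dataclass
class OverlapTest:
    """2×2 overlap test of two gene lists within a universe.

    odds_ratio = ad/bc on the table (|A∩B|, |A∖B|, |B∖A|, rest); when any
    cell is zero the Haldane +0.5 correction is applied and flagged.
    """

    overlap: int
    size_a: int
    size_b: int
    universe: int
    odds_ratio: float
    p_value: float
    haldane: bool


def derive_markers(
    expr: pd.DataFrame, criteria: MarkerCriteria | None = None
) -> list[MarkerSet]:
    """Call cell-type-specific markers from a cell-type × gene matrix.

    Gene g is a marker of cell type t iff expr(t, g) strictly exceeds
    ratio_min × mean of expr over the remaining cell types.
    """
    criteria = criteria or MarkerCriteria()
    if expr.shape[0] < 2:
        raise ValueError("need at least two cell types (background undefined)")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be >= 0")
    values = expr.to_numpy(dtype=float)
    n_types = values.shape[0]
    total = values.sum(axis=0)
    background = (total[None, :] - values) / (n_types - 1)
    is_marker = values > criteria.ratio_min * background
    out = []
    for i, cell_type in enumerate(expr.index):
        genes = [g for g, m in zip(expr.columns, is_marker[i]) if m]
        out.append(MarkerSet(cell_type=str(cell_type), gene_ids=genes))
    return out


def list_overlap_test(
    list_a: Iterable[str],
    list_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapTest:
    """Fisher exact test of the overlap between two gene lists.

    Both lists must be subsets of the universe.  ``alternative`` is
    'greater' (enrichment, default) or 'two-sided'.
    """
    sa, sb, su = set(list_a), set(list_b), set(universe)
    if not sa <= su or not sb <= su:
        stray = sorted((sa | sb) - su)
        raise ValueError(f"gene(s) outside universe: {stray[:10]}")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(su) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    haldane = (table == 0).any()
    t = table + (0.5 if haldane else 0.0)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapTest(
        overlap=a,
        size_a=len(sa),
        size_b=len(sb),
        universe=len(su),
        odds_ratio=float(odds),
        p_value=float(min(p, 1.0)),
        haldane=bool(haldane),
    )


def enrich_degs_by_celltype(
    deg_sets: Mapping[str, Iterable[str]],
    markers: list[MarkerSet],
    universe: Iterable[str],
    alternative: str = "greater",
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """All DEG set × cell type overlap tests, multiplicity-adjusted.

    Returns a long frame (deg_set, cell_type, overlap, odds_ratio, p_value,
    p_adjusted) with the adjustment applied across the whole matrix.
    """
    su = set(universe)
    rows = []
    for name, degs in deg_sets.items():
        degs = set(degs) & su
        for m in markers:
            marker_genes = set(m.gene_ids) & su
            t = list_overlap_test(degs, marker_genes, su, alternative=alternative)
            rows.append(
                {
                    "deg_set": name,
                    "cell_type": m.cell_type,
                    "overlap": t.overlap,
                    "size_degs": t.size_a,
                    "size_markers": t.size_b,
                    "odds_ratio": t.odds_ratio,
                    "p_value": t.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out


def read_marker_lists(path) -> list[MarkerSet]:
    """Read a TSV (cell_type, gene_id) into marker sets."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene_id"}.issubset(df.columns):
        raise ValueError(f"{path}: needs cell_type and gene_id columns")
    return [
        MarkerSet(cell_type=str(ct), gene_ids=sub["gene_id"].tolist())
        for ct, sub in df.groupby("cell_type", sort=True)
    ]
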