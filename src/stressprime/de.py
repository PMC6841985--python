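"""Differential-expression tables: I/O, DEG thresholding, union LFC matrices,
hierarchical clustering and overlap statistics.

The per-contrast DE table (gene id, base mean expression, log2 fold-change,
unadjusted p-value) is the universal input currency of every downstream
analysis in this package.  Tables are produced upstream by any DE engine
(DESeq2 in the original study, :func:`stressprime.simulate.simple_de` for
synthetic data); this module only consumes them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: DESeq2-style column names used when no dialect mapping is given.
DEFAULT_DIALECT: dict[str, str] = {
    "gene_id": "gene",
    "base_mean": "baseMean",
    "lfc": "log2FoldChange",
    "p_value": "pvalue",
}

REQUIRED_COLUMNS = ("gene_id", "base_mean", "lfc", "p_value")


class DETableError(ValueError):
    """Raised when a DE table violates its invariants."""


@dataclass(frozen=True)
class SignificanceCriteria:
    """Thresholds defining a differentially expressed gene.

    Defaults follow the uncorrected-p criterion used for broad pattern
    identification: p < 0.05, |LFC| > 0.3785 (a fold-change of 30%), and a
    mean normalized count above 2.  All inequalities are strict.  The
    alternative LFC cutoff 0.3875 that appears in some descriptions of the
    same filter is accepted via ``lfc_min_abs``.
    """

    p_max: float = 0.05
    lfc_min_abs: float = 0.3785
    base_mean_min: float = 2.0
    protein_coding_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max < 1.0:
            raise ValueError(f"p_max must be in (0,1), got {self.p_max}")
        if self.lfc_min_abs < 0:
            raise ValueError("lfc_min_abs must be >= 0")
        if self.base_mean_min < 0:
            raise ValueError("base_mean_min must be >= 0")


@dataclass
class DETable:
    """One contrast's per-gene DE results.

    ``data`` holds columns ``gene_id``, ``base_mean``, ``lfc``, ``p_value``
    with unique, nonempty gene ids; base_mean >= 0; p in (0, 1]; finite LFC.
    """

    contrast: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DETableError(f"DE table missing columns: {missing}")
        if len(df) == 0:
            raise DETableError("DE table is empty")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise DETableError(
                f"duplicate gene_id in contrast {self.contrast!r}: "
                f"{sorted(set(dup))[:10]}"
            )
        if (df["gene_id"].astype(str).str.len() == 0).any():
            raise DETableError("empty gene_id")
        if (df["base_mean"] < 0).any():
            raise DETableError("base_mean must be >= 0")
        bad_p = (df["p_value"] <= 0) | (df["p_value"] > 1)
        if bad_p.any():
            raise DETableError(
                f"p_value outside (0,1] for genes "
                f"{df.loc[bad_p, 'gene_id'].tolist()[:10]}"
            )
        if not np.isfinite(df["lfc"]).all():
            raise DETableError("non-finite lfc")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Series:
        return self.data["gene_id"]

    def lfc_by_gene(self) -> pd.Series:
        return self.data.set_index("gene_id")["lfc"]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_de_table(
    path,
    dialect: Mapping[str, str] | None = None,
    contrast: str | None = None,
) -> DETable:
    """Read a TSV/CSV DE table, mapping columns via ``dialect``.

    ``dialect`` maps canonical names (gene_id, base_mean, lfc, p_value) to
    the file's column names; defaults to DESeq2-style names.  Rows with
    missing LFC or p, or with p outside (0, 1], are dropped with a logged
    count.  Duplicate gene ids are an error.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in mapping.values() if v not in raw.columns]
    if missing and dialect is None and set(REQUIRED_COLUMNS) <= set(raw.columns):
        # the package's own canonical header is accepted without a dialect
        mapping = {c: c for c in REQUIRED_COLUMNS}
        missing = []
    if missing:
        raise DETableError(f"{path}: missing required column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in mapping.items()})
    df = df[list(REQUIRED_COLUMNS)].copy()
    for col in ("base_mean", "lfc", "p_value"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    n0 = len(df)
    df = df.dropna(subset=["lfc", "p_value"])
    df = df[(df["p_value"] > 0) & (df["p_value"] <= 1)]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing/invalid p or LFC", path, n_dropped)
    return DETable(contrast=contrast or str(path), data=df)


def filter_degs(
    table: DETable,
    criteria: SignificanceCriteria | None = None,
    annotation: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the DEG significance filter to one contrast.

    A gene is a DEG iff p < p_max AND |LFC| > lfc_min_abs AND
    base_mean > base_mean_min (all strict), and — when
    ``protein_coding_only`` is set — its biotype is ``protein_coding`` in
    ``annotation``.  Returns a frame with gene_id, lfc, p_value, base_mean
    and direction ('up'/'down' from the sign of LFC).
    """
    criteria = criteria or SignificanceCriteria()
    df = table.data
    keep = (
        (df["p_value"] < criteria.p_max)
        & (df["lfc"].abs() > criteria.lfc_min_abs)
        & (df["base_mean"] > criteria.base_mean_min)
    )
    if criteria.protein_coding_only:
        if annotation is None:
            raise ValueError("protein_coding_only requires a gene annotation")
        unknown = [g for g in df["gene_id"] if g not in annotation]
        if unknown:
            raise KeyError(
                f"annotation missing biotype for {len(unknown)} gene(s), "
                f"e.g. {unknown[:5]}"
            )
        keep &= df["gene_id"].map(annotation).eq("protein_coding")
    out = df.loc[keep, ["gene_id", "lfc", "p_value", "base_mean"]].copy()
    out["direction"] = np.where(out["lfc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def deg_direction_map(degs: pd.DataFrame) -> dict[str, str]:
    """gene_id -> 'up'/'down' from a :func:`filter_degs` frame."""
    return dict(zip(degs["gene_id"], degs["direction"]))


def lfc_to_percent_fc(lfc_threshold: float) -> float:
    """Convert a log2 fold-change threshold to a percent fold-change.

    0.3785 -> 30.006..., i.e. an LFC cutoff of 0.3785 corresponds to a
    fold-change of 30%.
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    return (2.0 ** lfc_threshold - 1.0) * 100.0


def percent_fc_to_lfc(percent: float) -> float:
    """Inverse of :func:`lfc_to_percent_fc`."""
    if percent < 0:
        raise ValueError("percent must be >= 0")
    return float(np.log2(1.0 + percent / 100.0))


def union_lfc_matrix(
    tables: Sequence[DETable],
    deg_sets: Sequence[Iterable[str]],
) -> pd.DataFrame:
    """LFC matrix over the union of DEG sets, one column per contrast.

    Rows are the union of all genes in ``deg_sets``; entries are each
    contrast's LFC for that gene regardless of significance there.  A union
    gene absent from any table is a hard error (fold-changes are never
    imputed).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    union: list[str] = []
    seen: set[str] = set()
    for degs in deg_sets:
        for g in degs:
            if g not in seen:
                seen.add(g)
                union.append(g)
    cols = {}
    for t in tables:
        lfc = t.lfc_by_gene()
        absent = [g for g in union if g not in lfc.index]
        if absent:
            raise KeyError(
                f"gene(s) {absent[:10]} missing from contrast {t.contrast!r}"
            )
        cols[t.contrast] = lfc.reindex(union)
    return pd.DataFrame(cols, index=pd.Index(union, name="gene_id"))


@dataclass
class ClusterResult:
    """Average-linkage clustering of an LFC matrix on 1 − Pearson distance."""

    row_order: list[str]
    #: scipy linkage matrix; column 2 holds nondecreasing merge heights.
    merge_table: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merge_table[:, 2]


def cluster_rows(matrix: pd.DataFrame) -> ClusterResult:
    """Cluster matrix rows by 1 − Pearson correlation, average linkage.

    Rows are canonicalized to lexicographic gene_id order before
    agglomeration so the result is invariant to input row order and
    height ties break deterministically.  Zero-variance rows make the
    Pearson correlation undefined and are an error.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    m = matrix.sort_index()
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = m.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance row(s), Pearson undefined: {flat[:10]}")
    dist = 1.0 - np.corrcoef(values)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(row_order=[m.index[i] for i in leaves], merge_table=z)


@dataclass
class OverlapReport:
    """Venn-region counts and pairwise/triple percent overlaps of DEG sets."""

    set_sizes: dict[str, int]
    #: exclusive Venn region -> sorted gene list, keyed by frozenset of names
    regions: dict[frozenset, list[str]]
    #: per name combination: intersection, union, percent overlaps
    overlaps: pd.DataFrame

    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}


def deg_overlap(named_sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """All Venn-region gene lists plus percent overlap per pair/triple.

    Two percent definitions are emitted for each combination:
    ``pct_of_union`` = 100·|∩|/|∪| and ``pct_of_smaller`` = 100·|∩|/min size.
    """
    sets = {name: set(genes) for name, genes in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    regions: dict[frozenset, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = sorted(inside - outside)
    rows = []
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            union = set.union(*(sets[n] for n in combo))
            smaller = min(len(sets[n]) for n in combo)
            rows.append(
                {
                    "sets": "&".join(combo),
                    "intersection": len(inter),
                    "union": len(union),
                    "pct_of_union": 100.0 * len(inter) / len(union) if union else 0.0,
                    "pct_of_smaller": 100.0 * len(inter) / smaller if smaller else 0.0,
                }
            )
    return OverlapReport(
        set_sizes={n: len(s) for n, s in sets.items()},
        regions=regions,
        overlaps=pd.DataFrame(rows),
    )


def read_gene_annotation(path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, biotype) into a lookup dict."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "biotype"}.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs gene_id and biotype columns")
    return dict(zip(df["gene_id"], df["biotype"]))
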