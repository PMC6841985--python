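"""Two-sided rank–rank hypergeometric overlap (RRHO) and difference maps.

RRHO compares two differential-expression comparisons without thresholds.
Each gene list is scored by −log10(p) × sign(LFC), split at zero into an
up- and a down-regulated sublist, and for every pair of rank thresholds
(multiples of a step) the overlap between the top genes of each sublist is
tested with a hypergeometric tail probability against the shared gene
universe.  The four sublist pairings form quadrants: co-up and co-down
capture concordant regulation (signed positive), up-down and down-up
capture discordant regulation (signed negative).

A difference map contrasts two congruent RRHO grids pixel by pixel via the
normal approximation of the difference in overlap log odds ratios, giving a
Z score, p-value, and multiplicity-adjusted p per pixel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import DETable

logger = logging.getLogger(__name__)

#: cap on −log10(p) to avoid floating-point infinities
NEGLOG10_CAP = 320.0

#: (a sublist, b sublist, quadrant name, sign of the pixel values)
QUADRANTS = (
    ("up", "up", "co-up", 1),
    ("down", "down", "co-down", 1),
    ("up", "down", "up-down", -1),
    ("down", "up", "down-up", -1),
)


@dataclass
class RankedList:
    """Genes sorted descending by signed significance score.

    score = −log10(p_value) × sign(lfc); genes with base mean expression at
    or below ``min_base_mean`` are removed to avoid low-expression
    artifacts.  Ties break by ascending gene_id for determinism.
    """

    name: str
    frame: pd.DataFrame  # columns gene_id, score, lfc, p_value
    min_base_mean: float = 2.0

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise ValueError(f"ranked list {self.name!r} is empty")
        if self.frame["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in ranked list")
        if not (np.diff(self.frame["score"].to_numpy()) <= 0).all():
            raise ValueError("scores not sorted descending")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.frame["gene_id"].to_numpy()

    def restricted(self, genes: set) -> "RankedList":
        keep = self.frame["gene_id"].isin(genes)
        return RankedList(self.name, self.frame[keep].reset_index(drop=True), self.min_base_mean)

    def sublist(self, which: str) -> np.ndarray:
        """Gene ids of the up (score>0) or down (score<0) sublist, most
        extreme first."""
        s = self.frame["score"].to_numpy()
        if which == "up":
            return self.frame["gene_id"].to_numpy()[s > 0]
        if which == "down":
            return self.frame["gene_id"].to_numpy()[s < 0][::-1]
        raise ValueError(which)


def signed_rank_scores(table: DETable, min_base_mean: float = 2.0) -> RankedList:
    """Build the signed −log10(p) ranking for one DE comparison."""
    df = table.data
    keep = df["base_mean"] > min_base_mean
    if not keep.any():
        raise ValueError(
            f"no genes with base_mean > {min_base_mean} in {table.contrast!r}"
        )
    sub = df[keep].copy()
    sub["score"] = -np.log10(sub["p_value"]) * np.sign(sub["lfc"])
    sub = sub.sort_values(
        ["score", "gene_id"], ascending=[False, True], ignore_index=True
    )
    return RankedList(
        name=table.contrast,
        frame=sub[["gene_id", "score", "lfc", "p_value"]],
        min_base_mean=min_base_mean,
    )


@dataclass
class QuadrantGrid:
    """One quadrant's pixel matrices at rank thresholds (i·step, j·step)."""

    name: str
    sign: int
    thresholds_a: np.ndarray  # rank cutoffs into list A's sublist
    thresholds_b: np.ndarray
    counts: np.ndarray  # observed overlap, shape (len(ta), len(tb))
    expected: np.ndarray
    p_values: np.ndarray
    signed_neglogp: np.ndarray


@dataclass
class RRHOGrid:
    """Two-sided RRHO result: four quadrant grids over a shared universe."""

    list_a: str
    list_b: str
    step: int
    n_universe: int
    sublist_sizes: dict  # (list, 'up'/'down') -> size
    quadrants: dict[str, QuadrantGrid] = field(default_factory=dict)

    def max_pixel(self) -> tuple[str, int, int, float]:
        """(quadrant, i, j, signed value) of the largest |signed −log10 p|."""
        best = None
        for q in self.quadrants.values():
            if q.signed_neglogp.size == 0:
                continue
            idx = np.unravel_index(np.argmax(np.abs(q.signed_neglogp)), q.signed_neglogp.shape)
            val = q.signed_neglogp[idx]
            if best is None or abs(val) > abs(best[3]):
                best = (q.name, int(idx[0]), int(idx[1]), float(val))
        if best is None:
            raise ValueError("all quadrants empty")
        return best

    def assembled_signed_map(self) -> np.ndarray:
        """Single signed −log10(p) matrix in the standard panel layout.

        Rows are list A, columns list B; the most significant genes of each
        sublist sit at the centre, so co-up fills the lower-left quadrant
        and co-down the upper-right, with discordant quadrants off-diagonal.
        Rows/columns absent because a sublist was shorter than one step
        contribute nothing.
        """
        g = self.quadrants
        tl = g["down-up"].signed_neglogp[::-1, ::-1]
        tr = g["co-down"].signed_neglogp[::-1, :]
        bl = g["co-up"].signed_neglogp[:, ::-1]
        br = g["up-down"].signed_neglogp
        top = np.hstack([tl, tr]) if tl.size or tr.size else np.empty((0, 0))
        bottom = np.hstack([bl, br]) if bl.size or br.size else np.empty((0, 0))
        return np.vstack([top, bottom])


def _hypergeom_sf(counts: np.ndarray, n_universe: int, ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """P(X >= observed overlap) drawing tb from n_universe with ta marked."""
    return stats.hypergeom.sf(
        counts - 1, n_universe, ta[:, None], tb[None, :]
    )


def _quadrant_grid(
    name: str,
    sign: int,
    genes_a: np.ndarray,
    genes_b: np.ndarray,
    step: int,
    n_universe: int,
) -> QuadrantGrid:
    na, nb = len(genes_a), len(genes_b)
    da, db = na // step, nb // step
    if da == 0 or db == 0:
        warnings.warn(
            f"quadrant {name}: sublist shorter than step ({na}x{nb} vs step {step}); "
            "empty grid",
            stacklevel=3,
        )
        empty = np.empty((da, db))
        ta = (np.arange(da) + 1) * step
        tb = (np.arange(db) + 1) * step
        return QuadrantGrid(name, sign, ta, tb, empty.copy(), empty.copy(), empty.copy(), empty.copy())
    ta = (np.arange(da) + 1) * step
    tb = (np.arange(db) + 1) * step
    pos_b = {g: r for r, g in enumerate(genes_b)}
    ra, rb = [], []
    for r, g in enumerate(genes_a):
        if r >= da * step:
            break
        p = pos_b.get(g)
        if p is not None and p < db * step:
            ra.append(r)
            rb.append(p)
    hist, _, _ = np.histogram2d(
        np.asarray(ra, dtype=float),
        np.asarray(rb, dtype=float),
        bins=[np.arange(0, (da + 1) * step, step), np.arange(0, (db + 1) * step, step)],
    )
    counts = hist.cumsum(axis=0).cumsum(axis=1)
    expected = np.outer(ta, tb) / n_universe
    p = _hypergeom_sf(counts, n_universe, ta, tb)
    neglogp = np.clip(-np.log10(np.maximum(p, 10.0 ** -NEGLOG10_CAP)), 0.0, NEGLOG10_CAP)
    return QuadrantGrid(name, sign, ta, tb, counts, expected, p, sign * neglogp)


def rrho_two_sided(a: RankedList, b: RankedList, step: int | None = None) -> RRHOGrid:
    """Two-sided RRHO between two ranked lists.

    The gene universe is the intersection of the two filtered lists (its
    size logged); each list is split at score zero, and every quadrant's
    overlap counts are tested against the hypergeometric tail P(X ≥ k)
    with that shared universe size.  ``step`` defaults to
    max(1, N // 100).
    """
    common = set(a.gene_ids) & set(b.gene_ids)
    if not common:
        raise ValueError("ranked lists share no genes")
    n_universe = len(common)
    if n_universe < max(len(a), len(b)):
        logger.info(
            "RRHO universe restricted to %d shared genes (from %d / %d)",
            n_universe, len(a), len(b),
        )
    a_r, b_r = a.restricted(common), b.restricted(common)
    if step is None:
        step = max(1, n_universe // 100)
    if step < 1:
        raise ValueError("step must be a positive integer")
    sub = {
        ("a", "up"): a_r.sublist("up"),
        ("a", "down"): a_r.sublist("down"),
        ("b", "up"): b_r.sublist("up"),
        ("b", "down"): b_r.sublist("down"),
    }
    grid = RRHOGrid(
        list_a=a.name,
        list_b=b.name,
        step=int(step),
        n_universe=n_universe,
        sublist_sizes={k: len(v) for k, v in sub.items()},
    )
    for side_a, side_b, name, sign in QUADRANTS:
        grid.quadrants[name] = _quadrant_grid(
            name, sign, sub[("a", side_a)], sub[("b", side_b)], int(step), n_universe
        )
    return grid


@dataclass
class QuadrantDiff:
    """Per-pixel log-odds-ratio difference between two congruent quadrants."""

    name: str
    logor_diff: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray


@dataclass
class RRHODiffGrid:
    """Pixelwise Z-test of overlap log-odds differences between two maps."""

    step: int
    n_universe: int
    method: str
    quadrants: dict[str, QuadrantDiff] = field(default_factory=dict)


def _log_odds(counts: np.ndarray, ta: np.ndarray, tb: np.ndarray, n: int):
    """logOR and SE of each pixel's 2×2 overlap table.

    Table cells: overlap, listA-only, listB-only, neither.  Any zero cell
    triggers the Haldane–Anscombe +0.5 correction on all four cells of that
    pixel's table.
    """
    a = counts
    b = ta[:, None] - a
    c = tb[None, :] - a
    d = n - ta[:, None] - tb[None, :] + a
    cells = np.stack([a, b, c, d])
    zero = (cells == 0).any(axis=0)
    cells = cells + np.where(zero, 0.5, 0.0)
    logor = np.log(cells[0]) + np.log(cells[3]) - np.log(cells[1]) - np.log(cells[2])
    se = np.sqrt((1.0 / cells).sum(axis=0))
    return logor, se


def rrho_difference(
    g1: RRHOGrid, g2: RRHOGrid, method: str = "fdr_bh"
) -> RRHODiffGrid:
    """Difference map between two congruent RRHO grids.

    Per pixel: Z = (logOR₁ − logOR₂) / sqrt(SE₁² + SE₂²) with the standard
    asymptotic SE (square root of the summed reciprocal cell counts of the
    2×2 overlap table), two-sided normal p, and adjustment across all
    pixels of the map (Benjamini–Hochberg by default, ``method='bonferroni'``
    available).
    """
    if g1.step != g2.step or g1.n_universe != g2.n_universe:
        raise ValueError(
            f"grids not congruent: step {g1.step}/{g2.step}, "
            f"N {g1.n_universe}/{g2.n_universe}"
        )
    flat_p: list[np.ndarray] = []
    partial: dict[str, tuple] = {}
    for name in g1.quadrants:
        q1, q2 = g1.quadrants[name], g2.quadrants[name]
        if q1.counts.shape != q2.counts.shape:
            raise ValueError(f"quadrant {name}: shapes differ")
        if q1.counts.size == 0:
            partial[name] = (np.empty(q1.counts.shape),) * 4
            continue
        l1, s1 = _log_odds(q1.counts, q1.thresholds_a, q1.thresholds_b, g1.n_universe)
        l2, s2 = _log_odds(q2.counts, q2.thresholds_a, q2.thresholds_b, g2.n_universe)
        diff = l1 - l2
        se = np.sqrt(s1**2 + s2**2)
        z = diff / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        partial[name] = (diff, se, z, p)
        flat_p.append(p.ravel())
    if flat_p:
        allp = np.concatenate(flat_p)
        adj = multipletests(allp, method=method)[1]
    else:
        adj = np.empty(0)
    out = RRHODiffGrid(step=g1.step, n_universe=g1.n_universe, method=method)
    pos = 0
    for name, (diff, se, z, p) in partial.items():
        k = p.size
        padj = adj[pos : pos + k].reshape(p.shape) if k else np.empty(p.shape)
        pos += k
        out.quadrants[name] = QuadrantDiff(name, diff, se, z, p, padj)
    return out


def grid_to_frames(grid: RRHOGrid) -> dict[str, pd.DataFrame]:
    """Quadrant signed −log10(p) matrices as DataFrames (TSV-ready)."""
    out = {}
    for name, q in grid.quadrants.items():
        out[name] = pd.DataFrame(
            q.signed_neglogp,
            index=pd.Index(q.thresholds_a, name="rank_a"),
            columns=q.thresholds_b,
        )
    return out
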