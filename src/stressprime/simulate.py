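"""Synthetic data with the statistical structure the analyses assume.

The generator emulates a 2×2 two-hit stress design — early-life stress
(ELS) crossed with adult stress — with planted gene classes:

* ``null``: no effect anywhere;
* ``els_persistent``: shifted in both ELS groups (an early-life effect
  that persists regardless of adult stress);
* ``stress_responsive``: shifted in both adult-stress groups;
* ``primed`` / ``primed_opposite``: shifted (±δ) only in the two-hit
  ELS-Stress group — the latent pattern the priming filter detects.

Log2 expression is Normal(μ_g + β, σ²) per sample; a Welch t-test per gene
stands in for the DE engine since downstream modules consume only
(lfc, p, base mean).  Ground truth is emitted for parameter-recovery
tests.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import GROUPS
from .de import DETable
from .signature import Signature, StressProfile

CLASSES = ("null", "els_persistent", "stress_responsive", "primed", "primed_opposite")

DEFAULT_PROPORTIONS: dict[str, float] = {
    "null": 0.80,
    "els_persistent": 0.05,
    "stress_responsive": 0.05,
    "primed": 0.05,
    "primed_opposite": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Expression-simulation parameters.

    δ (``delta``) is the planted log2 effect magnitude, σ the residual
    log2-scale noise; baseline log2 abundance μ_g ~ Normal(baseline_mean,
    baseline_sd) so that nearly all genes clear the base-mean > 2 filter.
    """

    n_genes: int = 5_000
    n_per_group: int = 6
    delta: float = 1.0
    sigma: float = 0.5
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.proportions) != set(CLASSES):
            raise ValueError(f"proportions must cover classes {CLASSES}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_per_group < 3:
            raise ValueError("need >= 3 samples per group")


def _class_effects(cls: str, delta: float) -> dict[str, float]:
    """True per-group log2 shift β for one gene class."""
    beta = dict.fromkeys(GROUPS, 0.0)
    if cls == "els_persistent":
        beta["ELS-Ctl"] = beta["ELS-Stress"] = delta
    elif cls == "stress_responsive":
        beta["Std-Stress"] = beta["ELS-Stress"] = delta
    elif cls == "primed":
        beta["ELS-Stress"] = delta
    elif cls == "primed_opposite":
        beta["ELS-Stress"] = -delta
    return beta


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the four-group log2 expression matrix with ground truth.

    Returns ``(expr, truth)``: ``expr`` is gene × sample (columns named
    ``<group>_<replicate>``), ``truth`` records each gene's class and true
    per-group shift.
    """
    rng = np.random.default_rng(config.seed)
    classes = rng.choice(
        CLASSES, size=config.n_genes, p=[config.proportions[c] for c in CLASSES]
    )
    width = len(str(config.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    beta = np.zeros((config.n_genes, len(GROUPS)))
    for gi, cls in enumerate(classes):
        eff = _class_effects(cls, config.delta)
        beta[gi] = [eff[g] for g in GROUPS]

    cols, blocks = [], []
    for gj, group in enumerate(GROUPS):
        noise = rng.normal(0.0, config.sigma, size=(config.n_genes, config.n_per_group))
        blocks.append(mu[:, None] + beta[:, [gj]] + noise)
        cols.extend(f"{group}_{r + 1}" for r in range(config.n_per_group))
    expr = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene_id"), columns=cols
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "gene_class": classes}
    )
    for gj, group in enumerate(GROUPS):
        truth[f"beta_{group}"] = beta[:, gj]
    return expr, truth


def sample_groups(expr: pd.DataFrame) -> pd.Series:
    """Group label per sample column (from the ``<group>_<rep>`` names)."""
    return pd.Series(
        {c: c.rsplit("_", 1)[0] for c in expr.columns}, name="group"
    )


def simple_de(expr: pd.DataFrame, case_group: str, ref_group: str) -> DETable:
    """Per-gene Welch t-test between two groups of a simulated matrix.

    lfc = case mean − ref mean on the log2 scale; base_mean = mean of 2^y
    across both groups' samples; degenerate-variance genes get p = 1.
    """
    groups = sample_groups(expr)
    case_cols = groups.index[groups == case_group]
    ref_cols = groups.index[groups == ref_group]
    for name, cols in ((case_group, case_cols), (ref_group, ref_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} absent or has fewer than 2 samples")
    case = expr[case_cols].to_numpy()
    ref = expr[ref_cols].to_numpy()
    lfc = case.mean(axis=1) - ref.mean(axis=1)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # constant genes trigger a precision-loss warning; they get p = 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(case, ref, axis=1, equal_var=False)
    p = np.asarray(t.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    base_mean = (2.0 ** np.hstack([case, ref])).mean(axis=1)
    return DETable(
        contrast=f"{case_group}_vs_{ref_group}",
        data=pd.DataFrame(
            {
                "gene_id": expr.index,
                "base_mean": base_mean,
                "lfc": lfc,
                "p_value": p,
            }
        ),
    )


def nb_counts_from_log2(
    expr: pd.DataFrame, dispersion: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Optional negative-binomial count emitter for realism.

    Treats 2^y as the NB mean with a gene-wise dispersion; no downstream
    module requires counts, this exists for interoperability with
    count-based DE engines.
    """
    rng = np.random.default_rng(seed)
    mean = 2.0 ** expr.to_numpy()
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=expr.index, columns=expr.columns)


def simulate_ranked_pair(
    n_genes: int = 2_000,
    rho: float = 0.5,
    seed: int = 0,
    effect_sd: float = 0.5,
    obs_se: float = 0.25,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
) -> tuple[DETable, DETable]:
    """Pair of DE tables whose signed rankings correlate with strength ρ.

    Latent per-gene effects are bivariate normal with correlation ρ and
    standard deviation ``effect_sd``; each table observes its latent effect
    plus Normal(0, obs_se) noise, and the p-value comes from the implied
    z statistic obs/obs_se.  ρ = 0 gives null RRHO concordance, ρ < 0
    discordant regulation.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    cov = effect_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    base_mean = 2.0 ** rng.normal(baseline_mean, baseline_sd, size=n_genes)
    tables = []
    for k, label in enumerate(("list_a", "list_b")):
        obs = latent[:, k] + rng.normal(0.0, obs_se, size=n_genes)
        z = obs / obs_se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        tables.append(
            DETable(
                contrast=label,
                data=pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "base_mean": base_mean,
                        "lfc": obs,
                        "p_value": p,
                    }
                ),
            )
        )
    return tables[0], tables[1]


def simulate_signature_profile(
    sig: Signature,
    concordance: float = 0.5,
    noise_sd: float = 0.2,
    n_background: int = 1_000,
    seed: int = 0,
    name: str | None = None,
) -> StressProfile:
    """Profile with controlled concordance to a signature.

    logFC = concordance × (+1 on signature-up genes, −1 on down genes)
    plus Normal(0, noise_sd) everywhere; background genes are pure noise.
    """
    if not -1.0 <= concordance <= 1.0:
        raise ValueError("|concordance| must be <= 1")
    rng = np.random.default_rng(seed)
    up = sorted(sig.up_genes)
    down = sorted(sig.down_genes)
    width = len(str(max(n_background, 1)))
    bg = [f"bg{i:0{width}d}" for i in range(n_background)]
    genes = up + down + bg
    signal = np.concatenate(
        [
            np.full(len(up), concordance),
            np.full(len(down), -concordance),
            np.zeros(n_background),
        ]
    )
    logfc = signal + rng.normal(0.0, noise_sd, size=len(genes))
    return StressProfile(
        name=name or f"sim_concordance_{concordance:+.2f}",
        logfc=pd.Series(logfc, index=pd.Index(genes, name="gene_id")),
    )


#: depression-like direction and realistic baseline (mean, sd) per measure
BEHAVIOR_BASELINES: dict[str, tuple[float, float, int]] = {
    # measure: (control mean, control sd, +1 if depression-like is higher)
    "nsf_ratio": (1.5, 0.5, +1),
    "fst_latency_to_immobility": (60.0, 15.0, -1),
    "sucrose_preference_pct": (75.0, 10.0, -1),
    "grooming_duration_s": (100.0, 25.0, -1),
}


def simulate_behavior_cohort(
    n_per_group: int = 12,
    effects: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-group behavioral cohort with planted two-hit effects.

    ``effects`` maps measure → shift in control-SD units applied to the
    ELS-Stress group in the depression-like direction (default 1.5 SD on
    every measure except sucrose preference, mirroring a two-hit phenotype
    carried by three of the four tests).
    """
    if n_per_group < 3:
        raise ValueError("need >= 3 mice per group")
    if effects is None:
        effects = {
            "nsf_ratio": 1.5,
            "fst_latency_to_immobility": 1.5,
            "sucrose_preference_pct": 0.0,
            "grooming_duration_s": 1.5,
        }
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        for r in range(n_per_group):
            row = {"mouse_id": f"{group}_{r + 1}", "group": group}
            for measure, (mu, sd, sign) in BEHAVIOR_BASELINES.items():
                shift = sign * effects.get(measure, 0.0) * sd if group == "ELS-Stress" else 0.0
                row[measure] = rng.normal(mu + shift, sd)
            rows.append(row)
    df = pd.DataFrame(rows)
    df["sucrose_preference_pct"] = df["sucrose_preference_pct"].clip(0.0, 100.0)
    return df
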