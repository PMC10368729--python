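"""Simulation of gene-level de novo variant datasets with known ground truth.

Two scenarios, mirroring the generative mixture model end to end:

* **Bulk scenario** — a fixed fraction of genes (default 3.7%) are risk
  genes; risk genes draw their scalar expression-rank covariate from the
  normalised sigmoid density (inverse-CDF sampling) and their counts from the
  Gamma-Poisson with true relative risks (defaults: LGD 20, Dmis 12);
  non-risk genes draw the covariate uniformly and counts from the Poisson
  background.  Per-gene mutation rates come from a truncated log-normal
  synthesizer (or a supplied rate table) and are scaled by ``2 * n_trios``.

* **Single-cell scenario** — a non-linear map from a cell-type
  fraction-expressing matrix to the risk prior is constructed from labelled
  genes: SVD of the labelled submatrix, projection onto the components
  explaining >= 95% of variance, elastic-net logistic regression, and the
  predicted probabilities squared then scaled to a target mean prior
  (default 3.2%).  Risk genes are sampled once from this prior and held fixed
  across replicates; counts are redrawn per replicate.  A labelled subset
  (~100 risk / ~300 non-risk) is emitted for semi-supervised training and
  excluded from evaluation.

All randomness flows from the config seed; identical configs give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV

from .bulk_model import SigmoidPrior
from .sc_model import LabelSet

__all__ = [
    "BulkScenarioConfig",
    "ScScenarioConfig",
    "SimulatedDataset",
    "synthesize_mutation_rates",
    "simulate_bulk_scenario",
    "synthesize_expression_matrix",
    "build_sc_prior",
    "simulate_sc_scenario",
]


@dataclass(frozen=True)
class BulkScenarioConfig:
    """Truth settings of the bulk simulation study."""

    n_genes: int = 18_000
    risk_fraction: float = 0.037
    gamma_true: Dict[str, float] = field(
        default_factory=lambda: {"LGD": 20.0, "Dmis": 12.0}
    )
    beta_true: Dict[str, float] = field(
        default_factory=lambda: {"LGD": 0.84, "Dmis": 0.90}
    )
    sigmoid_true: Tuple[float, float, float] = (104.15, 0.74, 0.28)  # (A, B, C)
    cohort_sizes: Tuple[int, ...] = (2645, 5000, 10_000, 20_000)
    n_replicates: int = 1
    seed: int = 0
    # log10 mutation-rate synthesizer: Normal(mu, sd) truncated to [lo, hi]
    log10_mu_mean: float = -5.8
    log10_mu_sd: float = 0.6
    log10_mu_range: Tuple[float, float] = (-8.0, -3.5)
    rate_table: Optional[pd.DataFrame] = None  # columns gene, mu_<class>

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_fraction < 1.0:
            raise ValueError("risk_fraction must lie in (0, 1)")
        if any(n <= 0 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        A, B, C = self.sigmoid_true
        SigmoidPrior(0.5, A, B, C)  # validates sigmoid parameters


@dataclass
class SimulatedDataset:
    """One simulated cohort: gene table plus the generating truth."""

    genes: pd.DataFrame          # gene, d_<class>, M_<class>, x (bulk only)
    y_true: np.ndarray           # binary risk indicators
    pi_true: np.ndarray          # per-gene generating prior
    truth: Dict[str, object]     # parameter values used
    cohort_size: int
    replicate: int
    labels: Optional[LabelSet] = None  # sc scenario: semi-supervision subset


def synthesize_mutation_rates(
    n_genes: int,
    classes: Sequence[str],
    rng: np.random.Generator,
    log10_mean: float = -5.8,
    log10_sd: float = 0.6,
    log10_range: Tuple[float, float] = (-8.0, -3.5),
) -> Dict[str, np.ndarray]:
    """Per-gene per-class mutation rates from a truncated log10-normal."""
    lo, hi = log10_range
    rates = {}
    for v in classes:
        z = rng.normal(log10_mean, log10_sd, size=n_genes)
        # redraw out-of-range values (truncation, not clipping)
        bad = (z < lo) | (z > hi)
        while np.any(bad):
            z[bad] = rng.normal(log10_mean, log10_sd, size=bad.sum())
            bad = (z < lo) | (z > hi)
        rates[v] = 10.0 ** z
    return rates


def _sample_sigmoid_covariate(
    n: int, prior: SigmoidPrior, rng: np.random.Generator, grid: int = 10_001
) -> np.ndarray:
    """Inverse-CDF draws from the normalised sigmoid density on [0, 1]."""
    xs = np.linspace(0.0, 1.0, grid)
    cdf = prior.cdf(xs)
    cdf = cdf / cdf[-1]  # guard rounding at the right edge
    u = rng.uniform(size=n)
    return np.interp(u, cdf, xs)


def _draw_counts(
    y: np.ndarray,
    M: Dict[str, np.ndarray],
    gamma_true: Dict[str, float],
    beta_true: Dict[str, float],
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    counts = {}
    risk = y == 1
    for v in M:
        lam = M[v].copy()
        k = gamma_true[v] * beta_true[v]
        gam = rng.gamma(shape=k, scale=1.0 / beta_true[v], size=int(risk.sum()))
        lam[risk] = lam[risk] * gam
        counts[v] = rng.poisson(lam)
    return counts


def simulate_bulk_scenario(
    config: BulkScenarioConfig,
    cohort_size: Optional[int] = None,
    replicate: int = 0,
) -> SimulatedDataset:
    """Generate one bulk-scenario dataset for a given cohort size/replicate.

    The (cohort_size, replicate) pair is folded into the seed stream so each
    dataset of a study is reproducible in isolation.
    """
    if cohort_size is None:
        cohort_size = config.cohort_sizes[0]
    seed = np.random.SeedSequence(
        [config.seed, int(cohort_size), int(replicate)]
    )
    rng = np.random.default_rng(seed)
    classes = tuple(config.gamma_true)
    n = config.n_genes
    if config.rate_table is not None:
        mu = {v: config.rate_table[f"mu_{v}"].to_numpy(dtype=float)[:n] for v in classes}
        if any(len(mu[v]) != n for v in classes):
            raise ValueError("rate_table shorter than n_genes")
    else:
        mu = synthesize_mutation_rates(
            n, classes, rng, config.log10_mu_mean, config.log10_mu_sd,
            config.log10_mu_range,
        )
    M = {v: 2.0 * cohort_size * mu[v] for v in classes}
    y = (rng.uniform(size=n) < config.risk_fraction).astype(int)
    A, B, C = config.sigmoid_true
    sig = SigmoidPrior(config.risk_fraction, A, B, C)
    x = rng.uniform(size=n)
    x[y == 1] = _sample_sigmoid_covariate(int(y.sum()), sig, rng)
    counts = _draw_counts(y, M, config.gamma_true, config.beta_true, rng)
    genes = pd.DataFrame({"gene": [f"g{i:05d}" for i in range(n)]})
    for v in classes:
        genes[f"d_{v}"] = counts[v]
        genes[f"M_{v}"] = M[v]
    genes["x"] = x
    pi_true = np.minimum(sig.prior(x), 1.0)
    truth = {
        "risk_fraction": config.risk_fraction,
        "gamma_true": dict(config.gamma_true),
        "beta_true": dict(config.beta_true),
        "sigmoid_true": config.sigmoid_true,
        "cohort_size": cohort_size,
    }
    return SimulatedDataset(genes, y, pi_true, truth, cohort_size, replicate)


# ---------------------------------------------------------------------------
# single-cell scenario
# ---------------------------------------------------------------------------

def synthesize_expression_matrix(
    n_genes: int = 18_000,
    n_cell_types: int = 60,
    n_programs: int = 8,
    seed: int = 0,
) -> Tuple[pd.DataFrame, LabelSet]:
    """Synthetic fraction-expressing matrix with latent co-expression programs.

    Genes load on a few latent programs; cell types mix the programs, and the
    fraction-of-cells-expressing value is a logistic squash of the loading
    into [0, 1].  A subset of "risk-like" genes shares elevated loadings on
    two of the programs, from which 59 positive and 86 negative label genes
    are drawn — emulating the structure that lets labelled genes define a
    prior, without modelling counts or dropout of real single-cell data.
    """
    rng = np.random.default_rng(seed)
    gene_load = rng.normal(0, 1.0, size=(n_genes, n_programs))
    risk_like = rng.uniform(size=n_genes) < 0.08
    gene_load[risk_like, :2] += 1.5
    ct_mix = rng.normal(0, 1.0, size=(n_programs, n_cell_types))
    ct_mix[:2, : n_cell_types // 3] += 1.0  # programs 0-1 drive a cell-type block
    raw = gene_load @ ct_mix + rng.normal(0, 0.8, size=(n_genes, n_cell_types))
    frac = 1.0 / (1.0 + np.exp(-(raw - 2.0) / 2.0))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cols = [f"ct{j:02d}" for j in range(n_cell_types)]
    expr = pd.DataFrame(frac, index=gene_ids, columns=cols)
    risk_idx = np.flatnonzero(risk_like)
    nonrisk_idx = np.flatnonzero(~risk_like)
    pos = rng.choice(risk_idx, size=min(59, risk_idx.size), replace=False)
    neg = rng.choice(nonrisk_idx, size=min(86, nonrisk_idx.size), replace=False)
    labels = LabelSet([gene_ids[i] for i in pos], [gene_ids[i] for i in neg])
    return expr, labels


@dataclass(frozen=True)
class ScScenarioConfig:
    """Truth settings of the single-cell simulation study."""

    expression: pd.DataFrame = None          # genes x cell types, fractions
    prior_positives: Sequence[str] = ()      # genes defining the prior map
    prior_negatives: Sequence[str] = ()
    variance_explained: float = 0.95
    target_mean_prior: float = 0.032
    elastic_net_l1_ratio: float = 0.5
    cohort_size: int = 16_616
    gamma_true: Dict[str, float] = field(
        default_factory=lambda: {"LGD": 20.0, "Dmis": 12.0}
    )
    beta_true: Dict[str, float] = field(
        default_factory=lambda: {"LGD": 0.84, "Dmis": 0.90}
    )
    n_replicates: int = 50
    n_label_risk: int = 100
    n_label_nonrisk: int = 300
    seed: int = 0
    log10_mu_mean: float = -5.8
    log10_mu_sd: float = 0.6
    log10_mu_range: Tuple[float, float] = (-8.0, -3.5)

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_explained < 1.0:
            raise ValueError("variance_explained must lie in (0, 1)")
        if not 0.0 < self.target_mean_prior < 1.0:
            raise ValueError("target_mean_prior must lie in (0, 1)")


def build_sc_prior(config: ScScenarioConfig) -> pd.Series:
    """Construct the simulated risk prior from expression and labelled genes.

    SVD of the (centred) labelled-gene expression submatrix; all genes are
    projected onto the leading components explaining >= ``variance_explained``
    of labelled-gene variance; an elastic-net logistic regression fitted on
    the labelled genes is applied to every gene, and its probabilities are
    squared then linearly scaled to ``target_mean_prior`` (clipped at 1).
    """
    expr = config.expression
    ids = list(config.prior_positives) + list(config.prior_negatives)
    missing = [g for g in ids if g not in expr.index]
    if missing:
        raise ValueError(f"labelled genes absent from expression: {missing[:5]}")
    Xlab = expr.loc[ids].to_numpy(dtype=float)
    centre = Xlab.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xlab - centre, full_matrices=False)
    if np.sum(s > 1e-12) < 2:
        raise ValueError("labelled expression submatrix is (near) rank deficient")
    var_ratio = (s ** 2) / np.sum(s ** 2)
    k = int(np.searchsorted(np.cumsum(var_ratio), config.variance_explained) + 1)
    V = Vt[:k]
    Zlab = (Xlab - centre) @ V.T
    t = np.array([1.0] * len(config.prior_positives) + [0.0] * len(config.prior_negatives))
    clf = LogisticRegressionCV(
        Cs=10,
        cv=5,
        penalty="elasticnet",
        solver="saga",
        l1_ratios=[config.elastic_net_l1_ratio],
        max_iter=5000,
        random_state=config.seed & 0x7FFFFFFF,
    )
    clf.fit(Zlab, t)
    Zall = (expr.to_numpy(dtype=float) - centre) @ V.T
    p = clf.predict_proba(Zall)[:, 1]
    p2 = p ** 2
    pi = np.minimum(p2 * (config.target_mean_prior / p2.mean()), 1.0)
    out = pd.Series(pi, index=expr.index, name="pi_true")
    out.attrs["n_components"] = k
    out.attrs["variance_ratio"] = var_ratio
    return out


def simulate_sc_scenario(
    config: ScScenarioConfig,
    replicates: Optional[Sequence[int]] = None,
) -> List[SimulatedDataset]:
    """Generate sc-scenario datasets sharing one prior and risk assignment.

    The prior map, risk-gene draw and semi-supervision labels are fixed by
    ``config.seed``; only the count draws differ across replicates.
    """
    if config.expression is None:
        raise ValueError("config.expression is required")
    pi = build_sc_prior(config).to_numpy()
    gene_ids = list(config.expression.index)
    n = len(gene_ids)
    classes = tuple(config.gamma_true)
    root = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    y = (root.uniform(size=n) < pi).astype(int)
    mu = synthesize_mutation_rates(
        n, classes, root, config.log10_mu_mean, config.log10_mu_sd,
        config.log10_mu_range,
    )
    M = {v: 2.0 * config.cohort_size * mu[v] for v in classes}
    risk_idx = np.flatnonzero(y == 1)
    nonrisk_idx = np.flatnonzero(y == 0)
    lab_pos = root.choice(risk_idx, size=min(config.n_label_risk, risk_idx.size),
                          replace=False)
    lab_neg = root.choice(nonrisk_idx,
                          size=min(config.n_label_nonrisk, nonrisk_idx.size),
                          replace=False)
    labels = LabelSet([gene_ids[i] for i in lab_pos],
                      [gene_ids[i] for i in lab_neg])
    if replicates is None:
        replicates = range(config.n_replicates)
    out = []
    truth = {
        "target_mean_prior": config.target_mean_prior,
        "gamma_true": dict(config.gamma_true),
        "beta_true": dict(config.beta_true),
        "cohort_size": config.cohort_size,
        "n_risk_genes": int(y.sum()),
    }
    for rep in replicates:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, int(config.cohort_size), int(rep)])
        )
        counts = _draw_counts(y, M, config.gamma_true, config.beta_true, rng)
        genes = pd.DataFrame({"gene": gene_ids})
        for v in classes:
            genes[f"d_{v}"] = counts[v]
            genes[f"M_{v}"] = M[v]
        out.append(
            SimulatedDataset(genes, y.copy(), pi.copy(), dict(truth),
                             config.cohort_size, rep, labels=labels)
        )
    return out
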