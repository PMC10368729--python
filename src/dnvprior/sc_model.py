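"""Single-cell expression prior network and semi-supervised variational fit.

The per-gene risk prior ``pi_g`` is a learned function of the gene's
expression profile ``x_g`` — a vector of fraction-of-cells-expressing values
across (time-resolved) cell types.  The function is a small feed-forward
network: a 32-unit encoding block and a 2-unit sampler block, each a linear
layer followed by ELU activation and layer normalization; the two sampler
scores are softmax-normalised into ``(pi, 1 - pi)``.

Training minimises the negative evidence lower bound

    loss = sum_g KL[Bern(pi_g) || Bern(pi_bar)]
           - [pi_g * log P_alt(d_g) + (1 - pi_g) * log P_null(d_g)]

where the expectation over the binary risk indicator is computed exactly
(two-term sum) rather than by Monte-Carlo reparameterization, and ``pi_bar``
is the KL anchor — the expected overall fraction of risk genes, typically
taken from the expression-free baseline fit.  Training is two-phase:
supervised pretraining with cross-entropy on labelled genes (known risk genes
as positives, genes with LGD variants in controls as negatives) at a larger
learning rate, then unsupervised ELBO training on all genes with the
relative-risk hyperparameters (gamma_bar, beta_bar) learned jointly on the
log scale, learning rate decaying each epoch.

Everything is plain numpy with hand-written backpropagation and Adam; the
network is tiny (~100 inputs) and trains in seconds on CPU at atlas scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import digamma, expit
from scipy.stats import spearmanr

from .core_stats import (
    RelativeRiskParams,
    alt_marginal_loglik,
    bayesian_fdr,
    null_loglik,
    ppa,
)

__all__ = [
    "PriorNetwork",
    "LabelSet",
    "TrainingConfig",
    "ScFitResult",
    "forward_prior",
    "elbo_loss",
    "supervised_loss",
    "train_semisupervised",
    "celltype_association",
    "pseudo_bulk",
]

_EPS = 1e-5       # layer-norm variance floor
_PI_CLIP = 1e-7   # keep pi strictly inside (0, 1) for the KL/BCE logs


@dataclass
class LabelSet:
    """Gene labels for semi-supervised pretraining (disjoint id lists)."""

    positives: List[str]
    negatives: List[str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"labels overlap: {sorted(overlap)[:5]} ...")


@dataclass
class TrainingConfig:
    pretrain_epochs: int = 50
    unsup_epochs: int = 60
    pretrain_lr: float = 1e-2
    unsup_lr_initial: float = 1e-3
    lr_decay: float = 0.95
    batch_size: Optional[int] = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pretrain_epochs <= 0 or self.unsup_epochs <= 0:
            raise ValueError("epoch counts must be > 0")
        if self.pretrain_lr <= 0 or self.unsup_lr_initial <= 0:
            raise ValueError("learning rates must be > 0")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")


def _elu(z):
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z):
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


class PriorNetwork:
    """Two-block prior network mapping an expression profile to ``pi_g``.

    Architecture: a 32-unit encoding block, Linear(C, 32) -> ELU ->
    LayerNorm, followed by a 2-unit sampler block, Linear(32, 2) -> ELU,
    whose two class scores are softmax-normalised; the first probability is
    ``pi_g``.  The sampler block carries no layer norm: normalising a
    2-vector reduces it to the sign of the score difference, which would
    collapse the output to two constants and kill the gradient.  The forward
    pass is deterministic given the weights.
    """

    def __init__(self, n_inputs: int, hidden: int = 32, pi_bar: float = 0.05,
                 seed: int = 0):
        if not 0.0 < pi_bar < 1.0:
            raise ValueError("pi_bar (KL anchor) must lie strictly in (0, 1)")
        self.n_inputs = int(n_inputs)
        self.hidden = int(hidden)
        self.kl_weight_pi_bar = float(pi_bar)
        rng = np.random.default_rng(seed)
        self.params: Dict[str, np.ndarray] = {
            "W1": rng.normal(0, np.sqrt(1.0 / n_inputs), (n_inputs, hidden)),
            "b1": np.zeros(hidden),
            "g1": np.ones(hidden),
            "c1": np.zeros(hidden),
            "W2": rng.normal(0, np.sqrt(1.0 / hidden), (hidden, 2)),
            "b2": np.zeros(2),
        }

    # -- forward / backward -------------------------------------------------

    def _block(self, X, W, b, g, c):
        z = X @ W + b
        a = _elu(z)
        mu = a.mean(axis=1, keepdims=True)
        var = a.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (a - mu) * inv
        return z, xhat, inv, g * xhat + c

    def forward(self, X: np.ndarray, cache: bool = False):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expression profile has {X.shape[1]} features, network expects "
                f"{self.n_inputs}"
            )
        p = self.params
        z1, xh1, inv1, h1 = self._block(X, p["W1"], p["b1"], p["g1"], p["c1"])
        z2 = h1 @ p["W2"] + p["b2"]
        s = _elu(z2)
        pi = expit(s[:, 0] - s[:, 1])  # softmax of the two class scores
        if cache:
            return pi, (X, z1, xh1, inv1, h1, z2, pi)
        return float(pi[0]) if squeeze else pi

    @staticmethod
    def _block_backward(dh, z, xhat, inv, X_in, W, g):
        n_feat = xhat.shape[1]
        dg = (dh * xhat).sum(axis=0)
        dc = dh.sum(axis=0)
        dxhat = dh * g
        da = (inv / n_feat) * (
            n_feat * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )
        dz = da * _elu_grad(z)
        dW = X_in.T @ dz
        db = dz.sum(axis=0)
        dX = dz @ W.T
        return dX, {"W": dW, "b": db, "g": dg, "c": dc}

    def backward(self, cache, dpi: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all weights, given dloss/dpi."""
        X, z1, xh1, inv1, h1, z2, pi = cache
        p = self.params
        ds = (dpi * pi * (1.0 - pi))[:, None] * np.array([1.0, -1.0])
        dz2 = ds * _elu_grad(z2)
        dW2 = h1.T @ dz2
        db2 = dz2.sum(axis=0)
        dh1 = dz2 @ p["W2"].T
        _, g1 = self._block_backward(dh1, z1, xh1, inv1, X, p["W1"], p["g1"])
        return {
            "W1": g1["W"], "b1": g1["b"], "g1": g1["g"], "c1": g1["c"],
            "W2": dW2, "b2": db2,
        }


def forward_prior(net: PriorNetwork, x) -> float:
    """Prior risk probability ``pi_g`` for one expression profile (or batch)."""
    return net.forward(x)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _bern_kl(pi, pi_bar):
    pi = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
    return pi * (np.log(pi) - np.log(pi_bar)) + (1 - pi) * (
        np.log1p(-pi) - np.log1p(-pi_bar)
    )


def _class_logliks(genes: pd.DataFrame, rr: RelativeRiskParams):
    la = np.zeros(len(genes))
    ln = np.zeros(len(genes))
    for v in rr.classes:
        d = genes[f"d_{v}"].to_numpy(dtype=float)
        M = genes[f"M_{v}"].to_numpy(dtype=float)
        la += alt_marginal_loglik(d, M, rr.gamma_bar[v], rr.beta_bar[v])
        ln += null_loglik(d, M)
    return la, ln


def elbo_loss(net: PriorNetwork, genes: pd.DataFrame, rr: RelativeRiskParams,
              X: Optional[np.ndarray] = None,
              pis: Optional[np.ndarray] = None) -> float:
    """Negative ELBO of a gene batch under the current network and likelihood.

    ``sum_g KL[Bern(pi_g)||Bern(pi_bar)] - E_{y~Bern(pi_g)} log p(d_g | y)``
    with the expectation over ``y`` taken in closed form.  ``X`` supplies the
    expression rows for the batch (ignored if ``pis`` is given directly).
    """
    if len(genes) == 0:
        raise ValueError("empty gene batch")
    pb = net.kl_weight_pi_bar
    if pb <= 0.0 or pb >= 1.0:
        raise ValueError("pi_bar in {0, 1} makes the Bernoulli KL degenerate")
    if pis is None:
        if X is None:
            raise ValueError("need expression rows X (or explicit pis)")
        pis = np.atleast_1d(net.forward(X))
    la, ln = _class_logliks(genes, rr)
    kl = _bern_kl(pis, pb)
    return float(np.sum(kl - (pis * la + (1 - pis) * ln)))


def supervised_loss(net: PriorNetwork, labels: LabelSet,
                    expression: pd.DataFrame) -> float:
    """Mean binary cross-entropy of ``pi_g`` against the labelled genes."""
    ids = list(labels.positives) + list(labels.negatives)
    if not ids:
        raise ValueError("empty label set")
    missing = [g for g in ids if g not in expression.index]
    if missing:
        raise ValueError(f"label genes absent from expression: {missing[:5]}")
    X = expression.loc[ids].to_numpy(dtype=float)
    t = np.array([1.0] * len(labels.positives) + [0.0] * len(labels.negatives))
    pi = np.clip(np.atleast_1d(net.forward(X)), _PI_CLIP, 1 - _PI_CLIP)
    return float(-np.mean(t * np.log(pi) + (1 - t) * np.log1p(-pi)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes: Dict[str, tuple], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _nb_hyper_grads(d, M, gamma, beta):
    """d logNB / d(log gamma), d logNB / d(log beta), summed later per gene."""
    r = gamma * beta
    core = digamma(d + r) - digamma(r) + np.log(beta) - np.log(beta + M)
    dgamma = beta * core
    dbeta = gamma * core + r * (1.0 / beta - 1.0 / (beta + M)) - d / (beta + M)
    return gamma * dgamma, beta * dbeta  # chain rule through the log scale


@dataclass
class ScFitResult:
    net: PriorNetwork
    rr: RelativeRiskParams
    posterior_table: pd.DataFrame
    posterior_table_unlabeled: pd.DataFrame
    pis: pd.Series
    history: Dict[str, List[float]] = field(default_factory=dict)


def train_semisupervised(
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    labels: LabelSet,
    rr_init: RelativeRiskParams,
    config: Optional[TrainingConfig] = None,
    pi_bar: Optional[float] = None,
    hidden: int = 32,
) -> ScFitResult:
    """Two-phase fit of the prior network jointly with the count likelihood.

    Phase 1 pretrains on the labelled genes with cross-entropy at a larger
    learning rate; phase 2 minimises the negative ELBO over all genes with
    (gamma_bar, beta_bar) learned jointly on the log scale, learning rate
    decaying each epoch.  Returns PPA for every gene and Bayesian FDR tables
    both over all genes and with the training-label genes removed.

    ``expression`` is a genes x cell-types DataFrame of fraction-expressing
    values; ``genes`` the count table (columns gene, d_<class>, M_<class>);
    ``pi_bar`` the KL anchor — supply the mixture proportion estimated by the
    expression-free baseline (``bulk_model.fit_uniform_prior``).
    """
    if pi_bar is None:
        raise ValueError(
            "pi_bar is required: estimate the average risk-gene proportion "
            "first (e.g. bulk_model.fit_uniform_prior) and pass it here"
        )
    config = config or TrainingConfig()
    gene_ids = genes["gene"].tolist()
    missing = [g for g in gene_ids if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    Xall = expression.loc[gene_ids].to_numpy(dtype=float)
    net = PriorNetwork(Xall.shape[1], hidden=hidden, pi_bar=pi_bar,
                       seed=config.seed)
    history: Dict[str, List[float]] = {"pretrain": [], "elbo": []}

    # ---- phase 1: supervised pretraining on labelled genes ----
    ids = list(labels.positives) + list(labels.negatives)
    if not ids:
        raise ValueError("label set is empty")
    missing = [g for g in ids if g not in expression.index]
    if missing:
        raise ValueError(f"label genes absent from expression: {missing[:5]}")
    Xlab = expression.loc[ids].to_numpy(dtype=float)
    t = np.array([1.0] * len(labels.positives) + [0.0] * len(labels.negatives))
    opt = _Adam({k: v.shape for k, v in net.params.items()}, config.pretrain_lr)
    for _ in range(config.pretrain_epochs):
        pi, cache = net.forward(Xlab, cache=True)
        pic = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
        loss = float(-np.mean(t * np.log(pic) + (1 - t) * np.log1p(-pic)))
        inside = (pi > _PI_CLIP) & (pi < 1 - _PI_CLIP)
        dpi = np.where(inside, (pic - t) / (pic * (1 - pic)) / len(t), 0.0)
        grads = net.backward(cache, dpi)
        opt.step(net.params, grads)
        history["pretrain"].append(loss)

    # ---- phase 2: unsupervised ELBO on all genes ----
    classes = rr_init.classes
    log_g = {v: np.log(rr_init.gamma_bar[v]) for v in classes}
    log_b = {v: np.log(rr_init.beta_bar[v]) for v in classes}
    d = {v: genes[f"d_{v}"].to_numpy(dtype=float) for v in classes}
    M = {v: genes[f"M_{v}"].to_numpy(dtype=float) for v in classes}
    ln = np.zeros(len(genes))
    for v in classes:
        ln += null_loglik(d[v], M[v])

    shapes = {k: v.shape for k, v in net.params.items()}
    shapes.update({f"log_g_{v}": () for v in classes})
    shapes.update({f"log_b_{v}": () for v in classes})
    opt2 = _Adam(shapes, config.unsup_lr_initial)
    rng = np.random.default_rng(config.seed + 1)
    n = len(genes)
    pb = net.kl_weight_pi_bar
    logit_pb = np.log(pb) - np.log1p(-pb)
    for epoch in range(config.unsup_epochs):
        opt2.lr = config.unsup_lr_initial * config.lr_decay ** epoch
        if config.batch_size is None:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, max(1, n // config.batch_size))
        epoch_loss = 0.0
        for idx in batches:
            gam = {v: np.exp(log_g[v]) for v in classes}
            bet = {v: np.exp(log_b[v]) for v in classes}
            la = np.zeros(len(idx))
            for v in classes:
                la += alt_marginal_loglik(d[v][idx], M[v][idx], gam[v], bet[v])
            pi, cache = net.forward(Xall[idx], cache=True)
            pic = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
            kl = _bern_kl(pic, pb)
            loss = float(np.sum(kl - (pic * la + (1 - pic) * ln[idx])))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite ELBO at epoch {epoch}: check inputs/learning rate"
                )
            epoch_loss += loss
            inside = (pi > _PI_CLIP) & (pi < 1 - _PI_CLIP)
            dpi = np.where(
                inside,
                (np.log(pic) - np.log1p(-pic)) - logit_pb - (la - ln[idx]),
                0.0,
            )
            grads = net.backward(cache, dpi)
            for v in classes:
                ggrad, bgrad = _nb_hyper_grads(d[v][idx], M[v][idx], gam[v], bet[v])
                grads[f"log_g_{v}"] = -np.sum(pic * ggrad)
                grads[f"log_b_{v}"] = -np.sum(pic * bgrad)
            hyper = {f"log_g_{v}": np.asarray(log_g[v]) for v in classes}
            hyper.update({f"log_b_{v}": np.asarray(log_b[v]) for v in classes})
            allp = dict(net.params)
            allp.update(hyper)
            opt2.step(allp, grads)
            for v in classes:
                log_g[v] = float(allp[f"log_g_{v}"])
                log_b[v] = float(allp[f"log_b_{v}"])
        history["elbo"].append(epoch_loss)

    rr = RelativeRiskParams(
        gamma_bar={v: float(np.exp(log_g[v])) for v in classes},
        beta_bar={v: float(np.exp(log_b[v])) for v in classes},
    )
    pis = np.atleast_1d(net.forward(Xall))
    p = ppa(pis, d, M, rr)
    table = bayesian_fdr(p, gene_ids)
    labelled = set(ids)
    keep = ~np.isin(np.asarray(gene_ids, dtype=object), list(labelled))
    table_unlab = bayesian_fdr(np.asarray(p)[keep], np.asarray(gene_ids, dtype=object)[keep])
    return ScFitResult(net, rr, table, table_unlab,
                       pd.Series(pis, index=gene_ids, name="pi"), history)


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def celltype_association(expression: pd.DataFrame, pis) -> pd.DataFrame:
    """Spearman correlation of each cell-type column with the per-gene prior.

    Ties are mid-ranked (scipy default); a constant column is reported with
    correlation 0 and ``constant=True``.
    """
    pis = np.asarray(pis, dtype=float)
    if len(expression) != pis.size:
        raise ValueError("expression rows and pis differ in length")
    if pis.size < 3:
        raise ValueError("need at least 3 genes")
    rows = []
    for col in expression.columns:
        v = expression[col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            rows.append({"cell_type": col, "spearman_r": 0.0, "constant": True})
        else:
            r = spearmanr(v, pis).statistic
            rows.append({"cell_type": col, "spearman_r": float(r), "constant": False})
    return pd.DataFrame(rows)


def pseudo_bulk(
    cell_matrix,
    gene_ids: Sequence[str],
    batch_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fraction of cells with nonzero expression per gene, per source batch.

    ``cell_matrix`` is cells x genes (dense or scipy.sparse).  Batches are
    processed separately so data sources with different depths do not mix;
    with no batch labels a single column ``all`` is returned.
    """
    if sp.issparse(cell_matrix):
        mat = cell_matrix.tocsr()
        n_cells, n_genes = mat.shape
    else:
        mat = np.asarray(cell_matrix)
        if mat.size == 0:
            raise ValueError("empty cell matrix")
        n_cells, n_genes = mat.shape
    if n_cells == 0 or n_genes == 0:
        raise ValueError("empty cell matrix")
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match matrix columns")
    if batch_labels is None:
        batch_labels = ["all"] * n_cells
    batch_labels = np.asarray(batch_labels, dtype=object)
    out = {}
    for b in pd.unique(batch_labels):
        rows = np.flatnonzero(batch_labels == b)
        sub = mat[rows]
        if sp.issparse(sub):
            frac = np.asarray((sub != 0).sum(axis=0)).ravel() / len(rows)
        else:
            frac = (sub != 0).mean(axis=0)
        out[str(b)] = frac
    return pd.DataFrame(out, index=list(gene_ids))
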