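"""Likelihoods, mixture posteriors and Bayesian FDR for de novo variant counts.

The observation model for a gene ``g`` and variant class ``v`` (e.g. LGD,
Dmis) is a two-component mixture over the latent risk indicator ``y_g``:

* non-risk (``y_g = 0``): ``d_gv ~ Poisson(M_gv)`` where ``M_gv`` is the
  expected number of de novo variants in the cohort under the background
  mutation-rate model (``M = 2 * n_trios * mu`` for autosomal genes);
* risk (``y_g = 1``): the per-gene relative risk ``gamma_gv`` is drawn from a
  Gamma distribution with mean ``gamma_bar_v`` and rate ``beta_bar_v``
  (shape ``gamma_bar * beta_bar``, scale ``1 / beta_bar``), and
  ``d_gv ~ Poisson(gamma_gv * M_gv)``.  Marginalising over ``gamma`` gives a
  negative-binomial (Gamma-Poisson) likelihood with closed form
  ``NB(d; size = gamma_bar * beta_bar, p = beta_bar / (beta_bar + M))``.

The posterior probability of association (PPA) combines the classes
(conditionally independent given ``y_g``) with a per-gene prior ``pi_g``, and
the Bayesian FDR of the top-``k`` list is the running mean of ``1 - PPA``
over genes ranked by decreasing PPA.

All arithmetic is in log space; every public function accepts scalars or
numpy arrays and broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "VARIANT_CLASSES",
    "GeneRecord",
    "RelativeRiskParams",
    "GeneRiskState",
    "null_loglik",
    "alt_marginal_loglik",
    "ppa",
    "bayesian_fdr",
    "write_posterior_table",
]

#: default variant classes, in table-column order
VARIANT_CLASSES = ("LGD", "Dmis")

ArrayLike = Union[float, int, np.ndarray]


@dataclass
class GeneRecord:
    """Per-gene input: DNV counts, expected null counts and expression covariate.

    ``x`` is a scalar expression rank percentile in [0, 1] for the bulk model,
    or a vector of per-cell-type fraction-expressing values in [0, 1] for the
    single-cell model; ``None`` when no expression is attached.
    """

    gene_id: str
    d: Dict[str, int] = field(default_factory=dict)
    M: Dict[str, float] = field(default_factory=dict)
    x: Optional[Union[float, np.ndarray]] = None

    def __post_init__(self) -> None:
        for v, cnt in self.d.items():
            if v not in self.M:
                raise ValueError(f"gene {self.gene_id}: class {v!r} has a count but no rate")
            if cnt < 0:
                raise ValueError(f"gene {self.gene_id}: negative count for {v!r}")
        for v, m in self.M.items():
            if not m > 0:
                raise ValueError(f"gene {self.gene_id}: non-positive rate for {v!r}")
        if self.x is not None:
            xa = np.atleast_1d(np.asarray(self.x, dtype=float))
            if np.any(xa < 0) or np.any(xa > 1):
                raise ValueError(f"gene {self.gene_id}: expression covariate outside [0, 1]")


@dataclass
class RelativeRiskParams:
    """Gamma hyperparameters of the relative risk, one pair per variant class.

    ``gamma_bar[v]`` is the mean relative risk and ``beta_bar[v]`` the Gamma
    rate (dispersion); the Gamma shape is ``gamma_bar * beta_bar`` and the
    scale ``1 / beta_bar``, the TADA/extTADA reporting convention.
    """

    gamma_bar: Dict[str, float]
    beta_bar: Dict[str, float]

    def __post_init__(self) -> None:
        for v in self.gamma_bar:
            if v not in self.beta_bar:
                raise ValueError(f"class {v!r} missing beta_bar")
            if not (self.gamma_bar[v] > 0 and np.isfinite(self.gamma_bar[v])):
                raise ValueError(f"class {v!r}: gamma_bar must be finite and > 0")
            if not (self.beta_bar[v] > 0 and np.isfinite(self.beta_bar[v])):
                raise ValueError(f"class {v!r}: beta_bar must be finite and > 0")

    @property
    def classes(self) -> tuple:
        return tuple(self.gamma_bar)

    def shape(self, v: str) -> float:
        return self.gamma_bar[v] * self.beta_bar[v]

    def scale(self, v: str) -> float:
        return 1.0 / self.beta_bar[v]


@dataclass
class GeneRiskState:
    """Latent risk indicator and its prior probability for one gene."""

    y: int
    pi: float

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError("y must be 0 or 1")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")


def _check_dm(d: ArrayLike, M: ArrayLike) -> tuple:
    d = np.asarray(d, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(d < 0) or np.any(d != np.floor(d)):
        raise ValueError("counts must be non-negative integers")
    if np.any(M <= 0) or not np.all(np.isfinite(M)):
        raise ValueError("expected null counts M must be positive and finite")
    return d, M


def null_loglik(d: ArrayLike, M: ArrayLike) -> ArrayLike:
    """Poisson log-likelihood of count ``d`` under the background rate ``M``."""
    d, M = _check_dm(d, M)
    out = d * np.log(M) - M - gammaln(d + 1.0)
    return out if out.ndim else float(out)


def alt_marginal_loglik(
    d: ArrayLike,
    M: ArrayLike,
    gamma_bar: ArrayLike,
    beta_bar: ArrayLike,
) -> ArrayLike:
    """Gamma-Poisson (negative binomial) marginal log-likelihood under risk.

    Integrates ``Poisson(d | gamma * M)`` against
    ``Gamma(gamma | shape=gamma_bar*beta_bar, rate=beta_bar)`` in closed form:
    ``NB(d; size=gamma_bar*beta_bar, p=beta_bar/(beta_bar+M))`` where ``p`` is
    the probability assigned to the size parameter's "success" convention.
    """
    d, M = _check_dm(d, M)
    gamma_bar = np.asarray(gamma_bar, dtype=float)
    beta_bar = np.asarray(beta_bar, dtype=float)
    if np.any(gamma_bar <= 0) or np.any(beta_bar <= 0):
        raise ValueError("gamma_bar and beta_bar must be > 0")
    r = gamma_bar * beta_bar
    # log p = log(beta) - log(beta + M); log(1-p) = log(M) - log(beta + M)
    log_denom = np.log(beta_bar + M)
    out = (
        gammaln(d + r)
        - gammaln(r)
        - gammaln(d + 1.0)
        + r * (np.log(beta_bar) - log_denom)
        + d * (np.log(M) - log_denom)
    )
    return out if out.ndim else float(out)


def _class_logliks(
    d: Mapping[str, ArrayLike],
    M: Mapping[str, ArrayLike],
    rr: RelativeRiskParams,
) -> tuple:
    """Summed per-gene log-likelihoods across variant classes, (alt, null)."""
    la = 0.0
    ln = 0.0
    for v in d:
        la = la + alt_marginal_loglik(d[v], M[v], rr.gamma_bar[v], rr.beta_bar[v])
        ln = ln + null_loglik(d[v], M[v])
    return np.asarray(la, dtype=float), np.asarray(ln, dtype=float)


def ppa(
    pi: ArrayLike,
    d: Mapping[str, ArrayLike],
    M: Mapping[str, ArrayLike],
    rr: RelativeRiskParams,
) -> ArrayLike:
    """Posterior probability of association for a gene (or vector of genes).

    ``PPA = pi * P_alt / (pi * P_alt + (1 - pi) * P_null)`` with the
    variant-class likelihoods multiplied (classes independent given the risk
    state); evaluated stably in log space.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    la, ln = _class_logliks(d, M, rr)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        log_num = np.log(pi) + la
        log_other = np.log1p(-pi) + ln
        # logistic of the log-odds; exact at pi = 0 or 1
        out = np.where(
            pi == 0.0,
            0.0,
            np.where(pi == 1.0, 1.0, 1.0 / (1.0 + np.exp(log_other - log_num))),
        )
    return out if out.ndim else float(out)


def bayesian_fdr(
    ppas: Sequence[float],
    gene_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Rank genes by PPA and attach the Bayesian FDR of each top-``k`` list.

    ``FDR_k`` is the mean of ``1 - PPA`` over the ``k`` highest-PPA genes —
    the expected false-discovery proportion if the top-``k`` list is reported.
    Ties keep the original input order (stable sort).

    Returns a DataFrame with columns ``gene``, ``PPA``, ``rank`` (1-based),
    ``FDR``, sorted by PPA descending.
    """
    p = np.asarray(ppas, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one PPA")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("PPA values must lie in [0, 1]")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(p.size)]
    genes = np.asarray(list(gene_ids), dtype=object)
    if genes.size != p.size:
        raise ValueError("gene_ids and ppas differ in length")
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    fdr = np.cumsum(1.0 - p_sorted) / np.arange(1, p.size + 1)
    return pd.DataFrame(
        {
            "gene": genes[order],
            "PPA": p_sorted,
            "rank": np.arange(1, p.size + 1),
            "FDR": fdr,
        }
    )


def write_posterior_table(table: pd.DataFrame, path) -> None:
    """Write a posterior table (gene, PPA, FDR, ...) as TSV, PPA descending."""
    cols = [c for c in ("gene", "PPA", "rank", "FDR") if c in table.columns]
    table.sort_values("PPA", ascending=False, kind="stable")[cols].to_csv(
        path, sep="\t", index=False
    )
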