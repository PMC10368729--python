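"""Bulk-expression mixture model: sigmoid prior, MCMC fit and uniform baseline.

With a scalar expression covariate ``x_g`` (rank percentile in [0, 1]) the
per-gene risk prior is

    pi_g = pi_bar * Sigmoid(x_g | A, B, C)
    Sigmoid(x | A, B, C) = C + L / (1 + exp(A * (B - x)))
    L = (1 - C) * A / (log(e^A + e^{A B}) - log(e^{A B} + 1))

``L`` is the exact constant that makes the sigmoid integrate to 1 on [0, 1],
so ``pi_bar`` is the average prior risk probability across the covariate
range.  ``A`` is the steepness, ``B`` the inflection point on the rank scale
and ``C`` the floor relative to the normalised curve.

The latent risk indicator is marginalised analytically, giving a per-gene
mixture log-likelihood ``log(pi * P_alt + (1 - pi) * P_null)``; the model has
8 free parameters (pi_bar, A, B, C and per-class relative-risk pairs).  The
uniform-prior baseline fixes ``pi_g = pi_bar`` (5 free parameters) and is the
expression-free comparator used throughout the evaluation module.

Posteriors are sampled with an affine-invariant ensemble sampler (emcee);
walkers are treated as chains for the Rhat/ESS diagnostics.  A fast MAP path
(posterior mode by L-BFGS on transformed parameters) serves replicate-heavy
power studies where only point estimates are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .core_stats import (
    RelativeRiskParams,
    bayesian_fdr,
    null_loglik,
    ppa,
)

__all__ = [
    "SigmoidPrior",
    "BulkFitConfig",
    "BulkFitResult",
    "sigmoid_prior",
    "sigmoid_cdf",
    "fit_bulk",
    "fit_uniform_prior",
]


def _log_l_denominator(A: float, B: float) -> float:
    """log-sum-exp form of log(e^A + e^{AB}) - log(e^{AB} + 1)."""
    return np.logaddexp(A, A * B) - np.logaddexp(A * B, 0.0)


@dataclass(frozen=True)
class SigmoidPrior:
    """Parameters of the normalised sigmoid prior on the rank-percentile scale."""

    pi_bar: float
    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_bar <= 1.0:
            raise ValueError("pi_bar must lie in [0, 1]")
        if not self.A > 0:
            raise ValueError("steepness A must be > 0")
        if not 0.0 <= self.C < 1.0:
            raise ValueError("floor C must lie in [0, 1)")

    @property
    def L(self) -> float:
        """Normaliser making the sigmoid integrate to 1 over [0, 1]."""
        return (1.0 - self.C) * self.A / _log_l_denominator(self.A, self.B)

    def sigmoid(self, x):
        """Normalised sigmoid density C + L / (1 + exp(A (B - x))) on [0, 1]."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("x must lie in [0, 1]")
        out = self.C + self.L * expit(self.A * (x - self.B))
        return out if out.ndim else float(out)

    def prior(self, x):
        """Per-gene risk prior pi_bar * Sigmoid(x)."""
        out = self.pi_bar * np.asarray(self.sigmoid(x))
        return out if out.ndim else float(out)

    def cdf(self, x):
        """Analytic CDF of the sigmoid density on [0, 1] (for sampling/tests)."""
        x = np.asarray(x, dtype=float)
        # integral of L*expit(A(t-B)) dt from 0 to x = (L/A)(softplus(A(x-B)) - softplus(-AB))
        sp = np.logaddexp(0.0, self.A * (x - self.B)) - np.logaddexp(0.0, -self.A * self.B)
        out = self.C * x + (self.L / self.A) * sp
        return out if out.ndim else float(out)


def sigmoid_prior(x, params: SigmoidPrior):
    """Per-gene prior probability of risk, ``pi_bar * Sigmoid(x | A, B, C)``."""
    return params.prior(x)


def sigmoid_cdf(x, params: SigmoidPrior):
    """CDF of the normalised sigmoid density at ``x``."""
    return params.cdf(x)


# ---------------------------------------------------------------------------
# priors on model parameters (weakly informative; overridable via config)
# ---------------------------------------------------------------------------

DEFAULT_HYPERPRIORS = {
    "pi_bar_beta": (1.0, 9.0),     # Beta(a, b)
    "gamma_mean": 20.0,            # Exponential-shaped Gamma prior mean, truncated > 1
    # Gamma(shape, rate) on the dispersion; zero density at 0 regularises the
    # beta -> 0 overdispersion escape that otherwise absorbs no-signal data
    "beta_gamma": (2.0, 2.0),
    "A_halfnormal_sd": 200.0,
}


@dataclass
class BulkFitConfig:
    """Sampler and prior settings for the bulk fits.

    ``walkers`` ensemble members double as chains for diagnostics;
    ``steps`` is the total iteration count per walker with ``warmup`` of them
    discarded (defaults mirror a 2000-iteration, half-warm-up run).
    """

    walkers: int = 32
    steps: int = 2000
    warmup: int = 1000
    seed: int = 0
    min_genes: int = 500
    method: str = "mcmc"  # "mcmc" or "map"
    classes: Tuple[str, ...] = ("LGD", "Dmis")
    hyperpriors: Dict[str, object] = field(default_factory=lambda: dict(DEFAULT_HYPERPRIORS))
    map_restarts: int = 3


@dataclass
class BulkFitResult:
    """Posterior summary plus the per-gene posterior table at posterior means."""

    summary: pd.DataFrame
    posterior_table: pd.DataFrame
    params: Dict[str, float]
    rr: RelativeRiskParams
    converged: bool
    warnings: Tuple[str, ...] = ()


def _prepare_arrays(genes: pd.DataFrame, classes: Sequence[str], need_x: bool):
    d = {}
    M = {}
    for v in classes:
        dc, mc = f"d_{v}", f"M_{v}"
        if dc not in genes.columns or mc not in genes.columns:
            raise ValueError(f"gene table must contain columns {dc!r} and {mc!r}")
        d[v] = genes[dc].to_numpy(dtype=float)
        M[v] = genes[mc].to_numpy(dtype=float)
        if np.any(d[v] < 0):
            raise ValueError(f"negative counts in {dc}")
        if np.any(M[v] <= 0):
            raise ValueError(f"non-positive rates in {mc}")
    x = None
    if need_x:
        if "x" not in genes.columns:
            raise ValueError("bulk model needs a scalar covariate column 'x'")
        xcol = genes["x"]
        if xcol.map(np.ndim).max() > 0:
            raise ValueError(
                "covariate 'x' is not scalar; vector expression profiles belong "
                "to the single-cell model (sc_model.train_semisupervised)"
            )
        x = xcol.to_numpy(dtype=float)
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("covariate 'x' must lie in [0, 1]")
    return d, M, x


def _mixture_loglik(pi, la, ln):
    """Sum over genes of log(pi * P_alt + (1-pi) * P_null), broadcasting pi."""
    with np.errstate(divide="ignore"):
        a = np.log(pi) + la
        b = np.log1p(-pi) + ln
    return np.sum(np.logaddexp(a, b), axis=-1)


class _BulkPosterior:
    """Vectorised log-posterior for the sigmoid-prior or uniform-prior model.

    Parameter vector layout (sigmoid): [pi_bar, A, B, C, gamma_1.., beta_1..];
    uniform model drops (A, B, C).  Log-density evaluations broadcast over a
    leading walker axis.
    """

    def __init__(self, d, M, x, classes, hyper, uniform: bool):
        self.classes = tuple(classes)
        self.uniform = uniform
        self.hyper = hyper
        self.x = x
        self.d = np.stack([d[v] for v in self.classes])  # (V, G)
        self.M = np.stack([M[v] for v in self.classes])
        self.null = np.stack(
            [null_loglik(d[v], M[v]) for v in self.classes]
        ).sum(axis=0)  # (G,)
        # counts take few distinct values; cache them so gammaln(d + r) is
        # evaluated once per distinct count instead of once per gene
        self._d_unique = []
        self._d_inverse = []
        for i in range(len(self.classes)):
            uq, inv = np.unique(self.d[i], return_inverse=True)
            self._d_unique.append(uq)
            self._d_inverse.append(inv)
        self._lgamma_d1 = [gammaln(self.d[i] + 1.0) for i in range(len(self.classes))]
        self.ndim = (1 if uniform else 4) + 2 * len(self.classes)

    def names(self):
        base = ["pi_bar"] if self.uniform else ["pi_bar", "A", "B", "C"]
        return base + [f"gamma_bar_{v}" for v in self.classes] + [
            f"beta_bar_{v}" for v in self.classes
        ]

    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        nV = len(self.classes)
        if self.uniform:
            pi_bar = theta[..., 0]
            A = B = C = None
            g = theta[..., 1 : 1 + nV]
            b = theta[..., 1 + nV : 1 + 2 * nV]
        else:
            pi_bar, A, B, C = (theta[..., i] for i in range(4))
            g = theta[..., 4 : 4 + nV]
            b = theta[..., 4 + nV : 4 + 2 * nV]
        return pi_bar, A, B, C, g, b

    def log_prior(self, theta):
        pi_bar, A, B, C, g, b = self.split(theta)
        ok = (
            (pi_bar > 0)
            & (pi_bar < 1)
            & np.all(g > 1.0, axis=-1)
            & np.all(b > 0.0, axis=-1)
        )
        if not self.uniform:
            ok = ok & (A > 0) & (B > 0) & (B < 1) & (C >= 0) & (C < 1)
        lp = np.where(ok, 0.0, -np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            a0, b0 = self.hyper["pi_bar_beta"]
            lp = lp + np.where(
                ok, (a0 - 1) * np.log(pi_bar) + (b0 - 1) * np.log1p(-pi_bar), 0.0
            )
            gm = self.hyper["gamma_mean"]
            lp = lp + np.where(ok, -np.sum(g, axis=-1) / gm, 0.0)
            kb, rb = self.hyper["beta_gamma"]
            lp = lp + np.where(
                ok, np.sum((kb - 1.0) * np.log(np.abs(b)) - rb * b, axis=-1), 0.0
            )
            if not self.uniform:
                sA = self.hyper["A_halfnormal_sd"]
                lp = lp + np.where(ok, -0.5 * (A / sA) ** 2, 0.0)
        return lp

    def gene_prior(self, theta):
        """Per-gene pi (walkers..., G)."""
        pi_bar, A, B, C, _, _ = self.split(theta)
        if self.uniform:
            return np.broadcast_to(
                pi_bar[..., None], pi_bar.shape + (self.null.shape[0],)
            )
        A = A[..., None]
        B = B[..., None]
        C = C[..., None]
        L = (1.0 - C) * A / (np.logaddexp(A, A * B) - np.logaddexp(A * B, 0.0))
        sig = C + L * expit(A * (self.x - B))
        return pi_bar[..., None] * sig

    def alt_loglik(self, g, b):
        """Summed alt log-likelihood per gene for hyperparameters (…, V)."""
        out = 0.0
        for i, _ in enumerate(self.classes):
            gi = g[..., i, None]   # (..., 1)
            bi = b[..., i, None]
            r = gi * bi
            # gammaln over distinct counts only, then scatter back per gene
            lg = gammaln(self._d_unique[i] + r) - gammaln(r)
            lg = lg[..., self._d_inverse[i]]
            log_denom = np.log(bi + self.M[i])
            out = out + (
                lg
                - self._lgamma_d1[i]
                + r * (np.log(bi) - log_denom)
                + self.d[i] * (np.log(self.M[i]) - log_denom)
            )
        return out

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        scalar = theta.ndim == 1
        if scalar:
            theta = theta[None, :]
        lp = self.log_prior(theta)
        ll = np.full(lp.shape, -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            th = theta[ok]
            _, _, _, _, g, b = self.split(th)
            pi = self.gene_prior(th)
            bad = np.max(pi, axis=-1) >= 1.0
            la = self.alt_loglik(g, b)
            llv = _mixture_loglik(np.clip(pi, 0.0, 1.0 - 1e-12), la, self.null)
            llv = np.where(bad, -np.inf, llv)
            ll[ok] = llv
        out = lp + ll
        return float(out[0]) if scalar else out


def _initial_point(post: _BulkPosterior):
    nV = len(post.classes)
    base = [0.03] if post.uniform else [0.03, 50.0, 0.7, 0.3]
    return np.array(base + [10.0] * nV + [0.8] * nV)


def _run_emcee(post: _BulkPosterior, config: BulkFitConfig):
    import emcee

    rng = np.random.default_rng(config.seed)
    nw = max(config.walkers, 2 * post.ndim + 2)
    p0 = _initial_point(post)
    init = np.empty((nw, post.ndim))
    for i in range(nw):
        while True:
            cand = p0 * np.exp(rng.normal(0, 0.2, size=post.ndim))
            # keep unit-interval params inside (0,1)
            names = post.names()
            for j, nm in enumerate(names):
                if nm in ("pi_bar", "B", "C"):
                    cand[j] = np.clip(cand[j], 1e-3, 0.97)
                if nm.startswith("gamma_bar"):
                    cand[j] = max(cand[j], 1.05)
            if np.isfinite(post(cand)):
                init[i] = cand
                break
    sampler = emcee.EnsembleSampler(
        nw, post.ndim, post, vectorize=True
    )
    sampler.random_state = np.random.RandomState(config.seed & 0x7FFFFFFF).get_state()
    sampler.run_mcmc(init, config.steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=config.warmup)  # (steps-warmup, nw, ndim)
    return np.moveaxis(chain, 0, 1)  # (chains, draws, ndim)


def _summarise(chain: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    import arviz as az

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, nm in enumerate(names):
            draws = chain[:, :, j]
            flat = draws.reshape(-1)
            ds = az.convert_to_dataset(draws)
            rows.append(
                {
                    "parameter": nm,
                    "mean": float(np.mean(flat)),
                    "sd": float(np.std(flat, ddof=1)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "n_eff": float(az.ess(ds)["x"].values),
                    "rhat": float(az.rhat(ds)["x"].values),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


# transforms for MAP: positives on log scale, unit-interval on logit scale
def _to_unconstrained(theta, names):
    z = np.array(theta, dtype=float)
    for j, nm in enumerate(names):
        if nm in ("pi_bar", "B", "C"):
            z[j] = logit(np.clip(theta[j], 1e-9, 1 - 1e-9))
        elif nm.startswith("gamma_bar"):
            z[j] = np.log(theta[j] - 1.0)
        else:
            z[j] = np.log(theta[j])
    return z


def _from_unconstrained(z, names):
    theta = np.array(z, dtype=float)
    for j, nm in enumerate(names):
        if nm in ("pi_bar", "B", "C"):
            theta[j] = expit(z[j])
        elif nm.startswith("gamma_bar"):
            theta[j] = 1.0 + np.exp(z[j])
        else:
            theta[j] = np.exp(z[j])
    return theta


def _run_map(post: _BulkPosterior, config: BulkFitConfig):
    names = post.names()
    rng = np.random.default_rng(config.seed)
    best = None
    for attempt in range(max(1, config.map_restarts)):
        p0 = _initial_point(post)
        if attempt > 0:
            p0 = p0 * np.exp(rng.normal(0, 0.3, size=post.ndim))
            for j, nm in enumerate(names):
                if nm in ("pi_bar", "B", "C"):
                    p0[j] = np.clip(p0[j], 1e-3, 0.97)
                if nm.startswith("gamma_bar"):
                    p0[j] = max(p0[j], 1.1)
        z0 = _to_unconstrained(p0, names)
        neg = lambda z: -post(_from_unconstrained(z, names))
        res = minimize(neg, z0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    theta = _from_unconstrained(best.x, names)
    return theta, names


def _posterior_outputs(genes, post, means: Dict[str, float], config):
    classes = post.classes
    rr = RelativeRiskParams(
        gamma_bar={v: means[f"gamma_bar_{v}"] for v in classes},
        beta_bar={v: means[f"beta_bar_{v}"] for v in classes},
    )
    if post.uniform:
        pi = np.full(len(genes), means["pi_bar"])
    else:
        sp = SigmoidPrior(means["pi_bar"], means["A"], means["B"], means["C"])
        pi = np.minimum(sp.prior(post.x), 1.0)
    d = {v: post.d[i] for i, v in enumerate(classes)}
    M = {v: post.M[i] for i, v in enumerate(classes)}
    p = ppa(pi, d, M, rr)
    table = bayesian_fdr(p, genes["gene"])
    return table, rr


def _fit(genes: pd.DataFrame, config: BulkFitConfig, uniform: bool) -> BulkFitResult:
    if len(genes) < config.min_genes:
        raise ValueError(
            f"insufficient data: {len(genes)} genes < min_genes={config.min_genes}"
        )
    d, M, x = _prepare_arrays(genes, config.classes, need_x=not uniform)
    post = _BulkPosterior(d, M, x, config.classes, config.hyperpriors, uniform)
    warns: list = []
    if config.method == "map":
        theta, names = _run_map(post, config)
        means = dict(zip(names, theta))
        summary = pd.DataFrame(
            {
                "mean": list(theta),
                "sd": np.nan,
                "q2.5": np.nan,
                "q97.5": np.nan,
                "n_eff": np.nan,
                "rhat": np.nan,
            },
            index=pd.Index(names, name="parameter"),
        )
        converged = True
    elif config.method == "mcmc":
        chain = _run_emcee(post, config)
        names = post.names()
        summary = _summarise(chain, names)
        means = summary["mean"].to_dict()
        converged = bool((summary["rhat"] < 1.1).all())
        if not converged:
            warns.append(
                "Rhat > 1.1 for: "
                + ", ".join(summary.index[summary["rhat"] >= 1.1])
            )
            warnings.warn(warns[-1])
    else:
        raise ValueError(f"unknown method {config.method!r}")
    table, rr = _posterior_outputs(genes, post, means, config)
    return BulkFitResult(summary, table, means, rr, converged, tuple(warns))


def fit_bulk(genes: pd.DataFrame, config: Optional[BulkFitConfig] = None) -> BulkFitResult:
    """Fit the sigmoid-prior mixture model to a bulk gene table.

    ``genes`` needs columns ``gene``, ``d_<class>``, ``M_<class>`` per variant
    class, and a scalar expression rank column ``x`` in [0, 1].  Returns
    posterior summaries for the 8 parameters and the per-gene PPA/FDR table
    computed at posterior means.
    """
    return _fit(genes, config or BulkFitConfig(), uniform=False)


def fit_uniform_prior(
    genes: pd.DataFrame, config: Optional[BulkFitConfig] = None
) -> BulkFitResult:
    """Fit the expression-free baseline (constant prior ``pi_g = pi_bar``).

    Same Gamma-Poisson mixture with 5 free parameters; the extTADA-style
    comparator used in all power studies.
    """
    return _fit(genes, config or BulkFitConfig(), uniform=True)
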