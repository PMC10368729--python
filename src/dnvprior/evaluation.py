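"""Calibration, power and baseline metrics for posterior gene tables.

These are the readouts of the simulation studies: realized false-discovery
proportion against the nominal Bayesian FDR, precision-recall over PPA
thresholds, recall stratified by mutation rate, and the single-tail Poisson
test with Benjamini-Hochberg correction as the frequentist baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .core_stats import null_loglik

__all__ = [
    "realized_fdr",
    "precision_recall",
    "recall_by_mutation_rate",
    "poisson_baseline",
]


def _align_truth(posterior: pd.DataFrame, truth: pd.Series,
                 exclude: Optional[Iterable[str]] = None) -> pd.DataFrame:
    tab = posterior.copy()
    truth = pd.Series(truth)
    common = tab["gene"].isin(truth.index)
    if not common.any():
        raise ValueError("no overlap between posterior genes and truth genes")
    tab = tab[common]
    if exclude is not None:
        tab = tab[~tab["gene"].isin(set(exclude))]
    tab = tab.copy()
    tab["is_risk"] = truth.reindex(tab["gene"]).to_numpy().astype(int)
    return tab


def realized_fdr(
    posterior: pd.DataFrame,
    truth: pd.Series,
    cutoffs: Sequence[float] = (0.01, 0.05, 0.1, 0.2),
    exclude: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Realized false-discovery proportion at each nominal Bayesian FDR cutoff.

    ``posterior`` is a table with columns gene/PPA/FDR; ``truth`` a Series of
    0/1 risk indicators indexed by gene; ``exclude`` removes genes (e.g. the
    semi-supervision labels) before thresholding.  A cutoff with zero
    discoveries reports FDP 0 with ``n_discoveries`` 0.
    """
    tab = _align_truth(posterior, truth, exclude)
    rows = []
    for c in sorted(cutoffs):
        sel = tab[tab["FDR"] <= c]
        n = len(sel)
        fp = int((sel["is_risk"] == 0).sum())
        rows.append(
            {"cutoff": c, "realized_fdp": fp / max(1, n), "n_discoveries": n}
        )
    return pd.DataFrame(rows)


def precision_recall(
    posterior: pd.DataFrame,
    truth: pd.Series,
    exclude: Optional[Iterable[str]] = None,
    fdr_limit: Optional[float] = None,
) -> pd.DataFrame:
    """Precision-recall pairs over the PPA-descending threshold sweep.

    Recall denominators count all true risk genes after exclusions; with
    ``fdr_limit`` set, only the curve segment with estimated FDR below the
    limit is returned (the published curves stop at FDR 0.2).
    """
    tab = _align_truth(posterior, truth, exclude)
    tab = tab.sort_values("PPA", ascending=False, kind="stable")
    n_true = int(tab["is_risk"].sum())
    if n_true == 0:
        raise ValueError("truth contains no risk genes after exclusions")
    tp = np.cumsum(tab["is_risk"].to_numpy())
    k = np.arange(1, len(tab) + 1)
    out = pd.DataFrame(
        {
            "PPA": tab["PPA"].to_numpy(),
            "FDR": tab["FDR"].to_numpy(),
            "precision": tp / k,
            "recall": tp / n_true,
        }
    )
    if fdr_limit is not None:
        out = out[out["FDR"] <= fdr_limit]
    return out.reset_index(drop=True)


def recall_by_mutation_rate(
    posterior: pd.DataFrame,
    truth: pd.Series,
    mutation_rate: pd.Series,
    n_bins: int = 5,
    fdr_cutoff: float = 0.05,
    exclude: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Recall at the FDR cutoff within mutation-rate bins (default quintiles).

    ``mutation_rate`` is a per-gene Series (e.g. summed class rates); bins
    with no true risk genes report recall as NaN.
    """
    tab = _align_truth(posterior, truth, exclude)
    rates = pd.Series(mutation_rate).reindex(tab["gene"]).to_numpy(dtype=float)
    edges = np.quantile(rates, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bins = np.digitize(rates, edges[1:-1])
    disc = tab["FDR"].to_numpy() <= fdr_cutoff
    is_risk = tab["is_risk"].to_numpy().astype(bool)
    rows = []
    for b in range(n_bins):
        m = bins == b
        nt = int((is_risk & m).sum())
        rows.append(
            {
                "bin": b,
                "n_genes": int(m.sum()),
                "n_true": nt,
                "recall": (int((is_risk & m & disc).sum()) / nt) if nt else np.nan,
            }
        )
    return pd.DataFrame(rows)


def poisson_baseline(
    genes: pd.DataFrame,
    classes: Sequence[str] = ("LGD", "Dmis"),
    combine: str = "bonferroni",
) -> pd.DataFrame:
    """Single-tail Poisson tests per gene with BH correction across genes.

    Per class, ``p = P(X >= d | Poisson(M))``; classes are combined either by
    a Bonferroni-corrected minimum (default, ``min(1, n_classes * min_p)``) or
    by Fisher's method.  Returns per-gene p and BH q values.
    """
    pvals = {}
    for v in classes:
        d = genes[f"d_{v}"].to_numpy(dtype=float)
        M = genes[f"M_{v}"].to_numpy(dtype=float)
        null_loglik(d, M)  # validates domains
        pvals[v] = poisson.sf(d - 1, M)  # P(X >= d)
    P = np.column_stack([pvals[v] for v in classes])
    if combine == "bonferroni":
        p = np.minimum(1.0, len(classes) * P.min(axis=1))
    elif combine == "fisher":
        from scipy.stats import combine_pvalues

        p = np.array([combine_pvalues(row, method="fisher").pvalue for row in P])
    else:
        raise ValueError(f"unknown combine {combine!r}")
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"gene": genes["gene"], "p": p, "q": q})
    for v in classes:
        out[f"p_{v}"] = pvals[v]
    return out
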