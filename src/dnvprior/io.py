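"""Table and sparse-matrix I/O, gene filtering and run manifests.

Formats: TSV throughout for gene tables (columns ``gene, dn_LGD, dn_Dmis``
for counts; ``gene, mu_LGD, mu_Dmis`` for per-haploid per-generation rates or
``gene, M_LGD, M_Dmis`` for pre-aggregated expected null counts); MatrixMarket
triplets plus name files for sparse cells x genes input; one-gene-per-line
text for label and exclusion lists.

Gene identifiers are matched as exact strings; alias resolution is the
caller's responsibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("dnvprior")

__all__ = [
    "GeneFilterPolicy",
    "RunManifest",
    "load_dnv_table",
    "load_mutation_rates",
    "build_gene_table",
    "load_expression_bulk",
    "load_expression_sc_table",
    "load_expression_sc_mtx",
    "join_expression",
    "load_gene_list",
    "write_manifest",
]

#: gene families excluded from association analysis (high mutability /
#: mapping artefacts): olfactory receptors, HLA, mucins
DEFAULT_EXCLUDE_PATTERNS = (r"^OR\d+[A-Z]", r"^HLA-", r"^MUC\d")


@dataclass
class GeneFilterPolicy:
    """Symbol-pattern exclusion applied before any model fitting."""

    patterns: Tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS
    extra_symbols: Tuple[str, ...] = ()

    def excluded(self, genes: Iterable[str]) -> List[str]:
        regs = [re.compile(p) for p in self.patterns]
        extra = set(self.extra_symbols)
        return [
            g for g in genes
            if g in extra or any(r.match(str(g)) for r in regs)
        ]

    def apply(self, table: pd.DataFrame, col: str = "gene") -> pd.DataFrame:
        drop = set(self.excluded(table[col]))
        if drop:
            logger.info("gene filter removed %d genes: %s%s", len(drop),
                        ", ".join(sorted(drop)[:8]),
                        " ..." if len(drop) > 8 else "")
        return table[~table[col].isin(drop)].reset_index(drop=True)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_dnv_table(
    path,
    policy: Optional[GeneFilterPolicy] = None,
    classes: Sequence[str] = ("LGD", "Dmis"),
) -> pd.DataFrame:
    """Read a per-gene DNV count table (columns ``gene, dn_<class>...``).

    Duplicate gene rows are summed with a warning; excluded-family genes are
    dropped and logged; negative counts are a hard error naming the row.
    """
    cols = [f"dn_{v}" for v in classes]
    df = _read_tsv(path, ["gene"] + cols)
    for c in cols:
        bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() | (df[c] < 0)]
        if len(bad):
            raise ValueError(
                f"{path}: invalid count in column {c} at row(s) {list(bad[:5])}"
            )
    dup = df["gene"].duplicated()
    if dup.any():
        logger.warning("summing %d duplicated gene rows", int(dup.sum()))
        df = df.groupby("gene", as_index=False, sort=False)[cols].sum()
    if policy is not None:
        df = policy.apply(df)
    return df.rename(columns={f"dn_{v}": f"d_{v}" for v in classes})


def load_mutation_rates(
    path,
    classes: Sequence[str] = ("LGD", "Dmis"),
    dialect: str = "mu",
    n_trios: Optional[int] = None,
) -> pd.DataFrame:
    """Read per-gene mutation rates and return expected null counts ``M``.

    ``dialect='mu'`` expects per-generation per-haploid rates ``mu_<class>``
    and requires ``n_trios`` (``M = 2 * n_trios * mu``); ``dialect='M'``
    expects pre-aggregated ``M_<class>`` columns used as-is.
    """
    if dialect == "mu":
        if n_trios is None or n_trios <= 0:
            raise ValueError("dialect='mu' requires a positive n_trios")
        df = _read_tsv(path, ["gene"] + [f"mu_{v}" for v in classes])
        for v in classes:
            df[f"M_{v}"] = 2.0 * n_trios * df[f"mu_{v}"].astype(float)
    elif dialect == "M":
        df = _read_tsv(path, ["gene"] + [f"M_{v}" for v in classes])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for v in classes:
        if (df[f"M_{v}"] <= 0).any():
            row = df.index[df[f"M_{v}"] <= 0][0]
            raise ValueError(f"{path}: non-positive rate at row {row} ({v})")
    return df[["gene"] + [f"M_{v}" for v in classes]]


def build_gene_table(
    counts: pd.DataFrame,
    rates: pd.DataFrame,
    classes: Sequence[str] = ("LGD", "Dmis"),
) -> pd.DataFrame:
    """Inner-join counts and rates into the canonical modelling table.

    Genes present in only one input are dropped with a log line; missing
    counts for a rate-covered gene are treated as 0 only if explicitly listed.
    """
    merged = counts.merge(rates, on="gene", how="inner")
    lost = len(counts) - len(merged)
    if lost:
        logger.info("dropped %d genes without mutation-rate entries", lost)
    return merged


def load_expression_bulk(
    path,
    value_col: Optional[str] = None,
    compute_rank: bool = False,
) -> pd.Series:
    """Read a bulk expression file and return per-gene rank percentile.

    With ``compute_rank=False`` the value column must already be a rank in
    [0, 1]; with ``compute_rank=True`` raw expression values are converted to
    rank percentiles (average ranks for ties, divided by gene count, so the
    result lies in (0, 1]).
    """
    df = _read_tsv(path, ["gene"])
    if value_col is None:
        candidates = [c for c in df.columns if c != "gene"]
        if len(candidates) != 1:
            raise ValueError(f"ambiguous value column, specify one of {candidates}")
        value_col = candidates[0]
    vals = pd.to_numeric(df[value_col], errors="raise").astype(float)
    if compute_rank:
        out = vals.rank(method="average") / len(vals)
    else:
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("rank values outside [0, 1]; use compute_rank=True for raw values")
        out = vals
    out.index = df["gene"]
    return out.rename("x")


def load_expression_sc_table(path) -> pd.DataFrame:
    """Read a precomputed genes x cell-types TSV of fraction-expressing values."""
    df = _read_tsv(path, ["gene"]).set_index("gene")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{path}: fraction-expressing values outside [0, 1]")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def load_expression_sc_mtx(
    mtx_path,
    gene_names_path,
    cell_annotation_path,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Build the fraction-expressing matrix from a sparse cells x genes MTX.

    The annotation TSV needs columns ``cell_id, cell_type, timepoint`` (and
    optionally ``source_batch``); cell types are the timepoint-resolved
    annotation pairs, written ``<timepoint>|<cell_type>``.  Cell types backed
    by fewer than ``min_cells`` cells are removed (and logged).
    """
    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    genes = [l.strip() for l in Path(gene_names_path).read_text().splitlines() if l.strip()]
    ann = _read_tsv(cell_annotation_path, ["cell_id", "cell_type", "timepoint"])
    if mat.shape[0] != len(ann):
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but annotation lists {len(ann)}"
        )
    if mat.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but names file lists {len(genes)}"
        )
    ct = ann["timepoint"].astype(str) + "|" + ann["cell_type"].astype(str)
    nonzero = mat != 0
    cols = {}
    for label, idx in ct.groupby(ct).groups.items():
        rows = np.asarray(idx, dtype=int)
        if len(rows) < min_cells:
            logger.info("removed cell type %s with %d cells (< %d)",
                        label, len(rows), min_cells)
            continue
        frac = np.asarray(nonzero[rows].sum(axis=0)).ravel() / len(rows)
        cols[label] = frac
    if not cols:
        raise ValueError("no cell type passed the minimum-cell filter")
    return pd.DataFrame(cols, index=genes)


def join_expression(
    gene_table: pd.DataFrame,
    expression,
    missing: str = "drop",
) -> pd.DataFrame:
    """Attach the bulk covariate ``x`` (a per-gene Series) to the gene table.

    Genes without expression are dropped (default, logged) or imputed 0
    (``missing='impute0'``).
    """
    expr = pd.Series(expression)
    out = gene_table.copy()
    out["x"] = expr.reindex(out["gene"]).to_numpy()
    absent = out["x"].isna()
    if absent.any():
        if missing == "drop":
            logger.info("dropped %d genes without expression", int(absent.sum()))
            out = out[~absent].reset_index(drop=True)
        elif missing == "impute0":
            out.loc[absent, "x"] = 0.0
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    return out


def load_gene_list(path) -> List[str]:
    """One-gene-per-line text list (blank lines and #-comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    seed: int
    config: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)   # path -> md5
    version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        cfg_hash = hashlib.md5(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "config_hash": cfg_hash,
                "inputs": self.inputs,
                "version": self.version,
                "timestamp": self.timestamp,
            },
            indent=2,
            default=str,
        )


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, seed: int, config: Dict[str, object],
                   input_paths: Sequence[str] = ()) -> Path:
    """Write a reproducibility manifest (seed, config hash, input checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = RunManifest(
        seed=seed,
        config=config,
        inputs={str(p): _md5(p) for p in input_paths if Path(p).exists()},
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = out_dir / "manifest.json"
    path.write_text(man.to_json())
    return path
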