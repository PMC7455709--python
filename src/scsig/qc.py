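"""Cell and gene quality control, log-normalization, relative expression.

The QC cascade removes (i) cells whose mitochondrial UMI fraction exceeds
30% (damaged cells with compromised membranes), (ii) likely multiplets whose
log library size exceeds 2 median absolute deviations above the median,
(iii) low-quality cells detecting fewer than 500 genes, then (iv) genes seen
in fewer than 5 cells.  The three cell rules are evaluated jointly on the
input matrix and their removals unioned; gene filtering runs on the
cell-filtered matrix.  All boundary comparisons are strict: a cell at
exactly 30% mitochondrial UMIs or exactly 500 genes is retained.

Normalization is the standard library-size log transform
``ln(1 + count / cell_total * scale_factor)`` and "relative" expression is
per-gene centering (optionally unit variance) across all cells in the
aggregated cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_cells",
    "qc_genes",
    "log_normalize",
    "relative_expression",
]


@dataclass
class QCThresholds:
    max_mito_frac: float = 0.30
    min_genes_per_cell: int = 500
    libsize_mad_mult: float = 2.0
    min_cells_per_gene: int = 5
    mito_prefix: str = "MT-"
    mad_scaled: bool = False  # True: normal-consistent MAD (x1.4826)

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")
        if min(self.min_genes_per_cell, self.libsize_mad_mult, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    cell_metrics: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def _dense_sum(X, axis):
    out = np.asarray(X.sum(axis=axis)).ravel()
    return out


def cell_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metric table: genes detected, total UMIs, mito fraction,
    natural-log library size."""
    X = adata.X
    total = _dense_sum(X, axis=1).astype(float)
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        n_genes = (np.asarray(X) > 0).sum(axis=1)
    mito_mask = np.asarray(adata.var_names.str.startswith(mito_prefix))
    if "mito" in adata.var:
        mito_mask = mito_mask | adata.var["mito"].to_numpy(dtype=bool)
    if mito_mask.any():
        mito_total = _dense_sum(X[:, mito_mask], axis=1).astype(float)
    else:
        mito_total = np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1e-300), 0.0)
        log_lib = np.where(total > 0, np.log(np.maximum(total, 1e-300)), -np.inf)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "total_umis": total.astype(np.int64),
            "mito_fraction": mito_frac,
            "log_libsize": log_lib,
        },
        index=adata.obs_names,
    )


def qc_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Apply the three cell-level QC rules jointly and drop flagged cells."""
    thr = thresholds or QCThresholds()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")

    metrics = cell_metrics(adata, thr.mito_prefix)

    has_mito = adata.var_names.str.startswith(thr.mito_prefix).any() or (
        "mito" in adata.var and bool(adata.var["mito"].any())
    )
    if has_mito:
        mito_bad = metrics["mito_fraction"].to_numpy() > thr.max_mito_frac
    else:
        warnings.warn(
            f"no genes match mitochondrial prefix {thr.mito_prefix!r}; "
            "mitochondrial-fraction rule skipped",
            stacklevel=2,
        )
        mito_bad = np.zeros(adata.n_obs, dtype=bool)

    log_lib = metrics["log_libsize"].to_numpy()
    med = np.median(log_lib)
    mad = np.median(np.abs(log_lib - med))
    if thr.mad_scaled:
        mad *= 1.4826
    multiplet_bad = log_lib > med + thr.libsize_mad_mult * mad

    genes_bad = metrics["n_genes_detected"].to_numpy() < thr.min_genes_per_cell

    keep = ~(mito_bad | multiplet_bad | genes_bad)
    out = adata[keep].copy()
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=adata.n_vars,
        removed_by_rule={
            "mito_fraction": int(mito_bad.sum()),
            "libsize_mad": int(multiplet_bad.sum()),
            "min_genes": int(genes_bad.sum()),
            "any": int((~keep).sum()),
        },
        cell_metrics=metrics,
    )
    return out, report


def qc_genes(
    adata: ad.AnnData, min_cells_per_gene: int = 5, report: QCReport | None = None
) -> ad.AnnData:
    """Drop genes detected (nonzero) in fewer than ``min_cells_per_gene`` cells."""
    X = adata.X
    if sp.issparse(X):
        n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_cells = (np.asarray(X) > 0).sum(axis=0)
    keep = n_cells >= min_cells_per_gene
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    out = adata[:, keep].copy()
    if report is not None:
        report.n_genes_out = out.n_vars
        report.removed_by_rule["min_cells_per_gene"] = int((~keep).sum())
    return out


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size log normalization: ``ln(1 + count/total * scale_factor)``."""
    totals = _dense_sum(adata.X, axis=1)
    if np.any(totals <= 0):
        raise ValueError("cell with zero library size; run QC first")
    out = adata.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale_factor)
    sc.pp.log1p(out)
    return out


def relative_expression(
    norm: ad.AnnData, unit_variance: bool = True, clip: float | None = None
) -> ad.AnnData:
    """Center each gene across all cells (optionally scale to unit variance).

    Constant genes are left at 0.  ``clip`` caps absolute values (some
    scoring workflows clip scaled expression at 10); default is no clipping.
    """
    out = norm.copy()
    out.X = out.X.astype(np.float64)  # centering in double precision
    if unit_variance:
        sc.pp.scale(out, zero_center=True, max_value=None)
    else:
        X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
        out.X = X - X.mean(axis=0, keepdims=True)
    if clip is not None:
        out.X = np.clip(out.X, -clip, clip)
    return out
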