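"""Signature scoring: module scores, single-sample GSEA, bulk signature index.

Three scorers are implemented:

``module_score``
    Per-cell score for a gene set: the mean relative (centered) expression of
    the signature genes minus the mean over a control pool of
    expression-matched genes.  Controls are built by binning all expressed
    genes into equal-frequency bins of aggregate (mean log-normalized)
    expression and, for each signature gene, sampling ``n_ctrl_per_gene``
    genes from that gene's bin.  Matching controls on expression level
    removes the library-depth component of the raw average.

``ssgsea_score``
    Rank-weighted running-sum enrichment of a gene set within one sample:
    genes are ranked by expression, the weighted ECDF of signature ranks
    (weights ``rank ** alpha``) is integrated against the ECDF of the
    complement, and scores are optionally normalized by the range across the
    samples scored in the call.

``signature_index``
    Per-patient mean log2 expression over a signature's same-direction
    genes, ``(Σ_{g∈R} x_g) / n_R`` — the bulk index used for tertile
    survival stratification.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = [
    "GeneSignature",
    "ScoringParams",
    "bin_genes_by_expression",
    "module_score",
    "ssgsea_score",
    "signature_index",
]


@dataclass
class GeneSignature:
    """Named gene set with a direction tag.

    ``genes`` keeps first-seen order with duplicates removed; ``direction``
    is ``"up"``, ``"down"`` or ``"mixed"``.
    """

    name: str
    genes: list[str]
    direction: str = "up"
    description: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dups = [g for g in self.genes if g in seen or seen.setdefault(g, None)]
        if dups:
            warnings.warn(
                f"signature {self.name!r}: {len(dups)} duplicate genes dropped",
                stacklevel=2,
            )
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError("direction must be 'up', 'down' or 'mixed'")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, gene_names) -> list[str]:
        """Genes of the signature present in ``gene_names`` (signature order).

        Absent genes are dropped (logged) rather than treated as zeros; the
        effective signature size n_R is the length of the returned list.
        """
        available = set(map(str, gene_names))
        present = [g for g in self.genes if g in available]
        n_drop = len(self.genes) - len(present)
        if n_drop:
            warnings.warn(
                f"signature {self.name!r}: {n_drop} genes absent from the "
                f"matrix dropped (n_R = {len(present)})",
                stacklevel=2,
            )
        return present


@dataclass
class ScoringParams:
    n_bins: int = 25
    n_ctrl_per_gene: int = 100
    seed: int = 0
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def _signature_rng(seed: int, name: str) -> np.random.Generator:
    # one stream per (signature, seed): reproducible and independent of the
    # order in which signatures are scored
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def bin_genes_by_expression(norm: ad.AnnData, n_bins: int = 25) -> pd.Series:
    """Assign every gene to one of ``n_bins`` equal-frequency bins of mean
    log-normalized expression.

    Genes are sorted ascending by mean expression (ties broken by input gene
    order, stable) and cut into consecutive bins; when the gene count is not
    divisible by ``n_bins`` the remainder is allocated one gene each to the
    lowest bins, so bin sizes are non-increasing from bin 0 upward.
    """
    n_genes = norm.n_vars
    if n_bins > n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds the {n_genes} genes")
    means = np.asarray(_as_dense(norm.X).mean(axis=0)).ravel()
    order = np.argsort(means, kind="stable")
    base, rem = divmod(n_genes, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(bins, index=norm.var_names, name="expression_bin")


def module_score(
    relative: ad.AnnData,
    sig: GeneSignature,
    params: ScoringParams | None = None,
    bins: pd.Series | None = None,
) -> pd.Series:
    """Bin-matched control module score for one signature, per cell.

    ``relative`` holds centered relative expression; ``bins`` is the
    gene -> expression-bin map computed on the matching log-normalized
    matrix (required — binning on centered values would be meaningless).
    The control pool is the multiset union over signature genes of
    ``n_ctrl_per_gene`` genes sampled without replacement from each gene's
    bin; a bin smaller than ``n_ctrl_per_gene`` is sampled with replacement
    (with a warning).
    """
    params = params or ScoringParams()
    if bins is None:
        raise ValueError(
            "bins is required: compute bin_genes_by_expression on the "
            "log-normalized matrix"
        )
    genes = sig.present_in(relative.var_names)
    if not genes:
        raise ValueError(f"no genes of signature {sig.name!r} in the matrix")

    X = _as_dense(relative.X)
    col = {g: i for i, g in enumerate(relative.var_names)}
    bin_members: dict[int, np.ndarray] = {
        b: idx.to_numpy() for b, idx in pd.Series(
            np.arange(relative.n_vars), index=bins.to_numpy()
        ).groupby(level=0)
    }

    rng = _signature_rng(params.seed, sig.name)
    ctrl_cols: list[np.ndarray] = []
    warned = False
    for g in genes:
        members = bin_members[int(bins.loc[g])]
        if len(members) >= params.n_ctrl_per_gene:
            pick = rng.choice(members, size=params.n_ctrl_per_gene, replace=False)
        else:
            if not warned:
                warnings.warn(
                    f"bin of gene {g!r} has {len(members)} genes "
                    f"< n_ctrl_per_gene={params.n_ctrl_per_gene}; sampling "
                    "with replacement",
                    stacklevel=2,
                )
                warned = True
            pick = rng.choice(members, size=params.n_ctrl_per_gene, replace=True)
        ctrl_cols.append(pick)
    ctrl = np.concatenate(ctrl_cols)  # multiset: duplicates count

    sig_cols = np.array([col[g] for g in genes])
    # means as weighted matvecs (multiset weights = draw multiplicities)
    ctrl_w = np.bincount(ctrl, minlength=relative.n_vars) / len(ctrl)
    score = X[:, sig_cols].mean(axis=1) - X @ ctrl_w
    return pd.Series(score, index=relative.obs_names, name=sig.name)


def _ssgsea_one(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Unnormalized ssGSEA enrichment for one sample.

    ``expr`` is the sample's expression vector, ``in_set`` a boolean mask of
    signature membership.  Genes are walked from highest to lowest
    expression; the running weighted ECDF of signature genes (weight =
    expression rank ** alpha, average ranks for ties) minus the ECDF of the
    complement is summed over all positions.
    """
    n = len(expr)
    n_r = int(in_set.sum())
    ranks = rankdata(expr, method="average")  # highest expression -> rank n
    order = np.argsort(-expr, kind="stable")
    in_ord = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    num = np.where(in_ord, w, 0.0)
    p_in = np.cumsum(num) / num.sum()
    p_out = np.cumsum(~in_ord) / (n - n_r)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: ad.AnnData | pd.DataFrame,
    sigs: GeneSignature | list[GeneSignature],
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Rank-based single-sample enrichment scores.

    ``expr`` is samples x genes (AnnData) or genes x samples (DataFrame,
    the bulk convention).  Returns a samples x signatures DataFrame.  With
    ``ssgsea_normalize`` the scores are divided by the overall range
    (max - min) across every sample and signature scored in this call.
    """
    params = params or ScoringParams()
    single = isinstance(sigs, GeneSignature)
    sig_list = [sigs] if single else list(sigs)

    if isinstance(expr, ad.AnnData):
        X = _as_dense(expr.X)
        gene_names = list(expr.var_names)
        sample_names = list(expr.obs_names)
    else:
        X = expr.to_numpy(dtype=float).T  # -> samples x genes
        gene_names = list(expr.index)
        sample_names = list(expr.columns)

    n_genes = len(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    masks = []
    for sig in sig_list:
        genes = sig.present_in(gene_names)
        if not genes:
            raise ValueError(f"no genes of signature {sig.name!r} in the matrix")
        if len(genes) >= n_genes:
            raise ValueError(
                f"signature {sig.name!r} covers every gene; complement is empty"
            )
        mask = np.zeros(n_genes, dtype=bool)
        mask[[col[g] for g in genes]] = True
        masks.append(mask)

    scores = np.empty((len(sample_names), len(sig_list)))
    for s in range(len(sample_names)):
        x = X[s]
        ranks = rankdata(x, method="average")
        order = np.argsort(-x, kind="stable")
        w_all = np.abs(ranks[order]) ** params.ssgsea_alpha
        for k, mask in enumerate(masks):
            in_ord = mask[order]
            num = np.where(in_ord, w_all, 0.0)
            p_in = np.cumsum(num) / num.sum()
            p_out = np.cumsum(~in_ord) / (n_genes - int(mask.sum()))
            scores[s, k] = np.sum(p_in - p_out)

    if params.ssgsea_normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
    return pd.DataFrame(
        scores, index=sample_names, columns=[s.name for s in sig_list]
    )


def signature_index(
    log2_expr: pd.DataFrame, sig: GeneSignature, direction: str | None = None
) -> pd.Series:
    """Per-patient signature index: mean log2 expression over the signature.

    ``log2_expr`` is genes x patients on the log2 scale.  Only genes
    regulated in one direction enter the index; a mixed-direction signature
    must be resolved with ``direction`` ("up" keeps the index as the mean,
    "down" negates it).
    """
    direction = direction or (sig.direction if sig.direction != "mixed" else None)
    if direction is None:
        raise ValueError(
            f"signature {sig.name!r} is mixed-direction; pass direction="
            "'up' or 'down'"
        )
    genes = sig.present_in(log2_expr.index)
    if not genes:
        raise ValueError(f"no genes of signature {sig.name!r} in the matrix")
    idx = log2_expr.loc[genes].mean(axis=0)
    if direction == "down":
        idx = -idx
    idx.name = sig.name
    return idx
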