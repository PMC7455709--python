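"""Random-gene-set empirical null and per-cell enrichment classification.

To decide whether a cell's signature score is larger than expected by
chance, many random gene sets of the same size as the signature are drawn
uniformly from all expressed genes and scored with the same scorer.  The
scores of every cell under every random set are pooled into a single null
distribution per signature, and its empirical upper quantile at the nominal
level (default 5%) becomes the enrichment threshold.  A cell is classified
"enriched" only when its observed score strictly surpasses that threshold.
Random sets are drawn uniformly (not expression-matched): the module scorer
already matches controls on expression, and matching the null sets as well
would apply the correction twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .scoring import GeneSignature, ScoringParams, module_score, ssgsea_score

__all__ = [
    "NullParams",
    "NullModel",
    "sample_null_sets",
    "null_threshold",
    "classify_enriched",
    "enrichment_by_sample",
    "build_null_model",
]


@dataclass
class NullParams:
    n_random_sets: int = 100
    level: float = 0.05
    seed: int = 0
    scorer: str = "module"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if self.scorer not in ("module", "ssgsea"):
            raise ValueError("scorer must be 'module' or 'ssgsea'")


@dataclass
class NullModel:
    signature: str
    sig_size: int
    null_scores: np.ndarray
    threshold: float
    level: float
    scorer: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "signature": self.signature,
            "sig_size": self.sig_size,
            "threshold": self.threshold,
            "level": self.level,
            "scorer": self.scorer,
            "seed": self.seed,
            "n_null_scores": int(len(self.null_scores)),
        }


def sample_null_sets(
    universe, size: int, params: NullParams | None = None
) -> list[list[str]]:
    """Draw ``n_random_sets`` gene sets of ``size`` distinct genes uniformly
    from the universe (all expressed genes post-QC); seeded, reproducible."""
    params = params or NullParams()
    genes = np.asarray(sorted(map(str, universe)))
    if size > len(genes):
        raise ValueError(f"set size {size} exceeds universe of {len(genes)} genes")
    rng = np.random.default_rng(params.seed)
    return [
        list(rng.choice(genes, size=size, replace=False))
        for _ in range(params.n_random_sets)
    ]


def null_threshold(null_scores, level: float = 0.05) -> float:
    """Empirical upper (1 - level) quantile of the pooled null scores.

    Uses the linear-interpolation quantile rule (numpy's default, "type 7"):
    the threshold interpolates between order statistics, so e.g. scores
    1..100 at level 0.05 give 95.05.
    """
    scores = np.asarray(null_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("null_scores is empty")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return float(np.quantile(scores, 1.0 - level))


def build_null_model(
    relative: ad.AnnData,
    sig: GeneSignature,
    params: NullParams | None = None,
    scoring_params: ScoringParams | None = None,
    bins: pd.Series | None = None,
    norm: ad.AnnData | None = None,
) -> NullModel:
    """Score ``n_random_sets`` random size-matched gene sets on every cell
    and pool them into a single per-signature null distribution.

    ``relative`` is the matrix the chosen scorer consumes (centered relative
    expression for the module scorer; any monotone-equivalent expression for
    ssGSEA).  The module scorer additionally needs ``bins`` (or ``norm`` to
    compute them).
    """
    params = params or NullParams()
    scoring_params = scoring_params or ScoringParams(seed=params.seed)
    genes = sig.present_in(relative.var_names)
    if not genes:
        raise ValueError(f"no genes of signature {sig.name!r} in the matrix")
    size = len(genes)

    if params.scorer == "module" and bins is None:
        if norm is None:
            raise ValueError("module scorer needs bins or the log-normalized matrix")
        from .scoring import bin_genes_by_expression

        bins = bin_genes_by_expression(norm, scoring_params.n_bins)

    sets = sample_null_sets(relative.var_names, size, params)
    pooled = []
    for i, members in enumerate(sets):
        rand_sig = GeneSignature(name=f"__null_{sig.name}_{i}", genes=members)
        if params.scorer == "module":
            s = module_score(relative, rand_sig, scoring_params, bins=bins)
        else:
            s = ssgsea_score(relative, rand_sig, scoring_params).iloc[:, 0]
        pooled.append(s.to_numpy())
    null_scores = np.concatenate(pooled)
    return NullModel(
        signature=sig.name,
        sig_size=size,
        null_scores=null_scores,
        threshold=null_threshold(null_scores, params.level),
        level=params.level,
        scorer=params.scorer,
        seed=params.seed,
    )


def classify_enriched(
    scores: pd.DataFrame | pd.Series, model: NullModel, scorer: str | None = None
) -> pd.DataFrame:
    """Label each cell enriched iff its score strictly surpasses the null
    threshold.

    ``scores`` is a per-cell Series (index = cell ids) or a DataFrame with
    columns (cell_id, sample_id, score).  ``scorer``, when given, is checked
    against the model's scorer (scores and null must come from the same
    method on the same matrix).
    """
    if scorer is not None and scorer != model.scorer:
        raise ValueError(
            f"scores produced by {scorer!r} but null model by {model.scorer!r}"
        )
    if isinstance(scores, pd.Series):
        df = pd.DataFrame(
            {"cell_id": scores.index, "sample_id": "all", "score": scores.to_numpy()}
        )
    else:
        df = scores.copy()
        missing = {"cell_id", "score"} - set(df.columns)
        if missing:
            raise ValueError(f"scores table lacks columns {sorted(missing)}")
        if "sample_id" not in df:
            df["sample_id"] = "all"
    df["signature"] = model.signature
    df["enriched"] = df["score"].to_numpy() > model.threshold
    return df[["cell_id", "sample_id", "signature", "score", "enriched"]]


def enrichment_by_sample(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample enrichment summary: n_cells, n_enriched, proportion,
    plus a totals row labeled ``__total__``."""
    if "sample_id" not in calls or calls["sample_id"].isna().any():
        raise ValueError("every call must carry a sample id")
    empty = calls.groupby("sample_id").size() == 0
    if empty.any():  # pragma: no cover - groupby drops empty groups
        warnings.warn("samples with zero cells excluded", stacklevel=2)
    grp = calls.groupby("sample_id", sort=True)["enriched"]
    out = pd.DataFrame(
        {"n_cells": grp.size(), "n_enriched": grp.sum().astype(int)}
    )
    out["proportion"] = out["n_enriched"] / out["n_cells"]
    total = pd.DataFrame(
        {
            "n_cells": [len(calls)],
            "n_enriched": [int(calls["enriched"].sum())],
        },
        index=pd.Index(["__total__"], name="sample_id"),
    )
    total["proportion"] = total["n_enriched"] / total["n_cells"]
    return pd.concat([out, total])
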