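"""End-to-end pipeline: cell calling -> QC -> scoring -> classification.

A :class:`PipelineConfig` collects every stage's parameters plus the single
seed from which all per-stage RNG substreams are derived.  ``run_pipeline``
executes the single-cell branch (and optionally the bulk survival branch),
writes per-stage TSV/JSON artifacts into the output directory, and finishes
with a run manifest recording versions, the seed and the effective config,
so any output can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import pandas as pd
import yaml

from . import __version__
from .cellcalling import call_cells
from .io import read_clinical, read_counts, read_gmt, write_json, write_tsv
from .nullmodel import NullParams, build_null_model, classify_enriched, enrichment_by_sample
from .qc import QCThresholds, log_normalize, qc_cells, qc_genes, relative_expression
from .scoring import ScoringParams, bin_genes_by_expression, module_score, signature_index, ssgsea_score
from .survival import cox_fit, km_curve, logrank, tertile_split

log = logging.getLogger("scsig")

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed offsets deriving independent per-stage substreams from the run seed
_STAGE_SEED_OFFSET = {"scoring": 1, "null": 2}


@dataclass
class PipelineConfig:
    counts_path: str = ""
    gmt_path: str = ""
    out_dir: str = "scsig_out"
    seed: int = 0
    # cell calling
    barcode_reads_path: str | None = None
    knee_method: str = "secondderiv"
    # QC
    qc: QCThresholds = field(default_factory=QCThresholds)
    # scoring
    scoring: ScoringParams = field(default_factory=ScoringParams)
    scorer: str = "module"
    # null / classification
    null: NullParams = field(default_factory=NullParams)
    # bulk survival (optional branch)
    bulk_expr_path: str | None = None
    clinical_path: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["age", "metastatic_status", "subgroup"])
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCThresholds(**d["qc"])
        if isinstance(d.get("scoring"), dict):
            d["scoring"] = ScoringParams(**d["scoring"])
        if isinstance(d.get("null"), dict):
            d["null"] = NullParams(**d["null"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write artifacts under ``config.out_dir``.

    Returns the manifest dict.  Any stage error propagates as an exception
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "config.yaml")

    stages_run: list[str] = []
    artifacts: dict[str, str] = {}

    def _stage(name):
        stages_run.append(name)
        log.info("stage: %s", name)

    try:
        adata: ad.AnnData | None = None
        if config.counts_path:
            _stage("read_counts")
            adata = read_counts(config.counts_path)

            if config.barcode_reads_path:
                _stage("call_cells")
                reads = pd.read_csv(
                    config.barcode_reads_path, sep="\t", index_col=0
                ).iloc[:, 0]
                accepted, profile = call_cells(reads, knee_method=config.knee_method)
                adata = adata[adata.obs_names.isin(accepted)].copy()
                pd.Series(accepted).to_csv(
                    out / "accepted_barcodes.txt", index=False, header=False
                )
                write_json(
                    {
                        "n_input": int(len(reads)),
                        "knee_index": profile.knee_index,
                        "method": profile.method,
                    },
                    out / "cell_calling.json",
                )
                artifacts["cell_calling"] = "cell_calling.json"

            _stage("qc")
            adata, report = qc_cells(adata, config.qc)
            adata = qc_genes(adata, config.qc.min_cells_per_gene, report)
            write_json(report.to_dict(), out / "qc_report.json")
            write_tsv(report.cell_metrics, out / "cell_metrics.tsv")
            artifacts["qc_report"] = "qc_report.json"

            _stage("normalize")
            norm = log_normalize(adata)
            relative = relative_expression(norm)

            _stage("score")
            sigs = read_gmt(config.gmt_path)
            sp_ = dataclasses.replace(
                config.scoring, seed=config.seed + _STAGE_SEED_OFFSET["scoring"]
            )
            bins = bin_genes_by_expression(norm, sp_.n_bins)
            sample_ids = (
                adata.obs["sample"]
                if "sample" in adata.obs
                else pd.Series("all", index=adata.obs_names)
            )
            score_rows = []
            all_calls = []
            for sig in sigs:
                if config.scorer == "module":
                    scores = module_score(relative, sig, sp_, bins=bins)
                else:
                    scores = ssgsea_score(relative, sig, sp_).iloc[:, 0]
                score_rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": scores.index,
                            "sample_id": sample_ids.loc[scores.index].to_numpy(),
                            "signature": sig.name,
                            "method": config.scorer,
                            "score": scores.to_numpy(),
                        }
                    )
                )

                _stage(f"classify:{sig.name}")
                np_ = dataclasses.replace(
                    config.null,
                    seed=config.seed + _STAGE_SEED_OFFSET["null"],
                    scorer=config.scorer,
                )
                model = build_null_model(
                    relative, sig, np_, scoring_params=sp_, bins=bins
                )
                calls = classify_enriched(
                    pd.DataFrame(
                        {
                            "cell_id": scores.index,
                            "sample_id": sample_ids.loc[scores.index].to_numpy(),
                            "score": scores.to_numpy(),
                        }
                    ),
                    model,
                    scorer=config.scorer,
                )
                all_calls.append(calls)
                write_json(model.to_dict(), out / f"null_model_{sig.name}.json")

            score_table = pd.concat(score_rows, ignore_index=True)
            write_tsv(score_table, out / "cell_scores.tsv", index=False)
            artifacts["cell_scores"] = "cell_scores.tsv"
            calls_table = pd.concat(all_calls, ignore_index=True)
            write_tsv(calls_table, out / "enrichment_calls.tsv", index=False)
            artifacts["enrichment_calls"] = "enrichment_calls.tsv"
            props = pd.concat(
                [
                    enrichment_by_sample(g).assign(signature=name)
                    for name, g in calls_table.groupby("signature")
                ]
            )
            write_tsv(props, out / "enrichment_by_sample.tsv")
            artifacts["enrichment_by_sample"] = "enrichment_by_sample.tsv"

        if config.bulk_expr_path and config.clinical_path:
            _stage("survival")
            expr = pd.read_csv(config.bulk_expr_path, sep="\t", index_col=0)
            clinical = read_clinical(config.clinical_path)
            sigs = read_gmt(config.gmt_path)
            surv_report: dict = {}
            for sig in sigs:
                idx = signature_index(expr, sig)
                cohort = clinical.set_index("patient_id").copy()
                cohort["index"] = idx.reindex(cohort.index)
                cohort = cohort.dropna(subset=["index"])
                cohort["group"] = tertile_split(cohort["index"])
                km = {
                    g: km_curve(sub["time"], sub["event"])
                    for g, sub in cohort.groupby("group")
                }
                for g, est in km.items():
                    write_tsv(est.to_frame(), out / f"km_{sig.name}_{g}.tsv", index=False)
                chi2, df_, p = logrank(
                    cohort["time"], cohort["event"], cohort["group"]
                )
                uni = cox_fit(cohort.reset_index(), ["index"])
                covs = ["index"] + [
                    c for c in config.covariates if c in cohort.columns
                ]
                multi = cox_fit(cohort.reset_index(), covs)
                surv_report[sig.name] = {
                    "logrank": {"chi2": chi2, "df": df_, "p": p},
                    "median_survival": {
                        g: est.median for g, est in km.items()
                    },
                    "cox_univariate": uni.summary().to_dict(orient="index"),
                    "cox_multivariate": multi.summary().to_dict(orient="index"),
                }
                write_tsv(multi.summary(), out / f"cox_{sig.name}.tsv")
            write_json(surv_report, out / "survival_report.json")
            artifacts["survival_report"] = "survival_report.json"
    except Exception as exc:
        stage = stages_run[-1] if stages_run else "init"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "scsig_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": stages_run,
        "artifacts": artifacts,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
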