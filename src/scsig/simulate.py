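"""Synthetic droplet, single-cell and bulk-cohort generators.

These generators produce data with the statistical structure the rest of the
pipeline assumes, so every stage can be exercised and calibrated without any
external download:

* a droplet barcode pool with an ambient-RNA tail below a plateau of real
  cells (for knee-point cell calling);
* a negative-binomial UMI count matrix with log-normal gene means, per-cell
  library-size factors, a mitochondrial gene block, and a planted rare
  subpopulation whose signature genes are multiplicatively up-shifted
  (for QC, scoring and enrichment classification);
* a bulk expression cohort whose survival times follow a proportional-hazards
  model with a signature-index effect and independent censoring
  (for the tertile / Kaplan-Meier / Cox stage).

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; a fixed seed reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ScSimParams",
    "CohortSimParams",
    "SimTruth",
    "simulate_barcode_pool",
    "simulate_sc_counts",
    "simulate_bulk_cohort",
]

# log-normal read-count spread of the two droplet populations (cells are
# tighter than the ambient tail)
_REAL_SIGMA = 0.30
_AMBIENT_SIGMA = 0.60


@dataclass
class ScSimParams:
    """Parameters of the single-cell UMI count generator.

    Counts are negative binomial with variance ``mu + mu**2 / dispersion``;
    gene means are log-normal, per-cell size factors log-normal, and the
    planted subpopulation has its signature-gene means multiplied by
    ``exp(log_fc)``.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_mito_genes: int = 20
    planted_fraction: float = 0.05
    signature_size: int = 50
    log_fc: float = 1.5
    mean_log_mu: float = 0.0
    sd_log_mu: float = 1.0
    dispersion: float = 2.0
    libsize_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be in [0, n_genes)")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.signature_size <= 0:
            raise ValueError("signature_size must be positive")
        if self.signature_size > self.n_genes - self.n_mito_genes:
            raise ValueError(
                "signature_size exceeds the number of non-mitochondrial genes"
            )
        if self.log_fc < 0:
            raise ValueError("log_fc must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.libsize_sd < 0:
            raise ValueError("libsize_sd must be >= 0")

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_fraction * self.n_cells))


@dataclass
class CohortSimParams:
    """Parameters of the bulk survival-cohort generator.

    Event times are exponential with hazard
    ``baseline_hazard * exp(beta * z)`` where ``z`` is the per-patient
    signature index standardized to mean 0, SD 1; censoring times are drawn
    independently so that roughly ``censor_rate`` of patients are censored.
    """

    n_patients: int = 300
    signature_size: int = 40
    n_genes: int = 1000
    beta: float = math.log(2.0)
    baseline_hazard: float = 0.02
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ValueError("n_patients and n_genes must be positive")
        if self.signature_size <= 0 or self.signature_size > self.n_genes:
            raise ValueError("signature_size must be in [1, n_genes]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded alongside each simulated dataset."""

    planted_cell_ids: set[str] = field(default_factory=set)
    signature_genes: set[str] = field(default_factory=set)
    true_knee_index: int | None = None
    true_beta: float | None = None

    def to_dict(self) -> dict:
        return {
            "planted_cell_ids": sorted(self.planted_cell_ids),
            "signature_genes": sorted(self.signature_genes),
            "true_knee_index": self.true_knee_index,
            "true_beta": self.true_beta,
        }


def simulate_barcode_pool(
    n_cells: int,
    n_ambient: int,
    real_mean_reads: float = 1000.0,
    ambient_mean_reads: float = 5.0,
    seed: int = 0,
) -> tuple[pd.Series, SimTruth]:
    """Simulate per-barcode read counts for a droplet library.

    ``n_cells`` barcodes are drawn from a high log-normal read-count
    population (cell-containing droplets) and ``n_ambient`` from a low one
    (ambient RNA).  Returns a barcode -> reads Series (input order: cells
    first) and a :class:`SimTruth` whose ``true_knee_index`` is ``n_cells``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_ambient < 0:
        raise ValueError("n_ambient must be >= 0")
    if real_mean_reads <= 0 or ambient_mean_reads <= 0:
        raise ValueError("mean read counts must be positive")
    if n_ambient > 0 and real_mean_reads <= ambient_mean_reads:
        raise ValueError("real_mean_reads must exceed ambient_mean_reads")

    rng = np.random.default_rng(seed)
    real = rng.lognormal(math.log(real_mean_reads), _REAL_SIGMA, size=n_cells)
    amb = rng.lognormal(math.log(ambient_mean_reads), _AMBIENT_SIGMA, size=n_ambient)
    reads = np.maximum(np.rint(np.concatenate([real, amb])), 1).astype(np.int64)

    n_total = n_cells + n_ambient
    bc_len = 12
    codes = rng.integers(0, 4, size=(n_total, bc_len))
    alphabet = np.array(list("ACGT"))
    barcodes = ["".join(row) for row in alphabet[codes]]
    # regenerate the rare collision deterministically by suffixing
    seen: dict[str, int] = {}
    for i, bc in enumerate(barcodes):
        if bc in seen:
            barcodes[i] = f"{bc}-{seen[bc]}"
            seen[bc] += 1
        else:
            seen[bc] = 1

    table = pd.Series(reads, index=pd.Index(barcodes, name="barcode"), name="reads")
    truth = SimTruth(true_knee_index=n_cells)
    return table, truth


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, dispersion) counts."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def simulate_sc_counts(params: ScSimParams) -> tuple[ad.AnnData, SimTruth]:
    """Simulate a UMI count matrix with a planted signature-high subpopulation.

    Returns an AnnData (cells x genes) with obs columns ``sample`` and
    ``planted`` and var column ``mito``, plus the :class:`SimTruth`.
    Mitochondrial genes occupy the first ``n_mito_genes`` slots and are named
    with an ``MT-`` prefix so the default QC detector finds them; signature
    genes are drawn from the non-mitochondrial remainder.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    gene_mu = rng.lognormal(p.mean_log_mu, p.sd_log_mu, size=p.n_genes)
    size_factor = rng.lognormal(0.0, p.libsize_sd, size=p.n_cells)

    planted = np.zeros(p.n_cells, dtype=bool)
    if p.n_planted > 0:
        planted[rng.choice(p.n_cells, size=p.n_planted, replace=False)] = True
    sig_idx = rng.choice(
        np.arange(p.n_mito_genes, p.n_genes), size=p.signature_size, replace=False
    )

    mean = np.outer(size_factor, gene_mu)
    if p.log_fc > 0 and p.n_planted > 0:
        mean[np.ix_(planted, sig_idx)] *= math.exp(p.log_fc)
    counts = _nb_sample(rng, mean, p.dispersion).astype(np.int32)

    gene_names = [
        f"MT-G{i:05d}" if i < p.n_mito_genes else f"G{i:05d}" for i in range(p.n_genes)
    ]
    cell_names = [f"CELL{i:05d}" for i in range(p.n_cells)]
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"sample": "sim", "planted": planted}, index=pd.Index(cell_names, name="cell")
        ),
        var=pd.DataFrame(
            {"mito": np.arange(p.n_genes) < p.n_mito_genes},
            index=pd.Index(gene_names, name="gene"),
        ),
    )
    truth = SimTruth(
        planted_cell_ids={cell_names[i] for i in np.flatnonzero(planted)},
        signature_genes={gene_names[i] for i in sig_idx},
    )
    return adata, truth


def simulate_bulk_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a bulk expression matrix and matched survival table.

    Expression is gene x patient on the log2 scale; the per-patient signature
    index (mean log2 expression of the signature genes) is standardized and
    drives an exponential proportional-hazards event time with log hazard
    ratio ``beta`` per SD of index.  Censoring times are drawn independently
    of event times from an exponential calibrated to ``censor_rate``.

    Returns ``(expr, clinical, truth)`` where ``clinical`` has columns
    patient_id, time, event, age, metastatic_status, subgroup, index.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    gene_names = [f"G{i:05d}" for i in range(p.n_genes)]
    patient_ids = [f"P{i:04d}" for i in range(p.n_patients)]

    # log2 expression: gene-specific baseline plus patient noise, with a
    # shared per-patient activity factor on the signature genes so the index
    # varies between patients
    base = rng.normal(6.0, 1.5, size=p.n_genes)
    noise = rng.normal(0.0, 1.0, size=(p.n_genes, p.n_patients))
    activity = rng.normal(0.0, 1.0, size=p.n_patients)
    sig_idx = rng.choice(p.n_genes, size=p.signature_size, replace=False)
    expr = base[:, None] + noise
    expr[sig_idx, :] += activity[None, :]

    sig_mean = expr[sig_idx, :].mean(axis=0)
    z = (sig_mean - sig_mean.mean()) / sig_mean.std()

    hazard = p.baseline_hazard * np.exp(p.beta * z)
    event_time = rng.exponential(1.0 / hazard)
    if p.censor_rate > 0:
        # mean censoring time chosen so ~censor_rate of patients censor on
        # average for the baseline population
        cens_rate = p.baseline_hazard * p.censor_rate / (1.0 - p.censor_rate)
        censor_time = rng.exponential(1.0 / cens_rate, size=p.n_patients)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(p.n_patients, dtype=int)

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time": time,
            "event": event,
            "age": rng.normal(8.0, 3.0, size=p.n_patients).round(1),
            "metastatic_status": rng.integers(0, 2, size=p.n_patients),
            "subgroup": rng.choice(["Group3", "Group4"], size=p.n_patients),
            "index": sig_mean,
        }
    )
    expr_df = pd.DataFrame(expr, index=pd.Index(gene_names, name="gene"), columns=patient_ids)
    truth = SimTruth(
        signature_genes={gene_names[i] for i in sig_idx}, true_beta=p.beta
    )
    return expr_df, clinical, truth
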