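"""Readers and writers for the formats the pipeline touches.

Counts travel as a 10x-style MTX triplet (MatrixMarket matrix with genes as
rows and cells as columns, plus gene and barcode TSVs, gzip transparently
handled) or as a dense genes x cells TSV with a header row of cell ids.
Gene sets use GMT (tab-separated: name, description, genes...).  All tabular
outputs are TSV with headers, floats at 10 significant digits.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .scoring import GeneSignature

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_tsv",
]

log = logging.getLogger("scsig")

FLOAT_FORMAT = "%.10g"


def _find(path: Path, stem_options) -> Path | None:
    for stem in stem_options:
        for suffix in ("", ".gz"):
            cand = path / f"{stem}{suffix}"
            if cand.exists():
                return cand
    return None


def _read_tsv_nohdr(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def _dedupe(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}-{seen[name]}")
            n_dup += 1
        else:
            seen[name] = 0
            out.append(name)
    if n_dup:
        log.warning("%d duplicate %s identifiers disambiguated with suffixes", n_dup, what)
    return out


def read_counts(path: str | os.PathLike) -> ad.AnnData:
    """Read a count matrix from an MTX triplet directory or a dense TSV.

    MTX triplets follow the 10x convention (genes as rows, cells as
    columns; ``matrix.mtx``, ``features.tsv``/``genes.tsv``,
    ``barcodes.tsv``, optionally gzipped).  Feature files may have 1, 2 or 3
    columns; the gene symbol is taken from the second column when present
    (10x: id, symbol, type), else the first.  Dense TSVs are genes x cells
    with a header row of cell ids and gene ids in the first column.

    Returns an AnnData with cells as obs and genes as var.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, ["matrix.mtx"])
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
        feat = _find(path, ["features.tsv", "genes.tsv"])
        bc = _find(path, ["barcodes.tsv"])
        if feat is None or bc is None:
            raise FileNotFoundError(f"missing features/genes or barcodes TSV in {path}")
        M = scipy.io.mmread(str(mtx)).tocsr()  # genes x cells
        feats = _read_tsv_nohdr(feat)
        bcs = _read_tsv_nohdr(bc)
        if feats.shape[0] != M.shape[0]:
            raise ValueError(
                f"{feat.name}: {feats.shape[0]} rows but matrix has {M.shape[0]} genes"
            )
        if bcs.shape[0] != M.shape[1]:
            raise ValueError(
                f"{bc.name}: {bcs.shape[0]} rows but matrix has {M.shape[1]} cells"
            )
        sym_col = 1 if feats.shape[1] >= 2 else 0
        genes = _dedupe(list(feats.iloc[:, sym_col]), "gene")
        cells = _dedupe(list(bcs.iloc[:, 0]), "barcode")
        adata = ad.AnnData(
            X=M.T.tocsr().astype(np.int32),
            obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        if feats.shape[1] >= 2:
            adata.var["feature_id"] = feats.iloc[:, 0].to_numpy()
        return adata

    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = _dedupe([str(g) for g in df.index], "gene")
    cells = _dedupe([str(c) for c in df.columns], "cell")
    return ad.AnnData(
        X=df.to_numpy().T.astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_counts(adata: ad.AnnData, path: str | os.PathLike) -> None:
    """Write an MTX triplet (genes x cells) readable by :func:`read_counts`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    M = sp.csc_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(path / "matrix.mtx"), M, field="integer")
    pd.DataFrame({0: adata.var_names}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: adata.obs_names}).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path: str | os.PathLike) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    Direction is inferred from a ``_UP`` / ``_DN`` name suffix (default
    "up").  Duplicate genes within a line are de-duplicated with a warning;
    empty lines are skipped; a line with fewer than 3 fields is an error.
    """
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            direction = "up"
            if name.upper().endswith("_DN") or name.upper().endswith("_DOWN"):
                direction = "down"
            sigs.append(
                GeneSignature(name=name, genes=genes, direction=direction, description=desc)
            )
    return sigs


def write_gmt(sigs, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, sig.description or "na", *sig.genes]) + "\n")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Read a clinical TSV with the expected header columns.

    Required: patient_id, time, event.  Optional covariates (age,
    metastatic_status, subgroup, ...) pass through.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
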