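"""Droplet cell calling from the barcode read-rank curve.

Cell-containing droplets are separated from ambient-RNA barcodes by locating
the inflection point ("knee") of the sorted barcode read-count curve: the
rank at which the log-log curve of reads against rank bends most sharply.
Barcodes at ranks up to the knee are accepted; the accepted set is always a
prefix of the read-sorted barcode list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BarcodeRankProfile", "call_cells"]


@dataclass
class BarcodeRankProfile:
    """Audit trail of a cell-calling run.

    barcodes are sorted by reads descending (ties broken by lexicographic
    barcode order); ``cumulative_fraction`` is the running fraction of total
    reads; ``knee_index`` is the 1-based accepted rank, or None when no knee
    was estimable (degenerate input).
    """

    barcodes: list[str]
    reads: np.ndarray
    cumulative_fraction: np.ndarray
    knee_index: int | None
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.barcodes) + 1),
                "barcode": self.barcodes,
                "reads": self.reads,
                "cumulative_fraction": self.cumulative_fraction,
            }
        )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    # centred window with edge truncation
    padded = np.pad(y, window // 2, mode="edge")
    sm = np.convolve(padded, kernel, mode="valid")
    return sm[: len(y)]


def _knee_second_derivative(log_reads: np.ndarray, smooth_window: int) -> int | None:
    y = _moving_average(log_reads, smooth_window)
    if len(y) < 3:
        return None
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    if np.all(d2 == 0):
        return None
    # most negative curvature = sharpest downward bend; d2[i] is centred on
    # 0-based index i + 1, i.e. 1-based rank i + 2
    return int(np.argmin(d2)) + 2


def _knee_chord(log_rank: np.ndarray, log_reads: np.ndarray) -> int | None:
    """Max perpendicular distance from the log-log curve to its end chord."""
    x0, y0 = log_rank[0], log_reads[0]
    x1, y1 = log_rank[-1], log_reads[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        return None
    dist = np.abs(dy * (log_rank - x0) - dx * (log_reads - y0)) / norm
    if np.all(dist == 0):
        return None
    return int(np.argmax(dist)) + 1


def call_cells(
    barcode_reads: pd.Series,
    min_barcodes: int = 10,
    knee_method: str = "secondderiv",
    smooth_window: int = 1,
) -> tuple[list[str], BarcodeRankProfile]:
    """Accept barcodes up to the knee of the read-rank curve.

    Parameters
    ----------
    barcode_reads
        barcode -> read count mapping (Series or dict-like). Zero-read
        barcodes are dropped before ranking.
    min_barcodes
        below this many nonzero barcodes no knee is estimable; all barcodes
        are accepted with a warning.
    knee_method
        ``"secondderiv"`` (rank minimizing the discrete second derivative of
        log10 reads over rank) or ``"chord"`` (rank of maximum perpendicular
        distance to the chord joining the log-log curve endpoints).
    smooth_window
        odd moving-average window applied to log reads before the
        second-derivative search; 1 disables smoothing. Smoothing blurs
        sharp steps into ramps with zero interior curvature, so it is off by
        default and intended only for very noisy profiles.

    Returns the accepted barcode list (read-rank order) and the profile.
    """
    if knee_method not in ("secondderiv", "chord"):
        raise ValueError(f"unknown knee_method {knee_method!r}")
    series = pd.Series(barcode_reads)
    if len(series) == 0:
        raise ValueError("no barcodes supplied")
    if (series < 0).any():
        raise ValueError("read counts must be nonnegative")
    series = series[series > 0]
    if len(series) == 0:
        raise ValueError("all barcodes have zero reads")

    # reads descending, ties by barcode lexicographic order (stable)
    series = series.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    reads = series.to_numpy(dtype=np.int64)
    barcodes = list(series.index)
    cumfrac = np.cumsum(reads) / reads.sum()

    knee: int | None = None
    if len(series) < min_barcodes:
        warnings.warn(
            f"only {len(series)} barcodes with reads; no knee estimable, "
            "accepting all",
            stacklevel=2,
        )
    else:
        log_reads = np.log10(reads.astype(float))
        log_rank = np.log10(np.arange(1, len(reads) + 1, dtype=float))
        if knee_method == "secondderiv":
            knee = _knee_second_derivative(log_reads, smooth_window)
        else:
            knee = _knee_chord(log_rank, log_reads)
        if knee is None:
            warnings.warn(
                "flat read-rank curve: no inflection point, accepting all",
                stacklevel=2,
            )

    profile = BarcodeRankProfile(
        barcodes=barcodes,
        reads=reads,
        cumulative_fraction=cumfrac,
        knee_index=knee,
        method=knee_method,
    )
    accepted = barcodes if knee is None else barcodes[:knee]
    return accepted, profile
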