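"""Coverage filtering, log2-CPM normalization, and the library-size
correlation filter.

Counts are spliced-junction (intron-spanning) read totals per transcript, so
no gene-length correction applies: a library-size rescaling to counts per
million followed by ``log2(x + 1)`` is the modeling scale for all downstream
statistics.  The library-size correlation filter is the swarm-tunable knob
that discards transcripts whose apparent expression merely tracks sequencing
depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "filter_low_coverage",
    "normalize",
    "libsize_correlation_filter",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 counts-per-million (pseudocount 1) with the library sizes.

    Attributes
    ----------
    values : pandas.DataFrame
        Transcripts x samples, ``log2(1e6 * count / libsize + 1)``.
    libsizes : pandas.Series
        Per-sample total spliced read count, indexed like the columns.
    """

    values: pd.DataFrame
    libsizes: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")
        if (self.libsizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if not self.values.columns.equals(self.libsizes.index):
            raise ValueError("libsize index must match sample columns")

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_transcripts(self, ids) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values.loc[list(ids)], self.libsizes)

    def subset_samples(self, ids) -> "NormalizedMatrix":
        ids = list(ids)
        return NormalizedMatrix(self.values[ids], self.libsizes[ids])


def filter_low_coverage(
    counts: pd.DataFrame, min_total: int = 30, min_samples: int = 3
) -> pd.DataFrame:
    """Drop transcripts with insufficient read coverage.

    Keeps transcripts with total count >= ``min_total`` AND a nonzero count
    in at least ``min_samples`` samples.  The sample set is unchanged.
    Idempotent: the surviving transcripts trivially satisfy both thresholds.
    """
    if min_total < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    totals = counts.sum(axis=1)
    expressed = (counts > 0).sum(axis=1)
    keep = (totals >= min_total) & (expressed >= min_samples)
    if not keep.any():
        raise ValueError(
            "coverage filter removed every transcript "
            f"(min_total={min_total}, min_samples={min_samples})"
        )
    return counts.loc[keep]


def normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """log2-CPM with pseudocount 1: ``log2(1e6 * count / libsize + 1)``."""
    libsizes = counts.sum(axis=0)
    zero = libsizes[libsizes == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero library size: {list(zero.index)}")
    cpm = counts.astype(float).div(libsizes, axis=1) * 1e6
    values = np.log2(cpm + 1.0)
    return NormalizedMatrix(values=values, libsizes=libsizes.astype(float))


def _row_pearson(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``values`` against ``y``; zero-variance rows
    (either side) get r = 0 so the filter is total."""
    x = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    if sy == 0:
        r[:] = 0.0
    return np.clip(r, -1.0, 1.0)


def libsize_correlation_filter(
    norm: NormalizedMatrix, lo: float, hi: float = 1.0
) -> pd.Index:
    """Transcripts whose Pearson correlation with log2 library size lies in
    ``[lo, hi]``.

    The correlation is computed on the normalized (log2-CPM) values against
    log2 library size; constant transcripts are assigned r = 0.
    """
    if not (-1.0 <= lo <= hi <= 1.0):
        raise ValueError(f"need -1 <= lo <= hi <= 1, got [{lo}, {hi}]")
    if norm.values.shape[1] < 3:
        raise ValueError("libsize correlation needs at least 3 samples")
    r = _row_pearson(norm.values.to_numpy(), np.log2(norm.libsizes.to_numpy()))
    keep = (r >= lo) & (r <= hi)
    return norm.transcripts[keep]


def libsize_correlations(norm: NormalizedMatrix) -> pd.Series:
    """Per-transcript Pearson r against log2 library size (QC report)."""
    r = _row_pearson(norm.values.to_numpy(), np.log2(norm.libsizes.to_numpy()))
    return pd.Series(r, index=norm.transcripts, name="libsize_cor")
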