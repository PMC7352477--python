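"""Per-transcript two-class ANOVA on the normalized scale with
Benjamini-Hochberg FDR control.

With exactly two groups the one-way fixed-effects F statistic equals the
square of the pooled-variance two-sample t statistic, with p from
F(1, n - 2); the implementation is vectorized across transcripts.
Constant transcripts (zero between- and within-group variance) are assigned
F = 0, p = 1 by convention so the test is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import NormalizedMatrix

__all__ = ["DifferentialResult", "anova_per_transcript", "bh_fdr", "select_by_fdr"]

SARCOMA = "sarcoma"
CONTROL = "control"


@dataclass(frozen=True)
class DifferentialResult:
    """Per-transcript F, p, BH q, and sarcoma-minus-control mean difference
    (log2 units), as a single table indexed by transcript id."""

    table: pd.DataFrame  # columns: F, p, q, mean_diff

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p"] < 0) | (t["p"] > 1)).any() or ((t["q"] < 0) | (t["q"] > 1)).any():
            raise ValueError("p and q must lie in [0, 1]")
        if (t["q"] < t["p"] - 1e-12).any():
            raise ValueError("BH can only increase p; q >= p violated")
        if (t["F"] < 0).any():
            raise ValueError("F statistics must be non-negative")


def _as_group_mask(labels: pd.Series | np.ndarray, samples: pd.Index) -> np.ndarray:
    labels = pd.Series(np.asarray(labels), index=samples) if not isinstance(
        labels, pd.Series
    ) else labels.loc[samples]
    classes = set(labels.unique())
    if classes != {SARCOMA, CONTROL}:
        raise ValueError(
            f"expected exactly the classes {{'{SARCOMA}', '{CONTROL}'}}, got {sorted(classes)}"
        )
    return (labels == SARCOMA).to_numpy()


def anova_per_transcript(norm: NormalizedMatrix, labels) -> DifferentialResult:
    """One-way ANOVA of each transcript's normalized level, sarcoma vs
    control, with BH-adjusted q values.

    Requires at least 2 samples per class.  ``labels`` is a pandas Series
    indexed by sample id (or an array aligned to the sample columns).
    """
    is_sar = _as_group_mask(labels, norm.samples)
    n1, n0 = int(is_sar.sum()), int((~is_sar).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 samples per class, got {n1} sarcoma / {n0} control")

    x = norm.values.to_numpy()
    g1, g0 = x[:, is_sar], x[:, ~is_sar]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    ss1 = ((g1 - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((g0 - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    pooled = (ss1 + ss0) / df
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = diff**2 / (pooled * (1.0 / n1 + 1.0 / n0))
    # constant transcripts: no variance anywhere -> no evidence, F = 0
    f = np.where((pooled == 0) & (diff == 0), 0.0, f)
    f = np.where(np.isnan(f), 0.0, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0.0, f), 1, df))
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"F": f, "p": p, "q": q, "mean_diff": diff}, index=norm.transcripts
    )
    return DifferentialResult(table)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_by_fdr(result: DifferentialResult, threshold: float) -> pd.Index:
    """Transcripts with q strictly below ``threshold``, sorted by ascending
    q, then ascending p, then transcript id (deterministic panels)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    t = result.table[result.table["q"] < threshold]
    order = t.assign(_id=t.index).sort_values(["q", "p", "_id"], kind="mergesort")
    return order.index
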