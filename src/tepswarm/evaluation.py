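"""Classifier performance reporting and the control experiments.

AUC uses the Mann-Whitney pair-counting definition (ties count one half),
with a stratified percentile-bootstrap confidence interval.  The two control
experiments re-run the whole swarm-optimization pipeline: the shuffled-label
control permutes class labels in the training + evaluation series before
optimizing (a permutation null — validation AUC should collapse to chance),
while the shuffled-training control re-draws the training/evaluation split
with labels intact (a split-robustness check — validation AUC should hold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import SARCOMA
from .io import ParamBounds
from .panel import tep_score
from .swarm import optimize

__all__ = [
    "PerformanceReport",
    "auc_mann_whitney",
    "roc_auc",
    "confusion_report",
    "shuffled_label_control",
    "shuffled_training_control",
    "VennPartition",
    "signature_overlap",
]


def _to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == SARCOMA).astype(int)
    return y.astype(int)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked concordantly,
    ties counting one half — the Mann-Whitney U statistic normalized."""
    scores = np.asarray(scores, dtype=float)
    y = _to_binary(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_auc(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """AUC with a stratified percentile-bootstrap 95% CI, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y = _to_binary(labels)
    auc = auc_mann_whitney(scores, y)
    rng = np.random.default_rng(seed)
    pos, neg = scores[y == 1], scores[y == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        boots[b] = auc_mann_whitney(
            np.concatenate([ps, ns]), np.r_[np.ones(len(ps)), np.zeros(len(ns))]
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = max(0.0, min(lo, auc)), min(1.0, max(hi, auc))
    return auc, (float(lo), float(hi))


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and rates for one series at one cutoff.

    Rates are stored at full precision; ``percent()`` applies the
    whole-percent display rounding used in reports.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    cutoff: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def percent(self) -> dict:
        def pct(x: float):
            return "NA" if np.isnan(x) else int(round(100 * x))

        return {
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "accuracy": pct(self.accuracy),
        }


def confusion_report(scores, labels, cutoff: float = 0.5) -> PerformanceReport:
    """2x2 cross-table at the cutoff (score >= cutoff calls sarcoma)."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    y = _to_binary(labels)
    called = scores >= cutoff
    tp = int((called & (y == 1)).sum())
    fn = int((~called & (y == 1)).sum())
    fp = int((called & (y == 0)).sum())
    tn = int((~called & (y == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("one class absent: its rate is undefined (NA)", stacklevel=2)
    return PerformanceReport(tp=tp, fn=fn, tn=tn, fp=fp, cutoff=cutoff)


def _run_pipeline_auc(
    norm, annotation: pd.DataFrame, labels: pd.Series, bounds: ParamBounds,
    n_particles: int, n_iterations: int, seed: int,
) -> float:
    """Optimize on training/evaluation of `annotation`, score validation
    with the true labels, return validation AUC."""
    tr = annotation.index[annotation["series"] == "training"]
    ev = annotation.index[annotation["series"] == "evaluation"]
    va = annotation.index[annotation["series"] == "validation"]
    res = optimize(
        norm.subset_samples(tr), labels.loc[tr],
        norm.subset_samples(ev), labels.loc[ev],
        bounds, n_particles=n_particles, n_iterations=n_iterations, seed=seed,
    )
    scores = tep_score(res.panel, norm.subset_samples(va), require_locked=True)
    return auc_mann_whitney(scores.to_numpy(), labels.loc[va].to_numpy())


def shuffled_label_control(
    norm,
    annotation: pd.DataFrame,
    bounds: ParamBounds,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_particles: int = 10,
    n_iterations: int = 3,
) -> dict:
    """Permutation null: shuffle training+evaluation class labels, re-run the
    full optimization, score the untouched validation series.

    Returns the median and IQR of the validation AUC over shuffles.  The
    particle budget defaults to a reduced setting (recorded in the output)
    because each shuffle repeats the whole swarm search.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng(seed)
    dev = annotation.index[annotation["series"].isin(["training", "evaluation"])]
    aucs = []
    for k in range(n_shuffles):
        labels = annotation["class"].copy()
        labels.loc[dev] = rng.permutation(labels.loc[dev].to_numpy())
        aucs.append(
            _run_pipeline_auc(
                norm, annotation, labels, bounds, n_particles, n_iterations,
                seed=int(rng.integers(2**31)),
            )
        )
    aucs = np.array(aucs)
    q25, q50, q75 = np.percentile(aucs, [25, 50, 75])
    return {
        "median_auc": float(q50),
        "iqr": float(q75 - q25),
        "aucs": aucs,
        "n_shuffles": n_shuffles,
        "n_particles": n_particles,
        "n_iterations": n_iterations,
    }


def shuffled_training_control(
    norm,
    annotation: pd.DataFrame,
    bounds: ParamBounds,
    n_iter: int = 1000,
    seed: int = 0,
    n_particles: int = 10,
    n_iterations: int = 3,
) -> dict:
    """Split-robustness control: re-draw the training/evaluation split
    (labels intact), re-optimize, score the fixed validation series."""
    if n_iter < 2:
        raise ValueError("need at least 2 iterations")
    rng = np.random.default_rng(seed)
    dev = annotation.index[annotation["series"].isin(["training", "evaluation"])]
    n_train = int((annotation["series"] == "training").sum())
    labels = annotation["class"]
    aucs = []
    for k in range(n_iter):
        perm = rng.permutation(dev.to_numpy())
        ann = annotation.copy()
        ann.loc[perm[:n_train], "series"] = "training"
        ann.loc[perm[n_train:], "series"] = "evaluation"
        # a redraw that collapses a class in either series is re-drawn
        ok = all(
            labels.loc[ann.index[ann["series"] == s]].nunique() == 2
            for s in ("training", "evaluation")
        )
        if not ok:
            continue
        aucs.append(
            _run_pipeline_auc(
                norm, ann, labels, bounds, n_particles, n_iterations,
                seed=int(rng.integers(2**31)),
            )
        )
    aucs = np.array(aucs)
    q25, q50, q75 = np.percentile(aucs, [25, 50, 75])
    return {
        "median_auc": float(q50),
        "iqr": float(q75 - q25),
        "aucs": aucs,
        "n_iter": len(aucs),
        "n_particles": n_particles,
        "n_iterations": n_iterations,
    }


@dataclass(frozen=True)
class VennPartition:
    """Exact cell counts for 2-3 named transcript sets.

    ``cells`` maps a frozenset of set names (the sets an element belongs to,
    and no others) to its count; cells sum to the size of the union.
    """

    names: tuple[str, ...]
    cells: dict

    def unique_count(self, name: str) -> int:
        return self.cells.get(frozenset([name]), 0)

    def set_size(self, name: str) -> int:
        return sum(c for k, c in self.cells.items() if name in k)

    def unique_fraction(self, name: str) -> str:
        total = self.set_size(name)
        uniq = self.unique_count(name)
        pct = int(round(100 * uniq / total)) if total else 0
        return f"{uniq}/{total} ({pct}%)"

    def intersection_all(self) -> int:
        return self.cells.get(frozenset(self.names), 0)


def signature_overlap(sets: dict) -> VennPartition:
    """Partition 2 or 3 named transcript signatures into Venn cells."""
    if len(sets) not in (2, 3):
        raise ValueError("signature overlap expects 2 or 3 sets")
    names = tuple(sets)
    sets = {k: set(v) for k, v in sets.items()}
    for k, v in sets.items():
        if not v:
            warnings.warn(f"signature {k!r} is empty", stacklevel=2)
    cells: dict = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            cell = set.intersection(*(sets[k] for k in inside))
            for k in names:
                if k not in inside:
                    cell -= sets[k]
            if cell:
                cells[frozenset(inside)] = len(cell)
    return VennPartition(names=names, cells=cells)
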