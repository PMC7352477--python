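"""Biomarker-panel construction and the TEP-score SVM classifier.

A particle (one candidate hyperparameter setting) drives a fixed selection
pipeline on the training series only:

1. library-size correlation filter (floor tuned, ceiling 1.0);
2. per-transcript two-class ANOVA with BH-FDR on the survivors;
3. keep transcripts with q below the particle's FDR threshold;
4. keep transcripts whose |point-biserial label correlation| meets the floor;
5. rank by (q, p, transcript id) and take the top ``n_ranked``.

The surviving transcripts are z-scaled by their training mean/sd and an RBF
support-vector machine is fitted (C = 1, gamma = 1 / panel size), with a
Platt-style one-dimensional logistic calibration mapping decision values to
the TEP-score in [0, 1].  Everything needed to score a new sample — the
transcript list, the scaling constants, the support vectors and dual
coefficients, and the calibration line — is stored as plain arrays, so a
panel serializes to a single JSON artifact and a locked panel is immutable:
scoring reads only those arrays.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .differential import SARCOMA, anova_per_transcript, select_by_fdr
from .io import ParamBounds
from .preprocessing import NormalizedMatrix, libsize_correlation_filter

__all__ = [
    "ParticleParams",
    "BiomarkerPanel",
    "label_correlation",
    "build_panel",
    "tep_score",
    "classify",
    "loocv",
    "restrict_panel",
]


@dataclass(frozen=True)
class ParticleParams:
    """The four swarm-tuned panel-selection hyperparameters."""

    libsize_cor_lo: float
    fdr_threshold: float
    cor_threshold: float
    n_ranked: int

    def check_bounds(self, bounds: ParamBounds) -> None:
        checks = [
            ("libsize_cor_lo", self.libsize_cor_lo, bounds.libsize_cor),
            ("fdr_threshold", self.fdr_threshold, bounds.fdr),
            ("cor_threshold", self.cor_threshold, bounds.cor),
            ("n_ranked", self.n_ranked, bounds.n_ranked),
        ]
        for name, value, (lo, hi) in checks:
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")
        if int(self.n_ranked) != self.n_ranked or self.n_ranked < 1:
            raise ValueError("n_ranked must be a positive integer")

    @classmethod
    def default(cls, n_detected: int) -> "ParticleParams":
        """The pinned default particle: FDR 0.05, floor -0.1, correlation
        0.5, top min(1000, n_detected) transcripts."""
        return cls(-0.1, 0.05, 0.5, min(1000, n_detected))


@dataclass(frozen=True)
class BiomarkerPanel:
    """A selected transcript list plus the fitted, serializable classifier.

    ``degenerate`` marks particles whose filters left no transcript; such a
    panel scores every sample at chance (0.5) instead of crashing, so the
    swarm can traverse bad parameter regions.
    """

    transcripts: tuple[str, ...]
    mean: np.ndarray  # per-transcript training mean
    sd: np.ndarray  # per-transcript training sd (0 -> stored as 1)
    support_vectors: np.ndarray  # scaled training vectors retained by the SVM
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    platt_a: float  # TEP-score = sigmoid(platt_a * decision + platt_b)
    platt_b: float
    params: ParticleParams
    seed: int
    locked: bool = False
    degenerate: bool = False

    def lock(self) -> "BiomarkerPanel":
        return replace(self, locked=True)

    # --- scoring from stored arrays only ---------------------------------
    def decision_values(self, x_scaled: np.ndarray) -> np.ndarray:
        d2 = (
            (x_scaled**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * x_scaled @ self.support_vectors.T
        )
        k = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return k @ self.dual_coef + self.intercept

    def to_json(self) -> str:
        d = {
            "transcripts": list(self.transcripts),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "params": {
                "libsize_cor_lo": self.params.libsize_cor_lo,
                "fdr_threshold": self.params.fdr_threshold,
                "cor_threshold": self.params.cor_threshold,
                "n_ranked": int(self.params.n_ranked),
            },
            "seed": self.seed,
            "locked": self.locked,
            "degenerate": self.degenerate,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BiomarkerPanel":
        d = json.loads(text)
        return cls(
            transcripts=tuple(d["transcripts"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float).reshape(
                -1, len(d["transcripts"]) if d["transcripts"] else 0
            ),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            params=ParticleParams(**d["params"]),
            seed=int(d["seed"]),
            locked=bool(d["locked"]),
            degenerate=bool(d["degenerate"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BiomarkerPanel":
        return cls.from_json(Path(path).read_text())

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def label_correlation(norm: NormalizedMatrix, labels) -> pd.Series:
    """Point-biserial correlation of each transcript with the 0/1 class
    label (sarcoma = 1); zero-variance transcripts get r = 0."""
    labels = pd.Series(labels, index=norm.samples) if not isinstance(
        labels, pd.Series
    ) else labels.loc[norm.samples]
    y = (labels == SARCOMA).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("label correlation needs both classes present")
    from .preprocessing import _row_pearson

    r = _row_pearson(norm.values.to_numpy(), y)
    return pd.Series(r, index=norm.transcripts, name="label_cor")


def _degenerate(params: ParticleParams, seed: int) -> BiomarkerPanel:
    return BiomarkerPanel(
        transcripts=(),
        mean=np.zeros(0),
        sd=np.zeros(0),
        support_vectors=np.zeros((0, 0)),
        dual_coef=np.zeros(0),
        intercept=0.0,
        gamma=1.0,
        platt_a=0.0,
        platt_b=0.0,
        params=params,
        seed=seed,
        degenerate=True,
    )


def build_panel(
    norm_train: NormalizedMatrix,
    labels_train,
    params: ParticleParams,
    bounds: ParamBounds | None = None,
    seed: int = 0,
    universe: pd.Index | None = None,
) -> BiomarkerPanel:
    """Run the selection pipeline on the training series and fit the SVM.

    ``universe`` optionally restricts the candidate transcripts (used by
    :func:`restrict_panel`).  Returns an unlocked panel; a parameter setting
    that filters away every transcript yields a degenerate panel.
    """
    if bounds is not None:
        params.check_bounds(bounds)
    norm = norm_train if universe is None else norm_train.subset_transcripts(
        norm_train.transcripts.intersection(universe)
    )
    if norm.values.shape[0] == 0:
        return _degenerate(params, seed)

    kept = libsize_correlation_filter(norm, lo=params.libsize_cor_lo, hi=1.0)
    if len(kept) == 0:
        return _degenerate(params, seed)
    norm = norm.subset_transcripts(kept)

    diff = anova_per_transcript(norm, labels_train)
    if params.fdr_threshold >= 1.0:
        # threshold at the top of its range disables the FDR filter (the
        # strict q < 1 rule would still drop q == 1 ties); keep the ranking
        t = diff.table
        selected = t.assign(_id=t.index).sort_values(
            ["q", "p", "_id"], kind="mergesort"
        ).index
    else:
        selected = select_by_fdr(diff, params.fdr_threshold)
    if len(selected) == 0:
        return _degenerate(params, seed)

    r = label_correlation(norm.subset_transcripts(selected), labels_train)
    selected = pd.Index([t for t in selected if abs(r[t]) >= params.cor_threshold])
    if len(selected) == 0:
        return _degenerate(params, seed)

    # `selected` is already ranked (ascending q, p, id); take the head
    chosen = list(selected[: int(params.n_ranked)])

    x = norm.values.loc[chosen].to_numpy().T  # samples x transcripts
    labels_series = (
        labels_train.loc[norm.samples]
        if isinstance(labels_train, pd.Series)
        else pd.Series(labels_train, index=norm.samples)
    )
    y = (labels_series == SARCOMA).to_numpy(dtype=int)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mean) / sd

    gamma = 1.0 / len(chosen)
    svm = SVC(kernel="rbf", C=1.0, gamma=gamma, random_state=seed)
    svm.fit(xs, y)
    # SVC orders classes [0, 1]; decision > 0 means class 1 (sarcoma)
    dec = svm.decision_function(xs)
    platt = LogisticRegression(C=1.0, solver="lbfgs")
    platt.fit(dec[:, None], y)
    return BiomarkerPanel(
        transcripts=tuple(chosen),
        mean=mean,
        sd=sd,
        support_vectors=svm.support_vectors_.copy(),
        dual_coef=svm.dual_coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        gamma=gamma,
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
        params=params,
        seed=seed,
    )


def tep_score(
    panel: BiomarkerPanel,
    norm_samples: NormalizedMatrix,
    require_locked: bool = False,
) -> pd.Series:
    """TEP-score (probability of the sarcoma profile, in [0, 1]) per sample.

    Held-out (validation) scoring must pass ``require_locked=True``, which
    raises on an unlocked panel — the lock discipline that keeps validation
    independent of any further tuning.
    """
    if require_locked and not panel.locked:
        raise RuntimeError("panel must be locked before scoring held-out samples")
    if panel.degenerate:
        return pd.Series(0.5, index=norm_samples.samples, name="tep_score")
    missing = [t for t in panel.transcripts if t not in norm_samples.transcripts]
    if missing:
        raise ValueError(f"samples lack panel transcript(s): {missing[:5]}")
    x = norm_samples.values.loc[list(panel.transcripts)].to_numpy().T
    xs = (x - panel.mean) / panel.sd
    dec = panel.decision_values(xs)
    score = 1.0 / (1.0 + np.exp(-(panel.platt_a * dec + panel.platt_b)))
    return pd.Series(np.clip(score, 0.0, 1.0), index=norm_samples.samples, name="tep_score")


def classify(scores: pd.Series, cutoff: float = 0.5) -> pd.Series:
    """Predicted class per sample: sarcoma iff score >= cutoff (the tie at
    exactly the cutoff goes to sarcoma — the high-sensitivity direction)."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    return pd.Series(
        np.where(scores >= cutoff, "sarcoma", "control"),
        index=scores.index,
        name="predicted_class",
    )


def loocv(
    norm_train: NormalizedMatrix,
    labels_train: pd.Series,
    params: ParticleParams,
    seed: int = 0,
) -> pd.Series:
    """Leave-one-out TEP-scores for the training series.

    Each sample is scored by a panel selected and fitted entirely without
    it, so panel selection cannot leak the held-out sample.  A fold whose
    removal collapses a class is flagged and scored at chance (0.5).
    """
    counts = labels_train.value_counts()
    if (counts < 3).any() or len(counts) != 2:
        raise ValueError("LOOCV needs >= 3 samples per class")
    scores = {}
    for sample in norm_train.samples:
        rest = [s for s in norm_train.samples if s != sample]
        lab = labels_train.loc[rest]
        if lab.nunique() < 2 or lab.value_counts().min() < 2:
            scores[sample] = 0.5
            continue
        panel = build_panel(norm_train.subset_samples(rest), lab, params, seed=seed)
        scores[sample] = float(
            tep_score(panel, norm_train.subset_samples([sample])).iloc[0]
        )
    return pd.Series(scores, name="tep_score").loc[norm_train.samples]


def restrict_panel(
    panel: BiomarkerPanel,
    allowed,
    norm_train: NormalizedMatrix,
    labels_train,
    seed: int | None = None,
) -> BiomarkerPanel:
    """Retrain the same particle on a restricted candidate universe (e.g.
    only the disease-specific transcripts from a signature-overlap analysis)."""
    allowed = pd.Index(allowed)
    if len(allowed) == 0:
        raise ValueError("allowed transcript set must be nonempty")
    return build_panel(
        norm_train,
        labels_train,
        panel.params,
        seed=panel.seed if seed is None else seed,
        universe=allowed,
    )
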