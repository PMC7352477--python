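"""Unsupervised hierarchical clustering of the differential panel, the
cluster-group association test, and the swarm-assisted FDR choice for the
heatmap panel.

Samples are clustered on 1 - Pearson correlation of their Z-scored
expression columns with complete linkage and cut into two groups; a
two-sided Fisher exact test on the 2x2 cluster-by-class table quantifies how
well the unsupervised structure matches the diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .differential import anova_per_transcript, select_by_fdr
from .preprocessing import NormalizedMatrix, libsize_correlation_filter
from .swarm import run_pso

__all__ = [
    "ClusterResult",
    "zscore_rows",
    "hier_cluster",
    "cluster_association_p",
    "pso_cluster_panel",
]


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix over samples
    assignment: pd.Series  # sample -> cluster in {1, 2}
    zmatrix: pd.DataFrame  # transcripts x samples, Z-scored rows
    sample_order: list  # leaf order of the dendrogram
    association_p: float | None = None


def zscore_rows(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-transcript Z score, (x - mean) / sd with sample sd (ddof=1);
    constant transcripts become all-zero rows."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if values.shape[1] < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[~np.isfinite(z)] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def hier_cluster(z: pd.DataFrame) -> ClusterResult:
    """Complete-linkage clustering of samples at distance 1 - Pearson r,
    cut into exactly two clusters."""
    if z.shape[1] < 4:
        raise ValueError("clustering needs at least 4 samples")
    # scipy 'correlation' distance = 1 - Pearson r of the columns
    d = pdist(z.to_numpy().T, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)  # constant columns -> uninformative distance
    lk = linkage(d, method="complete")
    if not np.all(np.diff(lk[:, 2]) >= -1e-12):
        raise AssertionError("complete-linkage merge heights must be non-decreasing")
    cut = fcluster(lk, t=2, criterion="maxclust")
    assignment = pd.Series(cut, index=z.columns, name="cluster")
    from scipy.cluster.hierarchy import leaves_list

    order = [z.columns[i] for i in leaves_list(lk)]
    return ClusterResult(linkage=lk, assignment=assignment, zmatrix=z, sample_order=order)


def cluster_association_p(assignment: pd.Series, labels) -> float:
    """Two-sided Fisher exact p for the 2x2 cluster-by-class table."""
    labels = pd.Series(np.asarray(labels), index=assignment.index) if not isinstance(
        labels, pd.Series
    ) else labels.loc[assignment.index]
    clusters = sorted(assignment.unique())
    classes = sorted(labels.unique())
    if len(clusters) < 2:
        warnings.warn("a cluster is empty; association undefined (p = 1)", stacklevel=2)
        return 1.0
    if len(clusters) != 2 or len(classes) != 2:
        raise ValueError("association test expects 2 clusters and 2 classes")
    table = [
        [int(((assignment == c) & (labels == g)).sum()) for g in classes]
        for c in clusters
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pso_cluster_panel(
    norm: NormalizedMatrix,
    labels: pd.Series,
    fdr_bounds: tuple[float, float] = (0.00001, 1.0),
    n_particles: int = 200,
    n_iterations: int = 12,
    seed: int = 0,
    libsize_cor_lo: float = -0.1,
) -> dict:
    """Swarm the FDR threshold alone for the heatmap panel.

    Other selection parameters stay at their defaults (library-size floor
    -0.1, no label-correlation step — the heatmap panel is unsupervised
    downstream of the differential statistic).  Fitness of a threshold is
    -log10 of the cluster-class association p of the resulting panel's
    two-group cut, so the chosen panel is the one whose unsupervised
    structure separates the diagnosis best.
    """
    kept = libsize_correlation_filter(norm, lo=libsize_cor_lo, hi=1.0)
    base = norm.subset_transcripts(kept)
    diff = anova_per_transcript(base, labels)

    def panel_at(fdr: float) -> pd.Index:
        return select_by_fdr(diff, min(max(fdr, 1e-12), 1.0))

    def fitness(x: np.ndarray) -> float:
        ids = panel_at(float(x[0]))
        if len(ids) < 2:
            return 0.0
        z = zscore_rows(base.subset_transcripts(ids))
        res = hier_cluster(z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = cluster_association_p(res.assignment, labels)
        # monotone bounded transform of -log10 p into [0, 1]
        return min(-np.log10(max(p, 1e-300)), 300.0) / 300.0

    state = run_pso(
        np.array([list(fdr_bounds)]),
        fitness,
        n_particles=n_particles,
        n_iterations=n_iterations,
        seed=seed,
        pinned=np.array([0.05]),
    )
    best_fdr = float(state.gbest_pos[0])
    ids = panel_at(best_fdr)
    if len(ids) < 2:  # no threshold yields a usable panel: fall back to all
        ids = base.transcripts
    z = zscore_rows(base.subset_transcripts(ids))
    res = hier_cluster(z)
    p = cluster_association_p(res.assignment, labels)
    return {
        "fdr": best_fdr,
        "transcripts": ids,
        "cluster_result": ClusterResult(
            linkage=res.linkage,
            assignment=res.assignment,
            zmatrix=z,
            sample_order=res.sample_order,
            association_p=p,
        ),
        "association_p": p,
    }
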