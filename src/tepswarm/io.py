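"""Reading and writing the pipeline's tabular formats, the run
configuration, and structured stage logging.

The molecular input is a transcripts x samples matrix of spliced-junction
read counts, either tab-separated (transcript ids as the first column,
sample ids in the header) or MatrixMarket with ``<stem>.rows.txt`` /
``<stem>.cols.txt`` name sidecars.  Sample annotation is a CSV with columns
``sample_id, class, subtype, age, gender, series``.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ParamBounds",
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "check_sample_match",
    "stage_log",
]

CLASSES = {"sarcoma", "control"}
SERIES = {"training", "evaluation", "validation"}
ANNOT_COLUMNS = ["class", "subtype", "age", "gender", "series"]


@dataclass(frozen=True)
class ParamBounds:
    """Box constraints for the four swarm-tuned panel hyperparameters."""

    libsize_cor: tuple[float, float] = (-0.1, 1.0)
    fdr: tuple[float, float] = (0.00001, 1.0)
    cor: tuple[float, float] = (0.5, 1.0)
    n_ranked: tuple[int, int] = (200, 3799)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.libsize_cor, self.fdr, self.cor, self.n_ranked], dtype=float
        )

    def with_n_detected(self, n_detected: int) -> "ParamBounds":
        """Cap the ranked-transcript dimension at what the data offers."""
        lo = min(self.n_ranked[0], n_detected)
        return ParamBounds(self.libsize_cor, self.fdr, self.cor, (lo, n_detected))


@dataclass
class RunConfig:
    """Flat run configuration; YAML-serializable, every key mirrors a CLI flag."""

    counts: str | None = None
    annotation: str | None = None
    out: str = "tepswarm_out"
    seed: int = 0
    # PSO
    n_particles: int = 100
    n_iterations: int = 10
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: ParamBounds = field(default_factory=ParamBounds)
    # classifier
    kernel: str = "rbf"
    cutoff: float = 0.5
    # coverage filter
    min_total_reads: int = 30
    min_samples_expressed: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bounds = raw.pop("bounds", None)
        cfg = cls(**raw)
        if bounds is not None:
            cfg.bounds = ParamBounds(
                tuple(bounds["libsize_cor"]),
                tuple(bounds["fdr"]),
                tuple(bounds["cor"]),
                tuple(bounds["n_ranked"]),
            )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bounds"] = {k: list(v) for k, v in asdict(self.bounds).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _check_ids(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"duplicate {what} id(s): {dups}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Load a count matrix from TSV or MTX (extension-dispatched)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mtx":
        mat = spio.mmread(path)
        rows = Path(str(path) + ".rows.txt").read_text().split()
        cols = Path(str(path) + ".cols.txt").read_text().split()
        df = pd.DataFrame(
            np.asarray(mat.todense() if sparse.issparse(mat) else mat),
            index=pd.Index(rows, name="transcript_id"),
            columns=pd.Index(cols, name="sample_id"),
        )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "transcript_id"
        df.columns.name = "sample_id"
    _check_ids(df.index, "transcript")
    _check_ids(df.columns, "sample")
    arr = pd.DataFrame(df).apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(arr) | (arr != np.floor(arr)))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"non-integer count at transcript {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write TSV or MTX (+ ``.rows.txt`` / ``.cols.txt`` sidecars) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        spio.mmwrite(path, sparse.csr_matrix(counts.to_numpy()))
        Path(str(path) + ".rows.txt").write_text("\n".join(counts.index) + "\n")
        Path(str(path) + ".cols.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        counts.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-sample annotation CSV."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError("no samples in annotation file")
    missing = {"sample_id", *ANNOT_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"annotation is missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    _check_ids(df.index, "sample")
    bad_cls = set(df["class"].unique()) - CLASSES
    if bad_cls:
        raise ValueError(f"unknown class label(s): {sorted(bad_cls)}")
    bad_series = set(df["series"].dropna().unique()) - SERIES
    if bad_series:
        raise ValueError(f"unknown series label(s): {sorted(bad_series)}")
    return df[ANNOT_COLUMNS]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.reset_index(names="sample_id").to_csv(path, index=False)


def check_sample_match(counts: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Annotation rows must exactly cover the matrix columns."""
    orphans = counts.columns.difference(annotation.index)
    if len(orphans):
        raise ValueError(f"matrix sample(s) absent from annotation: {list(orphans)}")
    extra = annotation.index.difference(counts.columns)
    if len(extra):
        raise ValueError(f"annotation sample(s) absent from matrix: {list(extra)}")


def stage_log(stage: str, log_file: str | Path | None = None, **fields) -> None:
    """One structured line per pipeline stage, to stderr and optionally a file."""
    rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    line = json.dumps(rec, default=str)
    print(line, file=sys.stderr)
    if log_file is not None:
        with open(log_file, "a") as fh:
            fh.write(line + "\n")
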