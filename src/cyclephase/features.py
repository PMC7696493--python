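"""Per-sample 5-D kinematic feature vectors and cycle-aware dataset handling.

The recognition feature vector is P(x) = [kx, ky, hx, hy, a]: knee and
ankle horizontal/vertical accelerations plus the knee angle, taken
instantaneously at each sample (no windowed aggregation -- the classifier
decides phase from a single kinematic snapshot).  The knee angle alone is
ambiguous: every angle between the cycle extremes is visited twice per
revolution (once flexing, once extending), so the acceleration channels are
what break the tie.

A "group" is one phase segment of one riding cycle; 50 cycles x 4 phases
give 200 groups, split 100 train / 100 test at cycle granularity.  Group
representatives (per-segment median feature vectors) are used for
group-level training/evaluation, mirroring the experimental bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sim import CyclingRecording

__all__ = [
    "FEATURE_NAMES",
    "LabeledDataset",
    "extract",
    "standardize",
    "apply_standardization",
    "destandardize",
    "split_cycles",
    "group_representatives",
]

FEATURE_NAMES = ("kx", "ky", "hx", "hy", "a")


@dataclass
class LabeledDataset:
    """An (n x 5) feature matrix with phase labels and cycle indices.

    ``mean``/``scale`` are set once the dataset has been standardized (or
    had training-set parameters applied) and are ``None`` for raw data.
    """

    X: np.ndarray
    y: np.ndarray
    cycles: np.ndarray | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"feature matrix must be (n, {len(FEATURE_NAMES)})")
        if len(self.y) != len(self.X):
            raise ValueError("feature matrix and labels have different lengths")
        if len(self.y) and not np.isin(self.y, [1, 2, 3, 4]).all():
            raise ValueError("labels must be drawn from {1, 2, 3, 4}")
        if self.cycles is not None:
            self.cycles = np.asarray(self.cycles, dtype=int)
            if len(self.cycles) != len(self.X):
                raise ValueError("cycle indices and features have different lengths")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[mask],
            y=self.y[mask],
            cycles=None if self.cycles is None else self.cycles[mask],
            mean=self.mean,
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path)
        missing = [c for c in (*FEATURE_NAMES, "label") if c not in df.columns]
        if missing:
            raise ValueError(f"dataset CSV missing columns: {missing}")
        return cls(X=df[list(FEATURE_NAMES)].to_numpy(float),
                   y=df["label"].to_numpy(int))


def _cycle_ids_from_labels(labels: np.ndarray) -> np.ndarray:
    """Cycle index per sample: a new cycle starts at each entry into the
    pedaling phase (label 1)."""
    lab = np.asarray(labels)
    entering = (lab == 1) & np.concatenate([[True], lab[:-1] != 1])
    ids = np.cumsum(entering)
    return ids - ids[0] if len(ids) else ids


def extract(rec: CyclingRecording) -> LabeledDataset:
    """One feature row [kx, ky, hx, hy, a] per sample, labels copied."""
    if rec.label is None:
        raise ValueError("recording has no phase labels; cannot build a dataset")
    X = np.column_stack([getattr(rec, name) for name in FEATURE_NAMES])
    return LabeledDataset(X=X, y=rec.label, cycles=_cycle_ids_from_labels(rec.label))


def standardize(ds: LabeledDataset) -> tuple[LabeledDataset, tuple[np.ndarray, np.ndarray]]:
    """Zero-mean unit-variance per feature; returns the fit parameters.

    Zero-variance features get scale 1 (mapped to zeros).  The parameters
    must be re-applied to held-out data with :func:`apply_standardization`
    -- never refit on test data.
    """
    if len(ds) == 0:
        raise ValueError("cannot standardize an empty dataset")
    mean = ds.X.mean(axis=0)
    scale = ds.X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return apply_standardization(ds, mean, scale), (mean, scale)


def apply_standardization(
    ds: LabeledDataset, mean: np.ndarray, scale: np.ndarray
) -> LabeledDataset:
    return replace(ds, X=(ds.X - mean) / scale, mean=np.asarray(mean),
                   scale=np.asarray(scale))


def destandardize(ds: LabeledDataset) -> LabeledDataset:
    """Inverse of :func:`apply_standardization` (identity round-trip)."""
    if ds.mean is None or ds.scale is None:
        raise ValueError("dataset carries no standardization parameters")
    return replace(ds, X=ds.X * ds.scale + ds.mean, mean=None, scale=None)


def split_cycles(
    ds: LabeledDataset, n_train_cycles: int, n_test_cycles: int, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random train/test split at cycle granularity.

    No sample of one cycle lands in both sets; deterministic under ``seed``.
    """
    if ds.cycles is None:
        raise ValueError("dataset has no cycle indices; build it with extract()")
    unique = np.unique(ds.cycles)
    if len(unique) < n_train_cycles + n_test_cycles:
        raise ValueError(
            f"need {n_train_cycles + n_test_cycles} cycles, have {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    train_ids = set(perm[:n_train_cycles].tolist())
    test_ids = set(perm[n_train_cycles : n_train_cycles + n_test_cycles].tolist())
    train = ds.subset(np.array([c in train_ids for c in ds.cycles]))
    test = ds.subset(np.array([c in test_ids for c in ds.cycles]))
    return train, test


def group_representatives(ds: LabeledDataset) -> LabeledDataset:
    """Collapse each (cycle, phase) segment to its median feature vector.

    The result has one row per group -- 4 rows per complete cycle -- and
    keeps the cycle index so it can still be split at cycle granularity.
    """
    if ds.cycles is None:
        raise ValueError("dataset has no cycle indices; build it with extract()")
    rows, labels, cyc = [], [], []
    for c in np.unique(ds.cycles):
        in_cycle = ds.cycles == c
        for phase in (1, 2, 3, 4):
            mask = in_cycle & (ds.y == phase)
            if not mask.any():
                continue
            rows.append(np.median(ds.X[mask], axis=0))
            labels.append(phase)
            cyc.append(c)
    return LabeledDataset(X=np.array(rows), y=np.array(labels), cycles=np.array(cyc),
                          mean=ds.mean, scale=ds.scale)
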