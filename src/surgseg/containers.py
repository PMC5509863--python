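"""Core data containers shared by the generator, preprocessing and clustering stages.

Conventions
-----------
* Multivariate streams are stored channels-by-frames, i.e. a ``d x N`` array
  whose columns are time frames.
* A segmentation is a boundary vector ``s`` of length ``M + 1`` with
  ``s[0] = 0`` and ``s[M] = N`` (0-based, half-open segments) plus one integer
  cluster label per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: The six feature-stream combinations the pipeline accepts.
FEATURE_SETS = ("ssc", "si", "ssc+si", "ssc+evt", "si+evt", "ssc+si+evt")


@dataclass
class Segmentation:
    """A partition of ``N`` frames into ``M`` contiguous labeled segments.

    ``boundaries`` has length ``M + 1``; segment ``m`` covers frames
    ``[boundaries[m], boundaries[m + 1])`` and carries cluster label
    ``labels[m]`` in ``[0, K)``.
    """

    boundaries: np.ndarray
    labels: np.ndarray
    K: int
    N: int
    energy: float | None = field(default=None, compare=False)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.boundaries.ndim != 1 or self.boundaries.size < 2:
            raise ValidationError("boundaries must be a 1-d vector of length M+1 >= 2")
        if self.boundaries[0] != 0 or self.boundaries[-1] != self.N:
            raise ValidationError(
                f"boundaries must start at 0 and end at N={self.N}, "
                f"got [{self.boundaries[0]}, {self.boundaries[-1]}]"
            )
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValidationError("boundaries must be strictly increasing")
        if self.labels.size != self.boundaries.size - 1:
            raise ValidationError("labels must have one entry per segment")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValidationError(f"labels must lie in [0, {self.K})")

    @property
    def M(self) -> int:
        """Number of segments."""
        return self.labels.size

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def frame_labels(self) -> np.ndarray:
        """Expand to one label per frame (length ``N``)."""
        return np.repeat(self.labels, self.segment_lengths)

    @classmethod
    def from_frame_labels(cls, frame_labels: np.ndarray, K: int, **kw) -> "Segmentation":
        """Run-length encode per-frame labels into maximal constant segments."""
        fl = np.asarray(frame_labels, dtype=np.int64)
        if fl.ndim != 1 or fl.size == 0:
            raise ValidationError("frame_labels must be a non-empty 1-d vector")
        change = np.flatnonzero(np.diff(fl)) + 1
        bounds = np.concatenate(([0], change, [fl.size]))
        return cls(boundaries=bounds, labels=fl[bounds[:-1]], K=K, N=fl.size, **kw)

    def __eq__(self, other) -> bool:  # noqa: D105 - array fields need explicit comparison
        if not isinstance(other, Segmentation):
            return NotImplemented
        return (
            self.K == other.K
            and self.N == other.N
            and np.array_equal(self.boundaries, other.boundaries)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class ProcedureRecording:
    """Synchronized surgeon-console (SSC), patient-side (SI) and event streams."""

    ssc: np.ndarray  # d_ssc x N float
    si: np.ndarray  # d_si x N float
    evt: np.ndarray  # 8 x N binary
    rate_hz: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.ssc = np.asarray(self.ssc, dtype=np.float64)
        self.si = np.asarray(self.si, dtype=np.float64)
        self.evt = np.asarray(self.evt, dtype=np.uint8)
        n = {self.ssc.shape[1], self.si.shape[1], self.evt.shape[1]}
        if len(n) != 1:
            raise ValidationError(f"ssc/si/evt frame counts differ: {sorted(n)}")
        if self.N < 1:
            raise ValidationError("recording must contain at least one frame")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if self.evt.size and not np.isin(self.evt, (0, 1)).all():
            raise ValidationError("evt entries must be binary")

    @property
    def N(self) -> int:
        return self.ssc.shape[1]


@dataclass
class FeatureFrames:
    """Per-frame feature matrix ``X`` (``d x N``) fed to the clustering algorithms."""

    X: np.ndarray
    feature_set: str
    rate_hz_effective: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValidationError("X must be a d x N matrix with d > 0")
        if self.X.shape[1] < 2:
            raise ValidationError("X must contain at least two frames")

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]


@dataclass
class SymbolSequence:
    """Per-trial k-means quantization of frames into ``n_symbols`` discrete symbols."""

    symbols: np.ndarray  # length N, values in [0, n_symbols)
    centroids: np.ndarray  # n_symbols x d
    n_symbols: int
    inertia: float

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.symbols.size and self.symbols.max() >= self.n_symbols:
            raise ValidationError("symbol index out of range")
        if self.centroids.shape[0] != self.n_symbols:
            raise ValidationError("centroid count must equal n_symbols")
        if self.inertia < 0:
            raise ValidationError("inertia must be nonnegative")


@dataclass
class FrameKernel:
    """``N x N`` Gaussian frame-similarity matrix with unit diagonal."""

    F: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
            raise ValidationError("F must be square")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def N(self) -> int:
        return self.F.shape[0]


@dataclass
class ConfusionMatrix:
    """``K x K`` frame-count matrix; rows = predicted clusters, columns = true tasks."""

    C: np.ndarray
    K: int
    N: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.C.shape != (self.K, self.K):
            raise ValidationError("C must be K x K")
        if (self.C < 0).any():
            raise ValidationError("confusion counts must be nonnegative")
        if int(self.C.sum()) != self.N:
            raise ValidationError("confusion counts must sum to the frame count")


@dataclass
class TaskMetrics:
    """Per-task precision/recall/F1 after the accuracy-optimal cluster-task matching.

    Entries are NaN for tasks with no true frames (recall undefined); such
    tasks are excluded from the macro average.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    matching: np.ndarray  # matching[k] = predicted cluster matched to true task k
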