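"""Preprocessing: temporal reduction, channel normalization, symbolization and
the Gaussian frame kernel.

The clustering algorithms all consume either a per-frame feature matrix
``X`` (``d x N``) or the Gaussian frame-similarity matrix built from it,
``f_ij = exp(-||t_i - t_j||^2 / (2 sigma^2))``.  Kinematic channels are
z-scored and vector-quantized per trial with k-means into ``n_symbols``
discrete symbols, then each frame is re-embedded as its symbol's centroid so
the kernel sees graded between-symbol similarity; raw binary event channels
are appended unmodified.  Fewer symbols yield a visibly blockier kernel whose
diagonal blocks track the task structure.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .containers import FEATURE_SETS, FeatureFrames, FrameKernel, ProcedureRecording, SymbolSequence
from .containers import Segmentation
from .errors import ValidationError


def downsample(rec: ProcedureRecording, target_hz: float) -> ProcedureRecording:
    """Reduce temporal resolution by averaging non-overlapping windows.

    Kinematic channels are window means; event channels use an any-on rule
    (window maximum) so brief activations survive.  The final, possibly
    partial, window is kept.
    """
    if target_hz <= 0:
        raise ValidationError("target_hz must be positive")
    if target_hz > rec.rate_hz:
        raise ValidationError("target_hz must not exceed the recording rate")
    window = int(round(rec.rate_hz / target_hz))
    if window == 1:
        return rec
    return ProcedureRecording(
        ssc=_window_reduce(rec.ssc, window, "mean"),
        si=_window_reduce(rec.si, window, "mean"),
        evt=_window_reduce(rec.evt, window, "max"),
        rate_hz=rec.rate_hz / window,
        trial_id=rec.trial_id,
    )


def _window_reduce(arr: np.ndarray, window: int, how: str) -> np.ndarray:
    d, n = arr.shape
    n_full = n // window
    full = arr[:, : n_full * window].reshape(d, n_full, window)
    out = full.mean(axis=2) if how == "mean" else full.max(axis=2)
    if n % window:
        tail = arr[:, n_full * window :]
        red = tail.mean(axis=1) if how == "mean" else tail.max(axis=1)
        out = np.concatenate([out, red[:, None]], axis=1)
    return out.astype(arr.dtype) if how == "max" else out


def downsample_labels(frame_labels: np.ndarray, window: int) -> np.ndarray:
    """Downsample per-frame labels by window majority vote.

    Ties go to the smallest label, i.e. the earlier task under the fixed task
    ordering.
    """
    fl = np.asarray(frame_labels, dtype=np.int64)
    n_out = -(-fl.size // window)
    out = np.empty(n_out, dtype=np.int64)
    for i in range(n_out):
        out[i] = np.bincount(fl[i * window : (i + 1) * window]).argmax()
    return out


def downsample_segmentation(truth: Segmentation, window: int) -> Segmentation:
    """Majority-vote a ground-truth segmentation onto the downsampled grid."""
    return Segmentation.from_frame_labels(
        downsample_labels(truth.frame_labels(), window), K=truth.K
    )


def zscore_channels(X: FeatureFrames) -> FeatureFrames:
    """Standardize every channel to zero mean, unit (population) sd.

    Constant channels map to all-zeros rather than NaN.
    """
    mu = X.X.mean(axis=1, keepdims=True)
    sd = X.X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return FeatureFrames(
        X=(X.X - mu) / sd, feature_set=X.feature_set, rate_hz_effective=X.rate_hz_effective
    )


def symbolize(X: FeatureFrames, n_symbols: int, seed: int) -> SymbolSequence:
    """Quantize frames into ``n_symbols`` symbols with per-trial k-means.

    Runs 10 seeded restarts and keeps the lowest-inertia solution; the result
    is deterministic given the seed.
    """
    if n_symbols < 2:
        raise ValidationError("n_symbols must be at least 2")
    if n_symbols > X.N:
        raise ValidationError(f"n_symbols={n_symbols} exceeds frame count N={X.N}")
    km = KMeans(n_clusters=n_symbols, n_init=10, random_state=seed)
    symbols = km.fit_predict(X.X.T)
    return SymbolSequence(
        symbols=symbols,
        centroids=km.cluster_centers_,
        n_symbols=n_symbols,
        inertia=max(float(km.inertia_), 0.0),
    )


def build_features(
    rec: ProcedureRecording, feature_set: str, n_symbols: int = 15, seed: int = 0
) -> FeatureFrames:
    """Assemble the feature matrix for one of the six stream combinations.

    The requested kinematic streams are concatenated channel-wise, z-scored,
    symbolized, and each frame replaced by its symbol centroid.  If events are
    requested their 8 raw binary channels are appended unmodified; an
    event-only feature set is rejected because events alone were never used.
    """
    feature_set = feature_set.lower()
    if feature_set not in FEATURE_SETS:
        raise ValidationError(
            f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}"
        )
    streams = feature_set.split("+")
    kin_parts = [getattr(rec, s) for s in ("ssc", "si") if s in streams]
    kin = np.concatenate(kin_parts, axis=0)
    kin_ff = zscore_channels(
        FeatureFrames(X=kin, feature_set=feature_set, rate_hz_effective=rec.rate_hz)
    )
    sym = symbolize(kin_ff, n_symbols=min(n_symbols, kin_ff.N), seed=seed)
    X = sym.centroids[sym.symbols].T  # frames re-embedded as symbol centroids
    if "evt" in streams:
        X = np.concatenate([X, rec.evt.astype(np.float64)], axis=0)
    return FeatureFrames(X=X, feature_set=feature_set, rate_hz_effective=rec.rate_hz)


AUTO = "auto"


def frame_kernel(
    X: FeatureFrames, sigma: float | str = AUTO, *, subsample_seed: int = 0
) -> FrameKernel:
    """Build the ``N x N`` Gaussian frame-similarity matrix.

    With ``sigma='auto'`` the bandwidth is the median pairwise Euclidean
    distance over a seeded subsample of at most 2000 frames, excluding zero
    distances (the median heuristic).
    """
    pts = X.X.T
    if isinstance(sigma, str):
        if sigma != AUTO:
            raise ValidationError("sigma must be a positive number or 'auto'")
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(X.N, size=min(X.N, 2000), replace=False)
        dists = pdist(pts[idx])
        dists = dists[dists > 0]
        if dists.size == 0:
            raise ValidationError(
                "all frames identical; the median heuristic is undefined - pass an explicit sigma"
            )
        sigma = float(np.median(dists))
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    sq = squareform(pdist(pts, "sqeuclidean"))
    F = np.exp(-sq / (2.0 * sigma * sigma))
    F = 0.5 * (F + F.T)
    np.fill_diagonal(F, 1.0)
    return FrameKernel(F=F, sigma=float(sigma))
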