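"""Synthetic pseudo-procedure generation and trial container I/O.

The study this package emulates records da Vinci Si system streams while a
surgeon performs five training tasks back to back, treated as one continuous
"pseudo-procedure": two-handed robotic suturing, uterine horn dissection,
suspensary ligament dissection, running robotic suturing, and rectal artery
skeletonization and clipping.  The real dataset is proprietary, so this module
generates trials with the same statistical skeleton:

* task durations drawn from per-task Normal distributions matching the
  published duration statistics,
* smooth task-specific kinematics (per-channel AR(1) dynamics pulled toward a
  task-specific emission mean),
* eight binary system-event channels firing as Bernoulli processes with
  task-specific per-second rates.

Trials are written either to a single HDF5 file or to a directory of CSV
files, selected by path extension; segmentations are plain ``start,end,label``
CSV with 0-based half-open frame ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .containers import ProcedureRecording, Segmentation
from .errors import ParseError, ValidationError

#: Published per-task duration statistics (seconds): (name, mean, sd).
TASK_DURATION_STATS = (
    ("Two-handed robotic suturing", 1329.2, 733.9),
    ("Uterine horn dissection", 2159.7, 492.6),
    ("Suspensary ligament dissection", 1999.3, 1097.5),
    ("Running robotic suturing", 617.6, 126.7),
    ("Rectal artery skeletonization and clipping", 1474.7, 276.3),
)

#: Default AR(1) coefficients: each task has its own characteristic smoothness
#: (dissection tasks drift slowly; suturing has faster hand dynamics).
DEFAULT_SMOOTHNESS = (0.90, 0.97, 0.95, 0.80, 0.93)

#: Default per-second activation rates for the eight event channels
#: (camera control, left/right master clutch, following state for three
#: patient-side arms, energy activation, head in/out).  Rates differ across
#: tasks so that event features alone carry task identity.
DEFAULT_EVENT_RATES = (
    (0.05, 0.10, 0.10, 0.60, 0.60, 0.05, 0.02, 0.30),
    (0.15, 0.05, 0.08, 0.70, 0.30, 0.10, 0.25, 0.20),
    (0.20, 0.08, 0.05, 0.40, 0.60, 0.20, 0.30, 0.10),
    (0.02, 0.15, 0.15, 0.80, 0.20, 0.02, 0.01, 0.40),
    (0.10, 0.03, 0.12, 0.30, 0.40, 0.50, 0.40, 0.15),
)

N_TASKS = 5
N_EVENT_CHANNELS = 8
_EMISSION_GEOMETRY_SEED = 20170505  # fixed: emission directions are part of the study conditions


@dataclass
class GeneratorConfig:
    """Knobs of the pseudo-procedure generator.

    ``separation`` is the pairwise Euclidean distance between task emission
    means in units of ``noise_sd``; 6 puts tasks comfortably apart for a
    per-frame Bayes classifier, values near 1 make per-frame marginals overlap
    so only temporal structure distinguishes tasks.  ``time_scale`` shrinks
    all durations for desk-scale runs without touching the dynamics.
    """

    sample_rate_hz: float = 50.0
    time_scale: float = 1.0
    d_ssc: int = 12
    d_si: int = 24
    d_evt: int = N_EVENT_CHANNELS
    separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if not 0 < self.time_scale <= 1:
            raise ValidationError("time_scale must lie in (0, 1]")
        if self.d_ssc < 1 or self.d_si < 1:
            raise ValidationError("kinematic dimensions must be positive")
        if self.d_evt != N_EVENT_CHANNELS:
            raise ValidationError(f"d_evt is fixed at {N_EVENT_CHANNELS}")
        if self.separation < 0:
            raise ValidationError("separation must be nonnegative")

    @property
    def d_kin(self) -> int:
        return self.d_ssc + self.d_si


@dataclass
class TaskProfile:
    """Statistical profile of one surgical task."""

    task_id: int
    name: str
    mean_duration_s: float
    std_duration_s: float
    emission_mean: np.ndarray  # one entry per kinematic channel
    smoothness: float  # AR(1) coefficient of the latent dynamics
    noise_sd: float  # stationary sd of the kinematics around emission_mean
    event_rates: np.ndarray = field(
        default_factory=lambda: np.zeros(N_EVENT_CHANNELS)
    )  # per-second activation probability per event channel

    def __post_init__(self) -> None:
        self.emission_mean = np.asarray(self.emission_mean, dtype=np.float64)
        self.event_rates = np.asarray(self.event_rates, dtype=np.float64)
        if not 0 <= self.task_id < N_TASKS:
            raise ValidationError("task_id must lie in [0, 5)")
        if self.mean_duration_s <= 0:
            raise ValidationError("mean_duration_s must be positive")
        if self.std_duration_s < 0:
            raise ValidationError("std_duration_s must be nonnegative")
        if not 0 < self.smoothness < 1:
            raise ValidationError("smoothness must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.event_rates.shape != (N_EVENT_CHANNELS,):
            raise ValidationError(f"event_rates must have {N_EVENT_CHANNELS} entries")
        if ((self.event_rates < 0) | (self.event_rates > 1)).any():
            raise ValidationError("event_rates must lie in [0, 1]")


def default_profiles(
    config: GeneratorConfig,
    *,
    noise_sd: float = 1.0,
    smoothness: tuple[float, ...] = DEFAULT_SMOOTHNESS,
    event_rates=DEFAULT_EVENT_RATES,
) -> list[TaskProfile]:
    """Build the five default task profiles for a generator configuration.

    Emission means are placed at mutually orthogonal directions in kinematic
    space, scaled so every pair of tasks is ``config.separation * noise_sd``
    apart; the directions are fixed (independent of the trial seed) so the
    profiles describe a reproducible study population.
    """
    d = config.d_kin
    if d < N_TASKS:
        raise ValidationError("kinematic dimension must be at least the task count")
    rng = np.random.default_rng(_EMISSION_GEOMETRY_SEED)
    basis, _ = np.linalg.qr(rng.standard_normal((d, N_TASKS)))
    # orthonormal columns: pairwise distance between scaled columns is
    # scale * sqrt(2), so scale = separation * noise_sd / sqrt(2)
    means = basis.T * (config.separation * noise_sd / np.sqrt(2.0))
    return [
        TaskProfile(
            task_id=t,
            name=TASK_DURATION_STATS[t][0],
            mean_duration_s=TASK_DURATION_STATS[t][1],
            std_duration_s=TASK_DURATION_STATS[t][2],
            emission_mean=means[t],
            smoothness=smoothness[t],
            noise_sd=noise_sd,
            event_rates=np.asarray(event_rates[t], dtype=np.float64),
        )
        for t in range(N_TASKS)
    ]


def sample_durations(
    config: GeneratorConfig, profiles: list[TaskProfile], rng: np.random.Generator
) -> np.ndarray:
    """Draw the five task durations (seconds) for one trial.

    Durations are Normal(mean * time_scale, sd * time_scale), truncated below
    at ``max(5 / rate, 1 s) * time_scale`` so every task yields at least a
    handful of frames.
    """
    ts = config.time_scale
    means = np.array([p.mean_duration_s for p in profiles]) * ts
    sds = np.array([p.std_duration_s for p in profiles]) * ts
    floor = max(5.0 / config.sample_rate_hz, 1.0) * ts
    return np.maximum(rng.normal(means, sds), floor)


def _validate_profiles(config: GeneratorConfig, profiles: list[TaskProfile]) -> None:
    if len(profiles) != N_TASKS:
        raise ValidationError(f"expected {N_TASKS} task profiles, got {len(profiles)}")
    for p in profiles:
        if p.emission_mean.shape != (config.d_kin,):
            raise ValidationError(
                f"task {p.task_id}: emission_mean length {p.emission_mean.size} "
                f"!= configured kinematic dimension {config.d_kin}"
            )


def generate_trial(
    config: GeneratorConfig,
    profiles: list[TaskProfile] | None = None,
    seed: int | None = None,
    trial_id: str = "",
) -> tuple[ProcedureRecording, Segmentation]:
    """Generate one pseudo-procedure and its exact ground-truth segmentation.

    The five tasks are concatenated in fixed order 0..4.  Kinematics follow a
    per-channel AR(1) process toward the active task's emission mean with
    stationary standard deviation ``noise_sd``; the latent state carries over
    task boundaries so transitions are smooth.  Event channels fire
    independently per frame with probability ``rate / sample_rate_hz``.
    Identical ``(config, profiles, seed)`` reproduce the trial bit-exactly.
    """
    if profiles is None:
        profiles = default_profiles(config)
    _validate_profiles(config, profiles)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    durations_s = sample_durations(config, profiles, rng)
    lengths = np.maximum(np.rint(durations_s * config.sample_rate_hz).astype(np.int64), 1)
    N = int(lengths.sum())
    bounds = np.concatenate(([0], np.cumsum(lengths)))

    d = config.d_kin
    kin = np.empty((d, N))
    evt = np.empty((N_EVENT_CHANNELS, N), dtype=np.uint8)

    # start the latent state at the first task's stationary distribution
    x_prev = profiles[0].emission_mean + profiles[0].noise_sd * rng.standard_normal(d)
    for t, p in enumerate(profiles):
        n = int(lengths[t])
        a = p.smoothness
        innov_sd = p.noise_sd * np.sqrt(1.0 - a * a)
        e = innov_sd * rng.standard_normal((d, n))
        # deviation from the task mean follows y_n = a * y_{n-1} + e_n
        zi = (a * (x_prev - p.emission_mean))[:, None]
        y, _ = lfilter([1.0], [1.0, -a], e, axis=1, zi=zi)
        seg = p.emission_mean[:, None] + y
        kin[:, bounds[t] : bounds[t + 1]] = seg
        x_prev = seg[:, -1]
        p_frame = np.minimum(p.event_rates / config.sample_rate_hz, 1.0)
        evt[:, bounds[t] : bounds[t + 1]] = (
            rng.random((N_EVENT_CHANNELS, n)) < p_frame[:, None]
        ).astype(np.uint8)

    rec = ProcedureRecording(
        ssc=kin[: config.d_ssc],
        si=kin[config.d_ssc :],
        evt=evt,
        rate_hz=config.sample_rate_hz,
        trial_id=trial_id or f"synthetic-{seed}",
    )
    truth = Segmentation(boundaries=bounds, labels=np.arange(N_TASKS), K=N_TASKS, N=N)
    return rec, truth


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def write_segmentation(seg: Segmentation, path) -> None:
    """Write a segmentation as ``start,end,label`` CSV (0-based, half-open)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("start,end,label\n")
        for m in range(seg.M):
            fh.write(f"{seg.boundaries[m]},{seg.boundaries[m + 1]},{seg.labels[m]}\n")


def read_segmentation(path) -> Segmentation:
    """Read a ``start,end,label`` CSV written by :func:`write_segmentation`."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        header = fh.readline().strip()
        if header.split(",")[:3] != ["start", "end", "label"]:
            raise ParseError(f"{path}: expected header 'start,end,label', got {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 fields, got {len(parts)}")
            try:
                rows.append(tuple(int(x) for x in parts))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer field in {parts}") from exc
    if not rows:
        raise ParseError(f"{path}: no segments")
    starts = np.array([r[0] for r in rows])
    ends = np.array([r[1] for r in rows])
    labels = np.array([r[2] for r in rows])
    if not np.array_equal(starts[1:], ends[:-1]) or starts[0] != 0:
        raise ParseError(f"{path}: segments must tile [0, N) contiguously from 0")
    bounds = np.concatenate((starts, ends[-1:]))
    K = int(labels.max()) + 1
    return Segmentation(boundaries=bounds, labels=labels, K=K, N=int(ends[-1]))


def write_trial(rec: ProcedureRecording, truth: Segmentation | None, path) -> None:
    """Write a trial container.

    ``path`` ending in ``.h5``/``.hdf5`` selects a single HDF5 file with
    datasets ``/ssc``, ``/si``, ``/evt`` and attributes ``rate_hz`` and
    ``trial_id``; any other path is treated as a directory of CSV files
    (frames as rows) plus a JSON metadata sidecar.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("ssc", data=rec.ssc, dtype="f8")
            f.create_dataset("si", data=rec.si, dtype="f8")
            f.create_dataset("evt", data=rec.evt, dtype="u1")
            f.attrs["rate_hz"] = rec.rate_hz
            f.attrs["trial_id"] = rec.trial_id
            if truth is not None:
                f.create_dataset("truth/boundaries", data=truth.boundaries)
                f.create_dataset("truth/labels", data=truth.labels)
                f.attrs["truth_K"] = truth.K
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name in ("ssc", "si", "evt"):
            arr = getattr(rec, name)
            header = ",".join(f"{name}_{i}" for i in range(arr.shape[0]))
            fmt = "%d" if name == "evt" else "%.17g"
            np.savetxt(path / f"{name}.csv", arr.T, delimiter=",", header=header,
                       comments="", fmt=fmt)
        (path / "meta.json").write_text(
            json.dumps({"rate_hz": rec.rate_hz, "trial_id": rec.trial_id})
        )
        if truth is not None:
            write_segmentation(truth, path / "truth.csv")


def _read_trial_hdf5(path: Path) -> tuple[ProcedureRecording, Segmentation | None]:
    import h5py

    with h5py.File(path, "r") as f:
        for name in ("ssc", "si", "evt"):
            if name not in f:
                raise ParseError(f"{path}: missing dataset '/{name}'")
        if "rate_hz" not in f.attrs:
            raise ParseError(f"{path}: missing attribute 'rate_hz'")
        rec = ProcedureRecording(
            ssc=f["ssc"][()],
            si=f["si"][()],
            evt=f["evt"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            trial_id=str(f.attrs.get("trial_id", "")),
        )
        truth = None
        if "truth" in f:
            bounds = f["truth/boundaries"][()]
            labels = f["truth/labels"][()]
            truth = Segmentation(
                boundaries=bounds,
                labels=labels,
                K=int(f.attrs.get("truth_K", labels.max() + 1)),
                N=int(bounds[-1]),
            )
    return rec, truth


def _read_trial_csvdir(path: Path) -> tuple[ProcedureRecording, Segmentation | None]:
    arrays = {}
    for name in ("ssc", "si", "evt"):
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise ParseError(f"{path}: missing table '{name}.csv'")
        arrays[name] = np.loadtxt(fp, delimiter=",", skiprows=1, ndmin=2).T
    meta_fp = path / "meta.json"
    if not meta_fp.exists():
        raise ParseError(f"{path}: missing 'meta.json'")
    meta = json.loads(meta_fp.read_text())
    if "rate_hz" not in meta:
        raise ParseError(f"{path}: meta.json missing field 'rate_hz'")
    rec = ProcedureRecording(
        ssc=arrays["ssc"],
        si=arrays["si"],
        evt=arrays["evt"].astype(np.uint8),
        rate_hz=float(meta["rate_hz"]),
        trial_id=str(meta.get("trial_id", "")),
    )
    truth = read_segmentation(path / "truth.csv") if (path / "truth.csv").exists() else None
    return rec, truth


def read_trial(path) -> tuple[ProcedureRecording, Segmentation | None]:
    """Read a trial container written by :func:`write_trial`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_trial_hdf5(path)
    if path.is_dir():
        return _read_trial_csvdir(path)
    raise ParseError(f"{path}: not an HDF5 file or CSV directory")
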