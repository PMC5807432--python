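"""Synthetic cohorts of single-trial ROI time courses with known phase structure.

This module generates epoched, source-level signals that mimic the trial and
condition layout of a 2 x 2 gaze-by-duration face-viewing experiment: each
trial carries a ``(gaze, duration)`` label with gaze in {averted, direct} and
duration in {brief, long}.  Oscillatory "bursts" with von Mises distributed
trial phases are injected into selected regions of interest (ROIs), and
fixed-lag couplings between ROI pairs are injected for connectivity tests.
The phase concentration ``kappa`` controls the across-trial phase locking:
``kappa = 0`` gives uniform phases (no locking beyond chance), large ``kappa``
gives near-identical phases.

Everything is deterministic given the master seed; per-subject random streams
are derived with a counter-based (spawn-key) scheme so cohort generation does
not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import tukey
from scipy.spatial import Delaunay

GAZES = ("averted", "direct")
DURATIONS = ("brief", "long")

#: The four cells of the gaze-by-duration design, as (gaze, duration) tuples.
CONDITIONS = tuple((g, d) for g in GAZES for d in DURATIONS)

Condition = tuple[str, str]

#: Bilateral ROI set: early visual cortex, fusiform face area, posterior STS,
#: periamygdaloid cortex and orbitofrontal cortex, each hemisphere.
DEFAULT_ROI_NAMES = tuple(
    f"{roi}-{hemi}" for roi in ("V1", "FFA", "pSTS", "PAC", "OFC") for hemi in ("lh", "rh")
)


def _as_condition_set(conditions) -> frozenset[Condition]:
    out = frozenset(tuple(c) for c in conditions)
    for c in out:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}; must be one of {CONDITIONS}")
    return out


@dataclass(frozen=True)
class NoiseSpec:
    """Additive background noise: white Gaussian plus 1/f^exponent colored noise.

    Both components are expressed as standard deviations in the (arbitrary)
    source units of the simulation.  The colored component emulates the
    approximately 1/f background of resting MEG.
    """

    white_sd: float = 1.0
    pink_sd: float = 1.0
    exponent: float = 1.0


@dataclass(frozen=True)
class BurstSpec:
    """An oscillatory burst injected into one ROI for selected conditions.

    On trials whose label is in ``conditions`` the burst phase is drawn from a
    von Mises distribution with mean ``mu`` and concentration ``kappa``; on all
    other trials the phase is uniform, so amplitude/power is matched across
    conditions and only phase *consistency* differs.
    """

    roi: str
    conditions: frozenset[Condition]
    frequency: float
    window: tuple[float, float]
    amplitude: float = 1.0
    kappa: float = 0.0
    mu: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "conditions", _as_condition_set(self.conditions))
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.window[0] >= self.window[1]:
            raise ValueError(f"empty burst window {self.window}")


@dataclass(frozen=True)
class CouplingSpec:
    """A fixed-lag oscillation shared by two ROIs for selected conditions.

    On matching trials the first ROI receives a uniformly distributed phase
    and the second ROI the same phase plus a lag drawn from a von Mises
    distribution centred on ``phase_lag`` with concentration ``kappa``.  On
    non-matching trials both ROIs receive independent uniform phases, so the
    phase-locking value (PLV) differs between conditions while within-ROI
    phase locking does not.
    """

    roi_pair: tuple[str, str]
    conditions: frozenset[Condition]
    frequency: float
    window: tuple[float, float]
    phase_lag: float = 0.0
    kappa: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "conditions", _as_condition_set(self.conditions))
        if self.roi_pair[0] == self.roi_pair[1]:
            raise ValueError("roi_pair members must be distinct")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.window[0] >= self.window[1]:
            raise ValueError(f"empty coupling window {self.window}")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    The defaults are a desk-scale profile (12 subjects, 64 trials per
    condition, 300 Hz) preserving the design shape of a 60-subject study
    sampled at 600.615 Hz; the full scale is available by setting the fields.
    Epochs run from 0.5 s before stimulus onset to 1.44 s after.
    """

    n_subjects: int = 12
    n_trials_per_condition: int = 64
    sfreq: float = 300.0
    epoch_window: tuple[float, float] = (-0.5, 1.44)
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    bursts: tuple[BurstSpec, ...] = ()
    couplings: tuple[CouplingSpec, ...] = ()
    evoked_amplitude: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    master_seed: int = 0

    def __post_init__(self):
        self.roi_names = tuple(self.roi_names)
        self.bursts = tuple(self.bursts)
        self.couplings = tuple(self.couplings)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        tmin, tmax = self.epoch_window
        if not (tmin < 0 < tmax):
            raise ValueError("epoch_window must straddle stimulus onset (tmin < 0 < tmax)")
        nyquist = self.sfreq / 2.0
        for b in self.bursts:
            if b.frequency >= nyquist:
                raise ValueError(
                    f"burst in {b.roi!r} at {b.frequency} Hz is at or above the "
                    f"Nyquist frequency ({nyquist} Hz)"
                )
            if b.roi not in self.roi_names:
                raise ValueError(f"burst ROI {b.roi!r} not in roi_names")
            if b.window[0] < tmin or b.window[1] > tmax:
                raise ValueError(f"burst window {b.window} outside epoch {self.epoch_window}")
        for c in self.couplings:
            if c.frequency >= nyquist:
                raise ValueError(
                    f"coupling {c.roi_pair} at {c.frequency} Hz is at or above the "
                    f"Nyquist frequency ({nyquist} Hz)"
                )
            for roi in c.roi_pair:
                if roi not in self.roi_names:
                    raise ValueError(f"coupling ROI {roi!r} not in roi_names")
            if c.window[0] < tmin or c.window[1] > tmax:
                raise ValueError(f"coupling window {c.window} outside epoch {self.epoch_window}")

    @property
    def n_samples(self) -> int:
        tmin, tmax = self.epoch_window
        return int(round((tmax - tmin) * self.sfreq)) + 1

    @property
    def times(self) -> np.ndarray:
        tmin, _ = self.epoch_window
        return tmin + np.arange(self.n_samples) / self.sfreq


@dataclass
class EpochSet:
    """Single-trial ROI time courses for one subject.

    ``data`` has shape (n_trials, n_rois, n_samples) in signed, arbitrary
    source units (the stand-in for sign-preserving minimum-norm label time
    courses).  ``condition_labels[i]`` is the (gaze, duration) tuple of trial i.
    """

    subject_id: str
    data: np.ndarray
    sfreq: float
    tmin: float
    condition_labels: list[Condition]
    roi_names: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, rois, samples)")
        if len(self.condition_labels) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError("data ROI axis does not match roi_names")
        for lab in self.condition_labels:
            if tuple(lab) not in CONDITIONS:
                raise ValueError(f"unknown condition label {lab!r}")
        self.condition_labels = [tuple(l) for l in self.condition_labels]
        self.roi_names = tuple(self.roi_names)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def roi_index(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(f"ROI {roi!r} not in {self.roi_names}") from None

    def trials_in(self, conditions) -> np.ndarray:
        """Indices of trials whose label is in ``conditions`` (a condition or set)."""
        if isinstance(conditions, tuple) and len(conditions) == 2 and isinstance(conditions[0], str):
            conditions = {conditions}
        sel = _as_condition_set(conditions)
        return np.array([i for i, lab in enumerate(self.condition_labels) if lab in sel], dtype=int)

    def condition_counts(self) -> dict[Condition, int]:
        return {c: sum(1 for lab in self.condition_labels if lab == c) for c in CONDITIONS}


@dataclass
class SourceMesh:
    """A triangulated source mesh with a condition-averaged activation map.

    ``adjacency`` is a tuple of neighbor index tuples (symmetric by
    construction from the triangulation).  ``truth_label`` records the planted
    peak-plus-plateau region that a correct ≥fraction-of-max label grower must
    recover; it is ground truth for tests, not an input to any algorithm.
    """

    n_vertices: int
    adjacency: tuple[tuple[int, ...], ...]
    activation: np.ndarray
    anatomical_mask: np.ndarray
    peak_vertex: int | None = None
    truth_label: frozenset[int] | None = None

    def __post_init__(self):
        self.activation = np.asarray(self.activation, dtype=float)
        self.anatomical_mask = np.asarray(self.anatomical_mask, dtype=int)
        if self.activation.shape != (self.n_vertices,):
            raise ValueError("activation must have one value per vertex")
        if not np.all(np.isfinite(self.activation)):
            raise ValueError("non-finite activation")
        if self.anatomical_mask.size and (
            self.anatomical_mask.min() < 0 or self.anatomical_mask.max() >= self.n_vertices
        ):
            raise ValueError("anatomical_mask refers to vertices outside the mesh")
        for v, nbrs in enumerate(self.adjacency):
            for u in nbrs:
                if v not in self.adjacency[u]:
                    raise ValueError("adjacency is not symmetric")


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    # spawn-key derivation: independent substream per subject, order-free
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(subject_index,)))


def _colored_noise(rng: np.random.Generator, shape: tuple[int, ...], exponent: float,
                   sfreq: float) -> np.ndarray:
    """Unit-SD 1/f^exponent noise via spectral shaping of white noise."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _evoked_waveform(times: np.ndarray, amplitude: float) -> np.ndarray:
    """A smooth post-stimulus transient, identical on every trial."""
    resp = np.zeros_like(times)
    post = times > 0
    tp = times[post]
    resp[post] = np.sin(2 * np.pi * 4.0 * tp) * np.exp(-(((tp - 0.17) / 0.12) ** 2))
    return amplitude * resp


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> slice:
    i0 = int(np.searchsorted(times, window[0] - 1e-12))
    i1 = int(np.searchsorted(times, window[1] + 1e-12))
    return slice(i0, i1)


def simulate_subject_epochs(config: SimulationConfig, subject_index: int) -> EpochSet:
    """Simulate one subject's single-trial ROI time courses.

    Each trial is evoked component + sum of tapered cosine bursts/couplings
    + white and 1/f noise.  Deterministic given (master_seed, subject_index).
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside cohort of {config.n_subjects}")
    rng = _subject_rng(config.master_seed, subject_index)

    times = config.times
    n_per = config.n_trials_per_condition
    labels: list[Condition] = [c for c in CONDITIONS for _ in range(n_per)]
    n_trials = len(labels)
    n_rois = len(config.roi_names)
    data = np.zeros((n_trials, n_rois, times.size))

    data += _evoked_waveform(times, config.evoked_amplitude)[None, None, :]

    label_arr = np.array([f"{g}|{d}" for g, d in labels])

    for b in config.bursts:
        sl = _window_slice(times, b.window)
        t_win = times[sl]
        taper = tukey(t_win.size, 0.5)
        match = np.isin(label_arr, [f"{g}|{d}" for g, d in b.conditions])
        locked = rng.vonmises(b.mu, b.kappa, size=n_trials)
        uniform = rng.uniform(-np.pi, np.pi, size=n_trials)
        phases = np.where(match, locked, uniform)
        wave = b.amplitude * np.cos(2 * np.pi * b.frequency * t_win[None, :] + phases[:, None])
        data[:, config.roi_names.index(b.roi), sl] += wave * taper[None, :]

    for c in config.couplings:
        sl = _window_slice(times, c.window)
        t_win = times[sl]
        taper = tukey(t_win.size, 0.5)
        match = np.isin(label_arr, [f"{g}|{d}" for g, d in c.conditions])
        base = rng.uniform(-np.pi, np.pi, size=n_trials)
        lag_locked = rng.vonmises(c.phase_lag, c.kappa, size=n_trials)
        lag_uniform = rng.uniform(-np.pi, np.pi, size=n_trials)
        lag = np.where(match, lag_locked, lag_uniform)
        ia = config.roi_names.index(c.roi_pair[0])
        ib = config.roi_names.index(c.roi_pair[1])
        carrier = 2 * np.pi * c.frequency * t_win[None, :]
        data[:, ia, sl] += c.amplitude * np.cos(carrier + base[:, None]) * taper[None, :]
        data[:, ib, sl] += c.amplitude * np.cos(carrier + (base + lag)[:, None]) * taper[None, :]

    noise = config.noise
    if noise.white_sd > 0:
        data += rng.normal(0.0, noise.white_sd, size=data.shape)
    if noise.pink_sd > 0:
        data += noise.pink_sd * _colored_noise(rng, data.shape, noise.exponent, config.sfreq)

    return EpochSet(
        subject_id=f"sub-{subject_index:03d}",
        data=data,
        sfreq=config.sfreq,
        tmin=config.epoch_window[0],
        condition_labels=labels,
        roi_names=config.roi_names,
    )


def simulate_cohort(config: SimulationConfig) -> list[EpochSet]:
    """Simulate all subjects of the configured cohort."""
    return [simulate_subject_epochs(config, i) for i in range(config.n_subjects)]


def _graph_distances(adjacency, start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for v in frontier:
            for u in adjacency[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def simulate_source_map(n_vertices: int, seed: int, plateau_fraction: float = 0.6) -> SourceMesh:
    """Random triangulated mesh with one planted activation peak and plateau.

    A connected plateau around the peak receives activation at or above
    ``plateau_fraction`` of the peak value; all other in-mask vertices stay
    strictly below.  The plateau (including the peak) is recorded as
    ``truth_label`` so region-growing implementations can be checked exactly.
    """
    if n_vertices < 3:
        raise ValueError("n_vertices must be >= 3")
    if not (0 < plateau_fraction <= 1):
        raise ValueError("plateau_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    points = rng.random((n_vertices, 2))
    tri = Delaunay(points)
    nbrs: list[set[int]] = [set() for _ in range(n_vertices)]
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
    adjacency = tuple(tuple(sorted(s)) for s in nbrs)

    peak = int(rng.integers(n_vertices))
    dist = _graph_distances(adjacency, peak)
    plateau = sorted(v for v, d in dist.items() if d <= 2)
    mask = sorted(v for v, d in dist.items() if d <= 4)

    activation = np.zeros(n_vertices)
    in_mask = np.zeros(n_vertices, bool)
    in_mask[mask] = True
    low = rng.uniform(0.02, max(plateau_fraction - 0.05, 0.01), size=n_vertices)
    activation[in_mask] = low[in_mask]
    activation[~in_mask] = rng.uniform(0.0, 1.0, size=(~in_mask).sum())
    activation[plateau] = rng.uniform(plateau_fraction + 0.01, 0.98, size=len(plateau))
    activation[peak] = 1.0

    return SourceMesh(
        n_vertices=n_vertices,
        adjacency=adjacency,
        activation=activation,
        anatomical_mask=np.array(mask, dtype=int),
        peak_vertex=peak,
        truth_label=frozenset(plateau),
    )


def default_config(**overrides) -> SimulationConfig:
    """Desk-scale cohort with effect templates patterned on the study design.

    Injected structure:

    * a stimulus-evoked 10 Hz burst in bilateral V1 locked in every condition
      (generic evoked phase locking);
    * an early (80-220 ms) beta burst in right PAC locked only for averted
      gaze (the early averted-gaze advantage);
    * a ~350 ms alpha burst in left FFA locked only for brief direct gaze;
    * a 700-950 ms alpha burst in right pSTS locked only for long direct gaze;
    * an early alpha coupling between left PAC and left OFC with a fixed
      pi/4 lag, locked only for averted gaze.
    """
    avert = frozenset({("averted", "brief"), ("averted", "long")})
    cfg = dict(
        bursts=(
            BurstSpec("V1-lh", frozenset(CONDITIONS), 10.0, (0.05, 0.25), 1.5, kappa=8.0),
            BurstSpec("V1-rh", frozenset(CONDITIONS), 10.0, (0.05, 0.25), 1.5, kappa=8.0),
            BurstSpec("PAC-rh", avert, 20.0, (0.08, 0.22), 1.0, kappa=6.0),
            BurstSpec("FFA-lh", frozenset({("direct", "brief")}), 10.0, (0.30, 0.45), 1.0, kappa=4.0),
            BurstSpec("pSTS-rh", frozenset({("direct", "long")}), 10.0, (0.70, 0.95), 1.0, kappa=4.0),
        ),
        couplings=(
            CouplingSpec(("PAC-lh", "OFC-lh"), avert, 10.0, (0.08, 0.22),
                         phase_lag=np.pi / 4, kappa=6.0),
        ),
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
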