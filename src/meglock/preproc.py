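"""Trial rejection, quality screening, filtering and evoked/contrast waves.

The preprocessing branch mirrors standard MEG practice: epochs whose
peak-to-peak amplitude exceeds a per-signal threshold are dropped; a signal
(here, an ROI time course) responsible for the rejection of 20% or more of
epochs is excluded from analysis instead of being allowed to discard data;
the time-course branch is low-pass filtered at 40 Hz and analysed on a
-200..+1300 ms window, while the time-frequency branch stays unfiltered on
the wide -500..+1440 ms window.  Evoked responses may be noise-normalized by
the pre-stimulus baseline standard deviation, a diagonal approximation of
dSPM-style noise normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .synth import CONDITIONS, Condition, EpochSet


@dataclass
class PreprocConfig:
    """Thresholds and windows for the two analysis branches.

    ``rejection_thresholds`` is either one peak-to-peak limit applied to every
    ROI or a mapping from ROI name to its limit, in the same (arbitrary,
    config-relative) units as the data.
    """

    rejection_thresholds: float | dict[str, float] = 25.0
    channel_exclusion_fraction: float = 0.20
    lowpass_cutoff: float = 40.0
    timecourse_window: tuple[float, float] = (-0.2, 1.3)
    tf_window: tuple[float, float] = (-0.5, 1.44)
    baseline_window: tuple[float, float] = (-0.2, 0.0)

    def __post_init__(self):
        if not (0 < self.channel_exclusion_fraction <= 1):
            raise ValueError("channel_exclusion_fraction must lie in (0, 1]")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline_window must precede stimulus onset")

    def threshold_for(self, roi: str) -> float:
        if isinstance(self.rejection_thresholds, dict):
            thr = self.rejection_thresholds[roi]
        else:
            thr = self.rejection_thresholds
        if thr <= 0:
            raise ValueError(f"rejection threshold for {roi!r} must be positive")
        return float(thr)


@dataclass
class RejectionReport:
    subject_id: str
    n_input_trials: int
    kept_trials: list[int]
    #: trial index -> list of (roi, peak_to_peak, limit) causes
    causes: dict[int, list[tuple[str, float, float]]]
    #: fraction of input epochs each ROI would reject on its own
    roi_rejection_fraction: dict[str, float]
    #: ROIs excluded under the >=channel_exclusion_fraction rule
    excluded_rois: list[str]
    condition_counts: dict[Condition, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_input_trials": self.n_input_trials,
            "n_kept_trials": len(self.kept_trials),
            "kept_trials": list(map(int, self.kept_trials)),
            "causes": {
                str(t): [[roi, float(p), float(l)] for roi, p, l in cs]
                for t, cs in self.causes.items()
            },
            "roi_rejection_fraction": {k: float(v) for k, v in self.roi_rejection_fraction.items()},
            "excluded_rois": list(self.excluded_rois),
            "condition_counts": {f"{g}/{d}": int(n) for (g, d), n in self.condition_counts.items()},
        }


def reject_trials(epochs: EpochSet, config: PreprocConfig,
                  exclude_flagged_rois: bool = True) -> tuple[EpochSet, RejectionReport]:
    """Drop trials whose peak-to-peak amplitude exceeds any ROI's threshold.

    An ROI whose spikes would on its own reject at least
    ``channel_exclusion_fraction`` of epochs is excluded from the returned
    EpochSet (when ``exclude_flagged_rois``) and no longer contributes to
    rejection, preventing one bad channel from discarding the recording.
    """
    limits = np.array([config.threshold_for(r) for r in epochs.roi_names])
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x rois
    exceed = ptp > limits[None, :]

    frac = exceed.mean(axis=0)
    flagged = [r for r, f in zip(epochs.roi_names, frac) if f >= config.channel_exclusion_fraction]

    keep_roi = np.ones(len(epochs.roi_names), bool)
    if exclude_flagged_rois and flagged:
        keep_roi = np.array([r not in flagged for r in epochs.roi_names])
        if not keep_roi.any():
            raise ValueError(
                f"every ROI flagged for exclusion for subject {epochs.subject_id!r}; "
                "recording unusable"
            )

    effective = exceed[:, keep_roi]
    drop = effective.any(axis=1)
    kept = np.nonzero(~drop)[0]
    if kept.size == 0:
        raise ValueError(f"all trials rejected for subject {epochs.subject_id!r}")

    causes: dict[int, list[tuple[str, float, float]]] = {}
    roi_names = np.array(epochs.roi_names)
    for t in np.nonzero(drop)[0]:
        js = np.nonzero(exceed[t] & keep_roi)[0]
        causes[int(t)] = [(str(roi_names[j]), float(ptp[t, j]), float(limits[j])) for j in js]

    out = EpochSet(
        subject_id=epochs.subject_id,
        data=epochs.data[np.ix_(kept, np.nonzero(keep_roi)[0])],
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        condition_labels=[epochs.condition_labels[i] for i in kept],
        roi_names=tuple(r for r, k in zip(epochs.roi_names, keep_roi) if k),
    )
    report = RejectionReport(
        subject_id=epochs.subject_id,
        n_input_trials=epochs.n_trials,
        kept_trials=[int(i) for i in kept],
        causes=causes,
        roi_rejection_fraction={r: float(f) for r, f in zip(epochs.roi_names, frac)},
        excluded_rois=flagged if exclude_flagged_rois else [],
        condition_counts=out.condition_counts(),
    )
    return out, report


@dataclass
class BalanceStats:
    """Per-condition surviving trial counts across a cohort."""

    counts: np.ndarray  # subjects x conditions, ordered as CONDITIONS
    conditions: tuple[Condition, ...]
    min_count: int
    #: (condition A, condition B) -> paired-test p-value across subjects
    pairwise_p: dict[tuple[Condition, Condition], float]


def check_trial_balance(reports: list[RejectionReport]) -> BalanceStats:
    """Compare surviving trial counts between conditions across subjects.

    Uses a paired t-test per condition pair.  Identical counts in every
    subject give p = 1 (no evidence of imbalance); a constant nonzero
    difference (zero variance) gives p = 0.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 subjects for a balance check")
    counts = np.array([[r.condition_counts.get(c, 0) for c in CONDITIONS] for r in reports],
                      dtype=float)
    pairwise: dict[tuple[Condition, Condition], float] = {}
    for i, a in enumerate(CONDITIONS):
        for j in range(i + 1, len(CONDITIONS)):
            b = CONDITIONS[j]
            diff = counts[:, i] - counts[:, j]
            if np.allclose(diff, 0):
                p = 1.0
            elif np.allclose(diff, diff[0]):
                p = 0.0
            else:
                p = float(stats.ttest_rel(counts[:, i], counts[:, j]).pvalue)
            pairwise[(a, b)] = p
    return BalanceStats(
        counts=counts.astype(int),
        conditions=CONDITIONS,
        min_count=int(counts.min()),
        pairwise_p=pairwise,
    )


def lowpass_filter(epochs: EpochSet, cutoff: float) -> EpochSet:
    """Zero-phase low-pass (4th-order Butterworth, forward-backward)."""
    if cutoff >= epochs.sfreq / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({epochs.sfreq / 2} Hz)")
    sos = signal.butter(4, cutoff, btype="low", fs=epochs.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=2)
    return EpochSet(
        subject_id=epochs.subject_id,
        data=filtered,
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        condition_labels=list(epochs.condition_labels),
        roi_names=epochs.roi_names,
    )


def crop_epochs(epochs: EpochSet, tmin: float, tmax: float) -> EpochSet:
    """Restrict epochs to [tmin, tmax] (inclusive, sample-aligned)."""
    times = epochs.times
    keep = (times >= tmin - 1e-9) & (times <= tmax + 1e-9)
    if not keep.any():
        raise ValueError(f"window [{tmin}, {tmax}] outside epoch [{times[0]}, {times[-1]}]")
    new_tmin = float(times[keep][0])
    return EpochSet(
        subject_id=epochs.subject_id,
        data=epochs.data[:, :, keep],
        sfreq=epochs.sfreq,
        tmin=new_tmin,
        condition_labels=list(epochs.condition_labels),
        roi_names=epochs.roi_names,
    )


@dataclass
class EvokedTimecourse:
    """Trial-averaged ROI time courses for one condition of one subject."""

    values: np.ndarray  # rois x samples
    roi_names: tuple[str, ...]
    sfreq: float
    tmin: float
    n_trials: int
    condition: Condition
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite evoked values")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.values.shape[1]) / self.sfreq


@dataclass
class ContrastWave:
    """One subject's condition-A-minus-condition-B evoked wave for one ROI."""

    values: np.ndarray
    roi: str
    condition_pair: tuple[Condition, Condition]
    sfreq: float
    tmin: float
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


def evoked(epochs: EpochSet, condition: Condition) -> EvokedTimecourse:
    """Average the trials of one condition."""
    idx = epochs.trials_in(condition)
    if idx.size == 0:
        raise ValueError(f"no surviving trials in condition {condition!r} "
                         f"for subject {epochs.subject_id!r}")
    return EvokedTimecourse(
        values=epochs.data[idx].mean(axis=0),
        roi_names=epochs.roi_names,
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        n_trials=int(idx.size),
        condition=tuple(condition),
        subject_id=epochs.subject_id,
    )


def baseline_noise_normalize(evk: EvokedTimecourse,
                             baseline_window: tuple[float, float]) -> EvokedTimecourse:
    """Divide each ROI by its baseline-period standard deviation.

    This is the diagonal approximation of dSPM noise normalization: the full
    sensor noise covariance is replaced by each source's own baseline
    variability, making the output scale-invariant and unitless.
    """
    times = evk.times
    inb = (times >= baseline_window[0] - 1e-9) & (times <= baseline_window[1] + 1e-9)
    if inb.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    sd = evk.values[:, inb].std(axis=1, ddof=1)
    for roi, s in zip(evk.roi_names, sd):
        if s == 0:
            raise ValueError(f"zero baseline variance in ROI {roi!r}")
    return EvokedTimecourse(
        values=evk.values / sd[:, None],
        roi_names=evk.roi_names,
        sfreq=evk.sfreq,
        tmin=evk.tmin,
        n_trials=evk.n_trials,
        condition=evk.condition,
        subject_id=evk.subject_id,
    )


def evoked_and_contrast(epochs: EpochSet, condition_a: Condition,
                        condition_b: Condition) -> dict[str, ContrastWave]:
    """Per-ROI contrast waves: trial mean of A minus trial mean of B."""
    ev_a = evoked(epochs, condition_a)
    ev_b = evoked(epochs, condition_b)
    diff = ev_a.values - ev_b.values
    return {
        roi: ContrastWave(
            values=diff[i],
            roi=roi,
            condition_pair=(tuple(condition_a), tuple(condition_b)),
            sfreq=epochs.sfreq,
            tmin=epochs.tmin,
            subject_id=epochs.subject_id,
        )
        for i, roi in enumerate(epochs.roi_names)
    }
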