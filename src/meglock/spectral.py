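"""Complex Morlet wavelet time-frequency decomposition.

The wavelet family uses a number of cycles equal to f/7 at every analysis
frequency f.  With the Gaussian-envelope convention sigma_t = n_cycles /
(2*pi*f) this makes the temporal standard deviation identical at every
frequency (sigma_t = 1/(14*pi) s, about 22.7 ms), i.e. a constant analysis
time window across the 8-30 Hz grid, trading frequency resolution at high f
for uniform temporal resolution.

Note that at the low end of the grid the wavelet holds barely more than one
cycle (8/7 cycles at 8 Hz) and is deliberately *not* corrected to zero mean:
the family is applied exactly as specified, and the resulting DC leakage at
low frequencies is accepted and documented rather than silently altered.
Edge-contaminated samples (within half a kernel of the epoch boundaries) are
trimmed, not zero-padded, so every retained phase estimate is supported by
real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .synth import Condition, EpochSet

#: Cycle rule: n_cycles = f / CYCLES_DIVISOR.
CYCLES_DIVISOR = 7.0

#: Default analysis grid, integer steps over the alpha and beta ranges.
DEFAULT_FREQS = np.arange(8.0, 31.0)

#: Band definitions in Hz.  13 Hz belongs to alpha; beta starts above 13.
BANDS: dict[str, tuple[float, float]] = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class Wavelet:
    frequency: float
    n_cycles: float
    sigma_t: float
    sfreq: float
    kernel: np.ndarray  # complex, unit energy

    @property
    def half_width(self) -> int:
        return (len(self.kernel) - 1) // 2


def make_morlet(frequency: float, sfreq: float) -> Wavelet:
    """Complex Morlet wavelet with n_cycles = f/7 and unit-energy kernel.

    sigma_t = n_cycles/(2*pi*f) is independent of f, so the kernel support
    (+-5 sigma_t) is the same number of samples at every grid frequency.
    """
    if not 0 < frequency < sfreq / 2:
        raise ValueError(f"frequency {frequency} Hz must lie in (0, Nyquist={sfreq / 2} Hz)")
    n_cycles = frequency / CYCLES_DIVISOR
    # n_cycles/(2*pi*f) reduces to a frequency-free constant: evaluate it that
    # way so the constant-window property holds to the last bit
    sigma_t = 1.0 / (2 * np.pi * CYCLES_DIVISOR)
    half = int(np.ceil(5 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    kernel = np.exp(2j * np.pi * frequency * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kernel = kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))
    return Wavelet(frequency=float(frequency), n_cycles=float(n_cycles),
                   sigma_t=float(sigma_t), sfreq=float(sfreq), kernel=kernel)


@dataclass
class TFR:
    """Complex single-trial wavelet coefficients for one ROI.

    ``coefficients`` has shape (n_trials, n_freqs, n_times); the instantaneous
    phase is the complex argument.  ``times`` is already trimmed of the
    edge-contaminated samples at each end of the epoch.
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    roi: str
    subject_id: str = ""
    condition_labels: list[Condition] | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.coefficients.shape[1:] != (self.freqs.size, self.times.size):
            raise ValueError("coefficient axes do not match freqs/times")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite wavelet coefficients")

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]

    def phases(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def select_conditions(self, conditions) -> "TFR":
        """Subset the trials whose labels fall in ``conditions``."""
        if self.condition_labels is None:
            raise ValueError("TFR carries no condition labels")
        if isinstance(conditions, tuple) and conditions and isinstance(conditions[0], str):
            conditions = {conditions}
        sel = {tuple(c) for c in conditions}
        idx = [i for i, lab in enumerate(self.condition_labels) if tuple(lab) in sel]
        if not idx:
            raise ValueError(f"no trials in conditions {sorted(sel)}")
        return TFR(
            coefficients=self.coefficients[idx],
            freqs=self.freqs,
            times=self.times,
            sfreq=self.sfreq,
            roi=self.roi,
            subject_id=self.subject_id,
            condition_labels=[self.condition_labels[i] for i in idx],
        )


def _tfr_array(data: np.ndarray, sfreq: float, freqs: np.ndarray) -> tuple[np.ndarray, int]:
    """Wavelet-transform (trials, samples) data; returns (coeffs, trim)."""
    wavelets = [make_morlet(f, sfreq) for f in freqs]
    half = wavelets[0].half_width  # identical across the grid by construction
    n_samples = data.shape[-1]
    if n_samples < len(wavelets[0].kernel):
        raise ValueError(
            f"epoch of {n_samples} samples is shorter than the wavelet kernel "
            f"({len(wavelets[0].kernel)} samples); need at least {len(wavelets[0].kernel)}"
        )
    out = np.empty((data.shape[0], len(wavelets), n_samples - 2 * half), dtype=complex)
    for j, w in enumerate(wavelets):
        conv = fftconvolve(data, np.conj(w.kernel[::-1])[None, :], mode="same", axes=-1)
        out[:, j, :] = conv[:, half:n_samples - half]
    return out, half


def tfr_transform(epochs: EpochSet, freqs: np.ndarray = DEFAULT_FREQS,
                  rois: list[str] | None = None) -> dict[str, TFR]:
    """Per-ROI single-trial wavelet decomposition of an EpochSet.

    Samples within half a kernel of either epoch edge are trimmed from the
    output; with the constant-window family the trim is the same at every
    frequency, so the time axis stays rectangular.
    """
    freqs = np.asarray(freqs, float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    names = list(rois) if rois is not None else list(epochs.roi_names)
    out: dict[str, TFR] = {}
    for roi in names:
        i = epochs.roi_index(roi)
        coeffs, half = _tfr_array(epochs.data[:, i, :], epochs.sfreq, freqs)
        times = epochs.times[half:epochs.n_samples - half]
        out[roi] = TFR(
            coefficients=coeffs,
            freqs=freqs,
            times=times,
            sfreq=epochs.sfreq,
            roi=roi,
            subject_id=epochs.subject_id,
            condition_labels=list(epochs.condition_labels),
        )
    return out


def band_mask(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Boolean mask of grid frequencies belonging to a band.

    Named bands follow the 13-Hz ownership rule: alpha is 8 <= f <= 13,
    beta is 13 < f <= 30 (the shared printed endpoint is assigned to alpha).
    A (low, high) tuple selects low <= f <= high.
    """
    freqs = np.asarray(freqs, float)
    if isinstance(band, str):
        try:
            lo, hi = BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
        mask = (freqs > lo) & (freqs <= hi) if band == "beta" else (freqs >= lo) & (freqs <= hi)
    else:
        lo, hi = band
        mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band!r} selects no grid frequencies from {freqs}")
    return mask


def band_slice(obj, band: str | tuple[float, float]):
    """Restrict a TFR or PhaseLockingMap to one frequency band."""
    mask = band_mask(obj.freqs, band)
    from .phase_locking import PhaseLockingMap  # local import to avoid a cycle

    if isinstance(obj, TFR):
        return TFR(
            coefficients=obj.coefficients[:, mask, :],
            freqs=obj.freqs[mask],
            times=obj.times,
            sfreq=obj.sfreq,
            roi=obj.roi,
            subject_id=obj.subject_id,
            condition_labels=None if obj.condition_labels is None
            else list(obj.condition_labels),
        )
    if isinstance(obj, PhaseLockingMap):
        return PhaseLockingMap(
            values=obj.values[mask, :],
            mask=obj.mask[mask, :],
            freqs=obj.freqs[mask],
            times=obj.times,
            kind=obj.kind,
            label=obj.label,
            n_trials=obj.n_trials,
            subject_id=obj.subject_id,
            condition=obj.condition,
        )
    raise TypeError(f"cannot band-slice object of type {type(obj).__name__}")
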