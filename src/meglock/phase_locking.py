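"""Across-trial phase-consistency statistics: PLF within an ROI, PLV between two.

Both statistics are the magnitude of the circular mean of unit phasors and
lie in [0, 1], with 1 meaning perfect synchrony.  The phase-locking factor
(PLF, also called inter-trial coherence) measures the consistency of the
phase angle across trials at each time-frequency point within one region:

    PLF(t, f) = | (1/N) sum_n exp(i * phi_n(t, f)) |

The phase-locking value (PLV) applies the same estimator to the across-trial
distribution of phase *differences* between two regions and indexes
functional connectivity:

    PLV(t, f) = | (1/N) sum_n exp(i * (phi_n^a(t, f) - phi_n^b(t, f))) |

Under independent uniform phases E[PLF^2] = 1/N, so the chance level scales
as 1/sqrt(N); no small-sample bias correction is applied, since trial counts
are balanced by design and verified upstream.  Points where any trial has a
zero-magnitude coefficient (undefined angle) are masked, never silently
treated as zero phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import TFR
from .synth import Condition


@dataclass
class PhaseLockingMap:
    """A frequency-by-time map of PLF or PLV values in [0, 1].

    ``mask`` is True where the value is undefined (some trial had zero
    coefficient magnitude there); such points carry value NaN.
    """

    values: np.ndarray  # freqs x times
    mask: np.ndarray  # freqs x times, True = undefined
    freqs: np.ndarray
    times: np.ndarray
    kind: str  # "plf" or "plv"
    label: str  # ROI name, or "roiA:roiB" for a pair
    n_trials: int
    subject_id: str = ""
    condition: Condition | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("values axes do not match freqs/times")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if self.n_trials < 2:
            raise ValueError("phase locking requires at least 2 trials")
        ok = self.values[~self.mask]
        if ok.size and (ok.min() < -1e-9 or ok.max() > 1 + 1e-9):
            raise ValueError("phase-locking values must lie in [0, 1]")


def _unit_phasors(coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize coefficients to unit magnitude; flag zero-magnitude points."""
    mag = np.abs(coeffs)
    undefined = mag == 0
    phasors = np.where(undefined, 0.0, coeffs / np.where(undefined, 1.0, mag))
    return phasors, undefined.any(axis=0)


def plf(tfr: TFR, condition: Condition | None = None) -> PhaseLockingMap:
    """Phase-locking factor across trials of a single-ROI TFR."""
    if condition is not None:
        tfr = tfr.select_conditions(condition)
    if tfr.n_trials < 2:
        raise ValueError("PLF requires at least 2 trials")
    phasors, undef = _unit_phasors(tfr.coefficients)
    values = np.abs(phasors.mean(axis=0))
    values = np.clip(values, 0.0, 1.0)
    values[undef] = np.nan
    return PhaseLockingMap(
        values=values, mask=undef, freqs=tfr.freqs, times=tfr.times,
        kind="plf", label=tfr.roi, n_trials=tfr.n_trials,
        subject_id=tfr.subject_id, condition=condition,
    )


def plv(tfr_a: TFR, tfr_b: TFR, condition: Condition | None = None) -> PhaseLockingMap:
    """Phase-locking value between two trial-aligned single-ROI TFRs."""
    if condition is not None:
        tfr_a = tfr_a.select_conditions(condition)
        tfr_b = tfr_b.select_conditions(condition)
    if tfr_a.n_trials != tfr_b.n_trials:
        raise ValueError(
            f"trial-count mismatch: {tfr_a.roi} has {tfr_a.n_trials}, "
            f"{tfr_b.roi} has {tfr_b.n_trials}"
        )
    if tfr_a.n_trials < 2:
        raise ValueError("PLV requires at least 2 trials")
    if not (np.array_equal(tfr_a.freqs, tfr_b.freqs)
            and np.allclose(tfr_a.times, tfr_b.times)):
        raise ValueError("frequency/time grids of the two TFRs do not match")

    pa, undef_a = _unit_phasors(tfr_a.coefficients)
    pb, undef_b = _unit_phasors(tfr_b.coefficients)
    diff = pa * np.conj(pb)  # unit phasor of the phase difference
    undef = undef_a | undef_b
    values = np.clip(np.abs(diff.mean(axis=0)), 0.0, 1.0)
    values[undef] = np.nan
    return PhaseLockingMap(
        values=values, mask=undef, freqs=tfr_a.freqs, times=tfr_a.times,
        kind="plv", label=f"{tfr_a.roi}:{tfr_b.roi}", n_trials=tfr_a.n_trials,
        subject_id=tfr_a.subject_id, condition=condition,
    )


def plf_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLF of an array of phase angles with trials on the first axis.

    Convenience for calibration work (e.g. verifying E[PLF^2] = 1/N under
    uniform phases) without building a TFR.
    """
    phases = np.asarray(phases, float)
    return np.abs(np.exp(1j * phases).mean(axis=0))
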