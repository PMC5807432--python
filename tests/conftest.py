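import numpy as np
import pytest

import meglock as mg

A = ("averted", "brief")
B = ("direct", "brief")


@pytest.fixture(scope="session")
def tiny_epochs() -> mg.EpochSet:
    """A small noisy cohort member used by several structural tests."""
    cfg = mg.SimulationConfig(
        n_subjects=1, n_trials_per_condition=6, sfreq=300.0,
        roi_names=("R1", "R2"),
        bursts=(mg.BurstSpec("R1", frozenset({A}), 10.0, (0.1, 0.4), 1.0, kappa=5.0),),
        master_seed=7,
    )
    return mg.simulate_subject_epochs(cfg, 0)


def phases_to_tfr(phases: np.ndarray, roi: str = "R1",
                  magnitudes: np.ndarray | None = None) -> mg.TFR:
    """Build a TFR whose coefficients have the given phases (trials, F, T)."""
    phases = np.asarray(phases, float)
    coeffs = np.exp(1j * phases)
    if magnitudes is not None:
        coeffs = coeffs * magnitudes
    n_t = phases.shape[2]
    return mg.TFR(
        coefficients=coeffs,
        freqs=np.arange(8.0, 8.0 + phases.shape[1]),
        times=np.arange(n_t) / 100.0,
        sfreq=100.0,
        roi=roi,
    )
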