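"""End-to-end orchestration: cohort -> preprocessing -> two branches -> tables.

Branch 1 (time domain): epochs are cropped to the time-course window,
low-pass filtered at 40 Hz, averaged per condition, baseline-noise-normalized
and subtracted into per-subject contrast waves, which enter a sign-flip
cluster-mass permutation test per ROI.

Branch 2 (time-frequency): unfiltered epochs on the wide window are wavelet
decomposed; per-condition PLF maps per ROI and PLV maps per configured ROI
pair are computed, split into alpha and beta bands, Gaussian smoothed, and
submitted to the constrained label-shuffle cluster test per contrast.

The four default contrasts are the gaze contrasts within each duration and
the duration contrasts within each gaze.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster_stats import Cluster, PermutationConfig, permutation_test_time, permutation_test_tf
from .io import write_cohort, write_json, write_maps
from .phase_locking import PhaseLockingMap, plf, plv
from .preproc import (PreprocConfig, baseline_noise_normalize, check_trial_balance, crop_epochs,
                      evoked, lowpass_filter, reject_trials)
from .spectral import DEFAULT_FREQS, band_slice, tfr_transform
from .synth import Condition, EpochSet, SimulationConfig, default_config, simulate_cohort

logger = logging.getLogger("meglock")

#: Gaze contrasts within each duration, then duration contrasts within each gaze.
DEFAULT_CONTRASTS: tuple[tuple[Condition, Condition], ...] = (
    (("averted", "brief"), ("direct", "brief")),
    (("averted", "long"), ("direct", "long")),
    (("averted", "brief"), ("averted", "long")),
    (("direct", "brief"), ("direct", "long")),
)

RESULT_COLUMNS = [
    "analysis", "label", "hemisphere", "band", "contrast", "direction",
    "t_start_ms", "t_end_ms", "f_low_hz", "f_high_hz", "mass", "p",
    "significant", "n_subjects",
]


@dataclass
class AnalysisConfig:
    simulation: SimulationConfig = field(default_factory=default_config)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    freqs: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    bands: tuple[str, ...] = ("alpha", "beta")
    contrasts: tuple[tuple[Condition, Condition], ...] = DEFAULT_CONTRASTS
    #: ROI pairs for PLV; None derives the pairs from the simulated couplings.
    plv_pairs: tuple[tuple[str, str], ...] | None = None
    normalize_timecourse: bool = True

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        valid = set()
        for a, b in self.contrasts:
            valid.update((tuple(a), tuple(b)))
        from .synth import CONDITIONS
        unknown = valid - set(CONDITIONS)
        if unknown:
            raise ValueError(f"contrasts reference unknown conditions: {sorted(unknown)}")

    def resolved_plv_pairs(self) -> tuple[tuple[str, str], ...]:
        if self.plv_pairs is not None:
            return tuple((a, b) for a, b in self.plv_pairs)
        return tuple(c.roi_pair for c in self.simulation.couplings)


def _contrast_name(pair: tuple[Condition, Condition]) -> str:
    (ga, da), (gb, db) = pair
    return f"{ga}-{da}_vs_{gb}-{db}"


def _hemisphere(label: str) -> str:
    parts = [p for p in label.split(":")]
    hemis = {p.rsplit("-", 1)[-1] for p in parts if "-" in p}
    if hemis == {"lh"}:
        return "lh"
    if hemis == {"rh"}:
        return "rh"
    return "both"


def _cluster_row(cl: Cluster, analysis: str, label: str, band: str, contrast: str,
                 times: np.ndarray, freqs: np.ndarray | None, n_subjects: int,
                 alpha: float) -> dict:
    if freqs is None:
        t_idx = cl.indices[0]
        f_low = f_high = np.nan
    else:
        f_idx, t_idx = cl.indices
        f_low, f_high = float(freqs[f_idx].min()), float(freqs[f_idx].max())
    return {
        "analysis": analysis,
        "label": label,
        "hemisphere": _hemisphere(label),
        "band": band,
        "contrast": contrast,
        "direction": "A>B" if cl.sign > 0 else "B>A",
        "t_start_ms": round(float(times[t_idx].min()) * 1000, 3),
        "t_end_ms": round(float(times[t_idx].max()) * 1000, 3),
        "f_low_hz": f_low,
        "f_high_hz": f_high,
        "mass": round(float(cl.mass), 6),
        "p": float(cl.p),
        "significant": bool(cl.p <= alpha),
        "n_subjects": n_subjects,
    }


def _perm_config(base: PermutationConfig, test_index: int) -> PermutationConfig:
    # deterministic, distinct stream per statistical test
    return dataclasses.replace(base, seed=int(base.seed) + 104729 * (test_index + 1))


def run_pipeline(config: AnalysisConfig, out_dir: str | Path | None = None,
                 cohort: list[EpochSet] | None = None) -> pd.DataFrame:
    """Run both analysis branches and return the cluster results table.

    With ``out_dir`` set, persists the rejection reports, the per-subject
    phase-locking maps, the results table (CSV + JSON) and a run log with the
    seeds and counts used.
    """
    if cohort is None:
        logger.info("simulating cohort of %d subjects", config.simulation.n_subjects)
        cohort = simulate_cohort(config.simulation)

    clean: list[EpochSet] = []
    reports = []
    for es in cohort:
        ces, rep = reject_trials(es, config.preproc)
        clean.append(ces)
        reports.append(rep)
    balance = check_trial_balance(reports) if len(reports) >= 2 else None
    if balance is not None:
        logger.info("minimum surviving trials per condition: %d", balance.min_count)

    n_subjects = len(clean)
    rows: list[dict] = []
    test_index = 0

    # ---- branch 1: time domain ------------------------------------------
    tc_waves: dict[tuple[str, int], list[np.ndarray]] = {}
    tc_times = None
    for es in clean:
        tc = crop_epochs(es, *config.preproc.timecourse_window)
        tc = lowpass_filter(tc, config.preproc.lowpass_cutoff)
        tc_times = tc.times
        evs = {}
        for pair in config.contrasts:
            for cond in pair:
                if cond not in evs:
                    ev = evoked(tc, cond)
                    if config.normalize_timecourse:
                        ev = baseline_noise_normalize(ev, config.preproc.baseline_window)
                    evs[cond] = ev
        for ci, (a, b) in enumerate(config.contrasts):
            diff = evs[a].values - evs[b].values
            for ri, roi in enumerate(tc.roi_names):
                tc_waves.setdefault((roi, ci), []).append(diff[ri])

    for ci, pair in enumerate(config.contrasts):
        cname = _contrast_name(pair)
        for roi in clean[0].roi_names:
            waves = np.stack(tc_waves[(roi, ci)])
            clusters = permutation_test_time(waves, _perm_config(config.permutation, test_index))
            test_index += 1
            for cl in clusters:
                rows.append(_cluster_row(cl, "timecourse", roi, "", cname, tc_times, None,
                                         n_subjects, config.permutation.cluster_alpha))

    # ---- branch 2: time-frequency ---------------------------------------
    conditions_needed = sorted({tuple(c) for pair in config.contrasts for c in pair})
    pairs = config.resolved_plv_pairs()
    plf_rois = list(clean[0].roi_names)
    pair_rois = sorted({r for p in pairs for r in p})

    all_maps: dict[tuple[str, str, Condition], list[PhaseLockingMap]] = {}
    stored_maps: list[PhaseLockingMap] = []
    for es in clean:
        tf = crop_epochs(es, *config.preproc.tf_window)
        tfrs = tfr_transform(tf, config.freqs, rois=sorted(set(plf_rois) | set(pair_rois)))
        for roi in plf_rois:
            for cond in conditions_needed:
                m = plf(tfrs[roi], condition=cond)
                all_maps.setdefault(("plf", roi, cond), []).append(m)
                stored_maps.append(m)
        for a, b in pairs:
            for cond in conditions_needed:
                m = plv(tfrs[a], tfrs[b], condition=cond)
                all_maps.setdefault(("plv", f"{a}:{b}", cond), []).append(m)
                stored_maps.append(m)
        del tfrs

    tested_labels = [("plf", roi) for roi in plf_rois] + \
                    [("plv", f"{a}:{b}") for a, b in pairs]
    for kind, label in tested_labels:
        for pair in config.contrasts:
            cname = _contrast_name(pair)
            a_cond, b_cond = pair
            for band in config.bands:
                maps_a = [band_slice(m, band) for m in all_maps[(kind, label, tuple(a_cond))]]
                maps_b = [band_slice(m, band) for m in all_maps[(kind, label, tuple(b_cond))]]
                clusters = permutation_test_tf(maps_a, maps_b,
                                               _perm_config(config.permutation, test_index))
                test_index += 1
                for cl in clusters:
                    rows.append(_cluster_row(cl, kind, label, band, cname,
                                             maps_a[0].times, maps_a[0].freqs,
                                             n_subjects, config.permutation.cluster_alpha))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results = results.sort_values(
        by=["analysis", "label", "band", "contrast", "t_start_ms"]).reset_index(drop=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(out / "rejection_reports.json", [r.to_dict() for r in reports])
        if balance is not None:
            write_json(out / "trial_balance.json", {
                "min_count": balance.min_count,
                "pairwise_p": {f"{a[0]}-{a[1]}|{b[0]}-{b[1]}": p
                               for (a, b), p in balance.pairwise_p.items()},
            })
        write_maps(out / "phase_locking_maps.h5", stored_maps)
        report(results, out)
        write_json(out / "run_log.json", {
            "meglock_version": __version__,
            "master_seed": config.simulation.master_seed,
            "permutation_seed": config.permutation.seed,
            "n_permutations": config.permutation.n_permutations,
            "n_subjects": n_subjects,
            "n_statistical_tests": test_index,
            "min_trials_per_condition": None if balance is None else balance.min_count,
        })
    return results


def report(results: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the results table as CSV and JSON plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = results.reindex(columns=RESULT_COLUMNS)
    csv_path = out / "results.csv"
    results.to_csv(csv_path, index=False)
    json_path = out / "results.json"
    write_json(json_path, results.to_dict(orient="records"))
    lines = ["meglock cluster results", "=" * 23, ""]
    sig = results[results["significant"]]
    lines.append(f"{len(results)} clusters found, {len(sig)} significant")
    for _, r in sig.iterrows():
        band = f" {r['band']}" if r["band"] else ""
        lines.append(
            f"  {r['analysis']}{band} {r['label']} [{r['contrast']}] {r['direction']}"
            f" {r['t_start_ms']:.0f}-{r['t_end_ms']:.0f} ms"
            f" mass={r['mass']:.2f} p={r['p']:.4g}"
        )
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "json": json_path, "summary": summary_path}


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.reindex(columns=RESULT_COLUMNS)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
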