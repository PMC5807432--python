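"""Hierarchical on-disk containers for cohorts and phase-locking maps.

Cohorts are stored in one HDF5 file with a group per subject holding the
(trials, rois, samples) array plus per-trial condition labels; sampling rate,
epoch start and ROI names are attributes, so every artifact self-describes
its axes.  Phase-locking maps are stored per subject / label / condition with
frequency and time axes as attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .phase_locking import PhaseLockingMap
from .synth import EpochSet


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_cohort(path: str | Path, cohort: list[EpochSet]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "meglock-epochs-v1"
        for es in cohort:
            g = f.create_group(es.subject_id)
            g.create_dataset("data", data=es.data, compression="gzip", compression_opts=1)
            g.create_dataset("gaze", data=np.array([c[0] for c in es.condition_labels], dtype="S"))
            g.create_dataset("duration",
                             data=np.array([c[1] for c in es.condition_labels], dtype="S"))
            g.attrs["sfreq"] = es.sfreq
            g.attrs["tmin"] = es.tmin
            g.attrs["roi_names"] = [r.encode() for r in es.roi_names]


def read_cohort(path: str | Path) -> list[EpochSet]:
    out: list[EpochSet] = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            gaze = [_as_str(s) for s in g["gaze"][()]]
            dur = [_as_str(s) for s in g["duration"][()]]
            out.append(EpochSet(
                subject_id=sid,
                data=g["data"][()],
                sfreq=float(g.attrs["sfreq"]),
                tmin=float(g.attrs["tmin"]),
                condition_labels=list(zip(gaze, dur)),
                roi_names=tuple(_as_str(r) for r in g.attrs["roi_names"]),
            ))
    return out


def _cond_key(condition) -> str:
    return f"{condition[0]}__{condition[1]}"


def write_maps(path: str | Path, maps: list[PhaseLockingMap]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "meglock-maps-v1"
        for m in maps:
            key = f"{m.subject_id}/{m.kind}/{m.label}/{_cond_key(m.condition)}"
            g = f.create_group(key)
            g.create_dataset("values", data=m.values)
            g.create_dataset("mask", data=m.mask)
            g.attrs["freqs"] = m.freqs
            g.attrs["times"] = m.times
            g.attrs["n_trials"] = m.n_trials


def read_maps(path: str | Path) -> list[PhaseLockingMap]:
    out: list[PhaseLockingMap] = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            for kind in sorted(f[sid].keys()):
                for label in sorted(f[sid][kind].keys()):
                    for ck in sorted(f[sid][kind][label].keys()):
                        g = f[sid][kind][label][ck]
                        gaze, dur = ck.split("__")
                        out.append(PhaseLockingMap(
                            values=g["values"][()],
                            mask=g["mask"][()],
                            freqs=np.asarray(g.attrs["freqs"]),
                            times=np.asarray(g.attrs["times"]),
                            kind=kind,
                            label=label,
                            n_trials=int(g.attrs["n_trials"]),
                            subject_id=sid,
                            condition=(gaze, dur),
                        ))
    return out


def write_json(path: str | Path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
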