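"""Load analysis configurations from TOML or YAML files."""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import yaml

from .cluster_stats import PermutationConfig
from .pipeline import DEFAULT_CONTRASTS, AnalysisConfig
from .preproc import PreprocConfig
from .spectral import DEFAULT_FREQS
from .synth import BurstSpec, CouplingSpec, NoiseSpec, SimulationConfig, default_config


def _conds(raw) -> frozenset:
    return frozenset(tuple(c) for c in raw)


def simulation_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    bursts = tuple(
        BurstSpec(
            roi=b["roi"],
            conditions=_conds(b["conditions"]),
            frequency=float(b["frequency"]),
            window=tuple(b["window"]),
            amplitude=float(b.get("amplitude", 1.0)),
            kappa=float(b.get("kappa", 0.0)),
            mu=float(b.get("mu", 0.0)),
        )
        for b in d.pop("bursts", [])
    )
    couplings = tuple(
        CouplingSpec(
            roi_pair=tuple(c["roi_pair"]),
            conditions=_conds(c["conditions"]),
            frequency=float(c["frequency"]),
            window=tuple(c["window"]),
            phase_lag=float(c.get("phase_lag", 0.0)),
            kappa=float(c.get("kappa", 0.0)),
            amplitude=float(c.get("amplitude", 1.0)),
        )
        for c in d.pop("couplings", [])
    )
    noise = NoiseSpec(**d.pop("noise", {}))
    if "epoch_window" in d:
        d["epoch_window"] = tuple(d["epoch_window"])
    if "roi_names" in d:
        d["roi_names"] = tuple(d["roi_names"])
    return SimulationConfig(bursts=bursts, couplings=couplings, noise=noise, **d)


def analysis_from_dict(d: dict) -> AnalysisConfig:
    sim = simulation_from_dict(d["simulation"]) if "simulation" in d else default_config()
    pre_d = dict(d.get("preproc", {}))
    for key in ("timecourse_window", "tf_window", "baseline_window"):
        if key in pre_d:
            pre_d[key] = tuple(pre_d[key])
    pre = PreprocConfig(**pre_d)
    perm = PermutationConfig(**d.get("permutation", {}))
    ana = dict(d.get("analysis", {}))
    freqs = np.asarray(ana.pop("freqs", DEFAULT_FREQS), float)
    bands = tuple(ana.pop("bands", ("alpha", "beta")))
    contrasts = tuple(
        (tuple(a), tuple(b)) for a, b in ana.pop("contrasts", DEFAULT_CONTRASTS)
    )
    plv_pairs = ana.pop("plv_pairs", None)
    if plv_pairs is not None:
        plv_pairs = tuple(tuple(p) for p in plv_pairs)
    return AnalysisConfig(
        simulation=sim,
        preproc=pre,
        permutation=perm,
        freqs=freqs,
        bands=bands,
        contrasts=contrasts,
        plv_pairs=plv_pairs,
        **ana,
    )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raw = tomllib.loads(path.read_text())
    return analysis_from_dict(raw)
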