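"""Configuration files and named parameter presets.

A run specification is a mapping with two sections::

    model:
      kind: rps | erps | rpsls | custom
      p: [2.5, 1.0, 0.5]
      sigma: 1.0        # optional, default 1
      mu: 1.0           # optional, default 1
      invades: [[0,1], [1,2], [2,0]]   # custom models only
    run:
      L: 100
      M: 1.0e-3         # or eps (= 2 M L^2)
      t_max: 1000
      seed: 0
      init: [0.333, 0.333, 0.333]      # optional
      snapshots: [500, 1000]           # optional

YAML or JSON files are accepted; unknown keys are rejected with the
offending field path.  The preset catalog ships the canonical parameter
sets of each game, e.g. ``rps_pa5.2`` or ``erps_pd0.01``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .models import InteractionModel, RunConfig, make_model

__all__ = ["PRESETS", "load_config", "preset_config", "build"]

_RPS = {"kind": "rps", "sigma": 1.0, "mu": 1.0}
_ERPS = {"kind": "erps", "sigma": 1.0, "mu": 1.0}
_RPSLS = {"kind": "rpsls", "sigma": 1.0, "mu": 1.0}
_RUN = {"L": 100, "M": 1e-3, "t_max": 1000, "seed": 0}

#: canonical parameter sets, one per studied regime
PRESETS: Dict[str, dict] = {
    "rps_pa2.5": {"model": {**_RPS, "p": [2.5, 1.0, 0.5]}, "run": dict(_RUN)},
    "rps_pa5.2": {"model": {**_RPS, "p": [5.2, 1.0, 0.5]}, "run": dict(_RUN)},
    "rps_pa100": {"model": {**_RPS, "p": [100.0, 1.0, 0.5]}, "run": dict(_RUN)},
    "erps_pc3.3": {"model": {**_ERPS, "p": [1.9, 2.0, 3.3, 1.3, 0.7]}, "run": dict(_RUN)},
    "erps_pc5.65": {"model": {**_ERPS, "p": [1.9, 2.0, 5.65, 1.3, 0.7]}, "run": dict(_RUN)},
    "erps_pc6.5": {"model": {**_ERPS, "p": [1.9, 2.0, 6.5, 1.3, 0.7]}, "run": dict(_RUN)},
    "erps_pc100": {"model": {**_ERPS, "p": [1.9, 2.0, 100.0, 1.3, 0.7]}, "run": dict(_RUN)},
    "erps_pd0.01": {"model": {**_ERPS, "p": [1.9, 2.0, 100.0, 0.01, 0.7]}, "run": dict(_RUN)},
    "rpsls_pe2.2": {"model": {**_RPSLS, "p": [0.3, 1.1, 2.5, 0.7, 2.2]}, "run": dict(_RUN)},
    "rpsls_pe3.3": {"model": {**_RPSLS, "p": [0.3, 1.1, 2.5, 0.7, 3.3]}, "run": dict(_RUN)},
    "rpsls_pe9.3": {"model": {**_RPSLS, "p": [0.3, 1.1, 2.5, 0.7, 9.3]}, "run": dict(_RUN)},
    "rpsls_pe100": {"model": {**_RPSLS, "p": [0.3, 1.1, 2.5, 0.7, 100.0]}, "run": dict(_RUN)},
    "rpsls_pa0.01": {"model": {**_RPSLS, "p": [0.01, 1.1, 2.5, 0.7, 100.0]}, "run": dict(_RUN)},
}

_MODEL_KEYS = {"kind", "p", "sigma", "mu", "invades"}
_RUN_KEYS = {"L", "M", "eps", "t_max", "seed", "init", "snapshots"}


def _validate(spec: dict) -> dict:
    if not isinstance(spec, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(spec) - {"model", "run"}
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    model = spec.get("model")
    if not isinstance(model, dict) or "kind" not in model or "p" not in model:
        raise ValueError("model: requires at least 'kind' and 'p'")
    bad = set(model) - _MODEL_KEYS
    if bad:
        raise ValueError(f"model: unknown keys {sorted(bad)}")
    run = spec.get("run", {})
    bad = set(run) - _RUN_KEYS
    if bad:
        raise ValueError(f"run: unknown keys {sorted(bad)}")
    return {"model": dict(model), "run": dict(run)}


def build(spec: dict) -> Tuple[InteractionModel, Optional[RunConfig]]:
    """Instantiate the model (and run configuration, if any) of a spec."""
    spec = _validate(spec)
    mspec = spec["model"]
    try:
        model = make_model(
            mspec["kind"],
            p=mspec["p"],
            sigma=mspec.get("sigma", 1.0),
            mu=mspec.get("mu", 1.0),
            custom_invades=mspec.get("invades"),
        )
    except ValueError as exc:
        raise ValueError(f"model.p: {exc}") from exc
    rspec = spec["run"]
    if not rspec:
        return model, None
    cfg = RunConfig(
        lattice_side=int(rspec.get("L", 100)),
        t_max=float(rspec.get("t_max", 1000)),
        seed=int(rspec.get("seed", 0)),
        mobility=rspec.get("M"),
        epsilon=rspec.get("eps"),
        initial_densities=tuple(rspec.get("init", ())),
        snapshot_times=tuple(rspec.get("snapshots", ())),
    )
    return model, cfg


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run specification."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        spec = json.loads(text)
    else:
        spec = yaml.safe_load(text)
    return _validate(spec)


def preset_config(name: str) -> dict:
    """A deep copy of a named preset, validated."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return _validate(json.loads(json.dumps(PRESETS[name])))
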