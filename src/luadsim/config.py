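"""Configuration loading.

A bundled YAML file carries every model, treatment, population and
validation default; a user file with the same structure overrides any
subset (deep merge). Loaded sections are materialised into the typed
parameter containers of the other modules.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .clinical import RecistPolicy
from .core import GrowthParams
from .signaling import SignalingParams
from .treatment import DoseBlock, PDParams, PKParams
from .validation import ValidationConfig
from .vpop import (BaselineTable, ContinuousSpec, VPopSpec,
                   estimate_sd_from_quantiles)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@lru_cache(maxsize=1)
def _default_config_cached() -> str:
    return resources.files("luadsim.data").joinpath("default_config.yaml").read_text()


def default_config() -> dict:
    return yaml.safe_load(_default_config_cached())


def load_config(path: str | Path | None = None) -> dict:
    """Bundled defaults, deep-merged with an optional user config file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict (for run logging)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ModelSettings:
    """Everything needed to simulate one patient through to an outcome."""

    growth: GrowthParams
    signaling: SignalingParams
    pk: PKParams
    pd_params: PDParams
    regimen: tuple[DoseBlock, ...]
    recist: RecistPolicy
    follow_up_months: float
    capacity_factor: float


@lru_cache(maxsize=1)
def _default_settings() -> "ModelSettings":
    return model_settings(default_config())


def model_settings(cfg: dict | None = None) -> ModelSettings:
    if cfg is None:
        return _default_settings()
    sig = cfg["signaling"]
    return ModelSettings(
        growth=GrowthParams(**cfg["growth"]),
        signaling=SignalingParams(s0=sig["s0"], g_egfr=dict(sig["g_egfr"]),
                                  rho_res=dict(sig["rho_res"])),
        pk=PKParams(**cfg["pk"]),
        pd_params=PDParams(imax=cfg["pd"]["imax"], ic50_base=cfg["pd"]["ic50_base"],
                           hill=cfg["pd"]["hill"], potency=dict(cfg["pd"]["potency"])),
        regimen=tuple(DoseBlock(**b) for b in cfg["regimen"]),
        recist=RecistPolicy(**cfg["recist"]),
        follow_up_months=float(cfg["follow_up_months"]),
        capacity_factor=float(cfg["capacity_factor"]),
    )


def _continuous_spec(d: dict) -> ContinuousSpec:
    d = dict(d)
    dist = d.pop("dist")
    bounds = tuple(d.pop("bounds")) if "bounds" in d else None
    if dist == "truncnorm":
        if "sd" not in d:
            lo, hi = d.pop("range")
            d["sd"] = estimate_sd_from_quantiles(lo, hi, d.pop("coverage", 0.99))
        else:
            d.pop("range", None)
            d.pop("coverage", None)
        params = {"center": d["center"], "sd": d["sd"]}
    elif dist == "lognormal":
        params = {"median": d["median"], "sigma": d["sigma"]}
    elif dist == "uniform":
        params = {"lo": d["lo"], "hi": d["hi"]}
    else:
        raise ValueError(f"unknown distribution family {dist!r}")
    return ContinuousSpec(dist=dist, params=params, bounds=bounds)


def vpop_spec(cfg: dict | None = None, which: str = "luxlung7") -> VPopSpec:
    """Build the virtual-population spec named ``which`` from a config."""
    cfg = cfg or default_config()
    section = cfg["vpop"][which]
    return VPopSpec(
        categoricals={k: dict(v) for k, v in section["categoricals"].items()},
        continuous={k: _continuous_spec(v) for k, v in section["continuous"].items()},
        size_multiplier=float(section.get("size_multiplier", 10)),
    )


def default_population_size(cfg: dict | None = None, which: str = "luxlung7") -> int:
    cfg = cfg or default_config()
    section = cfg["vpop"][which]
    return int(round(section.get("size_multiplier", 10) * section["n_real_events"]))


def baseline_table(cfg: dict | None = None) -> BaselineTable:
    cfg = cfg or default_config()
    b = cfg["baseline"]
    return BaselineTable(
        categorical={k: dict(v) for k, v in b["categorical"].items()},
        continuous={k: {**v, "range": tuple(v["range"])}
                    for k, v in b.get("continuous", {}).items()},
    )


def validation_config(cfg: dict | None = None) -> ValidationConfig:
    cfg = cfg or default_config()
    return ValidationConfig(**cfg["validation"])
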