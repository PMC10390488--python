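"""Synthetic reference-data generation.

Real trial inputs (digitized PFS/OS survival curves, event tables) cannot
be bundled, so this module generates internally consistent stand-ins: each
synthetic subject receives a latent progression time and a death time; PFS
is the earlier of the two, OS is the death time, and both are right
censored at the follow-up cut-off (plus optional random early censoring).
Digitized-curve files are the KM estimates of those tables sampled on a
regular grid with at-risk counts, mimicking figure-extraction output.

The bundled ``luxlung7_like`` scenario is a synthetic stand-in shaped like
a 159-patient gefitinib arm (median TTP near 9 months, roughly 120
progression events over a 30-month window); it is not trial data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .validation import EventTable, SurvivalCurve, km_estimate


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative scenario for a synthetic trial arm.

    ``ttp_median``/``ttp_sigma`` parameterise a lognormal progression-time
    distribution (months); deaths are exponential with median
    ``os_median``; ``censor_rate`` is the monthly hazard of random early
    censoring; follow-up truncates everything.
    """

    n_patients: int = 159
    ttp_dist: str = "lognormal"
    ttp_median: float = 9.0
    ttp_sigma: float = 0.7
    os_median: float = 24.4
    censor_rate: float = 0.0
    follow_up_months: float = 30.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if self.follow_up_months <= 0:
            raise ValueError("follow_up_months must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class ReferenceDataset:
    """Consistent PFS/OS/TTP tables plus digitized-style KM curves."""

    pfs: EventTable
    os: EventTable
    ttp: EventTable
    pfs_curve: SurvivalCurve
    os_curve: SurvivalCurve

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in (("pfs_events", self.pfs), ("os_events", self.os),
                            ("ttp_events", self.ttp)):
            p = out / f"{name}.csv"
            table.to_frame().to_csv(p, index=False, float_format="%.6f")
            written.append(p)
        for name, curve in (("pfs_curve", self.pfs_curve), ("os_curve", self.os_curve)):
            p = out / f"{name}.csv"
            curve.to_frame().to_csv(p, index=False, float_format="%.6f")
            written.append(p)
        return written


def _curve_on_grid(events: EventTable, follow_up: float,
                   step: float = 0.5) -> SurvivalCurve:
    km = km_estimate(events)
    grid = np.arange(0.0, follow_up + 0.5 * step, step)
    surv = km.evaluate(grid)
    # at risk just before each grid time
    t_sorted = np.sort(events.times)
    n_risk = events.times.size - np.searchsorted(t_sorted, grid, side="left")
    return SurvivalCurve(times=grid, surv=surv, n_risk=n_risk.astype(float))


def generate_reference_dataset(spec: ScenarioSpec,
                               seed: int | None = None) -> ReferenceDataset:
    """Sample a synthetic trial arm under ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    if spec.ttp_dist == "lognormal":
        t_prog = rng.lognormal(math.log(spec.ttp_median), spec.ttp_sigma, size=n)
    elif spec.ttp_dist == "exponential":
        t_prog = rng.exponential(spec.ttp_median / math.log(2.0), size=n)
    else:
        raise ValueError(f"unknown ttp_dist {spec.ttp_dist!r}")
    t_death = rng.exponential(spec.os_median / math.log(2.0), size=n)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    cutoff = np.minimum(t_cens, spec.follow_up_months)

    ids = np.array([f"s-{i}" for i in range(n)])
    pfs_lat = np.minimum(t_prog, t_death)
    pfs = EventTable(np.minimum(pfs_lat, cutoff),
                     (pfs_lat <= cutoff).astype(int), ids)
    os_ = EventTable(np.minimum(t_death, cutoff),
                     (t_death <= cutoff).astype(int), ids)
    # TTP keeps subjects whose progression is observable (not pre-empted by
    # death); the rest are censored at their cut-off
    prog_first = t_prog <= t_death
    ttp_time = np.where(prog_first, np.minimum(t_prog, cutoff), cutoff)
    ttp_event = (prog_first & (t_prog <= cutoff)).astype(int)
    ttp = EventTable(ttp_time, ttp_event, ids)

    return ReferenceDataset(
        pfs=pfs, os=os_, ttp=ttp,
        pfs_curve=_curve_on_grid(pfs, spec.follow_up_months),
        os_curve=_curve_on_grid(os_, spec.follow_up_months),
    )
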