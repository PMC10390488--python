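"""Gefitinib pharmacokinetics and pharmacodynamics.

PK is a closed-form one-compartment oral model (Bateman function) with
superposition over repeated doses; no differential equations are solved.
PD is a Hill (Emax/IC50) inhibition of the EGFR signal whose effective
IC50 is multiplied by mutation-specific potency factors: the exon 19
deletion is more gefitinib-sensitive than L858R, while T790M and KRAS
shift potency far to the right.

The default regimen is 250 mg orally once daily starting at day 0. The PK
constants shipped here are package defaults chosen to give plasma exposure
in the range reported for daily oral gefitinib (average steady-state
concentration of roughly 0.25 mg/L); they are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import ConfigurationError, MutationProfile

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class PKParams:
    """One-compartment oral PK parameters for gefitinib."""

    dose_mg: float = 250.0
    interval_h: float = 24.0
    F: float = 0.6          # oral bioavailability
    ka: float = 0.5         # absorption rate, 1/h
    ke: float = 0.0169      # elimination rate, 1/h (half-life ~41 h)
    vd_l: float = 1400.0    # apparent distribution volume, L

    RATE_FIELDS = ("ka", "ke")

    def __post_init__(self) -> None:
        for name in ("dose_mg", "interval_h", "ka", "ke", "vd_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be positive")
        if not 0.0 < self.F <= 1.0:
            raise ValueError("bioavailability F must lie in (0, 1]")
        if math.isclose(self.ka, self.ke, rel_tol=1e-12):
            raise ConfigurationError("ka == ke degenerates the Bateman function")


@dataclass(frozen=True)
class PDParams:
    """Hill inhibition of EGFR signaling by plasma gefitinib."""

    imax: float = 0.95       # maximal inhibition fraction
    ic50_base: float = 0.05  # mg/L, for an un-mutated reference target
    hill: float = 1.0
    #: multiplicative shifts of IC50 per mutation present on the clone.
    potency: Mapping[str, float] = field(default_factory=lambda: {
        "exon19del": 0.8,   # more sensitive than L858R
        "l858r": 1.25,
        "t790m": 15.0,
        "kras": 4.0,
        "pik3ca": 1.0,
    })

    def __post_init__(self) -> None:
        if not 0.0 < self.imax <= 1.0:
            raise ValueError("imax must lie in (0, 1]")
        if self.hill <= 0:
            raise ValueError("hill coefficient must be > 0")
        if self.ic50_base <= 0:
            raise ValueError("ic50_base must be > 0")
        for name, m in self.potency.items():
            if m < 0:
                raise ValueError(f"potency multiplier {name} must be >= 0")


@dataclass(frozen=True)
class DoseBlock:
    """Repeated administration of ``dose_mg`` every ``interval_h`` hours
    from ``start_day`` until ``end_day`` (``None`` means open-ended)."""

    start_day: float = 0.0
    dose_mg: float = 250.0
    interval_h: float = 24.0
    end_day: float | None = None


def default_regimen(pk: PKParams | None = None) -> tuple[DoseBlock, ...]:
    """Daily 250 mg gefitinib from day 0 onwards."""
    pk = pk or PKParams()
    return (DoseBlock(0.0, pk.dose_mg, pk.interval_h, None),)


def concentration(t_h, pk: PKParams,
                  regimen: Sequence[DoseBlock] | None = None) -> np.ndarray | float:
    """Plasma concentration (mg/L) at time ``t_h`` hours from simulation start.

    Sums the Bateman response of every dose administered up to ``t_h``:
    ``F*D*ka / (Vd*(ka-ke)) * (exp(-ke*dt) - exp(-ka*dt))`` per dose, using
    closed-form geometric partial sums so evaluation is O(number of dose
    blocks) rather than O(number of doses). Zero before the first dose.
    """
    if regimen is None:
        regimen = default_regimen(pk)
    t = np.asarray(t_h, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    c = np.zeros_like(t)
    for block in regimen:
        tau = block.interval_h
        start_h = block.start_day * HOURS_PER_DAY
        end_h = math.inf if block.end_day is None else block.end_day * HOURS_PER_DAY
        rel = t - start_h
        active = rel >= 0
        if not np.any(active):
            continue
        # index of the last dose administered at or before t (capped by end)
        m = np.floor(rel[active] / tau)
        m_cap = math.floor((end_h - start_h) / tau) if math.isfinite(end_h) else math.inf
        m = np.minimum(m, m_cap)
        w = rel[active] - m * tau     # time since last administered dose
        n = m + 1.0                   # number of doses administered
        amp = pk.F * block.dose_mg * pk.ka / (pk.vd_l * (pk.ka - pk.ke))

        def s(alpha):
            q = np.exp(-alpha * tau)
            return np.exp(-alpha * w) * (1.0 - q**n) / (1.0 - q)

        c[active] += amp * (s(pk.ke) - s(pk.ka))
    c = np.maximum(c, 0.0)
    return float(c[0]) if scalar else c


def peak_time_single_dose(pk: PKParams) -> float:
    """Time to peak (h) of a single oral dose: ``ln(ka/ke)/(ka-ke)``."""
    return math.log(pk.ka / pk.ke) / (pk.ka - pk.ke)


def average_concentration_ss(pk: PKParams, dose_mg: float | None = None,
                             interval_h: float | None = None) -> float:
    """Average steady-state concentration ``F*D / (Vd*ke*tau)`` in mg/L."""
    d = pk.dose_mg if dose_mg is None else dose_mg
    tau = pk.interval_h if interval_h is None else interval_h
    return pk.F * d / (pk.vd_l * pk.ke * tau)


def effective_ic50(pd: PDParams, profile: MutationProfile) -> float:
    """IC50 shifted by the potency multipliers of every mutation present."""
    ic50 = pd.ic50_base
    for name in profile.present_mutations:
        ic50 *= pd.potency.get(name, 1.0)
    return ic50


def inhibition(c_mg_l, pd: PDParams, profile: MutationProfile):
    """Fractional target inhibition at plasma concentration ``c_mg_l``.

    ``Imax * C^h / (IC50_eff^h + C^h)``; vectorised over concentration,
    bounded by ``Imax`` and zero at ``C = 0``.
    """
    c = np.asarray(c_mg_l, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    ic50 = effective_ic50(pd, profile)
    ch = c**pd.hill
    out = pd.imax * ch / (ic50**pd.hill + ch)
    return out if out.ndim else float(out)
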