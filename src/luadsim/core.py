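"""Shared domain types: experimental settings, allometric scaling, mutation
profiles, growth parameters, virtual patients, and clone construction.

The simulator runs the same model structure in three settings (in vitro
spheroid, xenograft mouse, human). Rate parameters are carried across
settings with a power law of body mass ``Z = a * M**b`` (allometric
scaling); reference masses are 2.63 g for the in vitro setting, 23 g for
the mouse, and 70 kg for the human.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Days per month used for all clinical time conversions (Julian year / 12).
DAYS_PER_MONTH = 365.25 / 12.0

EGFR_VARIANTS = ("exon19del", "l858r")
SMOKING_CATEGORIES = ("never", "former", "current")
ETHNICITY_CATEGORIES = ("asian", "non_asian")
STAGE_CATEGORIES = ("IIIb", "IV")


class ConfigurationError(ValueError):
    """Raised when a parameter set or config file is internally inconsistent."""


@dataclass(frozen=True)
class Setting:
    """An experimental setting identified by its reference body mass.

    Parameters
    ----------
    name
        One of ``in_vitro``, ``mouse``, ``human``.
    reference_mass_g
        Mass in grams used as the allometric reference for this setting.
    """

    name: str
    reference_mass_g: float

    def __post_init__(self) -> None:
        if self.reference_mass_g <= 0:
            raise ValueError("reference_mass_g must be positive")


IN_VITRO = Setting("in_vitro", 2.63)
MOUSE = Setting("mouse", 23.0)
#: Human reference mass defaults to 70 kg; configurable via ``Setting``.
HUMAN = Setting("human", 70_000.0)


@dataclass(frozen=True)
class AllometryRule:
    """Power-law rule ``Z = a * M**b`` for one scaled quantity.

    ``a`` carries the units of the scaled quantity, ``b`` is dimensionless
    (typically in [-1, 1]; -0.25 for first-order rates under standard
    metabolic scaling).
    """

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("allometric coefficients must be finite")


def allometric_scale(a: float, b: float, mass_g: float) -> float:
    """Evaluate the allometric law ``Z = a * M**b`` at mass ``mass_g`` (grams)."""
    if mass_g <= 0:
        raise ValueError(f"mass must be positive, got {mass_g}")
    return a * mass_g**b


@dataclass(frozen=True)
class MutationProfile:
    """Mutational make-up of one tumor clone.

    Exactly one common activating EGFR variant (exon 19 deletion or L858R)
    is present; T790M, KRAS and PIK3CA are optional co-mutations.
    ``m_prolif`` is a dimensionless offset summarising the effect of
    implicit (unmodelled) mutations on the proliferation hallmark.
    """

    egfr_variant: str = "exon19del"
    t790m: bool = False
    kras: bool = False
    pik3ca: bool = False
    m_prolif: float = 0.0

    def __post_init__(self) -> None:
        if self.egfr_variant not in EGFR_VARIANTS:
            raise ValueError(
                f"egfr_variant must be one of {EGFR_VARIANTS}, got {self.egfr_variant!r}"
            )

    @property
    def resistance_mutations(self) -> tuple[str, ...]:
        out = []
        if self.t790m:
            out.append("t790m")
        if self.kras:
            out.append("kras")
        return tuple(out)

    @property
    def present_mutations(self) -> tuple[str, ...]:
        out = [self.egfr_variant]
        for name in ("t790m", "kras", "pik3ca"):
            if getattr(self, name):
                out.append(name)
        return tuple(out)


# Fixed field order shared with the compiled integrator kernel.
GROWTH_FIELD_ORDER = (
    "lambda_prolif",
    "delta0",
    "delta_q",
    "k_pq",
    "k_qp",
    "k_cl",
    "v_cell",
    "d_rim",
    "k_max",
    "alpha_ang",
    "rho_imm",
    "h_imm",
    "d_imm",
    "kappa_imm",
    "gamma_drug",
)


@dataclass(frozen=True)
class GrowthParams:
    """The 15 parameters of the per-clone tumor-growth submodel.

    Units: first-order rates in 1/day, ``v_cell`` in cm^3/cell, ``d_rim``
    (viable rim depth) in cm, ``k_max`` and ``h_imm`` in cells.
    """

    lambda_prolif: float = 0.044   # maximal proliferation rate, 1/day
    delta0: float = 0.005          # baseline death of proliferating cells, 1/day
    delta_q: float = 0.001         # death of quiescent cells, 1/day
    k_pq: float = 0.1              # quiescence entry (outside viable rim), 1/day
    k_qp: float = 0.005            # quiescence exit (inside viable rim), 1/day
    k_cl: float = 0.05             # clearance of dead cells, 1/day
    v_cell: float = 1.0e-9         # volume of one cell, cm^3
    d_rim: float = 1.0             # viable rim depth, cm (human default)
    k_max: float = 1.0e12          # maximal carrying capacity, cells
    alpha_ang: float = 0.008       # neo-angiogenic capacity growth, 1/day
    rho_imm: float = 5.0e-4        # immune-pressure recruitment, 1/day
    h_imm: float = 1.0e10          # immune half-saturation, cells
    d_imm: float = 0.1             # immune-pressure decay, 1/day
    kappa_imm: float = 1.0         # immune kill coefficient, 1/day per unit pressure
    gamma_drug: float = 0.01       # drug-induced death coefficient, 1/day

    #: Fields that are first-order rates and therefore allometrically scaled.
    RATE_FIELDS = (
        "lambda_prolif",
        "delta0",
        "delta_q",
        "k_pq",
        "k_qp",
        "k_cl",
        "alpha_ang",
        "rho_imm",
        "d_imm",
        "kappa_imm",
        "gamma_drug",
    )

    def __post_init__(self) -> None:
        for name in GROWTH_FIELD_ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"growth parameter {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        """Parameter vector in the canonical order used by the integrator."""
        return np.array([getattr(self, n) for n in GROWTH_FIELD_ORDER], dtype=float)


def scale_rates(params, factor: float):
    """Multiply every rate field of a parameter set by ``factor``.

    Used for the per-patient tumor pace multiplier: scaling all first-order
    rates together is an exact rescaling of the trajectory's time axis.
    """
    if factor <= 0:
        raise ValueError("rate scale factor must be > 0")
    rate_fields = getattr(params, "RATE_FIELDS", ())
    return dataclasses.replace(
        params, **{n: getattr(params, n) * factor for n in rate_fields})


def rescale_params(params, from_setting: Setting, to_setting: Setting,
                   rules: Mapping[str, AllometryRule] | None = None):
    """Carry a parameter set from one setting to another by allometry.

    Every rate parameter ``r`` becomes ``r * (M_to / M_from)**b_r``; other
    fields are left unchanged. ``rules`` maps field names to
    :class:`AllometryRule`; every name in ``params.RATE_FIELDS`` must be
    covered (pass ``None`` to use the default exponent -0.25 everywhere).
    """
    rate_fields = getattr(params, "RATE_FIELDS", None)
    if rate_fields is None:
        raise ConfigurationError(
            f"{type(params).__name__} does not declare RATE_FIELDS; cannot rescale"
        )
    if rules is None:
        rules = {name: AllometryRule(b=-0.25) for name in rate_fields}
    missing = [n for n in rate_fields if n not in rules]
    if missing:
        raise ConfigurationError(f"missing allometry rule(s) for rate parameter(s): {missing}")
    ratio = to_setting.reference_mass_g / from_setting.reference_mass_g
    updates = {
        name: getattr(params, name) * ratio ** rules[name].b for name in rate_fields
    }
    return dataclasses.replace(params, **updates)


@dataclass(frozen=True)
class CloneState:
    """Dynamic state of one tumor clone.

    ``P`` proliferating cells, ``Q`` quiescent cells, ``D`` dead (not yet
    cleared) cells, ``K`` carrying capacity in cells, ``I`` dimensionless
    immune pressure.
    """

    P: float
    Q: float
    D: float
    K: float
    I: float

    def __post_init__(self) -> None:
        for name in ("P", "Q", "D", "K", "I"):
            if getattr(self, name) < 0:
                raise ValueError(f"clone state {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.Q, self.D, self.K, self.I], dtype=float)


@dataclass(frozen=True)
class VirtualPatient:
    """One sampled virtual subject: demographics, mutation make-up and
    patient-level mechanistic parameter overrides.

    The default tumor holds two clones: a treatment-sensitive clone with
    the activating EGFR variant only, and a resistant subclone that
    additionally carries T790M and starts with fraction ``f_res`` of the
    initial cells. Richer clone structures (up to 16 clones) are expressed
    by passing ``clone_profiles`` and ``clone_fractions`` explicitly.
    ``pace`` multiplies every growth-submodel rate (a global tumor-speed
    descriptor); ``*_overrides`` replace individual parameter values.
    """

    id: str = "vp-0"
    sex: str = "female"
    age: float = 63.0
    smoking: str = "never"
    ethnicity: str = "asian"
    stage: str = "IV"
    egfr_variant: str = "exon19del"
    kras: bool = False
    pik3ca: bool = False
    m_prolif: float = 0.0
    r0_cm: float = 1.5
    prolif_frac: float = 0.8
    f_res: float = 1.2e-2
    pace: float = 1.0
    clone_profiles: tuple[MutationProfile, ...] | None = None
    clone_fractions: tuple[float, ...] | None = None
    growth_overrides: Mapping[str, float] = field(default_factory=dict)
    signaling_overrides: Mapping[str, float] = field(default_factory=dict)
    pk_overrides: Mapping[str, float] = field(default_factory=dict)
    pd_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r0_cm <= 0:
            raise ValueError("initial radius r0_cm must be > 0")
        if not 0.0 <= self.f_res < 1.0:
            raise ValueError("resistant fraction f_res must lie in [0, 1)")
        if not 0.0 <= self.prolif_frac <= 1.0:
            raise ValueError("initial proliferative fraction must lie in [0, 1]")
        if self.pace <= 0:
            raise ValueError("pace multiplier must be > 0")
        if self.clone_profiles is not None:
            n = len(self.clone_profiles)
            if not 2 <= n <= 16:
                raise ValueError("clone count must lie in [2, 16]")
            if self.clone_fractions is not None:
                if len(self.clone_fractions) != n:
                    raise ValueError("clone_fractions length must match clone_profiles")
                if abs(sum(self.clone_fractions) - 1.0) > 1e-9:
                    raise ValueError("clone_fractions must sum to 1")

    def profiles(self) -> tuple[MutationProfile, ...]:
        """Per-clone mutation profiles (default: sensitive + T790M subclone)."""
        if self.clone_profiles is not None:
            return tuple(self.clone_profiles)
        sensitive = MutationProfile(
            egfr_variant=self.egfr_variant, t790m=False,
            kras=self.kras, pik3ca=self.pik3ca, m_prolif=self.m_prolif,
        )
        resistant = dataclasses.replace(sensitive, t790m=True)
        return (sensitive, resistant)

    def fractions(self) -> tuple[float, ...]:
        """Initial cell fractions per clone (sum to 1)."""
        if self.clone_fractions is not None:
            return tuple(self.clone_fractions)
        if self.clone_profiles is not None:
            n = len(self.clone_profiles)
            # split f_res evenly over every clone carrying a resistance mutation
            res = [bool(p.resistance_mutations) for p in self.clone_profiles]
            n_res = sum(res)
            if n_res in (0, n):
                return tuple([1.0 / n] * n)
            fr = self.f_res / n_res
            fs = (1.0 - self.f_res) / (n - n_res)
            return tuple(fr if r else fs for r in res)
        return (1.0 - self.f_res, self.f_res)


def build_clones(patient: VirtualPatient, growth: GrowthParams,
                 capacity_factor: float = 1.5) -> list[CloneState]:
    """Initial clone states for one patient.

    The initial viable cell number fills a sphere of radius ``r0_cm``:
    ``N0 = (4/3) * pi * r0^3 / v_cell``, split across clones by their
    initial fractions; a fraction ``prolif_frac`` of each clone starts
    proliferating and the rest quiescent. Carrying capacity is seeded at
    ``capacity_factor`` times the initial total cell number for every clone
    (the pre-existing vasculature feeds the whole lesion), capped at
    ``k_max``; dead-cell pools and immune pressure start at zero.
    """
    if not 0.0 <= patient.f_res < 1.0:
        raise ValueError("resistant fraction f_res must lie in [0, 1)")
    n_tot = (4.0 / 3.0) * math.pi * patient.r0_cm**3 / growth.v_cell
    k0 = min(capacity_factor * n_tot, growth.k_max)
    states = []
    for frac in patient.fractions():
        n_c = frac * n_tot
        states.append(
            CloneState(
                P=patient.prolif_frac * n_c,
                Q=(1.0 - patient.prolif_frac) * n_c,
                D=0.0,
                K=k0,
                I=0.0,
            )
        )
    return states
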