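"""Algebraic EGFR/cMET signaling layer.

The signaling submodel carries no differential equations of its own: in
vitro it reproduces transient stimulus-response "surge" curves of pERK and
pAKT after EGF or HGF stimulation (calibrated by their peak amplitude and
peak time), and in vivo it reduces to a per-clone proliferation-signal
multiplier modulated by the clone's mutations and by drug inhibition.

The surge curve is ``A_max * (t/tau) * exp(1 - t/tau)``: the simplest
two-parameter form whose free parameters are exactly the two calibrated
quantities (peak value ``A_max``, attained exactly at ``t = tau``).

Resistance mutations (T790M, KRAS) act by attenuating the drug's effect on
the signal: the effective inhibition is multiplied by
``eff = prod(1 - rho_res)`` over the resistance mutations present, so a
KRAS-mutant clone keeps most of its proliferative signal under full
receptor blockade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MutationProfile


@dataclass(frozen=True)
class SurgeParams:
    """Peak activation (fraction of maximal phosphorylation) and its time."""

    a_max: float = 1.0   # dimensionless, in [0, 1]
    tau_min: float = 5.0  # minutes

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_max <= 1.0:
            raise ValueError("a_max must lie in [0, 1]")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")


def _default_surges() -> dict[tuple[str, str], SurgeParams]:
    # (readout, stimulus) -> surge; peak times in minutes, typical of
    # phospho-ERK/AKT transients after growth-factor stimulation.
    return {
        ("pERK", "EGF"): SurgeParams(1.0, 5.0),
        ("pAKT", "EGF"): SurgeParams(0.9, 10.0),
        ("pERK", "HGF"): SurgeParams(0.7, 15.0),
        ("pAKT", "HGF"): SurgeParams(1.0, 10.0),
    }


@dataclass(frozen=True)
class SignalingParams:
    """Parameters of the algebraic signaling layer."""

    s0: float = 1.0
    #: proliferative gain of each activating EGFR variant (dimensionless).
    g_egfr: Mapping[str, float] = field(
        default_factory=lambda: {"exon19del": 0.25, "l858r": 0.25}
    )
    #: attenuation of drug effect per resistance mutation, in [0, 1].
    rho_res: Mapping[str, float] = field(
        default_factory=lambda: {"t790m": 0.5, "kras": 0.8}
    )
    surges: Mapping[tuple[str, str], SurgeParams] = field(default_factory=_default_surges)

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("baseline signal s0 must be > 0")
        for name, rho in self.rho_res.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho_res[{name!r}] must lie in [0, 1]")


def surge_activation(t_min, params: SurgeParams):
    """Stimulus-response activation at time ``t_min`` minutes post stimulus.

    Vectorised over ``t_min``; raises on negative times.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since stimulus must be >= 0")
    x = t / params.tau_min
    out = params.a_max * x * np.exp(1.0 - x)
    return out if out.ndim else float(out)


def resistance_attenuation(profile: MutationProfile, params: SignalingParams) -> float:
    """``eff = prod(1 - rho_res)`` over resistance mutations the clone carries."""
    eff = 1.0
    for name in profile.resistance_mutations:
        eff *= 1.0 - params.rho_res.get(name, 0.0)
    return eff


def signal_multiplier(profile: MutationProfile, inhibition: float,
                      params: SignalingParams | None = None) -> float:
    """Proliferation-signal multiplier of one clone under drug inhibition.

    ``s = s0 * (1 + g_egfr + m_prolif) * (1 - eff * inhibition)`` with
    ``eff`` the clone's resistance attenuation; never negative.
    """
    if params is None:
        params = SignalingParams()
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError("inhibition must lie in [0, 1]")
    gain = 1.0 + params.g_egfr.get(profile.egfr_variant, 0.0) + profile.m_prolif
    eff = resistance_attenuation(profile, params)
    return max(params.s0 * gain * (1.0 - eff * inhibition), 0.0)


def stimulus_response_table(params: SignalingParams | None = None,
                            t_max_min: float = 60.0, n: int = 121) -> pd.DataFrame:
    """In vitro stimulus-response curves on a regular time grid.

    Returns a tidy frame (readout, stimulus, time_min, activation) suitable
    for writing as delimited text for visual predictive checks.
    """
    if params is None:
        params = SignalingParams()
    t = np.linspace(0.0, t_max_min, n)
    rows = []
    for (readout, stimulus), surge in params.surges.items():
        act = surge_activation(t, surge)
        rows.append(pd.DataFrame({
            "readout": readout, "stimulus": stimulus,
            "time_min": t, "activation": act,
        }))
    return pd.concat(rows, ignore_index=True)
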