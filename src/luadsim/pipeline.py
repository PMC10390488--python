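"""End-to-end cohort simulation: virtual patients -> trajectories -> outcomes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clinical import outcome_from_trajectory
from .config import ModelSettings, model_settings
from .core import DAYS_PER_MONTH, VirtualPatient
from .tumor import simulate_tumor
from .validation import EventTable

OUTCOME_COLUMNS = ("patient_id", "ttp_months", "event", "baseline_radius_cm",
                   "nadir_radius_cm", "change_6mo_pct", "kras")


def simulate_patient(patient: VirtualPatient, settings: ModelSettings | None = None,
                     method: str = "lsoda", dt_out_days: float = 1.0, **kw):
    """Trajectory of a single patient under the configured regimen."""
    settings = settings or model_settings()
    return simulate_tumor(
        patient,
        regimen=settings.regimen,
        t_end_days=settings.follow_up_months * DAYS_PER_MONTH,
        dt_out_days=dt_out_days,
        growth=settings.growth,
        signaling=settings.signaling,
        pk=settings.pk,
        pd_params=settings.pd_params,
        capacity_factor=settings.capacity_factor,
        method=method,
        **kw,
    )


def simulate_cohort(patients: list[VirtualPatient],
                    settings: ModelSettings | None = None,
                    method: str = "rk4",
                    dt_out_days: float = 1.0) -> pd.DataFrame:
    """Simulate every patient and summarise RECIST outcomes.

    Returns one row per patient with columns ``patient_id``, ``ttp_months``,
    ``event`` (1 progression / 0 censored at follow-up),
    ``baseline_radius_cm``, ``nadir_radius_cm``, ``change_6mo_pct`` and the
    ``kras`` carrier flag. The compiled fixed-step integrator is the
    default for population-scale runs.
    """
    settings = settings or model_settings()
    rows = []
    for patient in patients:
        traj = simulate_patient(patient, settings, method=method,
                                dt_out_days=dt_out_days)
        out = outcome_from_trajectory(traj, settings.recist, kras=patient.kras)
        rows.append((out.patient_id, out.ttp_months, out.event,
                     out.baseline_radius_cm, out.nadir_radius_cm,
                     out.radius_change_6mo_pct, out.kras))
    return pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))


def outcomes_to_events(outcomes: pd.DataFrame) -> EventTable:
    """Event table (TTP, progression flag) from a cohort outcome frame."""
    return EventTable(outcomes["ttp_months"].to_numpy(float),
                      outcomes["event"].to_numpy(int),
                      outcomes["patient_id"].to_numpy())
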