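"""Clinical layer: RECIST progression detection and per-patient outcomes.

Progression is an increase of the tumor's largest dimension (diameter) by
at least 20% and by at least 0.5 cm in absolute terms, relative to either
the baseline measurement or the running nadir (RECIST 1.1 convention; the
nadir is the default here, both policies are selectable). Because the
simulator tracks the radius, the 0.5 cm diameter increment is 0.25 cm on
the radius. Patients with no detected progression by the end of follow-up
are right-censored at the follow-up cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DAYS_PER_MONTH
from .tumor import TumorTrajectory


@dataclass(frozen=True)
class RecistPolicy:
    reference: str = "nadir"          # "nadir" or "baseline"
    rel_threshold: float = 0.20       # fractional increase of the dimension
    abs_diameter_cm: float = 0.5      # absolute increase of the diameter

    def __post_init__(self) -> None:
        if self.reference not in ("nadir", "baseline"):
            raise ValueError("reference must be 'nadir' or 'baseline'")


@dataclass(frozen=True)
class PatientOutcome:
    patient_id: str
    ttp_months: float
    event: int                      # 1 progression, 0 censored at follow-up
    baseline_radius_cm: float
    nadir_radius_cm: float
    radius_change_6mo_pct: float
    kras: bool = False

    def __post_init__(self) -> None:
        if self.ttp_months <= 0:
            raise ValueError("ttp_months must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


def detect_progression(traj: TumorTrajectory,
                       reference: str = "nadir",
                       rel_threshold: float = 0.20,
                       abs_threshold_diameter_cm: float = 0.5) -> tuple[float, int]:
    """Earliest RECIST progression time on the trajectory's output grid.

    Returns ``(ttp_months, event_flag)``; censored at the last grid time if
    no grid point satisfies both the relative and the absolute criterion.
    """
    r = np.asarray(traj.radius_cm, dtype=float)
    if r.size == 0:
        raise ValueError("empty trajectory")
    if reference == "baseline":
        ref = np.full_like(r, r[0])
    elif reference == "nadir":
        ref = np.minimum.accumulate(r)
    else:
        raise ValueError("reference must be 'nadir' or 'baseline'")
    hit = (r >= (1.0 + rel_threshold) * ref) & \
          (r - ref >= 0.5 * abs_threshold_diameter_cm)
    idx = np.flatnonzero(hit)
    if idx.size:
        return float(traj.t_days[idx[0]] / DAYS_PER_MONTH), 1
    return float(traj.t_days[-1] / DAYS_PER_MONTH), 0


def percent_change_radius(traj: TumorTrajectory, t_months: float) -> float:
    """Percent radius change at ``t_months`` versus baseline: ``100*(r(t)-r0)/r0``."""
    t_days = t_months * DAYS_PER_MONTH
    if t_days < traj.t_days[0] - 1e-9 or t_days > traj.t_days[-1] + 1e-9:
        raise ValueError(f"t={t_months} months lies outside the trajectory span")
    r = np.interp(t_days, traj.t_days, traj.radius_cm)
    r0 = traj.radius_cm[0]
    return float(100.0 * (r - r0) / r0)


def individual_ttp_match(predicted_ttp: float, observed_ttp: float,
                         visit_interval_months: float = 2.0) -> bool:
    """Whether a predicted TTP falls within the observation-time uncertainty.

    A prediction matches when ``observed - visit_interval <= predicted <=
    observed`` (boundaries inclusive): the real progression happened at an
    unknown time within one inter-visit interval before it was recorded.
    """
    if predicted_ttp <= 0 or observed_ttp <= 0 or visit_interval_months <= 0:
        raise ValueError("times and visit interval must be positive")
    return observed_ttp - visit_interval_months <= predicted_ttp <= observed_ttp


def match_fraction(predicted, observed, visit_interval_months: float = 2.0) -> float:
    """Fraction of predictions within the observation-time uncertainty window."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    hits = [individual_ttp_match(p, o, visit_interval_months)
            for p, o in zip(pred, obs)]
    return float(np.mean(hits))


def outcome_from_trajectory(traj: TumorTrajectory,
                            policy: RecistPolicy | None = None,
                            kras: bool = False) -> PatientOutcome:
    """Summarise one trajectory into a :class:`PatientOutcome` record."""
    policy = policy or RecistPolicy()
    ttp, event = detect_progression(traj, policy.reference,
                                    policy.rel_threshold, policy.abs_diameter_cm)
    r = traj.radius_cm
    span_months = traj.t_days[-1] / DAYS_PER_MONTH
    change6 = percent_change_radius(traj, 6.0) if span_months >= 6.0 else float("nan")
    return PatientOutcome(
        patient_id=traj.patient_id,
        ttp_months=ttp,
        event=event,
        baseline_radius_cm=float(r[0]),
        nadir_radius_cm=float(r.min()),
        radius_change_6mo_pct=change6,
        kras=kras,
    )
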