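"""Per-clone 5-state tumor-growth dynamics with spheroid geometry.

Each clone carries five states: proliferating cells ``P``, quiescent cells
``Q``, dead cells awaiting clearance ``D``, a neo-angiogenic carrying
capacity ``K`` (cells) and a dimensionless immune pressure ``I``. Clones
are coupled only through shared geometry (total volume sets the radius and
the viable-rim fraction) and through total viable burden (crowding against
each clone's capacity, and recruitment of immune pressure).

With ``N_tot = sum_c (P_c + Q_c)``, ``V_tot = v_cell * sum_c (P_c+Q_c+D_c)``,
``r = (3 V_tot / 4 pi)^(1/3)`` and viable fraction
``phi = 1 - ((r - d_rim)/r)^3`` (1 when ``r <= d_rim``):

    dP/dt = lam*s_c*phi*max(1 - N_tot/K_c, -1)*P - k_pq*(1-phi)*P
            + k_qp*phi*Q - (delta0 + kappa*I_c + gamma*inh_c)*P
    dQ/dt = k_pq*(1-phi)*P - k_qp*phi*Q - (delta_q + kappa*I_c)*Q
    dD/dt = (delta0 + kappa*I_c + gamma*inh_c)*P + (delta_q + kappa*I_c)*Q
            - k_cl*D
    dK/dt = alpha_ang*(P_c+Q_c)*(1 - K_c/k_max)
    dI/dt = rho_imm*N_tot/(h_imm + N_tot) - d_imm*I_c

``s_c`` is the clone's proliferation-signal multiplier and ``inh_c`` its
effective drug inhibition (resistance-attenuated).

Two integrators are provided: a stiff-capable reference path
(``method="lsoda"``, rtol 1e-6) supporting a fully time-resolved PK
forcing, and a compiled fixed-step RK4 path (``method="rk4"``) using the
steady-state average drug inhibition, for population-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from . import treatment as trt
from .core import (CloneState, GrowthParams, VirtualPatient, build_clones,
                   scale_rates)
from .signaling import SignalingParams, resistance_attenuation, signal_multiplier

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last time reached in ``last_t_days``."""

    def __init__(self, message: str, last_t_days: float):
        super().__init__(message)
        self.last_t_days = last_t_days


def radius_from_volume(v_cm3):
    """Radius (cm) of a sphere of volume ``v_cm3``; vectorised."""
    v = np.asarray(v_cm3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    out = (v / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def volume_from_radius(r_cm):
    r = np.asarray(r_cm, dtype=float)
    out = _FOUR_THIRDS_PI * r**3
    return out if out.ndim else float(out)


def viable_fraction(r_cm, d_rim_cm):
    """Fraction of a spherical tumor lying within the outer viable rim.

    ``1`` for ``r <= d_rim``, else ``1 - ((r - d_rim)/r)**3`` (the volume
    fraction of the shell of depth ``d_rim``).
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r < 0) or d_rim_cm < 0:
        raise ValueError("radius and rim depth must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(r <= d_rim_cm, 1.0, 1.0 - ((r - d_rim_cm) / np.maximum(r, 1e-300)) ** 3)
    return phi if phi.ndim else float(phi)


def growth_rhs(y: np.ndarray, gp: np.ndarray, s: np.ndarray,
               inh: np.ndarray) -> np.ndarray:
    """Time derivatives of the flat state vector ``y`` (5 entries per clone).

    ``gp`` is the parameter vector in ``GROWTH_FIELD_ORDER``; ``s`` and
    ``inh`` are per-clone signal multipliers and effective inhibitions.
    Pure-numpy reference implementation shared by the LSODA path and tests.
    """
    if np.any(np.isnan(y)):
        raise IntegrationError("NaN state encountered", math.nan)
    (lam, d0, dq, kpq, kqp, kcl, vcell, drim, kmax,
     aang, rimm, himm, dimm, kI, gdrug) = gp
    n = y.size // 5
    P, Q, D, K, I = (y[0::5], y[1::5], y[2::5], y[3::5], y[4::5])
    n_tot = np.sum(P + Q)
    v_tot = vcell * np.sum(P + Q + D)
    r = (v_tot / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    phi = 1.0 if r <= drim else 1.0 - ((r - drim) / r) ** 3
    dy = np.empty_like(y)
    for c in range(n):
        kill_p = d0 + kI * I[c] + gdrug * inh[c]
        kill_q = dq + kI * I[c]
        # crowding factor floored at -1: overcrowding suppression saturates
        # (keeps the system non-stiff when a clone's capacity is far below
        # the total burden)
        crowd = max(1.0 - n_tot / max(K[c], 1.0), -1.0)
        grow = lam * s[c] * phi * crowd * P[c]
        dy[5 * c + 0] = grow - kpq * (1.0 - phi) * P[c] + kqp * phi * Q[c] - kill_p * P[c]
        dy[5 * c + 1] = kpq * (1.0 - phi) * P[c] - kqp * phi * Q[c] - kill_q * Q[c]
        dy[5 * c + 2] = kill_p * P[c] + kill_q * Q[c] - kcl * D[c]
        dy[5 * c + 3] = aang * (P[c] + Q[c]) * (1.0 - K[c] / kmax)
        dy[5 * c + 4] = rimm * n_tot / (himm + n_tot) - dimm * I[c]
    return dy


def clone_derivatives(states: list[CloneState], gp: GrowthParams,
                      s: np.ndarray, inh: np.ndarray) -> np.ndarray:
    """Derivatives of a list of :class:`CloneState`, shape ``(n_clones, 5)``."""
    y = np.concatenate([st.as_array() for st in states])
    if np.any(y < 0):
        raise IntegrationError("negative state supplied", math.nan)
    return growth_rhs(y, gp.as_array(), np.asarray(s, float),
                      np.asarray(inh, float)).reshape(-1, 5)


@njit(cache=True)
def _rhs_nb(y, dy, gp, s, inh):  # pragma: no cover - exercised via _rk4_nb
    (lam, d0, dq, kpq, kqp, kcl, vcell, drim, kmax,
     aang, rimm, himm, dimm, kI, gdrug) = (gp[0], gp[1], gp[2], gp[3], gp[4],
                                           gp[5], gp[6], gp[7], gp[8], gp[9],
                                           gp[10], gp[11], gp[12], gp[13], gp[14])
    n = y.size // 5
    n_tot = 0.0
    v_sum = 0.0
    for c in range(n):
        n_tot += y[5 * c] + y[5 * c + 1]
        v_sum += y[5 * c] + y[5 * c + 1] + y[5 * c + 2]
    v_tot = vcell * v_sum
    r = (v_tot / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    phi = 1.0 if r <= drim else 1.0 - ((r - drim) / r) ** 3
    for c in range(n):
        P = y[5 * c]
        Q = y[5 * c + 1]
        D = y[5 * c + 2]
        K = y[5 * c + 3]
        I = y[5 * c + 4]
        kill_p = d0 + kI * I + gdrug * inh[c]
        kill_q = dq + kI * I
        crowd = 1.0 - n_tot / max(K, 1.0)
        if crowd < -1.0:
            crowd = -1.0
        grow = lam * s[c] * phi * crowd * P
        dy[5 * c + 0] = grow - kpq * (1.0 - phi) * P + kqp * phi * Q - kill_p * P
        dy[5 * c + 1] = kpq * (1.0 - phi) * P - kqp * phi * Q - kill_q * Q
        dy[5 * c + 2] = kill_p * P + kill_q * Q - kcl * D
        dy[5 * c + 3] = aang * (P + Q) * (1.0 - K / kmax)
        dy[5 * c + 4] = rimm * n_tot / (himm + n_tot) - dimm * I


@njit(cache=True)
def _rk4_nb(y0, gp, s_off, s_on, inh_on, t_on, t_grid, dt):  # pragma: no cover
    ny = y0.size
    nt = t_grid.size
    out = np.empty((nt, ny))
    y = y0.copy()
    out[0, :] = y
    k1 = np.empty(ny); k2 = np.empty(ny); k3 = np.empty(ny); k4 = np.empty(ny)
    tmp = np.empty(ny)
    zeros = np.zeros_like(inh_on)
    t = t_grid[0]
    for i in range(1, nt):
        target = t_grid[i]
        while t < target - 1e-9:
            h = min(dt, target - t)
            if t >= t_on:
                s = s_on; inh = inh_on
            else:
                s = s_off; inh = zeros
            _rhs_nb(y, k1, gp, s, inh)
            for j in range(ny):
                tmp[j] = y[j] + 0.5 * h * k1[j]
            _rhs_nb(tmp, k2, gp, s, inh)
            for j in range(ny):
                tmp[j] = y[j] + 0.5 * h * k2[j]
            _rhs_nb(tmp, k3, gp, s, inh)
            for j in range(ny):
                tmp[j] = y[j] + h * k3[j]
            _rhs_nb(tmp, k4, gp, s, inh)
            for j in range(ny):
                y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                if y[j] < 0.0:
                    y[j] = 0.0
            t += h
        out[i, :] = y
    return out


@dataclass(frozen=True)
class TumorTrajectory:
    """Dense per-clone trajectory of one patient.

    ``states`` has shape ``(n_times, n_clones, 5)`` in the order
    P, Q, D, K, I; ``t_days`` is the (strictly increasing) output grid.
    """

    t_days: np.ndarray
    states: np.ndarray
    v_cell: float
    patient_id: str = "vp-0"

    @property
    def n_clones(self) -> int:
        return self.states.shape[1]

    @property
    def volume_cm3(self) -> np.ndarray:
        return self.v_cell * self.states[:, :, :3].sum(axis=(1, 2))

    @property
    def radius_cm(self) -> np.ndarray:
        return radius_from_volume(self.volume_cm3)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        data = {"patient_id": self.patient_id, "t_days": self.t_days,
                "radius_cm": self.radius_cm, "v_total_cm3": self.volume_cm3}
        for c in range(self.n_clones):
            for j, name in enumerate(("P", "Q", "D")):
                data[f"clone{c}_{name}"] = self.states[:, c, j]
        return pd.DataFrame(data)


def _clone_forcings(patient: VirtualPatient, sig: SignalingParams,
                    pd_params: trt.PDParams, c_avg: float):
    """Per-clone constant (average-PK) signal multipliers and inhibitions."""
    profiles = patient.profiles()
    s_off = np.array([signal_multiplier(p, 0.0, sig) for p in profiles])
    inh_raw = np.array([trt.inhibition(c_avg, pd_params, p) for p in profiles])
    eff = np.array([resistance_attenuation(p, sig) for p in profiles])
    s_on = np.array([
        signal_multiplier(p, i, sig) for p, i in zip(profiles, inh_raw)
    ])
    return s_off, s_on, eff * inh_raw


def simulate_tumor(patient: VirtualPatient,
                   regimen=None,
                   t_end_days: float = 913.0,
                   dt_out_days: float = 1.0,
                   growth: GrowthParams | None = None,
                   signaling: SignalingParams | None = None,
                   pk: trt.PKParams | None = None,
                   pd_params: trt.PDParams | None = None,
                   method: str = "lsoda",
                   pk_mode: str = "average",
                   capacity_factor: float = 1.5,
                   rtol: float = 1e-6,
                   atol: float = 1e-3,
                   rk4_dt_days: float = 0.25) -> TumorTrajectory:
    """Integrate one patient's tumor from day 0 to ``t_end_days``.

    ``pk_mode="average"`` drives each clone with the steady-state average
    gefitinib concentration from the first dose onward; ``pk_mode="full"``
    (LSODA only) re-evaluates the closed-form PK at every step, resolving
    within-day concentration swings. Patient-level overrides stored on the
    :class:`VirtualPatient` are applied to the growth parameters here.

    Deterministic for fixed inputs. States are clipped at zero; an
    undershoot beyond tolerance aborts with :class:`IntegrationError`.
    """
    if t_end_days <= 0:
        raise ValueError("t_end_days must be > 0")
    import dataclasses as _dc

    growth = growth or GrowthParams()
    if patient.growth_overrides:
        growth = _dc.replace(growth, **dict(patient.growth_overrides))
    if patient.pace != 1.0:
        growth = scale_rates(growth, patient.pace)
    signaling = signaling or SignalingParams()
    pk = pk or trt.PKParams()
    if patient.pk_overrides:
        pk = _dc.replace(pk, **dict(patient.pk_overrides))
    pd_params = pd_params or trt.PDParams()
    if patient.pd_overrides:
        pd_params = _dc.replace(pd_params, **dict(patient.pd_overrides))
    if regimen is None:
        regimen = trt.default_regimen(pk)
    t_on = min((b.start_day for b in regimen), default=math.inf)
    # average exposure of the first (typically only) dose block
    if regimen:
        b = regimen[0]
        c_avg = trt.average_concentration_ss(pk, b.dose_mg, b.interval_h)
    else:
        c_avg = 0.0

    states0 = build_clones(patient, growth, capacity_factor)
    y0 = np.concatenate([st.as_array() for st in states0])
    t_grid = np.arange(0.0, t_end_days + 0.5 * dt_out_days, dt_out_days)
    gp = growth.as_array()
    s_off, s_on, inh_on = _clone_forcings(patient, signaling, pd_params, c_avg)
    profiles = patient.profiles()

    if method == "rk4":
        out = _rk4_nb(y0, gp, s_off, s_on, inh_on, t_on, t_grid, rk4_dt_days)
    elif method == "lsoda":
        eff = np.array([resistance_attenuation(p, signaling) for p in profiles])
        gains = np.array([
            signaling.s0 * (1.0 + signaling.g_egfr.get(p.egfr_variant, 0.0) + p.m_prolif)
            for p in profiles
        ])

        def rhs(t, y):
            if pk_mode == "full":
                c = trt.concentration(t * trt.HOURS_PER_DAY, pk, regimen)
                inh_raw = np.array([trt.inhibition(c, pd_params, p) for p in profiles])
            else:
                on = t >= t_on
                inh_raw = np.array([trt.inhibition(c_avg, pd_params, p) for p in profiles]) \
                    if on else np.zeros(len(profiles))
            s = np.maximum(gains * (1.0 - eff * inh_raw), 0.0)
            return growth_rhs(np.maximum(y, 0.0), gp, s, eff * inh_raw)

        sol = solve_ivp(rhs, (0.0, t_grid[-1]), y0, t_eval=t_grid,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"LSODA failed: {sol.message}",
                                   float(sol.t[-1]) if sol.t.size else 0.0)
        out = sol.y.T.copy()
        undershoot = -out.min(initial=0.0)
        if undershoot > max(atol, 1e-6 * y0.sum()):
            raise IntegrationError(
                f"state undershoot {undershoot:.3g} beyond tolerance", float(sol.t[-1]))
        out[out < 0.0] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    states = out.reshape(len(t_grid), -1, 5)
    return TumorTrajectory(t_days=t_grid, states=states, v_cell=growth.v_cell,
                           patient_id=patient.id)
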