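import dataclasses
import math

import numpy as np
import pytest

import luadsim as L
from luadsim.core import GROWTH_FIELD_ORDER
from luadsim.tumor import growth_rhs


class TestGeometry:
    @pytest.mark.parametrize("v,expected", [
        (0.0, 0.0),
        (4.0 * math.pi / 3.0, 1.0),
    ])
    def test_radius_examples(self, v, expected):
        assert L.radius_from_volume(v) == pytest.approx(expected, abs=1e-12)

    def test_round_trip(self):
        v = np.array([1e-6, 0.3, 4.2, 113.0])
        np.testing.assert_allclose(
            L.volume_from_radius(L.radius_from_volume(v)), v, rtol=1e-12)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            L.radius_from_volume(-1.0)

    def test_radius_monotone_in_volume(self):
        v = np.linspace(0.0, 50.0, 500)
        assert np.all(np.diff(L.radius_from_volume(v)) > 0)

    @pytest.mark.parametrize("r,d,expected", [
        (0.5, 1.0, 1.0),            # whole tumor inside viable rim
        (2.0, 0.0, 0.0),            # no viable shell
        (2.0, 1.0, 0.875),          # r = 2*d_rim -> 1 - (1/2)^3
    ])
    def test_viable_fraction_examples(self, r, d, expected):
        assert L.viable_fraction(r, d) == pytest.approx(expected, rel=1e-12)


def _states(*rows):
    return [L.CloneState(*row) for row in rows]


class TestCloneDerivatives:
    def test_extinction_is_absorbing(self):
        gp = L.GrowthParams()
        dy = L.clone_derivatives(_states((0, 0, 0, 1e9, 0), (0, 0, 0, 1e9, 0)),
                                 gp, s=[1.0, 1.0], inh=[0.0, 0.0])
        assert np.allclose(dy[:, :3], 0.0) and np.allclose(dy[:, 4], 0.0)

    def test_frozen_dynamics(self):
        gp = L.GrowthParams(lambda_prolif=0, delta0=0, delta_q=0, k_pq=0,
                            k_qp=0, k_cl=0, alpha_ang=0, rho_imm=0,
                            kappa_imm=0, gamma_drug=0)
        dy = L.clone_derivatives(_states((1e8, 1e7, 1e6, 1e9, 0.5),
                                         (1e5, 0, 0, 1e9, 0.5)),
                                 gp, s=[1.0, 1.0], inh=[1.0, 1.0])
        # immune decay is the only surviving term (d_imm > 0)
        assert np.allclose(dy[:, :4], 0.0)

    def test_exponential_growth_limit(self):
        # tiny tumor: phi = 1, N << K, no quiescents/immune/drug
        gp = L.GrowthParams(delta0=1e-3)
        st = _states((1e4, 0, 0, 1e12, 0), (0, 0, 0, 1e12, 0))
        s = [1.3, 1.3]
        dy = L.clone_derivatives(st, gp, s=s, inh=[0.0, 0.0])
        expected = (gp.lambda_prolif * 1.3 - gp.delta0) * 1e4
        assert dy[0, 0] == pytest.approx(expected, rel=1e-4)

    def test_carrying_capacity_saturation(self):
        # N_tot = K_c: the proliferation term vanishes for that clone
        gp = L.GrowthParams()
        st = _states((6e8, 4e8, 0, 1e9, 0.0), (0, 0, 0, 1e9, 0.0))
        dy_with = L.clone_derivatives(st, gp, s=[2.0, 2.0], inh=[0.0, 0.0])
        gp0 = dataclasses.replace(gp, lambda_prolif=0.0)
        dy_without = L.clone_derivatives(st, gp0, s=[2.0, 2.0], inh=[0.0, 0.0])
        np.testing.assert_allclose(dy_with, dy_without, rtol=0, atol=1e-9)

    def test_mass_bookkeeping(self, rng):
        """d(P+Q+D)/dt equals proliferation inflow minus clearance outflow."""
        gp_vec = L.GrowthParams().as_array()
        idx = {n: i for i, n in enumerate(GROWTH_FIELD_ORDER)}
        for _ in range(50):
            y = rng.uniform(0, 1e9, size=10)
            s = rng.uniform(0.2, 2.0, size=2)
            inh = rng.uniform(0, 1, size=2)
            dy = growth_rhs(y, gp_vec, s, inh).reshape(2, 5)
            P, Q, D, K, I = (y[0::5], y[1::5], y[2::5], y[3::5], y[4::5])
            n_tot = np.sum(P + Q)
            v_tot = gp_vec[idx["v_cell"]] * np.sum(P + Q + D)
            r = L.radius_from_volume(v_tot)
            phi = L.viable_fraction(r, gp_vec[idx["d_rim"]])
            for c in range(2):
                crowd = max(1.0 - n_tot / max(K[c], 1.0), -1.0)
                grow = gp_vec[idx["lambda_prolif"]] * s[c] * phi * crowd * P[c]
                kill = ((gp_vec[idx["delta0"]] + I[c] + inh[c]) * P[c]
                        + (gp_vec[idx["delta_q"]] + I[c]) * Q[c])
                lhs = dy[c, :3].sum()
                rhs = grow - gp_vec[idx["k_cl"]] * D[c]
                # tolerance scaled to the gross flows that cancel in the sum
                gross = abs(grow) + kill + gp_vec[idx["k_cl"]] * D[c] + 1.0
                assert abs(lhs - rhs) < 1e-10 * gross

    def test_invalid_states_rejected(self):
        with pytest.raises(L.IntegrationError):
            growth_rhs(np.array([np.nan, 0, 0, 1e9, 0]),
                       L.GrowthParams().as_array(),
                       np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            L.CloneState(-1.0, 0, 0, 1e9, 0)


def logistic(t, n0, k, g):
    return k * n0 * np.exp(g * t) / (k + n0 * (np.exp(g * t) - 1.0))


class TestSimulateTumor:
    def test_logistic_closed_form(self):
        """Untreated, rim-free, death-free growth follows the logistic curve."""
        gp = L.GrowthParams(delta0=0, delta_q=0, k_pq=0, k_qp=0, k_cl=0,
                            d_rim=1e3, alpha_ang=0, rho_imm=0, kappa_imm=0,
                            gamma_drug=0, lambda_prolif=0.05)
        sig = L.SignalingParams(g_egfr={"exon19del": 0.0, "l858r": 0.0})
        patient = L.VirtualPatient(f_res=0.5, m_prolif=0.0, prolif_frac=1.0)
        traj = L.simulate_tumor(patient, regimen=(), t_end_days=300.0,
                                growth=gp, signaling=sig, method="lsoda")
        n = traj.states[:, :, :2].sum(axis=(1, 2))
        n0 = n[0]
        k = traj.states[0, 0, 3]  # capacity is constant here
        expected = logistic(traj.t_days, n0, k, 0.05)
        np.testing.assert_allclose(n, expected, rtol=1e-4)

    def test_frozen_dynamics_stay_constant(self):
        gp = L.GrowthParams(lambda_prolif=0, delta0=0, delta_q=0, k_pq=0,
                            k_qp=0, k_cl=0, alpha_ang=0, rho_imm=0,
                            kappa_imm=0, gamma_drug=0)
        traj = L.simulate_tumor(L.VirtualPatient(), regimen=(),
                                t_end_days=50.0, growth=gp, method="rk4")
        np.testing.assert_allclose(traj.states[-1], traj.states[0], rtol=1e-12)

    def test_decline_then_relapse_under_treatment(self, settings):
        traj = L.simulate_patient(L.VirtualPatient(), settings, method="rk4")
        r = traj.radius_cm
        nadir = r.min()
        assert nadir < 0.95 * r[0]          # initial response
        assert r[-1] > 1.2 * nadir          # subsequent regrowth
        assert r.argmin() not in (0, r.size - 1)

    def test_rk4_agrees_with_lsoda(self, settings):
        p = L.VirtualPatient()
        fast = L.simulate_patient(p, settings, method="rk4")
        ref = L.simulate_patient(p, settings, method="lsoda")
        np.testing.assert_allclose(fast.radius_cm, ref.radius_cm, rtol=2e-3)

    def test_nonnegative_states_across_population(self, default_spec, settings):
        patients = L.sample_population(default_spec, 200, seed=9)
        for p in patients:
            traj = L.simulate_patient(p, settings, method="rk4")
            assert np.isfinite(traj.states).all()
            assert (traj.states >= 0).all()
            assert np.all(np.diff(traj.t_days) > 0)

    def test_immune_pressure_never_grows_tumor(self, settings):
        base = L.VirtualPatient()
        stronger = [
            L.VirtualPatient(growth_overrides={"kappa_imm": 3.0}),
            L.VirtualPatient(growth_overrides={"rho_imm": 5e-3}),
        ]
        r0 = L.simulate_patient(base, settings, method="rk4").radius_cm
        for p in stronger:
            r = L.simulate_patient(p, settings, method="rk4").radius_cm
            assert np.all(r <= r0 + 1e-9)

    def test_pace_rescales_time_axis(self, settings):
        slow = L.simulate_patient(L.VirtualPatient(pace=0.5), settings, method="rk4")
        base = L.simulate_patient(L.VirtualPatient(), settings, method="rk4")
        # radius at day 2t under half pace equals radius at day t at full pace
        np.testing.assert_allclose(slow.radius_cm[::2][:300], base.radius_cm[:300],
                                   rtol=1e-4)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            L.simulate_tumor(L.VirtualPatient(), t_end_days=0.0)
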