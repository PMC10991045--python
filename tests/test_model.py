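"""Deterministic mean-field simulator of the multi-turnover RC scheme."""

import numpy as np
import pytest

from rcflow.induction import initial_slope
from rcflow.model import (
    ModelError,
    RateParameters,
    RCStateDistribution,
    STATE_LABELS,
    load_rate_parameters,
    ode_rhs,
    save_rate_parameters,
    simulate,
    simulate_to_saturation,
)
from rcflow.traces import Trace


def idx(d, a, b):
    return STATE_LABELS.index((d, a, b))


class TestRateParameters:
    def test_invalid_rejected(self):
        good = dict(k_I=1e3, k2=1e9, rc_conc=1e-6, A1=1e3, A2=1e3, E=1e2,
                    p=0.2, pool=1.0)
        for bad in [dict(k_I=-1), dict(p=1.0), dict(p=-0.1), dict(pool=-1),
                    dict(rc_conc=0.0)]:
            with pytest.raises(ModelError):
                RateParameters(**{**good, **bad})

    def test_diffusion_limit_warning(self):
        with pytest.warns(UserWarning, match="diffusion limit"):
            RateParameters(k_I=1e3, k2=2e10, rc_conc=1e-6, A1=0, A2=0, E=0,
                           p=0.0, pool=0.0)

    def test_file_round_trip(self, tmp_path, pool_scan):
        for name in ("params.yaml", "params.json"):
            path = tmp_path / name
            save_rate_parameters(pool_scan, path)
            assert load_rate_parameters(path) == pool_scan

    def test_missing_key_rejected(self, tmp_path):
        path = tmp_path / "p.yaml"
        path.write_text("k_I: 1000\n")
        with pytest.raises(ModelError, match="missing"):
            load_rate_parameters(path)


class TestStateDistribution:
    def test_sum_enforced(self):
        frac = np.zeros(12)
        frac[0] = 0.5
        with pytest.raises(ModelError):
            RCStateDistribution(frac, 0.0)

    def test_all_open(self, pool_scan):
        s = RCStateDistribution.all_open(pool_scan)
        assert s.open_fraction == 1.0
        assert s.donor_conc == pool_scan.pool * pool_scan.rc_conc


class TestOdeRhs:
    def test_all_rates_zero(self):
        params = RateParameters(k_I=0, k2=0, rc_conc=1e-6, A1=0, A2=0, E=0,
                                p=0.3, pool=1.0)
        state = RCStateDistribution.all_open(params)
        dfrac, ddonor = ode_rhs(state, params)
        assert np.all(dfrac == 0) and ddonor == 0

    def test_fully_open_closure_flux(self):
        """With phi(0) = 0 the entire flux k_I leaves (P, QA, QB)."""
        params = RateParameters(k_I=5e3, k2=0, rc_conc=1e-6, A1=0, A2=0, E=0,
                                p=0.3, pool=0.0)
        state = RCStateDistribution.all_open(params)
        dfrac, ddonor = ode_rhs(state, params)
        assert dfrac[idx("P", "QA", "QB")] == pytest.approx(-5e3)
        assert dfrac[idx("P+", "QA-", "QB")] == pytest.approx(5e3)
        assert ddonor == 0
        assert dfrac.sum() == pytest.approx(0, abs=1e-9)

    def test_donor_mass_action(self):
        """Single P+ state: dP+/dt = -k2 d0 and pool consumption scales
        with rc_conc."""
        params = RateParameters(k_I=0, k2=1e9, rc_conc=2e-6, A1=0, A2=0, E=0,
                                p=0.0, pool=1.0)
        frac = np.zeros(12)
        frac[idx("P+", "QA", "QB")] = 1.0
        d0 = 3e-6
        state = RCStateDistribution(frac, d0)
        dfrac, ddonor = ode_rhs(state, params)
        assert dfrac[idx("P+", "QA", "QB")] == pytest.approx(-1e9 * d0)
        assert dfrac[idx("P", "QA", "QB")] == pytest.approx(1e9 * d0)
        assert ddonor == pytest.approx(-1e9 * d0 * 2e-6)

    def test_derivative_conserves_mass(self, qa_redox):
        rng = np.random.default_rng(0)
        frac = rng.dirichlet(np.ones(12))
        state = RCStateDistribution(frac, 1e-6)
        dfrac, _ = ode_rhs(state, qa_redox)
        assert dfrac.sum() == pytest.approx(0, abs=1e-9)


class TestSimulate:
    def test_zero_pool_single_turnover(self, pool_scan):
        """No donors: every RC closes exactly once and stays P+."""
        sim = simulate(pool_scan.replace(pool=0.0), 5e-3)
        assert sim.p_plus[-1] == pytest.approx(1.0, abs=1e-6)
        assert sim.cum_separations[-1] == pytest.approx(1.0, rel=1e-6)

    def test_terbutryn_ends_in_pqa_minus(self, pool_scan):
        """A1 = 0 with donors present: single separation, all RCs PQA-."""
        sim = simulate(pool_scan.replace(A1=0.0, pool=2.0), 0.05)
        assert sim.cum_separations[-1] == pytest.approx(1.0, rel=1e-6)
        assert sim.pqa_minus[-1] == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("pool", [0.0, 0.5, 2.0])
    def test_trajectory_invariants(self, pool_scan, pool):
        sim = simulate(pool_scan.replace(pool=pool), 5e-3)
        assert np.abs(sim.fractions.sum(axis=1) - 1).max() < 1e-8
        assert np.all(np.diff(sim.donor_conc) <= 1e-15)
        assert np.all(sim.donor_conc >= 0)
        assert np.all(np.diff(sim.cum_separations) >= -1e-12)
        for arr in (sim.phi, sim.p_plus, sim.x, sim.pqa_minus):
            assert arr.min() >= 0 and arr.max() <= 1 + 1e-12

    def test_light_off_freezes_closure(self, qa_redox):
        sim = simulate(qa_redox, light_on_duration=1e-4, total_time=5e-3)
        dark = sim.times > 1e-4
        assert sim.cum_separations[dark].max() == pytest.approx(
            sim.cum_separations[dark].min(), rel=1e-9
        )

    def test_qa_reduced_rises_then_decays(self, qa_redox):
        """PQA- transient: single maximum, monotone on both sides."""
        sim = simulate(qa_redox, 5e-3)
        i = int(np.argmax(sim.pqa_minus))
        assert 0 < i < len(sim.times) - 1
        assert np.all(np.diff(sim.pqa_minus[: i + 1]) >= -1e-9)
        assert np.all(np.diff(sim.pqa_minus[i:]) <= 1e-9)

    def test_single_turnover_area(self, pool_scan):
        """Supplementary area of a single-turnover induction is 1/k_I."""
        sim = simulate(pool_scan.replace(pool=0.0), 5e-3)
        area = np.trapezoid(1 - sim.phi, sim.times)
        assert area * pool_scan.k_I == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("p", [0.0, 0.3])
    def test_initial_slope_limit(self, pool_scan, p):
        """t -> 0 slope of phi equals (1 - p) k_I."""
        params = pool_scan.replace(p=p, pool=0.0)
        sim = simulate(params, 5e-3)
        slope = initial_slope(Trace(sim.times, sim.phi, "phi"))
        assert slope == pytest.approx((1 - p) * params.k_I, rel=0.02)

    def test_invalid_times_rejected(self, pool_scan):
        with pytest.raises(ModelError):
            simulate(pool_scan, 0.0)
        with pytest.raises(ModelError):
            simulate(pool_scan, 1e-3, total_time=1e-4)

    def test_csv_columns(self, tmp_path, pool_scan):
        sim = simulate(pool_scan.replace(pool=0.0), 1e-3, n_points=100)
        path = tmp_path / "traj.csv"
        sim.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_s,phi,p_plus,x,pqa_minus,donor_per_rc,cum_separations"


class TestAreaElectronCalibration:
    @pytest.mark.parametrize("p", [0.0, 0.15, 0.3])
    def test_area_linear_in_electrons(self, pool_scan, p):
        """Area x k_I is linear in charge separations per RC, with unit
        slope, independent of the hopping parameter."""
        pools = [0.0, 1.0, 2.0, 3.0, 5.0]
        areas, seps = [], []
        for pool in pools:
            sim = simulate_to_saturation(pool_scan.replace(p=p, pool=pool))
            areas.append(np.trapezoid(1 - sim.phi, sim.times) * pool_scan.k_I)
            seps.append(sim.cum_separations[-1])
        slope, intercept = np.polyfit(seps, areas, 1)
        pred = np.polyval([slope, intercept], seps)
        ss_res = np.sum((np.array(areas) - pred) ** 2)
        ss_tot = np.sum((np.array(areas) - np.mean(areas)) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert slope == pytest.approx(1.0, rel=0.02)
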