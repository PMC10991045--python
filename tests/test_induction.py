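"""Fluorescence-induction feature extraction and derived constants."""

import json

import numpy as np
import pytest

from rcflow.induction import (
    InductionError,
    analyze_induction,
    derive_connectivity,
    derive_photochemical_rate,
    electron_count,
    initial_slope,
    normalize_induction,
    supplementary_area,
)
from rcflow.model import simulate, simulate_to_saturation
from rcflow.synthetic import generate_induction_dataset, get_preset
from rcflow.traces import Trace, average_traces, read_trace


def exp_raw_trace(a=1.0, b=2.0, k=1e3, t_end=None, n=400):
    t_end = t_end if t_end is not None else 10 / k
    t = np.linspace(1e-6, t_end, n)
    return Trace(t, a + b * (1 - np.exp(-k * t)), "raw_fluorescence")


class TestNormalize:
    def test_closed_form_levels(self):
        raw = exp_raw_trace(a=1.0, b=2.0, k=1e3)
        phi, f0, fmax = normalize_induction(raw)
        assert f0 == pytest.approx(1.0, rel=0.01)
        assert fmax == pytest.approx(3.0, rel=0.01)
        assert phi.values.min() >= 0 and phi.values.max() <= 1

    def test_constant_trace_rejected(self):
        t = np.linspace(0, 1, 20)
        raw = Trace(t, np.full_like(t, 2.0), "raw_fluorescence")
        with pytest.raises(InductionError, match="no rise"):
            normalize_induction(raw)

    def test_decreasing_trace_rejected(self):
        t = np.linspace(0, 1, 50)
        raw = Trace(t, 3 - 2 * t, "raw_fluorescence")
        with pytest.raises(InductionError, match="not increasing"):
            normalize_induction(raw)

    def test_noisy_levels_recovered(self):
        sp = get_preset("pufC", terbutryn=True)
        sim = simulate_to_saturation(sp.params)
        rng = np.random.default_rng(17)
        f = 1.0 + 2.0 * sim.phi
        raw = Trace(sim.times, f * (1 + 0.01 * rng.standard_normal(f.size)),
                    "raw_fluorescence")
        _, f0, fmax = normalize_induction(raw)
        assert f0 == pytest.approx(1.0, rel=0.03)
        assert fmax == pytest.approx(3.0, rel=0.03)


class TestSupplementaryArea:
    def test_exponential_analytic(self):
        k = 1e3
        t = np.linspace(0, 12 / k, 4000)
        phi = Trace(t, 1 - np.exp(-k * t), "phi")
        assert supplementary_area(phi) == pytest.approx(1 / k, rel=0.005)

    def test_saturated_constant(self):
        t = np.linspace(0, 1, 10)
        assert supplementary_area(Trace(t, np.ones_like(t), "phi")) == 0.0

    def test_piecewise_linear_by_hand(self):
        t = np.array([0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0])
        v = np.where(t <= 1, 0.5 * t, 0.5 + 0.5 * (t - 1))
        assert supplementary_area(Trace(t, v, "phi")) == pytest.approx(1.0)

    def test_unsaturated_rejected_with_peak(self):
        t = np.linspace(0, 1, 20)
        phi = Trace(t, 0.8 * t, "phi")
        with pytest.raises(InductionError, match="0.8"):
            supplementary_area(phi)


class TestInitialSlope:
    def test_exponential_recovery(self):
        k = 1e3
        t = np.geomspace(1e-7, 10 / k, 2000)
        phi = Trace(t, 1 - np.exp(-k * t), "phi")
        assert initial_slope(phi) == pytest.approx(k, rel=0.03)

    def test_linear_exact(self):
        t = np.linspace(1e-4, 1.0, 50)
        phi = Trace(t, 0.12 * t, "phi")
        assert initial_slope(phi) == pytest.approx(0.12, rel=1e-9)

    def test_sparse_early_sampling_rejected(self):
        t = np.linspace(0.0, 10.0, 9)
        phi = Trace(t, np.clip(t / 0.5, 0, 1), "phi")
        with pytest.raises(InductionError, match="densely"):
            initial_slope(phi)


class TestDerivedConstants:
    def test_connectivity_values(self):
        assert derive_connectivity(1.9e-4, 4.1e3) == pytest.approx(0.221, abs=1e-12)
        assert derive_connectivity(0.25, 4.0) == pytest.approx(0.0, abs=1e-12)
        assert derive_connectivity(2e-4, 4e3) == pytest.approx(0.2, abs=1e-12)

    def test_connectivity_clamp_and_error(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert derive_connectivity(1.03, 1.0) == 0.0
        with pytest.raises(InductionError, match="inconsistent"):
            derive_connectivity(1.1, 1.0)

    def test_photochemical_rate_reciprocal(self):
        assert derive_photochemical_rate(1.9e-4) == pytest.approx(5.263e3, rel=1e-3)
        assert derive_photochemical_rate(1e-3) == pytest.approx(1e3)

    def test_electron_count_values(self):
        assert electron_count(0.51, 0.11) == pytest.approx(4.636, abs=1e-3)
        assert electron_count(0.3, 0.3) == 1.0
        assert electron_count(0.25, 0.12) == pytest.approx(2.083, abs=1e-3)

    def test_electron_count_warns_below_one(self):
        with pytest.warns(UserWarning, match="impossible"):
            electron_count(0.1, 0.2)


class TestPipelineRecovery:
    @pytest.mark.parametrize("k_I", [5e3, 1e4])
    @pytest.mark.parametrize("p", [0.0, 0.1, 0.2, 0.3])
    def test_noise_free_recovery(self, pool_scan, k_I, p):
        """Noise-free single-turnover traces return the generating k_I and
        p through the area/slope formulas."""
        params = pool_scan.replace(k_I=k_I, p=p, A1=0.0, pool=1.0)
        sim = simulate_to_saturation(params)
        raw = Trace(sim.times, 1.0 + 2.0 * sim.phi, "raw_fluorescence")
        feats = analyze_induction(raw)
        assert feats.k_I == pytest.approx(k_I, rel=0.03)
        assert feats.p == pytest.approx(p, abs=0.02)

    def test_noisy_recovery_mean(self, tmp_path):
        """1% multiplicative noise, 20 replicate estimates (each averaging
        three recordings, as in the experimental protocol): the mean
        recovered p stays within +/-0.03 and k_I within 3%."""
        sp = get_preset("pufC", terbutryn=True)
        ps, ks = [], []
        for seed in range(20):
            reps = [
                read_trace(
                    generate_induction_dataset(
                        sp, noise_sigma=0.01, seed=seed * 10 + r,
                        out_dir=tmp_path)[0],
                    "raw_fluorescence",
                )
                for r in range(3)
            ]
            feats = analyze_induction(average_traces(reps))
            ps.append(feats.p)
            ks.append(feats.k_I)
        assert np.mean(ps) == pytest.approx(sp.params.p, abs=0.03)
        assert np.mean(ks) == pytest.approx(sp.params.k_I, rel=0.03)

    def test_electron_count_monotone_in_pool(self, pool_scan):
        """N from simulated panels grows with the donor pool and is 1 at
        pool = 0."""
        single = simulate_to_saturation(pool_scan.replace(A1=0.0, pool=0.0))
        a_s = np.trapezoid(1 - single.phi, single.times)
        counts = []
        for pool in [0.0, 1.0, 2.0, 4.0]:
            sim = simulate_to_saturation(pool_scan.replace(pool=pool))
            a_m = np.trapezoid(1 - sim.phi, sim.times)
            counts.append(electron_count(a_m, a_s))
        assert counts[0] == pytest.approx(1.0, rel=0.02)
        assert np.all(np.diff(counts) > 0)


def test_feature_report_keys(pool_scan):
    sim = simulate_to_saturation(pool_scan.replace(A1=0.0, pool=0.0))
    raw = Trace(sim.times, 1 + 2 * sim.phi, "raw_fluorescence")
    feats = analyze_induction(raw)
    report = feats.to_dict()
    assert set(report) == {"F0", "Fmax", "slope_per_s", "area_s",
                           "k_I_per_s", "p", "N"}
    assert report["N"] is None
    assert json.dumps(report)  # serializable
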