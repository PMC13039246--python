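"""Circuit model: transfer function, sampling, responses, equalisation, tuning."""

import numpy as np
import pytest

from mbcircuit._rng import stream
from mbcircuit.circuit_model import (
    MBCircuit,
    TransferParams,
    TuningError,
    add_pn_noise,
    build_tuned_circuit,
    coding_level,
    equalise_weights,
    kc_responses,
    lateral_suppression,
    pn_transfer,
    relu,
    sample_connectivity,
    sample_thresholds,
    tune_parameters,
)
from mbcircuit.synthetic_data import gen_orn_panel


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(-1.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_values(self, x, expected):
        assert relu(x) == expected

    def test_vectorised_nonnegative(self, rng):
        x = rng.normal(size=1000)
        y = relu(x)
        assert np.all(y >= 0)
        np.testing.assert_array_equal(y[x > 0], x[x > 0])


class TestTransferFunction:
    def test_suppression_formula(self):
        # 24 channels at 50 Hz: s = 10.63 * 1200 / 190
        orn = np.full((1, 24), 50.0)
        s = lateral_suppression(orn, TransferParams())
        np.testing.assert_allclose(s, [10.63 * 1200 / 190])

    def test_suppression_zero_row_and_linearity(self):
        orn = np.vstack([np.zeros(24), np.full(24, 10.0), np.full(24, 20.0)])
        s = lateral_suppression(orn)
        assert s[0] == 0
        np.testing.assert_allclose(s[2], 2 * s[1])

    def test_transfer_zero_input(self):
        x = pn_transfer(np.zeros((3, 24)))
        np.testing.assert_array_equal(x, 0)

    def test_half_maximum_point(self):
        # ORN^e = s^e + sigma^e gives exactly R_max / 2
        p = TransferParams()
        orn_val = 30.0
        orn = np.full((1, 24), orn_val)
        s = lateral_suppression(orn, p)[0]
        target = (s**p.exponent + p.sigma_t**p.exponent) ** (1 / p.exponent)
        # rescale norm_const so that s recomputes to keep ORN == target
        x = p.r_max * target**p.exponent / (
            target**p.exponent + s**p.exponent + p.sigma_t**p.exponent
        )
        assert x == pytest.approx(p.r_max / 2)

    def test_uniform_panel_value(self):
        # independently derived: 24 channels at 50 Hz -> x ~ 61.7 each
        x = pn_transfer(np.full((1, 24), 50.0))
        np.testing.assert_allclose(x, 61.72, atol=0.01)

    def test_bounded_and_monotone(self, rng):
        p = TransferParams()
        orn = rng.gamma(1.0, 40.0, (50, 24))
        x = pn_transfer(orn, p)
        assert np.all(x < p.r_max) and np.all(x >= 0)
        # monotone in ORN for fixed s: bump one channel, recompute with same s
        s = lateral_suppression(orn, p)
        e = p.exponent
        x1 = p.r_max * orn**e / (orn**e + s[:, None]**e + p.sigma_t**e)
        orn2 = orn * 1.1
        x2 = p.r_max * orn2**e / (orn2**e + s[:, None]**e + p.sigma_t**e)
        assert np.all(x2 >= x1)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pn_transfer(np.array([[-1.0, 5.0]]))


class TestPnNoise:
    def test_zero_cv_identity(self):
        x = np.full((4, 24), 80.0)
        trials, ids = add_pn_noise(x, cv_fn=lambda v: np.zeros_like(v),
                                   n_trials=30, seed=0)
        assert trials.shape == (120, 24)
        np.testing.assert_array_equal(trials, np.repeat(x, 30, axis=0))
        assert list(ids[:31]) == [0] * 30 + [1]

    def test_noise_sd_matches_cv(self):
        x = np.full((1, 1), 100.0)
        trials, _ = add_pn_noise(x, cv_fn=lambda v: np.full_like(v, 0.2),
                                 n_trials=10_000, seed=1)
        # clipping at 0 is negligible at CV 0.2
        assert abs(trials.std() - 20.0) / 20.0 < 0.03

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            add_pn_noise(np.ones((2, 3)), cv_fn=lambda v: -np.ones_like(v),
                         n_trials=2, seed=0)


class TestConnectivitySampling:
    def test_claw_counts_in_range_and_distinct(self):
        claws, w = sample_connectivity(2000, 24, seed=3)
        counts = np.array([c.size for c in claws])
        assert counts.min() >= 2 and counts.max() <= 11
        for c in claws[:100]:
            assert len(np.unique(c)) == c.size
        # weights positive exactly on claws
        for j in (0, 17, 1999):
            nz = np.flatnonzero(w[:, j])
            np.testing.assert_array_equal(np.sort(nz), claws[j])
            assert np.all(w[nz, j] > 0)

    def test_mean_claw_count(self):
        claws, _ = sample_connectivity(2000, 24, seed=4)
        counts = np.array([c.size for c in claws])
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 6.0) < 3 * se

    def test_degenerate_claw_distribution(self):
        claws, _ = sample_connectivity(500, 24, claw_sigma=0.0, seed=5)
        assert all(c.size == 6 for c in claws)

    def test_too_few_pns(self):
        with pytest.raises(ValueError):
            sample_connectivity(10, 8, seed=0)


class TestThresholds:
    def test_cv_zero_gives_ones(self):
        np.testing.assert_array_equal(sample_thresholds(100, cv=0.0, seed=0),
                                      np.ones(100))

    def test_empirical_cv(self):
        theta = sample_thresholds(2000, cv=0.26, seed=1)
        assert np.all(theta > 0)
        cv = theta.std(ddof=1) / theta.mean()
        # SE of the CV is ~ cv/sqrt(2n)
        assert abs(cv - 0.26) < 3 * 0.26 / np.sqrt(2 * 2000)

    def test_invalid_cv(self):
        with pytest.raises(ValueError):
            sample_thresholds(10, cv=-0.1, seed=0)


def _toy_circuit(alpha=0.1, c_theta=2.0):
    w = np.array([
        [1.0, 0.0, 0.5, 0.0, 2.0],
        [0.0, 1.5, 0.5, 0.0, 0.0],
        [2.0, 0.0, 0.0, 1.0, 1.0],
    ])
    theta = np.array([1.0, 0.8, 1.2, 1.0, 0.9])
    claws = [np.flatnonzero(w[:, j]) for j in range(5)]
    return MBCircuit(M=5, n_pn=3, w=w, claws=claws, theta=theta,
                     alpha=alpha, c_theta=c_theta, claw_range=(1, 3))


class TestKCResponses:
    def test_matches_literal_equation(self):
        """Oracle: literal loop transcription of the KC response equation."""
        circuit = _toy_circuit(alpha=0.07, c_theta=1.5)
        x = np.array([3.0, 1.0, 2.0])
        resp = kc_responses(x, circuit)
        M, n_pn = 5, 3
        T = sum(circuit.w[i, j] * x[i] for j in range(M) for i in range(n_pn))
        for j in range(M):
            drive = sum(circuit.w[i, j] * x[i] for i in range(n_pn))
            expected = max(drive - circuit.alpha * T
                           - circuit.c_theta * circuit.theta[j], 0.0)
            assert resp.y[0, j] == pytest.approx(expected)
        assert resp.apl[0] == pytest.approx(T)

    def test_no_inhibition_no_threshold(self):
        circuit = _toy_circuit(alpha=0.0, c_theta=0.0)
        x = np.array([1.0, 2.0, 3.0])
        resp = kc_responses(x, circuit)
        np.testing.assert_allclose(resp.y[0], x @ circuit.w)
        assert np.all(resp.y >= 0)

    def test_huge_threshold_silences(self):
        circuit = _toy_circuit(c_theta=1e9)
        resp = kc_responses(np.array([5.0, 5.0, 5.0]), circuit)
        np.testing.assert_array_equal(resp.y, 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kc_responses(np.ones(4), _toy_circuit())

    def test_activity_monotone_in_alpha_and_ctheta(self, rng):
        """Total activity is non-increasing in alpha and C_theta (100 circuits)."""
        for _ in range(100):
            M = int(rng.integers(3, 12))
            n_pn = int(rng.integers(3, 8))
            w = rng.lognormal(0, 0.5, (n_pn, M)) * (rng.random((n_pn, M)) < 0.6)
            theta = rng.lognormal(0, 0.26, M)
            x = rng.gamma(1, 20, n_pn)
            alphas = np.sort(rng.random(3) * 0.1)
            cths = np.sort(rng.random(3) * 30)
            base = dict(M=M, n_pn=n_pn, w=w, claws=None, theta=theta,
                        claw_range=(1, n_pn))
            tot = lambda a, c: kc_responses(
                x, MBCircuit(alpha=a, c_theta=c, **base)).y.sum()
            assert tot(alphas[0], cths[1]) >= tot(alphas[1], cths[1]) >= tot(alphas[2], cths[1])
            assert tot(alphas[1], cths[0]) >= tot(alphas[1], cths[1]) >= tot(alphas[1], cths[2])

    def test_activity_monotone_in_weight_scale(self, rng):
        circuit = _toy_circuit(alpha=0.05, c_theta=1.0)
        x = np.array([2.0, 1.0, 4.0])
        totals = []
        for g in (0.0, 0.5, 1.0, 2.0):
            c = circuit.copy()
            c.w = circuit.w * g
            totals.append(kc_responses(x, c).y.sum())
        assert totals == sorted(totals)
        assert totals[0] == 0.0


class TestCodingLevel:
    def test_edge_cases(self):
        assert coding_level(np.zeros((3, 10))) == 0.0
        assert coding_level(np.ones((3, 10))) == 1.0
        with pytest.raises(ValueError):
            coding_level(np.empty((0, 0)))


class TestEqualisation:
    def test_equalises_mean_activity(self, small_panel):
        claws, w = sample_connectivity(300, 24, seed=8)
        theta = sample_thresholds(300, seed=8)
        x = pn_transfer(small_panel.rates)
        circuit = MBCircuit(M=300, n_pn=24, w=w, claws=claws, theta=theta,
                            alpha=0.0, c_theta=50.0)
        eq = equalise_weights(circuit, x, tol=0.02)
        E = x @ eq.w
        a = np.maximum(E - 50.0 * eq.theta[None, :], 0).mean(axis=0)
        assert np.abs(a / a.mean() - 1).max() <= 0.02 + 1e-9

    def test_fixed_point(self, small_panel):
        claws, w = sample_connectivity(200, 24, seed=9)
        theta = sample_thresholds(200, seed=9)
        x = pn_transfer(small_panel.rates)
        circuit = MBCircuit(M=200, n_pn=24, w=w, claws=claws, theta=theta)
        eq1 = equalise_weights(circuit, x, tol=0.01)
        eq2 = equalise_weights(eq1, x, tol=0.01)
        np.testing.assert_allclose(eq2.w, eq1.w, rtol=0.02)

    def test_zero_drive_kc_reported(self, small_panel):
        claws, w = sample_connectivity(50, 24, seed=10)
        theta = sample_thresholds(50, seed=10)
        w[:, 7] = 0.0   # silence one KC entirely
        x = pn_transfer(small_panel.rates)
        circuit = MBCircuit(M=50, n_pn=24, w=w, claws=claws, theta=theta)
        with pytest.warns(RuntimeWarning, match="zero panel drive"):
            eq = equalise_weights(circuit, x, tol=0.05)
        assert np.all(eq.w[:, 7] == 0)


class TestTuning:
    def test_targets_hit_on_small_instance(self, small_instance):
        inst = small_instance
        resp = kc_responses(inst.pn_inputs.trials, inst.circuit)
        assert coding_level(resp.y) == pytest.approx(0.10, abs=0.005)
        blocked = inst.circuit.copy()
        blocked.alpha = 0.0
        resp_b = kc_responses(inst.pn_inputs.trials, blocked)
        assert coding_level(resp_b.y) == pytest.approx(0.20, abs=0.005)

    def test_inconsistent_targets_rejected(self, small_instance):
        with pytest.raises(ValueError, match="cannot raise activity"):
            tune_parameters(small_instance.circuit,
                            small_instance.pn_inputs.trials,
                            target_full=0.2, target_blocked=0.1)

    def test_unreachable_target_reports_error(self, small_instance):
        # silent inputs cannot reach any positive coding level
        silent = np.zeros_like(small_instance.pn_inputs.trials[:5])
        with pytest.raises(TuningError):
            tune_parameters(small_instance.circuit, silent)

    def test_rng_substreams_independent(self):
        """Same connectivity regardless of the PN-noise stream draw order."""
        a = stream(42, "connectivity").normal(size=5)
        stream(42, "pn_noise").normal(size=100)
        b = stream(42, "connectivity").normal(size=5)
        np.testing.assert_array_equal(a, b)


class TestBuildTunedCircuit:
    def test_reproducible(self, small_panel):
        c1, _ = build_tuned_circuit(small_panel, M=200, seed=3, n_trials=5)
        c2, _ = build_tuned_circuit(small_panel, M=200, seed=3, n_trials=5)
        np.testing.assert_array_equal(c1.w, c2.w)
        assert c1.alpha == c2.alpha and c1.c_theta == c2.c_theta
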