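"""Causality measures: values, curves, matrices, Geweke and DTF variants."""

import numpy as np
import pytest

from megc import (
    BlockPartition,
    VARModel,
    all_pairs,
    band_mean,
    cgcm,
    cgcm_geweke_freq,
    dtf,
    fit_var,
    gcm,
    gcm_geweke_freq,
    random_stable_var,
    var_to_ss,
)
from megc.simkit import (
    NetworkSpec,
    calibrate_coefficient,
    make_topology,
    simulate,
)
from conftest import draw_assumable_model, make_partition


class TestGCM:
    def test_independent_channels_zero(self):
        model = VARModel.from_transition(np.diag([0.5, -0.3]), np.eye(2))
        res = gcm(var_to_ss(model), BlockPartition([0], [1]), 256)
        assert abs(res.time_value) < 1e-10
        assert np.max(np.abs(res.freq_curve)) < 1e-10

    def test_unidirectional_value_and_direction(self, bivar_unidirectional):
        ss = var_to_ss(bivar_unidirectional)
        fwd = gcm(ss, BlockPartition([0], [1]), 512)   # y -> x (real coupling)
        rev = gcm(ss, BlockPartition([1], [0]), 512)   # x -> y (absent)
        assert fwd.time_value > 0.5
        assert abs(rev.time_value) < 1e-9
        # closed form: Sigma_xx via Szego on S_x = 0.81/|1-0.8 e^{-it}|^2 + 1
        theta = np.linspace(0, np.pi, 20001)
        s_x = 0.81 / np.abs(1 - 0.8 * np.exp(-1j * theta)) ** 2 + 1.0
        sigma_xx = np.exp(np.trapezoid(np.log(s_x), theta) / np.pi)
        assert fwd.time_value == pytest.approx(np.log(sigma_xx), abs=1e-6)

    def test_curve_mean_equals_time_value(self, rng):
        model = random_stable_var(3, 2, rng, radius=0.8)
        res = gcm(var_to_ss(model), BlockPartition([0], [1]), 1024)
        assert band_mean(res.grid, res.freq_curve) == pytest.approx(res.time_value, abs=1e-6)


class TestCGCMVariants:
    def test_empty_z_all_variants_equal_gcm(self, rng):
        model = random_stable_var(3, 1, rng, radius=0.7)
        ss = var_to_ss(model)
        part = BlockPartition([0], [1])
        g = gcm(ss, part, 256).time_value
        for variant in ("Std", "SEnt", "JEnt"):
            assert cgcm(ss, part, variant, 256).time_value == pytest.approx(g, abs=1e-9)

    def test_zero_coupling_all_variants_zero(self, rng):
        model = random_stable_var(4, 2, rng, radius=0.7)
        coeffs = model.coeffs.copy()
        coeffs[:, 0, 1] = 0.0
        ss = var_to_ss(VARModel(coeffs, model.noise_cov))
        part = make_partition(4)
        for variant in ("Std", "SEnt", "JEnt"):
            assert abs(cgcm(ss, part, variant, 256).time_value) < 1e-10

    def test_time_frequency_consistency_all_variants(self, rng):
        model = draw_assumable_model(rng, 4, 2, radius=0.8)
        ss = var_to_ss(model)
        part = make_partition(4)
        for variant in ("Std", "SEnt", "JEnt"):
            res = cgcm(ss, part, variant, 1024)
            assert band_mean(res.grid, res.freq_curve) == pytest.approx(
                res.time_value, abs=1e-6
            ), variant


class TestGeweke:
    def test_independent_flat_zero(self):
        model = VARModel.from_transition(np.diag([0.4, 0.6]), np.eye(2))
        res = gcm_geweke_freq(var_to_ss(model), BlockPartition([0], [1]), 128)
        assert np.max(np.abs(res.freq_curve)) < 1e-10

    def test_mean_equals_gcm_and_curve_nonnegative(self, rng):
        for _ in range(5):
            model = random_stable_var(3, 2, rng, radius=0.75)
            ss = var_to_ss(model)
            part = BlockPartition([0], [1])
            g = gcm(ss, part, 1024)
            gw = gcm_geweke_freq(ss, part, 1024)
            assert gw.time_value == pytest.approx(g.time_value, abs=1e-6)
            assert gw.freq_curve.min() >= -1e-9

    def test_ent_and_geweke_curves_differ_for_coupled_models(self):
        """Same full-band mean, different curves: the distinction the
        entropy formulation introduces (visible once the innovations are
        instantaneously correlated)."""
        from megc.simkit import compound_symmetry_cov

        A = np.array([[0.3, 0.9], [0.0, 0.8]])
        ss = var_to_ss(VARModel.from_transition(A, compound_symmetry_cov(2)))
        part = BlockPartition([0], [1])
        g = gcm(ss, part, 512)
        gw = gcm_geweke_freq(ss, part, 512)
        assert gw.time_value == pytest.approx(g.time_value, abs=1e-6)
        assert np.max(np.abs(g.freq_curve - gw.freq_curve)) > 1e-3

    def test_conditional_empty_z_reduces_to_pairwise(self, rng):
        model = random_stable_var(3, 1, rng, radius=0.7)
        ss = var_to_ss(model)
        part = BlockPartition([0], [1])
        a = gcm_geweke_freq(ss, part, 256)
        b = cgcm_geweke_freq(ss, part, 256)
        assert np.allclose(a.freq_curve, b.freq_curve, atol=1e-12)

    def test_conditional_zero_coupling_flat_zero(self, rng):
        model = random_stable_var(4, 1, rng, radius=0.7)
        coeffs = model.coeffs.copy()
        coeffs[:, 0, 1] = 0.0
        ss = var_to_ss(VARModel(coeffs, model.noise_cov))
        res = cgcm_geweke_freq(ss, make_partition(4), 256)
        assert np.max(np.abs(res.freq_curve)) < 1e-8

    def test_conditional_mean_near_std_value(self, rng):
        """The conditional spectral decomposition integrates to the standard
        conditional measure only approximately (the minimum-phase condition
        behind the integral identity is generic, not guaranteed); mild
        models agree to a few percent, and the curve stays nonnegative."""
        rels = []
        for _ in range(5):
            model = draw_assumable_model(rng, 3, 1, radius=0.6)
            ss = var_to_ss(model)
            part = make_partition(3)
            std = cgcm(ss, part, "Std", 1024)
            gw = cgcm_geweke_freq(ss, part, 1024)
            assert gw.freq_curve.min() >= -1e-9
            rels.append(abs(gw.time_value - std.time_value) / max(std.time_value, 1e-6))
        assert max(rels) < 5e-2


class TestDTF:
    def test_single_channel_unity(self):
        model = VARModel.from_transition(np.array([[0.5]]), np.array([[1.0]]))
        _, curves = dtf(var_to_ss(model), 64)
        assert np.allclose(curves, 1.0)

    def test_rows_sum_to_one(self, random_ss):
        _, curves = dtf(random_ss, 128)
        assert np.allclose(curves.sum(axis=2), 1.0, atol=1e-12)
        assert curves.min() >= 0.0 and curves.max() <= 1.0 + 1e-12

    def test_independent_channels_off_diagonal_zero(self):
        model = VARModel.from_transition(np.diag([0.5, -0.3, 0.2]), np.eye(3))
        _, curves = dtf(var_to_ss(model), 64)
        off = curves * (1 - np.eye(3))[None]
        assert np.max(off) < 1e-12

    def test_unnormalized_flag(self, random_ss):
        _, raw = dtf(random_ss, 64, normalized=False)
        _, norm = dtf(random_ss, 64, normalized=True)
        denom = raw.sum(axis=2, keepdims=True)
        assert np.allclose(raw / denom, norm)


class TestAllPairs:
    def test_two_channels_conditional_equals_pairwise(self, rng):
        model = random_stable_var(2, 1, rng, radius=0.6)
        t1, b1 = all_pairs(model, method="cgcm-std", mode="conditional-on-rest", n_grid=128)
        t2, b2 = all_pairs(model, method="cgcm-std", mode="pairwise", n_grid=128)
        assert np.allclose(t1, t2, atol=1e-10)
        assert np.allclose(b1, b2, atol=1e-10)

    def test_diagonal_generator_all_zero(self):
        model = VARModel.from_transition(np.diag([0.5, -0.3, 0.2]), np.eye(3))
        tmat, _ = all_pairs(model, method="cgcm-jent", n_grid=128)
        off = tmat[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-9

    def test_star_network_directional_asymmetry(self):
        """Hub-to-boundary conditional JEnt entries dominate the reverse
        direction on a long draw from the star generator."""
        adj = make_topology("star")
        a, _ = calibrate_coefficient(adj)
        data = simulate(NetworkSpec(adjacency=adj, coefficient=a, T=100_000, seed=13))
        model = fit_var(data, 1)
        tmat, _ = all_pairs(model, method="cgcm-jent", n_grid=128)
        hub_out = tmat[1:, 0]      # row=target (boundary), col=source (hub)
        hub_in = tmat[0, 1:]
        ratio = np.median(hub_out) / max(np.median(hub_in), 1e-300)
        assert np.all(hub_out > 0)
        assert ratio > 5.0

    def test_row_column_convention(self, bivar_unidirectional):
        """Coupling y(ch 1) -> x(ch 0) lands at row 0, column 1."""
        tmat, _ = all_pairs(bivar_unidirectional, method="gcm", n_grid=128)
        assert tmat[0, 1] > 0.5
        assert abs(tmat[1, 0]) < 1e-9
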