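"""Minimum-entropy residual constructions and their identities."""

import numpy as np
import pytest

from megc import (
    BlockPartition,
    VARModel,
    band_mean,
    entropy_rate_time,
    jent_residual,
    me_residual_full,
    me_residual_pairwise,
    psd_from_ss,
    random_stable_var,
    sent_residual,
    subprocess_innovations,
    var_to_ss,
)
from megc.var_ss import MinimumPhaseError
from conftest import draw_assumable_model, make_partition


def _simulate(model, T, seed):
    rng = np.random.default_rng(seed)
    p, n = model.order, model.n_channels
    A = model.ar_coeffs
    chol = np.linalg.cholesky(model.noise_cov)
    u = np.zeros((T + 500, n))
    eps = rng.standard_normal((T + 500, n)) @ chol.T
    for t in range(p, T + 500):
        u[t] = sum(A[k] @ u[t - k - 1] for k in range(p)) + eps[t]
    return u[500:]


class TestPairwiseResidual:
    def test_independent_channels_residual_is_marginal(self):
        model = VARModel.from_transition(np.diag([0.5, -0.4]), np.eye(2))
        ss = var_to_ss(model)
        resid = me_residual_pairwise(ss, BlockPartition([0], [1]))
        S_res = resid.psd(128)
        S_x = psd_from_ss(subprocess_innovations(ss, [0]), 128)
        assert np.max(np.abs(S_res.values - S_x.values)) < 1e-10
        # entropy difference 2(h_x - h_{x||y}) = 0: nothing to regress
        assert entropy_rate_time(resid.driving_cov) == pytest.approx(
            entropy_rate_time(np.array([[1.0]]))
        )

    def test_unidirectional_gcm_against_long_ar_oracle(self, bivar_unidirectional):
        """F_{y->x} = ln(Sigma_xx / Omega_xx): the marginal innovation
        variance Sigma_xx is cross-checked by a long-AR fit of the x channel
        alone on a large simulated draw (brute-force oracle)."""
        from megc import fit_var

        ss = var_to_ss(bivar_unidirectional)
        resid = me_residual_pairwise(ss, BlockPartition([0], [1]))
        assert resid.driving_cov[0, 0] == pytest.approx(1.0, abs=1e-10)
        sigma_xx = subprocess_innovations(ss, [0]).V[0, 0]
        data = _simulate(bivar_unidirectional, 500_000, seed=11)
        long_ar = fit_var(data[:, [0]], 30)
        assert sigma_xx == pytest.approx(long_ar.noise_cov[0, 0], rel=0.02)

    def test_eq14_entropy_difference_identity(self, rng):
        """2(h_x - h_{x||y}) equals ln det Sigma_xx - ln det Omega_xx."""
        for _ in range(5):
            model = random_stable_var(3, 2, rng, radius=0.8)
            ss = var_to_ss(model)
            part = make_partition(3, 1, 2)
            sub = ss
            resid = me_residual_pairwise(sub, BlockPartition([0], [1, 2]))
            h_x = entropy_rate_time(subprocess_innovations(ss, [0]).V)
            # h_{x||y}: residual is minimum phase, so its entropy rate is the
            # closed form from the driving covariance
            h_resid = resid.entropy_rate()
            lhs = 2.0 * (h_x - h_resid)
            rhs = float(
                np.linalg.slogdet(subprocess_innovations(ss, [0]).V)[1]
                - np.linalg.slogdet(resid.driving_cov)[1]
            )
            assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_spectral_mean_equals_gcm(self, rng):
        model = random_stable_var(2, 2, rng, radius=0.75)
        ss = var_to_ss(model)
        resid = me_residual_pairwise(ss, BlockPartition([0], [1]))
        S_x = psd_from_ss(subprocess_innovations(ss, [0]), 1024)
        curve = S_x.log_det() - resid.psd(1024).log_det()
        gcm_time = float(
            np.linalg.slogdet(subprocess_innovations(ss, [0]).V)[1]
            - np.linalg.slogdet(resid.driving_cov)[1]
        )
        assert band_mean(S_x.grid, curve) == pytest.approx(gcm_time, abs=1e-6)


class TestFullResidual:
    def test_psd_is_block_inverse_by_construction(self, rng):
        model = random_stable_var(4, 1, rng, radius=0.7)
        ss = var_to_ss(model)
        part = make_partition(4, 1, 1)
        resid = me_residual_full(ss, part)
        # direct formula: G_xx^{-1} Omega_xx G_xx^{-*} with G the VAR filter
        theta = np.linspace(0, np.pi, 128)
        gxx = 1.0 + model.coeffs[0, 0, 0] * np.exp(-1j * theta)
        S_direct = model.noise_cov[0, 0] / np.abs(gxx) ** 2
        S = resid.psd(128)
        assert np.allclose(S.values[:, 0, 0].real, S_direct, atol=1e-10)
        assert resid.entropy_rate() == pytest.approx(
            entropy_rate_time(model.noise_cov[:1, :1])
        )


class TestJEnt:
    def test_empty_z_reduces_to_pair(self, rng):
        model = random_stable_var(2, 1, rng, radius=0.6)
        ss = var_to_ss(model)
        joint, nested = jent_residual(ss, BlockPartition([0], [1]))
        S_joint = psd_from_ss(joint.ss, 128)
        S_full = psd_from_ss(ss, 128)
        assert np.max(np.abs(S_joint.values - S_full.values)) < 1e-10

    def test_eq24_identity_two_routes(self, rng):
        """PSD of x||yz equals PSD of (x^JEnt||z)||(y^JEnt||z) pointwise."""
        for _ in range(10):
            n_z = int(rng.integers(1, 4))
            model = draw_assumable_model(rng, 2 + n_z, int(rng.integers(1, 3)), radius=0.8)
            ss = var_to_ss(model)
            part = make_partition(2 + n_z)
            r_full = me_residual_full(ss, part)
            _, nested = jent_residual(ss, part)
            d = np.max(np.abs(r_full.psd(256).values - nested.psd(256).values))
            assert d < 1e-8

    def test_zero_coupling_zero_measure(self, rng):
        """G_xy = 0 in the generator forces the JEnt measure to zero."""
        from megc import cgcm

        model = random_stable_var(4, 2, rng, radius=0.7)
        coeffs = model.coeffs.copy()
        coeffs[:, 0, 1] = 0.0
        model0 = VARModel(coeffs, model.noise_cov)
        res = cgcm(var_to_ss(model0), make_partition(4), "JEnt", 512)
        assert abs(res.time_value) < 1e-10


class TestSEnt:
    def test_empty_z_matches_pairwise_gcm(self, rng):
        from megc import cgcm, gcm

        model = random_stable_var(3, 1, rng, radius=0.7)
        ss = var_to_ss(model)
        part = BlockPartition([0], [1])
        g = gcm(ss, part, 512)
        s = cgcm(ss, part, "SEnt", 512)
        assert s.time_value == pytest.approx(g.time_value, abs=1e-9)
        assert np.max(np.abs(s.freq_curve - g.freq_curve)) < 1e-9

    def test_mutually_independent_blocks_zero(self):
        from megc import cgcm

        model = VARModel.from_transition(np.diag([0.5, -0.3, 0.4]), np.diag([1.0, 2.0, 0.5]))
        res = cgcm(var_to_ss(model), make_partition(3), "SEnt", 512)
        assert abs(res.time_value) < 1e-9

    def test_dare_and_wilson_routes_agree(self, rng):
        model = random_stable_var(3, 2, rng, radius=0.75)
        ss = var_to_ss(model)
        part = make_partition(3)
        _, r_dare = sent_residual(ss, part, method="dare")
        _, r_wilson = sent_residual(ss, part, n_grid=1024, method="wilson")
        rel = np.max(np.abs(r_dare.driving_cov - r_wilson.driving_cov)) / np.max(
            np.abs(r_dare.driving_cov)
        )
        assert rel < 1e-6

    def test_variant_ordering_bounds(self, rng):
        from megc import cgcm

        for _ in range(10):
            n_z = int(rng.integers(1, 4))
            model = draw_assumable_model(rng, 2 + n_z, 1, radius=0.8)
            ss = var_to_ss(model)
            part = make_partition(2 + n_z)
            f_std = cgcm(ss, part, "Std", 512).time_value
            f_sent = cgcm(ss, part, "SEnt", 512).time_value
            f_jent = cgcm(ss, part, "JEnt", 512).time_value
            assert f_jent >= f_std - 1e-9
            assert f_std >= f_sent - 1e-9
            assert f_sent >= -1e-9


class TestScaleInvariance:
    def test_static_transform_of_target_leaves_measures_unchanged(self, rng):
        """Replacing x by T x for nonsingular static T cancels in the log-det
        ratios of all three conditional measures."""
        from megc import cgcm

        model = random_stable_var(4, 1, rng, radius=0.7)
        part = BlockPartition([0, 1], [2], [3])
        Tmat = np.array([[2.0, 0.3], [-0.5, 1.5]])
        Tfull = np.eye(4)
        Tfull[:2, :2] = Tmat
        coeffs_t = np.einsum("ij,pjk,kl->pil", Tfull, model.coeffs, np.linalg.inv(Tfull))
        cov_t = Tfull @ model.noise_cov @ Tfull.T
        model_t = VARModel(coeffs_t, cov_t)
        for variant in ("Std", "SEnt", "JEnt"):
            v1 = cgcm(var_to_ss(model), part, variant, 512).time_value
            v2 = cgcm(var_to_ss(model_t), part, variant, 512).time_value
            assert v1 == pytest.approx(v2, abs=1e-8)


def test_minimum_phase_violation_raises():
    coeffs = np.array([[[1.2, -1.3], [1.0, -0.3]]])
    model = VARModel(coeffs, np.eye(2))
    with pytest.raises(MinimumPhaseError):
        me_residual_full(model, BlockPartition([0], [1]))
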