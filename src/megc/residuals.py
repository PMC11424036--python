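"""Minimum-entropy (ME) residual processes.

The ME residual of a target block b inside a jointly modelled process is

    b||rest = G_bb(L)^{-1} eps_b,

where G(L) is the joint model's monic whitening filter and eps_b the b-rows
of its innovations: the target signal minus a *strictly causal* filter of
the predictors' past, chosen to minimize the residual entropy rate.  Because
G_bb(L)^{-1} is monic, stable and (by assumption) minimum phase, the
residual is itself an innovations-form process driven by eps_b, so its
entropy rate is available in closed form from the driving covariance.

Three conditional constructions are provided:

* ``me_residual_full``  — x||yz from the full joint model (no factorization);
* ``jent_residual``     — joint entropy minimization: regress z out of the
  joint pair (x; y) first; purely analytic (a block inverse of the full
  whitening filter), no spectral factorization needed;
* ``sent_residual``     — separate entropy minimization: form x||z and y||z
  separately, realize them as one augmented system driven by the full
  innovations, spectral-factorize that system (DARE, with a grid-based
  Wilson route as cross-check), and regress y||z out of x||z inside it.

All constructions assume the relevant diagonal whitening blocks are stably
invertible; violations raise ``MinimumPhaseError``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lti import LTI, invert_monic, series, spectral_radius, stack_outputs
from .spectral import (
    FactorizationError,
    SpectralMatrix,
    default_grid,
    psd_from_ss,
    subprocess_innovations,
    wilson_factorize,
    DEFAULT_GRID_SIZE,
)
from .var_ss import (
    BlockPartition,
    MinimumPhaseError,
    StateSpaceModel,
    VARModel,
    var_to_ss,
)

__all__ = [
    "ResidualModel",
    "me_residual_pairwise",
    "me_residual_full",
    "jent_residual",
    "sent_residual",
]

#: inverse-filter spectral radius at or above (1 - this) is flagged unstable
INVERSE_STABILITY_TOL = 1e-8


@dataclass
class ResidualModel:
    """An ME residual process as an innovations-form realization.

    The residual equals a monic, stable, minimum-phase filter applied to a
    white driving process with covariance ``driving_cov``, so it is stored
    as a :class:`StateSpaceModel` whose innovations are that driving
    process.  ``label`` records which residual this is (e.g. ``"x||y"``).
    """

    ss: StateSpaceModel
    label: str

    @property
    def driving_cov(self) -> np.ndarray:
        return self.ss.V

    def psd(self, n: int = DEFAULT_GRID_SIZE) -> SpectralMatrix:
        return psd_from_ss(self.ss, n)

    def entropy_rate(self) -> float:
        from .spectral import entropy_rate_time

        return entropy_rate_time(self.ss.V)


def _whitening_block_inverse(
    ss: StateSpaceModel, idx: np.ndarray, label: str
) -> ResidualModel:
    """Residual idx||rest for an innovations model: G_bb(L)^{-1} eps_b.

    The inverse-block realization is closed under the whitening filter's
    state dimension: A_r = (A - KC) + K_b C_b, gain K_b, output C_b.
    """
    idx = np.atleast_1d(np.asarray(idx, dtype=int))
    A, C, K, V = ss.A, ss.C, ss.K, ss.V
    Kb = K[:, idx]
    Cb = C[idx, :]
    Ar = (A - K @ C) + Kb @ Cb
    rad = spectral_radius(Ar)
    if rad >= 1.0 - INVERSE_STABILITY_TOL:
        raise MinimumPhaseError(
            f"diagonal whitening block for channels {idx.tolist()} is not "
            f"stably invertible (inverse radius {rad:.6f}); the minimum-"
            "phase assumption fails for this model"
        )
    names = [ss.channel_names[i] for i in idx]
    sub_v = V[np.ix_(idx, idx)]
    return ResidualModel(StateSpaceModel(Ar, Cb, Kb, sub_v, names), label)


def _as_ss(model: VARModel | StateSpaceModel) -> StateSpaceModel:
    return var_to_ss(model) if isinstance(model, VARModel) else model


def me_residual_pairwise(ss_joint: StateSpaceModel, part: BlockPartition) -> ResidualModel:
    """ME residual x||y inside a joint innovations model of (x; y).

    ``part`` indexes channels of ``ss_joint`` itself (z must be empty);
    the driving covariance is the x-block of the joint innovation
    covariance, and the residual PSD is G_xx^{-1} V_xx G_xx^{-*}.
    """
    if part.z.size:
        raise ValueError("pairwise residual takes a partition with empty z")
    part.validate(ss_joint.n_channels)
    return _whitening_block_inverse(ss_joint, part.x, "x||y")


def me_residual_full(
    model: VARModel | StateSpaceModel, part: BlockPartition
) -> ResidualModel:
    """ME residual x||yz from the full joint model of (x; y; z)."""
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    return _whitening_block_inverse(ss, part.x, "x||yz")


def jent_residual(
    model: VARModel | StateSpaceModel, part: BlockPartition
) -> tuple[ResidualModel, ResidualModel]:
    """Joint-entropy-minimization residual (x; y)^JEnt || z.

    Regressing the past of z out of the joint pair (x; y) amounts to
    inverting the [xy, xy] diagonal block of the full whitening filter —
    an analytic construction with no spectral factorization.  Returns the
    joint residual and the nested pairwise residual obtained by regressing
    y^JEnt||z out of x^JEnt||z, which equals x||yz identically (the
    equality is exercised by the test suite, not assumed).
    """
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    if part.z.size == 0:
        # degenerate conditioning: the "joint residual" is (x; y) itself
        xy = np.concatenate([part.x, part.y])
        if xy.size == ss.n_channels and np.array_equal(xy, np.arange(ss.n_channels)):
            joint_ss = ss
        else:
            joint_ss = subprocess_innovations(ss, xy)
        joint = ResidualModel(joint_ss, "(x;y)||[] JEnt")
    else:
        xy = np.concatenate([part.x, part.y])
        joint = _whitening_block_inverse(ss, xy, "(x;y)||z JEnt")
    inner = BlockPartition(np.arange(part.x.size), part.x.size + np.arange(part.y.size))
    nested = me_residual_pairwise(joint.ss, inner)
    nested.label = "(x JEnt||z)||(y JEnt||z)"
    return joint, nested


def _residual_generator(full: LTI, sub: StateSpaceModel, sub_idx, target_rows) -> LTI:
    """LTI mapping the full innovations e_t to target||z for one branch.

    Cascade: full model (e -> u), select the sub-process channels, the
    sub-model's whitening filter (u_sub -> eps_hat), select the target
    rows, and the inverse diagonal block G_bb(L)^{-1} (eps_hat_b -> b||z).
    """
    sub_idx = np.atleast_1d(np.asarray(sub_idx, dtype=int))
    target_rows = np.atleast_1d(np.asarray(target_rows, dtype=int))
    pick_sub = full.select_outputs(sub_idx)
    whiten = invert_monic(sub.innovations_to_output())
    to_innov = series(pick_sub, whiten)
    resid = _whitening_block_inverse(sub, target_rows, "branch")
    inv_filter = LTI(
        resid.ss.A,
        resid.ss.K,
        resid.ss.C,
        np.eye(target_rows.size),
    )
    return series(to_innov.select_outputs(target_rows), inv_filter)


def sent_residual(
    model: VARModel | StateSpaceModel,
    part: BlockPartition,
    n_grid: int = DEFAULT_GRID_SIZE,
    method: str = "dare",
) -> tuple[ResidualModel, ResidualModel]:
    """Separate-entropy-minimization residual x^SEnt||yz = (x||z)||(y||z).

    Pipeline: (1) factorize the sub-processes (x; z) and (y; z); (2) form
    x||z and y||z by block-inverse whitening inside each; (3) realize the
    pair (x||z; y||z) as one augmented state-space system driven by the
    full innovations e_t (with a direct feedthrough of e_t); (4) obtain the
    innovations model of that joint residual process by spectral
    factorization — a DARE with correlated state/observation noise by
    default, or Wilson's grid iteration with ``method="wilson"``; (5)
    regress y||z out of x||z inside the factorized model.

    Returns (x||z, x^SEnt||yz) as residual models.
    """
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    if part.z.size == 0:
        # degenerate conditioning: x||z = x||[] needs the marginal model of x;
        # SEnt reduces exactly to the pairwise ME residual x||y.
        xy = np.concatenate([part.x, part.y])
        if xy.size == ss.n_channels and np.array_equal(xy, np.arange(ss.n_channels)):
            sub_xy = ss
        else:
            sub_xy = subprocess_innovations(ss, xy)
        x_marg = subprocess_innovations(ss, part.x)
        inner = BlockPartition(np.arange(part.x.size), part.x.size + np.arange(part.y.size))
        nested = me_residual_pairwise(sub_xy, inner)
        nested.label = "x SEnt||y"
        return ResidualModel(x_marg, "x||[]"), nested

    nx, ny = part.x.size, part.y.size
    xz = np.concatenate([part.x, part.z])
    yz = np.concatenate([part.y, part.z])
    try:
        sub_xz = subprocess_innovations(ss, xz)
        sub_yz = subprocess_innovations(ss, yz)
    except FactorizationError as exc:
        raise FactorizationError(f"SEnt stage 1 (sub-process models): {exc}") from exc

    full_filter = ss.innovations_to_output()
    branch_x = _residual_generator(full_filter, sub_xz, xz, np.arange(nx))
    branch_y = _residual_generator(full_filter, sub_yz, yz, np.arange(ny))
    aug = stack_outputs(branch_x, branch_y)

    if method == "dare":
        joint_ss = _factorize_lti_dare(aug, ss.V)
    elif method == "wilson":
        joint_ss = _factorize_lti_wilson(aug, ss.V, n_grid)
    else:
        raise ValueError("method must be 'dare' or 'wilson'")
    joint_ss.channel_names = (
        [f"x{i}||z" for i in range(nx)] + [f"y{i}||z" for i in range(ny)]
    )

    x_given_z = _whitening_block_inverse(sub_xz, np.arange(nx), "x||z")
    inner = BlockPartition(np.arange(nx), nx + np.arange(ny))
    nested = me_residual_pairwise(joint_ss, inner)
    nested.label = "x SEnt||yz"
    return x_given_z, nested


def _factorize_lti_dare(sys: LTI, input_cov: np.ndarray) -> StateSpaceModel:
    """Innovations model of w_t = C s_t + D e_t, s_{t+1} = A s_t + B e_t.

    State noise B e_t and observation noise D e_t are correlated; the
    stabilizing DARE solution gives the steady-state innovations form.
    """
    from scipy.linalg import solve_discrete_are

    from .spectral import _polish_dare

    A, B, C, D = sys.A, sys.B, sys.C, sys.D
    Q = B @ input_cov @ B.T
    R = D @ input_cov @ D.T
    S = B @ input_cov @ D.T
    try:
        P = solve_discrete_are(A.T, C.T, Q, R, s=S)
    except Exception as exc:
        raise FactorizationError(
            f"SEnt stage 4 (augmented DARE, state dim {A.shape[0]}): {exc}"
        ) from exc
    P = _polish_dare(P, A, C, Q, R, S)
    V = C @ P @ C.T + R
    K = np.linalg.solve(V.T, (A @ P @ C.T + S).T).T
    try:
        return StateSpaceModel(A, C, K, 0.5 * (V + V.T))
    except Exception as exc:
        raise FactorizationError(f"SEnt stage 4 produced invalid model: {exc}") from exc


def _factorize_lti_wilson(sys: LTI, input_cov: np.ndarray, n_grid: int) -> StateSpaceModel:
    """Grid route for the augmented factorization: evaluate the output PSD,
    run Wilson's iteration, and re-realize the whitening filter by fitting
    a state-space model to the causal factor's impulse response.

    Used as an independent cross-check of the DARE route; the DARE route is
    the default because it is exact up to Riccati accuracy.
    """
    theta = default_grid(n_grid)
    T = sys.freq_response(theta)
    S = np.einsum("nij,jk,nlk->nil", T, input_cov, T.conj())
    spec = SpectralMatrix(theta, S)
    psi, V = wilson_factorize(spec)
    # impulse response of the monic factor H = psi psi0^{-1}
    psi0 = np.fft.ifft(
        np.concatenate([psi, psi[-2:0:-1].conj()], axis=0), axis=0
    )[0].real
    Hgrid = psi @ np.linalg.inv(psi0)
    coeffs = np.fft.ifft(
        np.concatenate([Hgrid, Hgrid[-2:0:-1].conj()], axis=0), axis=0
    ).real
    n = V.shape[0]
    # truncated MA realization of H(L) = I + sum_k h_k L^k in companion form
    n_lags = min(coeffs.shape[0] // 2, 256)
    h = coeffs[1 : n_lags + 1]
    m = n_lags * n
    A = np.zeros((m, m))
    if n_lags > 1:
        A[n:, : m - n] = np.eye(m - n)
    K = np.zeros((m, n))
    K[:n] = np.eye(n)
    C = np.hstack([h[k] for k in range(n_lags)])
    return StateSpaceModel(A, C, K, V)
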