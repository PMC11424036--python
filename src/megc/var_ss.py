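"""Vector-autoregressive modelling and innovations-form state-space realizations.

A joint stationary Gaussian process u_t is modelled by a monic VAR filter

    G(L) u_t = eps_t,      G(L) = I + G_1 L + ... + G_p L^p,

with innovation covariance Omega = E[eps eps'].  In the usual transition
convention u_t = A_1 u_{t-1} + ... + A_p u_{t-p} + eps_t the coefficient
matrices are A_k = -G_k.  Estimation is per-equation ordinary least squares
on demeaned data; order selection uses Gaussian AIC/BIC on a common sample.

The companion-form innovations realization

    s_{t+1} = A_ss s_t + K_ss e_t,     u_t = C_ss s_t + e_t,

with state s_t = (u_{t-1}; ...; u_{t-p}) underpins all sub-process algebra:
its whitening filter G(L) = I - C L (I - (A-KC) L)^{-1} K reproduces the VAR
filter exactly, and sub-process innovations models are obtained from it by a
Riccati (DARE) step in the spectral module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._lti import LTI, invert_monic, spectral_radius

__all__ = [
    "VARModel",
    "StateSpaceModel",
    "BlockPartition",
    "AssumptionReport",
    "fit_var",
    "select_order",
    "var_to_ss",
    "check_assumptions",
]

#: spectral radius at or above (1 - this) counts as non-stationary
STATIONARITY_TOL = 1e-6


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when the VAR regressor Gram matrix is numerically singular."""


class MinimumPhaseError(np.linalg.LinAlgError):
    """A required whitening-block inverse is not stable (assumption violated)."""


@dataclass
class VARModel:
    """Monic VAR(p) model G(L) u_t = eps_t.

    Parameters
    ----------
    coeffs
        Array of shape (p, n, n) holding G_1 ... G_p (lag-operator
        convention; the implied transition matrices are ``-coeffs``).
    noise_cov
        Innovation covariance Omega, symmetric positive definite, (n, n).
    channel_names
        Optional channel labels; defaults to ``c0 ... c{n-1}``.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    stable: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        p, n, n2 = self.coeffs.shape
        if n != n2 or self.noise_cov.shape != (n, n):
            raise ValueError("inconsistent coefficient / covariance shapes")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise covariance must be positive definite")
        if not self.channel_names:
            self.channel_names = [f"c{i}" for i in range(n)]
        rad = spectral_radius(self.companion())
        self.stable = rad < 1.0 - STATIONARITY_TOL
        if not self.stable:
            warnings.warn(
                f"VAR companion spectral radius {rad:.6f} >= 1 - {STATIONARITY_TOL}: "
                "fitted model is (near-)nonstationary",
                stacklevel=2,
            )

    @classmethod
    def from_transition(
        cls, transition: np.ndarray, noise_cov: np.ndarray, channel_names=None
    ) -> "VARModel":
        """Build a VAR(1) model from u_t = A u_{t-1} + eps_t."""
        A = np.asarray(transition, dtype=float)
        return cls(-A[None, :, :], noise_cov, list(channel_names or []))

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def ar_coeffs(self) -> np.ndarray:
        """Transition-convention coefficients A_k = -G_k, shape (p, n, n)."""
        return -self.coeffs

    def companion(self) -> np.ndarray:
        p, n, _ = self.coeffs.shape
        top = np.hstack([-self.coeffs[k] for k in range(p)])
        comp = np.zeros((p * n, p * n))
        comp[:n, :] = top
        if p > 1:
            comp[n:, : (p - 1) * n] = np.eye((p - 1) * n)
        return comp


@dataclass
class StateSpaceModel:
    """Innovations-form realization (A, C, K, V).

    s_{t+1} = A s_t + K e_t,  u_t = C s_t + e_t, with white innovations e_t,
    cov(e) = V.  Stability (rho(A) < 1) and minimum phase (rho(A - KC) < 1)
    are checked at construction; the latter is the requirement that the
    whitening filter be stably invertible.
    """

    A: np.ndarray
    C: np.ndarray
    K: np.ndarray
    V: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        m = self.A.shape[0]
        n = self.C.shape[0]
        if self.A.shape != (m, m) or self.C.shape != (n, m):
            raise ValueError("inconsistent state-space shapes")
        if self.K.shape != (m, n) or self.V.shape != (n, n):
            raise ValueError("inconsistent state-space shapes")
        if not self.channel_names:
            self.channel_names = [f"c{i}" for i in range(n)]
        rad_A = spectral_radius(self.A)
        if rad_A >= 1.0:
            raise ValueError(f"state transition unstable (radius {rad_A:.6f})")
        rad_W = spectral_radius(self.A - self.K @ self.C)
        if rad_W >= 1.0:
            raise MinimumPhaseError(
                f"whitening filter unstable (radius {rad_W:.6f}); "
                "model is not minimum phase"
            )

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]

    def innovations_to_output(self) -> LTI:
        """Moving-average filter H(L): e_t -> u_t (monic)."""
        n = self.n_channels
        return LTI(self.A, self.K, self.C, np.eye(n))

    def whitening_filter(self) -> LTI:
        """Whitening filter G(L) = H(L)^{-1}: u_t -> e_t (monic, stable)."""
        return invert_monic(self.innovations_to_output())

    def transfer(self, theta: np.ndarray) -> np.ndarray:
        """H(e^{i theta}) = I + C (zI - A)^{-1} K, shape (N, n, n)."""
        return self.innovations_to_output().freq_response(theta)

    def whitening_transfer(self, theta: np.ndarray) -> np.ndarray:
        """G(e^{i theta}) = H(e^{i theta})^{-1} evaluated from its own stable
        realization (never by pointwise matrix inversion)."""
        return self.whitening_filter().freq_response(theta)


@dataclass
class BlockPartition:
    """Disjoint (target x; source y; conditioning z) channel index sets."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __init__(self, x, y, z=()):
        self.x = np.atleast_1d(np.asarray(x, dtype=int))
        self.y = np.atleast_1d(np.asarray(y, dtype=int))
        self.z = np.asarray(z, dtype=int).ravel()
        if self.x.size == 0 or self.y.size == 0:
            raise ValueError("x and y index sets must be nonempty")
        combined = np.concatenate([self.x, self.y, self.z])
        if len(np.unique(combined)) != len(combined):
            raise ValueError("x, y, z index sets must be pairwise disjoint")
        if np.any(combined < 0):
            raise ValueError("negative channel index")

    def validate(self, n_channels: int) -> None:
        combined = np.concatenate([self.x, self.y, self.z])
        if np.any(combined >= n_channels):
            raise ValueError(
                f"partition indexes channel {combined.max()} but the model "
                f"has only {n_channels} channels"
            )


def _design_matrix(data: np.ndarray, p: int, t0: int) -> tuple[np.ndarray, np.ndarray]:
    """Response rows t0.. and stacked lag-1..p regressors."""
    T = data.shape[0]
    Y = data[t0:]
    X = np.hstack([data[t0 - k : T - k] for k in range(1, p + 1)])
    return Y, X


def fit_var(
    data: np.ndarray,
    p: int,
    channel_names=None,
    ridge: float = 0.0,
) -> VARModel:
    """Least-squares VAR(p) fit on per-channel demeaned data.

    The innovation covariance is the empirical covariance of the one-step
    residuals (normalized by the effective sample size T - p, consistent
    with the Gaussian likelihood used for order selection).  An optional
    ridge penalty is available but off by default.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a (time, channels) matrix")
    if np.any(~np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    T, n = data.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if T < p * n + n + 1:
        raise ValueError(f"need at least {p * n + n + 1} time points for p={p}, n={n}")
    data = data - data.mean(axis=0)
    Y, X = _design_matrix(data, p, p)
    gram = X.T @ X
    if ridge > 0.0:
        gram = gram + ridge * np.eye(gram.shape[0])
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankDeficiencyError(
            f"regressor Gram matrix is rank deficient (cond={cond:.3e})"
        )
    B = np.linalg.solve(gram, X.T @ Y)  # (p*n, n)
    resid = Y - X @ B
    omega = resid.T @ resid / resid.shape[0]
    coeffs = np.stack([-B[k * n : (k + 1) * n, :].T for k in range(p)])
    with warnings.catch_warnings():
        # stationarity warning is surfaced via model.stable, not repeated here
        warnings.simplefilter("ignore")
        model = VARModel(coeffs, omega, list(channel_names or []))
    if not model.stable:
        warnings.warn("fitted VAR is (near-)nonstationary", stacklevel=2)
    return model


def _gaussian_loglik(omega: np.ndarray, t_eff: int) -> float:
    n = omega.shape[0]
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance not positive definite")
    return -0.5 * t_eff * (logdet + n * (1.0 + np.log(2.0 * np.pi)))


def select_order(data: np.ndarray, p_max: int, criterion: str = "BIC") -> int:
    """Order p in 1..p_max minimizing Gaussian AIC or BIC.

    All candidate orders are fit on the same effective sample (the first
    p_max rows are used only as regressors) so the criteria are comparable.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if T - p_max <= p_max * n + n:
        raise ValueError(f"sample of length {T} too short for p_max={p_max}")
    data = data - data.mean(axis=0)
    t_eff = T - p_max
    scores = []
    for p in range(1, p_max + 1):
        Y, X = _design_matrix(data, p, p_max)
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
        omega = resid.T @ resid / t_eff
        k = p * n * n + n * (n + 1) / 2.0
        ll = _gaussian_loglik(omega, t_eff)
        penalty = 2.0 * k if criterion == "AIC" else k * np.log(t_eff)
        scores.append(-2.0 * ll + penalty)
    return int(np.argmin(scores)) + 1


def var_to_ss(model: VARModel) -> StateSpaceModel:
    """Companion-form innovations realization of a VAR(p) model.

    State s_t = (u_{t-1}; ...; u_{t-p}); the realization's whitening filter
    is exactly G(L), so applying it to data reproduces the least-squares
    residuals to round-off.
    """
    p, n = model.order, model.n_channels
    A = model.companion()
    K = np.zeros((p * n, n))
    K[:n, :] = np.eye(n)
    C = np.hstack([-model.coeffs[k] for k in range(p)])
    return StateSpaceModel(A, C, K, model.noise_cov, list(model.channel_names))


@dataclass
class AssumptionReport:
    """Diagnostic spectral radii for the stable-invertibility assumptions."""

    radii: dict[str, float]
    flags: list[str]
    tol: float

    @property
    def ok(self) -> bool:
        return not self.flags


def check_assumptions(
    ss: StateSpaceModel, part: BlockPartition | None = None, tol: float = 1e-8
) -> AssumptionReport:
    """Report rho(A), rho(A - KC) and the inverse-stability radius of each
    diagonal whitening block G_bb(L)^{-1} (blocks b in {x, y, z})."""
    radii = {
        "A": spectral_radius(ss.A),
        "A_minus_KC": spectral_radius(ss.A - ss.K @ ss.C),
    }
    blocks: dict[str, np.ndarray] = {}
    if part is not None:
        part.validate(ss.n_channels)
        blocks = {"x": part.x, "y": part.y}
        if part.z.size:
            blocks["z"] = part.z
    whit = ss.whitening_filter()
    for name, idx in blocks.items():
        # G_bb(L)^{-1} realization: closed under the whitening state dimension
        sub = LTI(whit.A, whit.B[:, idx], whit.C[idx, :], np.eye(len(idx)))
        radii[f"Ginv_{name}{name}"] = spectral_radius(invert_monic(sub).A)
    flags = [name for name, r in radii.items() if r >= 1.0 - tol]
    return AssumptionReport(radii=radii, flags=flags, tol=tol)
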