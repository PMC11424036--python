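"""Power spectra, sub-process spectral factorization, and entropy rates.

Spectral convention: the PSD of an innovations model (A, C, K, V) is

    S(theta) = H(e^{i theta}) V H(e^{i theta})^*,   H(z) = I + C (zI - A)^{-1} K,

with no 1/(2*pi) prefactor.  Every causality measure in this package is a
ratio (difference of log-determinants), so the prefactor convention cancels
throughout; it only matters if absolute power levels are read off a curve.

Two independent routes to the innovations model of a sub-process are
provided: the primary state-space route solves a discrete algebraic Riccati
equation (DARE) for the steady-state Kalman filter of the kept channels, and
a grid-based Wilson iteration factorizes the spectral matrix directly.  The
two must agree; the test suite enforces this.

Entropy rates of a stationary Gaussian process (nats per time step):

    h = 1/2 ln det Sigma + n/2 (1 + ln 2 pi)                (innovations form)
      = 1/(4 pi) \\int_{-pi}^{pi} ln det S(theta) dtheta + n/2 (1 + ln 2 pi)

whose equality is the Kolmogorov-Szego theorem; the quadrature on the
uniform grid is trapezoidal, which for these smooth periodic integrands is
spectrally accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_are

from .var_ss import StateSpaceModel

__all__ = [
    "SpectralMatrix",
    "default_grid",
    "psd_from_ss",
    "subprocess_innovations",
    "wilson_factorize",
    "entropy_rate_time",
    "entropy_rate_spectral",
    "band_mean",
    "hz_band_to_theta",
]

#: default number of frequency grid points on [0, pi] inclusive
DEFAULT_GRID_SIZE = 1024

HALF_LOG_2PI_E = 0.5 * (1.0 + np.log(2.0 * np.pi))


class FactorizationError(np.linalg.LinAlgError):
    """Spectral factorization (DARE or Wilson iteration) failed."""


def default_grid(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Uniform angular frequencies on [0, pi], endpoints included."""
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(0.0, np.pi, n)


@dataclass
class SpectralMatrix:
    """Hermitian PSD matrices on a uniform [0, pi] grid.

    values has shape (N, n, n); scalar spectra are stored as (N, 1, 1).
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim == 1:
            self.values = self.values[:, None, None]
        if self.values.shape[0] != self.grid.shape[0]:
            raise ValueError("grid / values length mismatch")
        if abs(self.grid[0]) > 1e-12 or abs(self.grid[-1] - np.pi) > 1e-12:
            raise ValueError("grid must span [0, pi] inclusive")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        scale = max(1.0, float(np.max(np.abs(self.values))))
        herm_err = np.max(np.abs(self.values - self.values.conj().transpose(0, 2, 1)))
        if herm_err > 1e-8 * scale:
            raise ValueError(f"spectral values not Hermitian (rel err {herm_err / scale:.2e})")
        # kill round-off asymmetry once and for all
        self.values = 0.5 * (self.values + self.values.conj().transpose(0, 2, 1))

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def sub_block(self, idx) -> "SpectralMatrix":
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return SpectralMatrix(self.grid, self.values[:, idx[:, None], idx[None, :]])

    def log_det(self) -> np.ndarray:
        """ln det S(theta) on the grid (real-valued)."""
        sign, logdet = np.linalg.slogdet(self.values)
        if np.any(sign.real <= 0):
            k = int(np.argmax(sign.real <= 0))
            raise ValueError(
                f"spectrum not positive definite at theta={self.grid[k]:.6f}"
            )
        return logdet.real


def psd_from_ss(ss: StateSpaceModel, n: int = DEFAULT_GRID_SIZE) -> SpectralMatrix:
    """PSD S(theta) = H V H^* of an innovations model on the default grid."""
    theta = default_grid(n)
    H = ss.transfer(theta)
    S = np.einsum("nij,jk,nlk->nil", H, ss.V, H.conj())
    return SpectralMatrix(theta, S)


def _polish_dare(
    P: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    S: np.ndarray,
    iters: int = 12,
) -> np.ndarray:
    """A few fixed-point Riccati iterations to refine the QZ-based DARE
    solution toward machine precision (linear convergence at the squared
    closed-loop radius, so a dozen steps suffice for stable models)."""
    for _ in range(iters):
        G = A @ P @ C.T + S
        Vs = C @ P @ C.T + R
        Kp = np.linalg.solve(Vs.T, G.T).T
        P = A @ P @ A.T + Q - Kp @ G.T
        P = 0.5 * (P + P.T)
    return P


def subprocess_innovations(
    ss: StateSpaceModel, keep_idx, polish: bool = True
) -> StateSpaceModel:
    """Innovations-form model of the sub-process of the kept channels.

    The kept outputs are viewed as observations of the original state
    recursion with state noise K e_t and correlated observation noise (the
    kept rows of e_t); the stabilizing solution of the filtering DARE yields
    the steady-state innovation covariance and Kalman gain, hence a stable,
    minimum-phase realization whose PSD equals the corresponding sub-block
    of the full PSD.
    """
    keep_idx = np.atleast_1d(np.asarray(keep_idx, dtype=int))
    if keep_idx.size == 0:
        raise ValueError("keep_idx must be nonempty")
    if len(np.unique(keep_idx)) != keep_idx.size:
        raise ValueError("keep_idx contains duplicates")
    if np.any(keep_idx < 0) or np.any(keep_idx >= ss.n_channels):
        raise ValueError("keep_idx out of range")
    A, C, K, V = ss.A, ss.C, ss.K, ss.V
    Cs = C[keep_idx, :]
    Q = K @ V @ K.T
    R = V[np.ix_(keep_idx, keep_idx)]
    S = K @ V[:, keep_idx]
    try:
        # filtering DARE via duality with the control DARE
        P = solve_discrete_are(A.T, Cs.T, Q, R, s=S)
    except Exception as exc:  # pragma: no cover - scipy error paths vary
        raise FactorizationError(
            f"DARE failed for sub-process channels {keep_idx.tolist()}: {exc}"
        ) from exc
    if polish:
        P = _polish_dare(P, A, Cs, Q, R, S)
    Vs = Cs @ P @ Cs.T + R
    Ks = np.linalg.solve(Vs.T, (A @ P @ Cs.T + S).T).T
    names = [ss.channel_names[i] for i in keep_idx]
    try:
        return StateSpaceModel(A, Cs, Ks, 0.5 * (Vs + Vs.T), names)
    except Exception as exc:
        raise FactorizationError(
            f"DARE produced an invalid realization for channels "
            f"{keep_idx.tolist()}: {exc}"
        ) from exc


def _full_circle(S: SpectralMatrix) -> np.ndarray:
    """Extend S from [0, pi] (N points) to the full circle (2N-2 points)."""
    vals = S.values
    mirrored = vals[-2:0:-1].conj()  # S(-theta) = conj(S(theta)), elementwise
    return np.concatenate([vals, mirrored], axis=0)


def _plus_operator(G: np.ndarray) -> np.ndarray:
    """Causal part [G]_+ on the circle grid: half of lag 0 plus positive lags."""
    coeffs = np.fft.ifft(G, axis=0)
    M = G.shape[0]
    half = M // 2
    coeffs[0] *= 0.5
    coeffs[half + 1 :] = 0.0
    coeffs[half] *= 0.5 if M % 2 == 0 else 1.0
    return np.fft.fft(coeffs, axis=0)


def wilson_factorize(
    S: SpectralMatrix,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson's iterative minimum-phase factorization S = Psi Psi^*.

    Returns (psi, V) where psi holds the causal factor on the [0, pi] grid
    (shape (N, n, n)) and V = Psi_0 Psi_0^T is the innovation covariance.
    Newton-type convergence; iteration stops when successive factors differ
    by less than `tol` in max absolute value.
    """
    Sc = _full_circle(S)
    M, n, _ = Sc.shape
    eye = np.eye(n)
    S0 = np.fft.ifft(Sc, axis=0)[0].real  # zero-lag autocovariance
    try:
        psi = np.broadcast_to(np.linalg.cholesky(S0).astype(complex), Sc.shape).copy()
    except np.linalg.LinAlgError as exc:
        raise FactorizationError("spectrum has a non-PD mean") from exc
    last_rel = np.inf
    for _ in range(max_iter):
        # g = psi^{-1} S psi^{-*} + I
        tmp = np.linalg.solve(psi, Sc)
        g = np.linalg.solve(psi, tmp.conj().transpose(0, 2, 1)).conj().transpose(0, 2, 1)
        gplus = _plus_operator(g + eye[None, :, :])
        psi_new = psi @ gplus
        diff = np.max(np.abs(psi_new - psi))
        scale = max(1.0, np.max(np.abs(psi)))
        psi = psi_new
        last_rel = diff / scale
        if last_rel < tol:
            break
    else:
        raise FactorizationError(
            f"Wilson iteration did not converge (last rel step {last_rel:.3e})"
        )
    psi0 = np.fft.ifft(psi, axis=0)[0].real
    V = psi0 @ psi0.T
    return psi[: S.values.shape[0]], 0.5 * (V + V.T)


def entropy_rate_time(sigma: np.ndarray) -> float:
    """h = 1/2 ln det Sigma + n/2 (1 + ln 2 pi), nats per time step."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    n = sigma.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    return 0.5 * logdet + n * HALF_LOG_2PI_E


def entropy_rate_spectral(S: SpectralMatrix) -> float:
    """Entropy rate from the PSD integral (trapezoid over [0, pi], using
    the conjugate symmetry S(-theta) = conj(S(theta)))."""
    ld = S.log_det()
    mean_ld = np.trapezoid(ld, S.grid) / np.pi
    return 0.5 * mean_ld + S.n_channels * HALF_LOG_2PI_E


def band_mean(
    grid: np.ndarray,
    curve: np.ndarray,
    theta_lo: float = 0.0,
    theta_hi: float = np.pi,
) -> float:
    """Trapezoidal mean of a per-frequency curve over [theta_lo, theta_hi].

    Band edges need not coincide with grid points; curve values at the edges
    are linearly interpolated.
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if not (0.0 <= theta_lo < theta_hi <= np.pi + 1e-12):
        raise ValueError("band must satisfy 0 <= lo < hi <= pi")
    if theta_lo < grid[0] - 1e-12 or theta_hi > grid[-1] + 1e-12:
        raise ValueError("band extends outside the frequency grid")
    inside = (grid > theta_lo) & (grid < theta_hi)
    t = np.concatenate([[theta_lo], grid[inside], [theta_hi]])
    v = np.concatenate(
        [[np.interp(theta_lo, grid, curve)], curve[inside], [np.interp(theta_hi, grid, curve)]]
    )
    return float(np.trapezoid(v, t) / (theta_hi - theta_lo))


def hz_band_to_theta(f_lo: float, f_hi: float, tr: float) -> tuple[float, float]:
    """Convert a physical band in Hz to angular frequencies, theta = 2 pi f TR.

    `tr` is the sampling interval in seconds (for fMRI, the repetition time).
    """
    if tr <= 0:
        raise ValueError("sampling interval must be positive")
    lo, hi = 2.0 * np.pi * f_lo * tr, 2.0 * np.pi * f_hi * tr
    if hi > np.pi:
        raise ValueError("band exceeds the Nyquist frequency for this TR")
    return lo, hi
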