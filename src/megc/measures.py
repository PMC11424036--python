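"""Time- and frequency-domain causality measures.

Directions follow a uniform (source -> target | conditioning) signature; in
the block notation of the underlying model the target is x, the source y
and the conditioning set z.  Connectivity matrices use the row = target,
column = source convention.

Measures (values in nats, DTF dimensionless):

* GCM                 F_{y->x}      = ln det Sigma_xx - ln det Omega^xy_xx
* cGCM-Std            F_{y->x|z}    = ln det Omega^xz_xx - ln det Omega_xx
* cGCM-SEnt / JEnt    entropy differences of the separate / joint ME
                      residual constructions (lower / upper companions of
                      the standard measure)
* fGCM-Ent etc.       log-det ratios of the corresponding residual spectra;
                      the mean of each Ent-family curve over [0, pi] equals
                      its time-domain value, and the curves may be negative
                      at high frequencies (reported as computed, not
                      clipped)
* fGCM-Geweke etc.    the classical spectral decompositions, included for
                      comparison: nonnegative curves with the same full-band
                      mean as the Ent measures
* DTF                 row-normalized squared transfer magnitudes

Here Omega^S_xx denotes the x-block innovation covariance of the
sub-process model on channel set S (obtained by spectral factorization) and
Sigma_xx the innovation covariance of x modelled alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import (
    DEFAULT_GRID_SIZE,
    band_mean,
    default_grid,
    psd_from_ss,
    subprocess_innovations,
)
from .residuals import (
    jent_residual,
    me_residual_full,
    me_residual_pairwise,
    sent_residual,
)
from .var_ss import BlockPartition, StateSpaceModel, VARModel, var_to_ss

__all__ = [
    "CausalityResult",
    "gcm",
    "cgcm",
    "gcm_geweke_freq",
    "cgcm_geweke_freq",
    "dtf",
    "all_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class CausalityResult:
    source: list[str]
    target: list[str]
    conditioning: list[str]
    method: str
    time_value: float
    grid: np.ndarray
    freq_curve: np.ndarray
    band_values: dict[str, float] = field(default_factory=dict)

    def band(self, theta_lo: float, theta_hi: float, name: str | None = None) -> float:
        val = band_mean(self.grid, self.freq_curve, theta_lo, theta_hi)
        if name:
            self.band_values[name] = val
        return val


def _as_ss(model: VARModel | StateSpaceModel) -> StateSpaceModel:
    return var_to_ss(model) if isinstance(model, VARModel) else model


def _is_identity_order(idx: np.ndarray, n: int) -> bool:
    return idx.size == n and np.array_equal(idx, np.arange(n))


def _names(ss: StateSpaceModel, idx: np.ndarray) -> list[str]:
    return [ss.channel_names[i] for i in np.atleast_1d(idx)]


def _logdet_curve(S) -> np.ndarray:
    return S.log_det()


def gcm(
    model: VARModel | StateSpaceModel,
    part: BlockPartition,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> CausalityResult:
    """GCM from y to x with the ME frequency curve fGCM-Ent.

    time value  = ln det Sigma_xx - ln det Omega^xy_xx
    freq curve  = ln det S_x(theta) - ln det S_{x||y}(theta)

    Any z channels in the partition are ignored: the pairwise measure is
    computed from the (x; y) sub-process extracted from the full model.
    """
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    xy = np.concatenate([part.x, part.y])
    sub = ss if _is_identity_order(xy, ss.n_channels) else subprocess_innovations(ss, xy)
    x_marg = subprocess_innovations(sub, np.arange(part.x.size))
    inner = BlockPartition(np.arange(part.x.size), part.x.size + np.arange(part.y.size))
    resid = me_residual_pairwise(sub, inner)

    s_x = psd_from_ss(x_marg, n_grid)
    s_resid = resid.psd(n_grid)
    curve = _logdet_curve(s_x) - _logdet_curve(s_resid)
    _, ld_sigma = np.linalg.slogdet(x_marg.V)
    _, ld_omega = np.linalg.slogdet(resid.driving_cov)
    return CausalityResult(
        source=_names(ss, part.y),
        target=_names(ss, part.x),
        conditioning=[],
        method="fGCM-Ent",
        time_value=float(ld_sigma - ld_omega),
        grid=default_grid(n_grid),
        freq_curve=curve,
    )


def cgcm(
    model: VARModel | StateSpaceModel,
    part: BlockPartition,
    variant: str = "Std",
    n_grid: int = DEFAULT_GRID_SIZE,
) -> CausalityResult:
    """Conditional GCM from y to x given z; variant in {Std, SEnt, JEnt}.

    With empty z all three variants coincide with :func:`gcm`.
    """
    variant = variant.capitalize() if variant.lower() != "sent" else "SEnt"
    variant = {"Std": "Std", "Sent": "SEnt", "SEnt": "SEnt", "Jent": "JEnt", "JEnt": "JEnt"}[
        variant
    ]
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    if part.z.size == 0:
        res = gcm(ss, part, n_grid)
        res.method = f"fcGCM-{variant}" if variant != "Std" else "fcGCM-Std-Ent"
        res.conditioning = []
        return res

    theta = default_grid(n_grid)
    nx = part.x.size
    if variant == "Std":
        xz = np.concatenate([part.x, part.z])
        sub_xz = subprocess_innovations(ss, xz)
        inner = BlockPartition(np.arange(nx), nx + np.arange(part.z.size))
        r_xz = me_residual_pairwise(sub_xz, inner)
        r_full = me_residual_full(ss, part)
        curve = _logdet_curve(r_xz.psd(n_grid)) - _logdet_curve(r_full.psd(n_grid))
        _, ld_hat = np.linalg.slogdet(r_xz.driving_cov)
        _, ld_full = np.linalg.slogdet(r_full.driving_cov)
        tv = float(ld_hat - ld_full)
        method = "fcGCM-Std-Ent"
    elif variant == "SEnt":
        r_xz, r_sent = sent_residual(ss, part, n_grid=n_grid)
        curve = _logdet_curve(r_xz.psd(n_grid)) - _logdet_curve(r_sent.psd(n_grid))
        _, ld_hat = np.linalg.slogdet(r_xz.driving_cov)
        _, ld_sent = np.linalg.slogdet(r_sent.driving_cov)
        tv = float(ld_hat - ld_sent)
        method = "fcGCM-SEnt"
    else:  # JEnt
        joint, _ = jent_residual(ss, part)
        s_joint = joint.psd(n_grid).sub_block(np.arange(nx))
        r_full = me_residual_full(ss, part)
        curve = _logdet_curve(s_joint) - _logdet_curve(r_full.psd(n_grid))
        # the time-domain JEnt value is defined as the full-band mean of its
        # frequency curve (the x-marginal of the joint residual is not an
        # innovations process, so its entropy rate comes from quadrature)
        tv = band_mean(theta, curve)
        method = "fcGCM-JEnt"
    return CausalityResult(
        source=_names(ss, part.y),
        target=_names(ss, part.x),
        conditioning=_names(ss, part.z),
        method=method,
        time_value=tv,
        grid=theta,
        freq_curve=curve,
    )


def _partial_cov(V: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cov of V[a] given V[b]: V_aa - V_ab V_bb^{-1} V_ba."""
    Vaa = V[np.ix_(a, a)]
    Vab = V[np.ix_(a, b)]
    Vbb = V[np.ix_(b, b)]
    return Vaa - Vab @ np.linalg.solve(Vbb, Vab.T)


def gcm_geweke_freq(
    model: VARModel | StateSpaceModel,
    part: BlockPartition,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> CausalityResult:
    """Classical Geweke spectral GCM from y to x (nonnegative curve).

    The innovations are decorrelated by the static transform zeroing
    Omega_yx against Omega_xx; the causal contribution of y to S_x(theta)
    is then H_xy Omega_{y|x} H_xy^* and the measure is
    ln det S_x / det(S_x - causal part).  Its full-band mean equals the
    time-domain GCM for minimum-phase models.
    """
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    xy = np.concatenate([part.x, part.y])
    sub = ss if _is_identity_order(xy, ss.n_channels) else subprocess_innovations(ss, xy)
    nx = part.x.size
    xi = np.arange(nx)
    yi = nx + np.arange(part.y.size)
    theta = default_grid(n_grid)
    H = sub.transfer(theta)
    V = sub.V
    if np.linalg.cond(V[np.ix_(xi, xi)]) > 1e12:
        raise np.linalg.LinAlgError("x-block innovation covariance is near singular")
    S_x = np.einsum("nij,jk,nlk->nil", H[:, xi, :], V, H[:, xi, :].conj())
    vy_given_x = _partial_cov(V, yi, xi)
    Hxy = H[:, xi, :][:, :, yi]
    causal = np.einsum("nij,jk,nlk->nil", Hxy, vy_given_x, Hxy.conj())
    intrinsic = S_x - causal
    sign_s, ld_s = np.linalg.slogdet(S_x)
    sign_i, ld_i = np.linalg.slogdet(intrinsic)
    if np.any(sign_i.real <= 0):
        raise np.linalg.LinAlgError("intrinsic spectral part not positive definite")
    curve = (ld_s - ld_i).real
    return CausalityResult(
        source=_names(ss, part.y),
        target=_names(ss, part.x),
        conditioning=[],
        method="fGCM-Geweke",
        time_value=band_mean(theta, curve),
        grid=theta,
        freq_curve=curve,
    )


def cgcm_geweke_freq(
    model: VARModel | StateSpaceModel,
    part: BlockPartition,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> CausalityResult:
    """Conditional Geweke spectral measure (two-model construction).

    Whiten the reduced process (x; z) with its own model's whitening
    filter; in the transformed system the conditional measure y -> x | z
    becomes an unconditional measure onto the flat-spectrum reduced
    innovations, with causal part Q_xy Omega_{y|xz} Q_xy^* where
    Q = blkdiag(G^{xz}, I_y) H.  Nonnegative curve; full-band mean equals
    cGCM-Std up to numerical factorization error.
    """
    ss = _as_ss(model)
    part.validate(ss.n_channels)
    if part.z.size == 0:
        res = gcm_geweke_freq(ss, part, n_grid)
        res.method = "fcGCM-Std-Geweke"
        return res
    nx, ny, nz = part.x.size, part.y.size, part.z.size
    order = np.concatenate([part.x, part.y, part.z])
    theta = default_grid(n_grid)
    H = ss.transfer(theta)[:, order, :][:, :, order]
    V = ss.V[np.ix_(order, order)]
    xi = np.arange(nx)
    yi = nx + np.arange(ny)
    zi = nx + ny + np.arange(nz)
    xz_local = np.concatenate([xi, zi])

    sub_xz = subprocess_innovations(ss, np.concatenate([part.x, part.z]))
    G_red = sub_xz.whitening_transfer(theta)  # (N, nx+nz, nx+nz)
    V_red = sub_xz.V

    # Q = blkdiag-expanded reduced whitening applied to the full transfer
    BB = np.zeros((len(theta), nx + ny + nz, nx + ny + nz), dtype=complex)
    BB[:, xz_local[:, None], xz_local[None, :]] = G_red
    BB[:, yi, yi] = 1.0
    Q = BB @ H

    vy_given_xz = _partial_cov(V, yi, xz_local)
    Qxy = Q[:, xi, :][:, :, yi]
    causal = np.einsum("nij,jk,nlk->nil", Qxy, vy_given_xz, Qxy.conj())
    S_red_xx = np.broadcast_to(V_red[:nx, :nx], (len(theta), nx, nx))
    intrinsic = S_red_xx - causal
    sign_i, ld_i = np.linalg.slogdet(intrinsic)
    if np.any(sign_i.real <= 0):
        raise np.linalg.LinAlgError("intrinsic spectral part not positive definite")
    _, ld_s = np.linalg.slogdet(S_red_xx)
    curve = (ld_s - ld_i).real
    return CausalityResult(
        source=_names(ss, part.y),
        target=_names(ss, part.x),
        conditioning=_names(ss, part.z),
        method="fcGCM-Std-Geweke",
        time_value=band_mean(theta, curve),
        grid=theta,
        freq_curve=curve,
    )


def dtf(
    model: VARModel | StateSpaceModel,
    n_grid: int = DEFAULT_GRID_SIZE,
    normalized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed transfer function curves for all ordered pairs.

    Returns (theta, curves) with curves[k, i, j] the (squared, by default
    row-normalized) DTF from channel j to channel i at theta[k]:

        DTF^2_{ij}(theta) = |H_ij|^2 / sum_m |H_im|^2.

    With ``normalized=False`` the raw |H_ij|^2 is returned.  The
    time-domain DTF is the mean over the entire grid.
    """
    ss = _as_ss(model)
    theta = default_grid(n_grid)
    H = ss.transfer(theta)
    mag2 = np.abs(H) ** 2
    if normalized:
        denom = mag2.sum(axis=2, keepdims=True)
        if np.any(denom <= 0):
            raise np.linalg.LinAlgError("transfer function vanished on a full row")
        mag2 = mag2 / denom
    return theta, mag2


_MEASURE_DISPATCH = {
    "gcm": lambda m, p, n: gcm(m, p, n),
    "cgcm-std": lambda m, p, n: cgcm(m, p, "Std", n),
    "cgcm-sent": lambda m, p, n: cgcm(m, p, "SEnt", n),
    "cgcm-jent": lambda m, p, n: cgcm(m, p, "JEnt", n),
    "gcm-geweke": lambda m, p, n: gcm_geweke_freq(m, p, n),
    "cgcm-geweke": lambda m, p, n: cgcm_geweke_freq(m, p, n),
}


def all_pairs(
    model: VARModel | StateSpaceModel,
    method: str = "cgcm-std",
    mode: str = "conditional-on-rest",
    band: tuple[float, float] | None = None,
    n_grid: int = DEFAULT_GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Connectivity matrices for every ordered channel pair.

    Returns (time_matrix, band_matrix); entry (i, j) is the measure from
    channel j (column, source) to channel i (row, target).  In
    ``conditional-on-rest`` mode each pair is conditioned on all remaining
    channels; in ``pairwise`` mode the conditioning set is empty.  All
    extractions derive from the single fitted model.  Per-pair failures are
    logged and reported as NaN rather than aborting the sweep.
    """
    ss = _as_ss(model)
    n = ss.n_channels
    if method not in _MEASURE_DISPATCH:
        raise ValueError(f"unknown method '{method}'; choose from {sorted(_MEASURE_DISPATCH)}")
    if mode not in ("conditional-on-rest", "pairwise"):
        raise ValueError("mode must be 'conditional-on-rest' or 'pairwise'")
    fn = _MEASURE_DISPATCH[method]
    tmat = np.full((n, n), np.nan)
    bmat = np.full((n, n), np.nan)
    for i in range(n):  # target
        for j in range(n):  # source
            if i == j:
                continue
            rest = (
                np.array([k for k in range(n) if k not in (i, j)], dtype=int)
                if mode == "conditional-on-rest"
                else np.array([], dtype=int)
            )
            part = BlockPartition([i], [j], rest)
            try:
                res = fn(ss, part, n_grid)
            except Exception as exc:
                logger.warning("measure %s failed for pair %d->%d: %s", method, j, i, exc)
                continue
            tmat[i, j] = res.time_value
            bmat[i, j] = res.band(*band) if band else band_mean(res.grid, res.freq_curve)
    np.fill_diagonal(tmat, 0.0)
    np.fill_diagonal(bmat, 0.0)
    return tmat, bmat
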