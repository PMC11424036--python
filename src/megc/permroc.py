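"""Permutation-based significance testing and ROC evaluation.

The null distribution of a causality measure from source channel i is
generated by randomly permuting the time index of channel i only, refitting
the VAR model on the permuted data, and recomputing the measure for every
ordered pair with source i.  Random permutation (not circular shift) is
used; it destroys the permuted channel's autocorrelation along with its
cross-dependence, a deliberate and documented property of this test.

p-values use the add-one convention p = (1 + #{null >= observed}) / (1 + n_perm),
which lies in (0, 1] and is valid at finite permutation counts.

The pair-level accounting convention counts, per trial, one null sample per
permutation round for each unordered channel pair: n_perm * n (n - 1) / 2
(e.g. 1,000 permutations of each of 9 channels -> 36,000).

This module is the clear reference implementation built on the per-model
measures path; the vectorized engine in :mod:`megc.benchmark` reproduces it
at scale and is cross-checked against it in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .measures import _MEASURE_DISPATCH
from .spectral import band_mean
from .var_ss import BlockPartition, fit_var, var_to_ss

__all__ = [
    "PermutationNull",
    "PermutationResult",
    "ROCCurve",
    "permute_source",
    "permutation_null",
    "null_sample_count",
    "roc",
    "tpr_at_fpr",
]

logger = logging.getLogger(__name__)


def permute_source(
    data: np.ndarray, i: int, rng: np.random.Generator
) -> np.ndarray:
    """Copy of `data` with the time index of column i randomly permuted;
    all other columns are untouched."""
    data = np.asarray(data)
    if not (0 <= i < data.shape[1]):
        raise ValueError(f"channel {i} out of range")
    out = data.copy()
    out[:, i] = data[rng.permutation(data.shape[0]), i]
    return out


def null_sample_count(n_channels: int, n_perm: int) -> int:
    """Pair-level null samples per trial: n_perm * n (n-1) / 2."""
    return n_perm * n_channels * (n_channels - 1) // 2


@dataclass
class PermutationNull:
    """Null distribution and p-value for one directed pair."""

    source: int
    target: int
    observed: float
    null: np.ndarray
    n_dropped: int = 0

    @property
    def p_value(self) -> float:
        n_eff = len(self.null)
        return (1 + int(np.sum(self.null >= self.observed))) / (1 + n_eff)


@dataclass
class PermutationResult:
    pairs: dict[tuple[int, int], PermutationNull]  # keyed (source, target)
    n_channels: int
    n_perm: int

    @property
    def null_samples_per_trial(self) -> int:
        return null_sample_count(self.n_channels, self.n_perm)

    def p_matrix(self) -> np.ndarray:
        """(n, n) matrix of p-values, entry (target, source); NaN diagonal."""
        P = np.full((self.n_channels, self.n_channels), np.nan)
        for (src, tgt), pn in self.pairs.items():
            P[tgt, src] = pn.p_value
        return P


def _measure_stat(model_ss, part, method, band, n_grid):
    res = _MEASURE_DISPATCH[method](model_ss, part, n_grid)
    if band is None:
        return res.time_value
    return band_mean(res.grid, res.freq_curve, *band)


def permutation_null(
    data: np.ndarray,
    method: str = "cgcm-std",
    n_perm: int = 1000,
    seed: int = 0,
    order: int = 1,
    band: tuple[float, float] | None = None,
    mode: str = "conditional-on-rest",
    n_grid: int = 256,
) -> PermutationResult:
    """Permutation null distributions for every ordered pair.

    For each source channel i, ``n_perm`` permuted datasets are generated,
    the VAR(order) model is refit on each, and the statistic (time-domain
    value, or the mean of the frequency curve over `band`) is recomputed
    for every pair with source i.  Permutation streams are keyed by
    (seed, channel) so results do not depend on execution order across
    channels.  Draws whose refit or measure fails are dropped with a
    warning and the p-value denominator adjusted.
    """
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in _MEASURE_DISPATCH:
        raise ValueError(f"unknown method '{method}'")

    def stats_for_source(mat: np.ndarray, i: int) -> dict[int, float]:
        model = fit_var(mat, order)
        ss = var_to_ss(model)
        out = {}
        for j in range(n):
            if j == i:
                continue
            rest = (
                np.array([k for k in range(n) if k not in (i, j)], dtype=int)
                if mode == "conditional-on-rest"
                else np.array([], dtype=int)
            )
            out[j] = _measure_stat(ss, BlockPartition([j], [i], rest), method, band, n_grid)
        return out

    pairs: dict[tuple[int, int], PermutationNull] = {}
    for i in range(n):
        observed = stats_for_source(data, i)
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        null: dict[int, list[float]] = {j: [] for j in observed}
        dropped = 0
        for _ in range(n_perm):
            perm_data = permute_source(data, i, rng)
            try:
                st = stats_for_source(perm_data, i)
            except Exception as exc:
                dropped += 1
                logger.warning("dropped permutation draw for channel %d: %s", i, exc)
                continue
            for j, v in st.items():
                null[j].append(v)
        for j, obs in observed.items():
            pairs[(i, j)] = PermutationNull(
                source=i,
                target=j,
                observed=obs,
                null=np.asarray(null[j]),
                n_dropped=dropped,
            )
    return PermutationResult(pairs=pairs, n_channels=n, n_perm=n_perm)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def tpr_at(self, fpr: float) -> float:
        return float(np.interp(fpr, self.fpr, self.tpr))

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc(
    p_values: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> ROCCurve:
    """Pooled ROC of edge detection by p-value thresholding.

    `p_values` has shape (..., n, n) (leading dimensions pool trials),
    entry (target, source); the diagonal and NaN entries are ignored.
    `truth` is the (n, n) binary adjacency (row = target); self-loops are
    not scored.  An edge is declared when p <= threshold; the threshold
    sweep covers the sorted unique p-values plus {0, 1}.
    """
    p_values = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth)
    n = truth.shape[0]
    off = ~np.eye(n, dtype=bool)
    pv = np.reshape(p_values, (-1, n, n))[:, off].ravel()
    tv = np.broadcast_to(truth[off].astype(bool), (np.reshape(p_values, (-1, n, n)).shape[0], off.sum())).ravel()
    keep = np.isfinite(pv)
    pv, tv = pv[keep], tv[keep]
    n_pos = int(tv.sum())
    n_neg = int((~tv).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one edge and one non-edge")
    if thresholds is None:
        thresholds = np.concatenate([[0.0], np.unique(pv), [1.0]])
    thresholds = np.unique(thresholds)
    declared = pv[None, :] <= thresholds[:, None]
    tpr = (declared & tv[None, :]).sum(axis=1) / n_pos
    fpr = (declared & ~tv[None, :]).sum(axis=1) / n_neg
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def tpr_at_fpr(p_values: np.ndarray, truth: np.ndarray, fpr: float = 0.1) -> float:
    """Convenience: pooled TPR at a fixed FPR."""
    return roc(p_values, truth).tpr_at(fpr)
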