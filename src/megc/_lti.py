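"""Internal helpers for discrete-time LTI systems in (A, B, C, D) form.

These are plain containers used to build cascaded filter realizations
(whitening filters, their block inverses, and the augmented systems needed
for the separate-entropy-minimization residual).  They are deliberately
minimal: no balancing, no model reduction — state dimensions simply add up
under composition, which keeps the algebra exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def spectral_radius(M: np.ndarray) -> float:
    if M.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(M))))


@dataclass
class LTI:
    """State-space filter y_t = C s_t + D u_t,  s_{t+1} = A s_t + B u_t."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.D.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.D.shape[0]

    def freq_response(self, theta: np.ndarray) -> np.ndarray:
        """Transfer function D + C (zI - A)^{-1} B at z = exp(i*theta).

        Returns array of shape (len(theta), n_outputs, n_inputs).  Uses an
        eigendecomposition of A so the cost per frequency is a pair of small
        matrix products.
        """
        theta = np.asarray(theta, dtype=float)
        z = np.exp(1j * theta)
        if self.n_states == 0:
            return np.broadcast_to(self.D, (len(theta),) + self.D.shape).copy()
        m = self.n_states
        # batched direct solve; robust for defective A (companion forms are)
        zI_A = z[:, None, None] * np.eye(m)[None, :, :] - self.A[None, :, :]
        resolvent_B = np.linalg.solve(zI_A, np.broadcast_to(self.B, (len(z), m, self.n_inputs)))
        H = self.C[None, :, :] @ resolvent_B
        return self.D[None, :, :] + H

    def select_outputs(self, idx: np.ndarray) -> "LTI":
        return LTI(self.A, self.B, self.C[idx, :], self.D[idx, :])


def series(first: LTI, second: LTI) -> LTI:
    """Cascade: input -> `first` -> `second` -> output."""
    n1, n2 = first.n_states, second.n_states
    A = np.block(
        [
            [first.A, np.zeros((n1, n2))],
            [second.B @ first.C, second.A],
        ]
    )
    B = np.vstack([first.B, second.B @ first.D])
    C = np.hstack([second.D @ first.C, second.C])
    D = second.D @ first.D
    return LTI(A, B, C, D)


def stack_outputs(top: LTI, bottom: LTI) -> LTI:
    """Two systems sharing the same input; outputs stacked vertically."""
    n1, n2 = top.n_states, bottom.n_states
    A = np.block(
        [
            [top.A, np.zeros((n1, n2))],
            [np.zeros((n2, n1)), bottom.A],
        ]
    )
    B = np.vstack([top.B, bottom.B])
    C = np.block(
        [
            [top.C, np.zeros((top.n_outputs, n2))],
            [np.zeros((bottom.n_outputs, n1)), bottom.C],
        ]
    )
    D = np.vstack([top.D, bottom.D])
    return LTI(A, B, C, D)


def invert_monic(sys: LTI) -> LTI:
    """Inverse of a square filter with D = I (monic at lag zero)."""
    n_out = sys.n_outputs
    if sys.n_inputs != n_out:
        raise ValueError("only square filters can be inverted")
    if not np.allclose(sys.D, np.eye(n_out), atol=1e-12):
        raise ValueError("invert_monic requires an identity feedthrough")
    return LTI(sys.A - sys.B @ sys.C, sys.B, -sys.C, np.eye(n_out))
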