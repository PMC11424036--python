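"""Benchmark network simulator.

Generates 9-node VAR(1) systems u_{t+1} = A u_t + eps_t over three directed
topologies (a shipped demo network, a ring, and a star), with the common
coupling coefficient a calibrated so that the spectral radius of A is
exactly 0.85, and innovations drawn from a compound-symmetry covariance
(2 on the diagonal, 1 off it).  Positive a makes the channel dynamics
low-pass; the ``sign="-"`` option flips every coefficient for the high-pass
variant.  Series lengths default to 120 samples (60 for the star network),
deliberately short of what the asymptotics would like — the benchmark is
about detecting edges from small samples.

Also hosts ``random_stable_var``, the random stable model generator used
throughout the property tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .var_ss import VARModel

__all__ = [
    "NetworkSpec",
    "make_topology",
    "calibrate_coefficient",
    "compound_symmetry_cov",
    "simulate",
    "random_stable_var",
    "DEMO9_ADJACENCY",
]

TARGET_RADIUS = 0.85

# Synthetic 9-node demo adjacency (entry (i, j) = 1 means edge j -> i; all
# self-loops present).  This network imitates the flavour of the small VAR
# demo shipped with the MVGC MATLAB toolbox -- a sparse mix of chains and
# fan-outs -- but its exact edge set is this package's own construction and
# carries no authority; benchmark claims are anchored to the ring and star
# topologies, whose definitions are unambiguous.
DEMO9_ADJACENCY = np.array(
    [
        [1, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 1, 1, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 1, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 0, 0, 0, 0],
        [0, 0, 1, 0, 1, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 1, 0, 0],
        [0, 0, 0, 0, 1, 0, 1, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 1, 1],
    ],
    dtype=int,
)


@dataclass
class NetworkSpec:
    """Fully specified simulation: topology, coupling, length, seed."""

    adjacency: np.ndarray
    coefficient: float
    T: int
    seed: int
    target_radius: float = TARGET_RADIUS
    sign: str = "+"
    noise_cov: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency) != 1):
            raise ValueError("every node needs a self-loop (diagonal must be 1)")
        if not (0 < self.target_radius < 1):
            raise ValueError("target radius must lie in (0, 1)")
        if self.T < 10:
            raise ValueError("series length must be at least 10")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def transition(self) -> np.ndarray:
        return self.coefficient * self.adjacency


def make_topology(kind: str, n: int = 9) -> np.ndarray:
    """Adjacency for one of the benchmark topologies.

    ``circular``: node i receives from node i-1 (mod n) plus its self-loop;
    ``star``: node 0 is the hub feeding every boundary node; ``demo``
    (alias ``mvgc-demo``): the fixed shipped 9-node network.
    """
    if kind in ("demo", "mvgc-demo"):
        if n != 9:
            raise ValueError("the demo topology is defined for exactly 9 nodes")
        return DEMO9_ADJACENCY.copy()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    adj = np.eye(n, dtype=int)
    if kind == "circular":
        for i in range(n):
            adj[i, (i - 1) % n] = 1
    elif kind == "star":
        adj[1:, 0] = 1
    else:
        raise ValueError(f"unknown topology '{kind}'")
    return adj


def calibrate_coefficient(
    adjacency: np.ndarray,
    target_radius: float = TARGET_RADIUS,
    sign: str = "+",
) -> tuple[float, np.ndarray]:
    """Common coefficient a with spectral_radius(a * adjacency) == target.

    The radius is homogeneous of degree one in |a|, so the solution is
    closed-form: |a| = target / radius(adjacency).
    """
    adjacency = np.asarray(adjacency, dtype=float)
    base = float(np.max(np.abs(np.linalg.eigvals(adjacency))))
    if base <= 0:
        raise ValueError("adjacency is nilpotent; no coefficient can reach the target radius")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    a = target_radius / base
    if sign == "-":
        a = -a
    return a, a * adjacency


def compound_symmetry_cov(n: int) -> np.ndarray:
    """Innovation covariance with 2 on the diagonal and 1 elsewhere.

    Eigenvalues are 1 (multiplicity n-1) and n+1, so the matrix is positive
    definite for every n >= 1.
    """
    if n < 1:
        raise ValueError("dimension must be positive")
    return np.ones((n, n)) + np.eye(n)


def _burn_in(n: int, radius: float) -> int:
    return int(np.ceil(10.0 * n / max(1e-3, 1.0 - radius)))


def simulate(spec: NetworkSpec) -> np.ndarray:
    """Simulate the VAR(1) system; returns a (T, n) matrix.

    Innovations are Gaussian with the compound-symmetry covariance unless
    ``spec.noise_cov`` overrides it.  A burn-in of 10 n / (1 - radius)
    steps is discarded so the retained sample is effectively stationary.
    Fixed seeds give bitwise-identical output.
    """
    n = spec.n_nodes
    A = spec.transition
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius >= 1.0:
        raise ValueError(f"transition matrix unstable (radius {radius:.4f})")
    cov = spec.noise_cov if spec.noise_cov is not None else compound_symmetry_cov(n)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(spec.seed)
    burn = _burn_in(n, radius)
    eps = rng.standard_normal((burn + spec.T, n)) @ chol.T
    u = np.zeros((burn + spec.T, n))
    for t in range(1, burn + spec.T):
        u[t] = A @ u[t - 1] + eps[t - 1]
    return u[burn:]


def benchmark_model(kind: str, sign: str = "+") -> VARModel:
    """The exact generating VAR(1) model for a benchmark topology."""
    adj = make_topology(kind)
    _, A = calibrate_coefficient(adj, sign=sign)
    return VARModel.from_transition(A, compound_symmetry_cov(adj.shape[0]))


def random_stable_var(
    n: int,
    p: int,
    rng: np.random.Generator,
    radius: float = 0.8,
    noise_scale: float = 1.0,
) -> VARModel:
    """Random stable VAR(p) with companion spectral radius == `radius`
    and a well-conditioned random SPD innovation covariance."""
    coeffs = rng.normal(size=(p, n, n)) / np.sqrt(n * p)
    # scale the whole coefficient stack via the companion radius; the radius
    # of the companion is not homogeneous in the stack, so bisect
    def comp_radius(scale: float) -> float:
        top = np.hstack([scale * coeffs[k] for k in range(p)])
        comp = np.zeros((p * n, p * n))
        comp[:n, :] = top
        if p > 1:
            comp[n:, : (p - 1) * n] = np.eye((p - 1) * n)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    base = comp_radius(1.0)
    if base < 1e-12:
        coeffs[0] += np.eye(n) * 0.1
        base = comp_radius(1.0)
    lo, hi = 0.0, 1.0
    while comp_radius(hi) < radius:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if comp_radius(mid) < radius:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    W = rng.normal(size=(n, n + 2))
    cov = noise_scale * (W @ W.T / (n + 2) + 0.5 * np.eye(n))
    return VARModel(-scale * coeffs, cov)
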