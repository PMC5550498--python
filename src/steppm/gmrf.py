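"""Intrinsic Gaussian Markov random field structures: ICAR, RW2, iid.

These improper Gaussian priors are specified through a symmetric positive
semi-definite structure matrix Q with a known null space (constants per
connected component for the ICAR; constants and linear trends for the
second-order random walk).  Identification is restored with sum-to-zero
constraints, and the structures are "scaled" so that the geometric mean
of the constrained marginal variances equals one — making a single
precision hyperprior comparable across fields of different size and
topology.  Everything is computed by dense eigendecomposition, which is
exact and fast at the sizes areal models use (hundreds of nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .weights import SpatialWeights

__all__ = [
    "GMRFStructure",
    "icar_structure",
    "rw2_structure",
    "iid_structure",
    "scale_structure",
    "sample_constrained",
]

_NULL_TOL = 1e-9


@dataclass(frozen=True)
class GMRFStructure:
    """A (possibly rank-deficient) Gaussian field structure.

    The prior density is proportional to
    ``tau^((m-d)/2) * exp(-tau/2 * x' Q x)`` subject to ``A x = 0``,
    where ``d`` is the rank deficiency and the rows of ``A`` are the
    identifying linear constraints.  ``scale_factor`` records the factor
    already multiplied into Q by :func:`scale_structure`.
    """

    Q: np.ndarray
    rank_deficiency: int
    constraints: np.ndarray
    kind: str                         # "icar" | "rw2" | "iid"
    scale_factor: float = 1.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        A = np.asarray(self.constraints, dtype=float).reshape(-1, Q.shape[0])
        object.__setattr__(self, "constraints", A)
        if Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if Q.shape[0] == 0:
            raise ValueError("empty structure (m = 0)")
        if not np.allclose(Q, Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def m(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.m - self.rank_deficiency

    def quad_form(self, x) -> float:
        """x' Q x, the quantity entering the conjugate precision update."""
        x = np.asarray(x, dtype=float)
        return float(x @ (self.Q @ x))

    def _eig(self):
        """Cached eigendecomposition split into null / positive parts."""
        if "eig" not in self._cache:
            lam, V = np.linalg.eigh(self.Q)
            tol = _NULL_TOL * max(lam.max(), 1.0)
            pos = lam > tol
            if int((~pos).sum()) != self.rank_deficiency:
                raise ValueError(
                    f"declared rank deficiency {self.rank_deficiency} but Q has "
                    f"{int((~pos).sum())} (near-)zero eigenvalues")
            self._cache["eig"] = (lam, V, pos)
        return self._cache["eig"]

    def marginal_variances(self, tau: float = 1.0) -> np.ndarray:
        """Diagonal of the constrained generalized inverse of tau*Q.

        Computed on the eigenbasis orthogonal to the null space, i.e. the
        marginal variances under the identifying constraints.  Degenerate
        nodes (islands under the ICAR) have variance exactly zero.
        """
        lam, V, pos = self._eig()
        return (V[:, pos] ** 2 / lam[pos]).sum(axis=1) / tau


def icar_structure(w: SpatialWeights) -> GMRFStructure:
    """Intrinsic CAR structure Q = D - A from a binary neighbour graph.

    Rank deficiency equals the number of connected components; each
    component receives a sum-to-zero constraint (for an island a point
    constraint x_i = 0, its diagonal being zero).
    """
    if w.style != "binary":
        raise ValueError("icar_structure expects binary weights")
    A = w.to_sparse().toarray()
    Q = np.diag(A.sum(axis=1)) - A
    labels = np.asarray(w.component_labels)
    n_comp = len(set(w.component_labels))
    constraints = np.zeros((n_comp, w.n))
    for c in range(n_comp):
        constraints[c, labels == c] = 1.0
    return GMRFStructure(Q=Q, rank_deficiency=n_comp, constraints=constraints, kind="icar")


def rw2_structure(m: int) -> GMRFStructure:
    """Second-order random-walk structure on m ordered levels.

    Q = D'D with D the (m-2) x m second-difference operator; the null
    space holds constant and linear sequences (rank deficiency 2), the
    identifying constraint is sum-to-zero.  The interior stencil is the
    pentadiagonal (1, -4, 6, -4, 1).
    """
    if m < 3:
        raise ValueError("RW2 needs at least 3 levels")
    D = np.zeros((m - 2, m))
    for k in range(m - 2):
        D[k, k:k + 3] = (1.0, -2.0, 1.0)
    return GMRFStructure(Q=D.T @ D, rank_deficiency=2,
                         constraints=np.ones((1, m)), kind="rw2")


def iid_structure(m: int) -> GMRFStructure:
    """Exchangeable Gaussian structure: Q = I, full rank, no constraints."""
    if m < 1:
        raise ValueError("need m >= 1")
    return GMRFStructure(Q=np.eye(m), rank_deficiency=0,
                         constraints=np.zeros((0, m)), kind="iid")


def scale_structure(s: GMRFStructure) -> GMRFStructure:
    """Rescale Q so the geometric mean of the marginal variances is 1.

    Q is multiplied by the geometric mean of the constrained generalized
    inverse's diagonal (degenerate zero-variance nodes excluded), the
    factor is recorded, and the operation is idempotent.  An iid
    structure is already scaled and passes through unchanged.
    """
    var = s.marginal_variances()
    live = var > _NULL_TOL
    if not live.any():
        raise ValueError("structure has no non-degenerate nodes to scale by")
    g = float(np.exp(np.mean(np.log(var[live]))))
    if abs(g - 1.0) < 1e-12:
        return s
    return replace(s, Q=s.Q * g, scale_factor=s.scale_factor * g, _cache={})


def sample_constrained(s: GMRFStructure, tau: float, seed=None) -> np.ndarray:
    """Draw from N(0, (tau*Q)^-) under the structure's constraints.

    Sampling happens on the eigenbasis restricted to the positive
    eigenvalues — the subspace orthogonal to the null space — so the
    standard identifying constraints (sum-to-zero per component,
    orthogonality to linear trends for RW2, zero at islands) hold by
    construction; any remaining constraint residual is projected out.
    ``seed`` may be an int or a numpy Generator.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, V, pos = s._eig()
    z = rng.standard_normal(int(pos.sum()))
    x = V[:, pos] @ (z / np.sqrt(tau * lam[pos]))
    A = s.constraints
    if A.size:
        resid = A @ x
        if np.max(np.abs(resid)) > 1e-12:
            x -= A.T @ np.linalg.lstsq(A @ A.T, resid, rcond=None)[0]
    return x
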