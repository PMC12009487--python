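"""Intrinsic Gaussian Markov random field building blocks.

Every structured random effect in the space-time models is an intrinsic GMRF
with an improper density proportional to ``exp(-tau/2 * x' R x)`` for a
positive semi-definite structure matrix R:

* ICAR over regions: R is the graph Laplacian D - A, so the kernel is the
  pairwise-difference sum ``-tau/2 * sum_{i~j} (x_i - x_j)^2`` and the full
  conditionals are ``x_i | x_{-i} ~ N(mean of neighbours, 1/(tau * n_i))``.
* Random walk of order p over years: R = D_p' D_p with D_p the p-th
  difference operator; the RW2 kernel penalizes second differences and its
  null space is any linear trend.
* Knorr-Held interactions: Kronecker combinations of the above.

Identifiability is handled by working in the eigenbasis of R restricted to
its penalized (non-null) subspace: if ``R = V diag(lam) V'`` with lam > 0,
then ``x = V z`` with independent ``z_k ~ N(0, 1/(tau*lam_k))`` is a proper
parametrization that automatically satisfies the usual sum-to-zero
constraints (and, for Kronecker interactions, the margin constraints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import AdjacencyGraph

__all__ = [
    "rw_structure",
    "icar_structure",
    "EffectBasis",
    "penalized_basis",
    "interaction_basis",
    "sample_igmrf",
]

_NULL_TOL = 1e-9


def rw_structure(T: int, order: int = 2) -> np.ndarray:
    """Structure matrix of a random walk of the given order on T time points."""
    if T <= order:
        raise ValueError(f"need more than {order} time points for an RW{order}")
    D = np.diff(np.eye(T), n=order, axis=0)
    return D.T @ D


def icar_structure(graph: AdjacencyGraph) -> np.ndarray:
    """ICAR structure matrix (graph Laplacian)."""
    if graph.n_regions == 0:
        raise ValueError("empty graph")
    return graph.laplacian()


@dataclass(frozen=True)
class EffectBasis:
    """Eigenbasis of the penalized subspace of an intrinsic GMRF.

    ``basis`` has orthonormal columns spanning the non-null eigenspace of the
    structure matrix and ``eigenvalues`` the matching positive eigenvalues, so
    the prior on coefficients z is N(0, (tau * eigenvalues)^-1) elementwise.
    """

    basis: np.ndarray        # (m, r)
    eigenvalues: np.ndarray  # (r,)

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def expand(self, z: np.ndarray) -> np.ndarray:
        return self.basis @ z


def penalized_basis(R: np.ndarray) -> EffectBasis:
    """Eigendecompose a structure matrix and drop its null space."""
    w, V = np.linalg.eigh(R)
    tol = _NULL_TOL * max(w.max(), 1.0)
    keep = w > tol
    return EffectBasis(np.ascontiguousarray(V[:, keep]), w[keep])


def iid_contrast_basis(m: int) -> EffectBasis:
    """Orthonormal basis of the sum-to-zero subspace for an iid effect.

    The structure matrix is the identity restricted to the contrast space:
    all eigenvalues are 1 (a centered iid normal vector of m components has
    m - 1 free contrasts).
    """
    # Helmert-style contrasts via eigenbasis of the centering projector
    P = np.eye(m) - np.ones((m, m)) / m
    w, V = np.linalg.eigh(P)
    keep = w > 0.5
    return EffectBasis(np.ascontiguousarray(V[:, keep]), np.ones(int(keep.sum())))


def linear_trend_direction(T: int) -> np.ndarray:
    """Unit vector along the centered linear trend in time (RW2 null space
    component orthogonal to the constant)."""
    t = np.arange(T, dtype=float)
    t -= t.mean()
    return t / np.linalg.norm(t)


def interaction_basis(itype: str, graph: AdjacencyGraph, T: int,
                      walk_order: int = 1) -> EffectBasis:
    """Eigenbasis for a Knorr-Held space-time interaction.

    Types cross unstructured/structured space with unstructured/structured
    time: I = iid x iid, II = iid space x random walk in time, III = ICAR
    space x iid time, IV = ICAR space x random walk.  Cells are flattened
    row-major as (region, year) -> i*T + j, so Kronecker products are
    ``space (x) time``.  All null directions of the Kronecker structure
    matrix are dropped, which imposes the standard margin constraints.
    """
    n = graph.n_regions
    if itype == "I":
        return EffectBasis(np.eye(n * T), np.ones(n * T))
    if itype == "II":
        tb = penalized_basis(rw_structure(T, walk_order))
        return EffectBasis(np.kron(np.eye(n), tb.basis),
                           np.kron(np.ones(n), tb.eigenvalues))
    if itype == "III":
        sb = penalized_basis(icar_structure(graph))
        return EffectBasis(np.kron(sb.basis, np.eye(T)),
                           np.kron(sb.eigenvalues, np.ones(T)))
    if itype == "IV":
        sb = penalized_basis(icar_structure(graph))
        tb = penalized_basis(rw_structure(T, walk_order))
        return EffectBasis(np.kron(sb.basis, tb.basis),
                           np.kron(sb.eigenvalues, tb.eigenvalues))
    raise ValueError(f"unknown interaction type {itype!r}")


def sample_igmrf(basis: EffectBasis, sd: float, rng: np.random.Generator,
                 size: int | None = None) -> np.ndarray:
    """Draw from the intrinsic GMRF restricted to its penalized subspace.

    Equivalent to sampling with covariance ``sd**2 * R^+`` (Moore-Penrose
    pseudo-inverse) and projecting onto the constraint space; exact for the
    small structure matrices used here.
    """
    r = basis.rank
    shape = (r,) if size is None else (size, r)
    z = rng.standard_normal(shape) * (sd / np.sqrt(basis.eigenvalues))
    return z @ basis.basis.T if size is not None else basis.expand(z)
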