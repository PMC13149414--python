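"""Precision-structure matrices for the intrinsic Gaussian priors.

Both the ICAR (graph Laplacian ``Q = D - W``) and the first-order random walk
(first-difference penalty) are improper Gaussian priors with a known rank
deficiency: one null direction per connected component (ICAR) or the constant
vector (RW1).  Before use in the model each structure is *scaled* so that the
geometric mean of the marginal variances under its sum-to-zero constraint is
one — the reparameterization that makes a single precision parameter
interpretable and lets penalized-complexity priors be placed comparably on
every component.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .graphs import CountryGraph

_EIG_TOL = 1e-10


@dataclasses.dataclass
class StructureMatrix:
    """Symmetric PSD precision structure with explicit null space.

    Attributes
    ----------
    Q : ndarray
        The structure matrix (unscaled or scaled).
    null_basis : ndarray, shape (n, k)
        Orthonormal basis of the null space (the directions that must be
        fixed by linear constraints for the prior to be proper).
    kind : str
        "icar" or "rw1".
    scaled : bool
        Whether :func:`scale_structure` has been applied.
    scaling_factor : float or None
        The multiplier ``s`` with ``Q* = s * Q``.
    """

    Q: np.ndarray
    null_basis: np.ndarray
    kind: str
    scaled: bool = False
    scaling_factor: float | None = None

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(Q, Q.T, atol=1e-10):
            raise ValueError("structure matrix must be symmetric")
        self.Q = Q

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def n_null(self) -> int:
        return self.null_basis.shape[1]

    @property
    def rank(self) -> int:
        return self.n - self.n_null

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition (ascending); cached."""
        if not hasattr(self, "_eig"):
            self._eig = np.linalg.eigh(self.Q)
        return self._eig

    def generalized_inverse(self) -> np.ndarray:
        """Moore-Penrose pseudoinverse (covariance under sum-to-zero per null direction)."""
        vals, vecs = self.eig()
        scale = max(vals.max(), 1.0)
        inv = np.where(vals > _EIG_TOL * scale, 1.0 / np.where(vals > 0, vals, 1.0), 0.0)
        return (vecs * inv) @ vecs.T

    def marginal_variances(self) -> np.ndarray:
        """Diagonal of the constrained generalized inverse."""
        return np.diag(self.generalized_inverse()).copy()

    def nonnull_eigenvalues(self) -> np.ndarray:
        vals, _ = self.eig()
        scale = max(vals.max(), 1.0)
        return vals[vals > _EIG_TOL * scale]


def icar_structure(graph: CountryGraph) -> StructureMatrix:
    """Unscaled ICAR structure ``Q = D - W`` for an areal graph.

    Null space: one indicator per connected component (normalized).  An
    empty edge set is permitted but flagged with a warning — the ICAR part
    then degenerates and the spatial prior is effectively pure iid.
    """
    W = graph.adjacency()
    Q = np.diag(W.sum(axis=1)) - W
    comps = graph.components()
    null = np.zeros((graph.n_nodes, len(comps)))
    for k, comp in enumerate(comps):
        null[comp, k] = 1.0 / np.sqrt(len(comp))
    if not graph.edges:
        warnings.warn(
            "graph has no edges: ICAR structure is all-zero and the "
            "structured spatial component degenerates to pure iid",
            stacklevel=2,
        )
    return StructureMatrix(Q=Q, null_basis=null, kind="icar")


def rw1_structure(n_times: int) -> StructureMatrix:
    """Unscaled first-order random-walk structure (first-difference penalty)."""
    T = int(n_times)
    if T < 2:
        raise ValueError("RW1 needs at least two time points")
    D = np.zeros((T - 1, T))
    idx = np.arange(T - 1)
    D[idx, idx] = -1.0
    D[idx, idx + 1] = 1.0
    Q = D.T @ D
    null = np.full((T, 1), 1.0 / np.sqrt(T))
    return StructureMatrix(Q=Q, null_basis=null, kind="rw1")


def scale_structure(sm: StructureMatrix) -> StructureMatrix:
    """Variance-scale an intrinsic structure to generalized marginal variance 1.

    The scaling factor ``s`` is the geometric mean of the marginal variances
    (diagonal of the constrained generalized inverse of ``Q``); the scaled
    structure ``Q* = s Q`` then has marginal variances with geometric mean 1.
    For disconnected graphs the pseudoinverse is block-diagonal, so the
    per-component sum-to-zero scaling combines through one geometric mean
    over all (non-isolated) nodes.
    """
    if sm.rank < 1:
        raise ValueError("all-zero structure: variance scaling is undefined")
    mv = sm.marginal_variances()
    positive = mv > 0
    if not positive.all():
        warnings.warn(
            "isolated nodes have no ICAR marginal variance; excluded from "
            "the geometric mean",
            stacklevel=2,
        )
    s = float(np.exp(np.mean(np.log(mv[positive]))))
    return StructureMatrix(
        Q=s * sm.Q,
        null_basis=sm.null_basis.copy(),
        kind=sm.kind,
        scaled=True,
        scaling_factor=s,
    )


def bym2_scaling_factor(sm: StructureMatrix) -> float:
    """The geometric-mean marginal variance used to scale an ICAR structure."""
    return scale_structure(sm).scaling_factor
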