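"""Skeleton graph and its symmetrically normalized spatial operator.

The joint graph is the COCO skeleton: 17 vertices, edges along limbs,
torso and head, plus self-connections. The spatial operator of the graph
layer is

    Lambda^{-1/2} ((A + I) (x) M) Lambda^{-1/2}

where A is the adjacency, I the identity (self-loops), M a learnable
edge-importance mask (elementwise product, initialized to ones) and
Lambda the diagonal degree matrix Lambda_ii = sum_j (A_ij + I_ij). With
M = 1 this is the standard symmetric graph normalization, whose spectral
radius is at most 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coco import N_JOINTS, adjacency_matrix


@dataclass
class SkeletonGraph:
    """Adjacency, self-loops and edge-importance mask of the joint graph."""

    A: np.ndarray = field(default_factory=adjacency_matrix)
    M: np.ndarray = field(default_factory=lambda: np.ones((N_JOINTS, N_JOINTS)))

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.A = A
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != A.shape:
            raise ValueError("mask must match adjacency shape")

    @property
    def n_vertices(self) -> int:
        return self.A.shape[0]

    def degree(self) -> np.ndarray:
        """Diagonal of Lambda: row sums of A + I."""
        return (self.A + np.eye(self.n_vertices)).sum(axis=1)


def normalization_factors(graph: SkeletonGraph) -> np.ndarray:
    """Lambda^{-1/2} diagonal; raises if any vertex is isolated even with
    self-loops (cannot happen for a nonnegative adjacency, guarded anyway)."""
    deg = graph.degree()
    if np.any(deg <= 0):
        raise ValueError("zero-degree vertex in skeleton graph")
    return 1.0 / np.sqrt(deg)


def build_normalized_adjacency(graph: SkeletonGraph) -> np.ndarray:
    """The spatial operator Lambda^{-1/2}((A+I)(x)M)Lambda^{-1/2}.

    The degree normalization is computed from A + I only (the mask does not
    enter Lambda), so with M = 1 the operator is the standard symmetric
    normalization.
    """
    d = normalization_factors(graph)
    I = np.eye(graph.n_vertices)
    return d[:, None] * ((graph.A + I) * graph.M) * d[None, :]


def base_normalized_adjacency(graph: SkeletonGraph) -> np.ndarray:
    """The mask-free part Lambda^{-1/2}(A+I)Lambda^{-1/2}; multiplying it
    elementwise by M yields :func:`build_normalized_adjacency`."""
    d = normalization_factors(graph)
    I = np.eye(graph.n_vertices)
    return d[:, None] * (graph.A + I) * d[None, :]
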