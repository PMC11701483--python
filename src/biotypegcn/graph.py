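"""Population graph construction.

Subjects are nodes; node features are FNC vectors; edges encode phenotypic
similarity. The affinity between subjects u and v is

    s(u, v) = 1[gender_u == gender_v] + 1[|age_u - age_v| <= age_window]

optionally gated by a Gaussian kernel on the correlation distance between
their FNC vectors. The propagation matrix used by the graph-convolutional
model is the standard renormalized form D^{-1/2} (A + I) D^{-1/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    DataShapeError,
    DegenerateGraphError,
    DegenerateGraphWarning,
    InvalidAdjacencyError,
)
from .synthetic import SubjectRecord


@dataclass
class PopulationGraph:
    """Subjects-as-nodes weighted graph.

    ``X`` holds one FNC vector per row, ``A`` the symmetric non-negative
    adjacency with zero diagonal (self-loops are only added when the
    propagation matrix is formed), ``labels`` the binary diagnosis vector
    (1 = patient).
    """

    X: np.ndarray
    A: np.ndarray
    labels: np.ndarray
    ids: list[str]
    patient_mask: np.ndarray

    def __post_init__(self):
        n = self.X.shape[0]
        if self.A.shape != (n, n):
            raise DataShapeError("adjacency shape does not match feature rows")
        if len(self.labels) != n or len(self.ids) != n or len(self.patient_mask) != n:
            raise DataShapeError("labels/ids/patient_mask must have one entry per node")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise InvalidAdjacencyError("adjacency must be symmetric")
        if np.any(self.A < 0):
            raise InvalidAdjacencyError("adjacency must be non-negative")
        if np.any(np.diag(self.A) != 0):
            raise InvalidAdjacencyError("adjacency diagonal must be zero")
        if np.any(self.patient_mask != (self.labels == 1)):
            raise DataShapeError("patient_mask inconsistent with labels")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_patients(self) -> int:
        return int(self.patient_mask.sum())


def phenotypic_affinity(subjects: list[SubjectRecord], age_window: float) -> np.ndarray:
    ages = np.array([s.age for s in subjects])
    genders = np.array([s.gender for s in subjects])
    same_gender = (genders[:, None] == genders[None, :]).astype(float)
    close_age = (np.abs(ages[:, None] - ages[None, :]) <= age_window).astype(float)
    s = same_gender + close_age
    np.fill_diagonal(s, 0.0)
    return s


def feature_kernel(fnc: np.ndarray) -> np.ndarray:
    """Gaussian kernel on correlation distance, exp(-(1-corr)^2 / 2 sigma^2),
    with sigma the mean pairwise correlation distance.

    Edges are centered per feature first, so the subject-by-subject
    correlation reflects each subject's deviation pattern rather than the
    population-mean connectivity shared by everyone.
    """
    fnc = np.asarray(fnc, dtype=float)
    corr = np.corrcoef(fnc - fnc.mean(axis=0))
    dist = 1.0 - corr
    n = dist.shape[0]
    off = dist[~np.eye(n, dtype=bool)]
    sigma = float(off.mean())
    if sigma <= 0:
        sigma = 1.0
    k = np.exp(-(dist**2) / (2.0 * sigma**2))
    np.fill_diagonal(k, 0.0)
    return k


def topk_sparsify(a: np.ndarray, k: int) -> np.ndarray:
    """Keep each node's k strongest edges, then symmetrize by maximum."""
    n = a.shape[0]
    keep = np.zeros_like(a)
    for i in range(n):
        if k >= n - 1:
            keep[i] = a[i]
            continue
        idx = np.argpartition(a[i], -k)[-k:]
        keep[i, idx] = a[i, idx]
    return np.maximum(keep, keep.T)


def build_graph(
    subjects: list[SubjectRecord],
    fnc: np.ndarray,
    age_window: float = 24.0,
    use_feature_kernel: bool = True,
    k_sparsify: int | None = 10,
) -> PopulationGraph:
    """Assemble the population graph from phenotypes and FNC features."""
    fnc = np.asarray(fnc, dtype=float)
    if fnc.shape[0] != len(subjects):
        raise DataShapeError("fnc rows must align with subjects")
    if age_window <= 0:
        raise DataShapeError("age_window must be positive")
    a = phenotypic_affinity(subjects, age_window)
    if use_feature_kernel:
        a = a * feature_kernel(fnc)
    if k_sparsify is not None:
        a = topk_sparsify(a, int(k_sparsify))
    if not np.any(a > 0):
        warnings.warn(
            "population graph has an all-zero adjacency; training on it will fail",
            DegenerateGraphWarning,
            stacklevel=2,
        )
    labels = np.array([1 if s.diagnosis == "patient" else 0 for s in subjects])
    return PopulationGraph(
        X=fnc,
        A=a,
        labels=labels,
        ids=[s.id for s in subjects],
        patient_mask=labels == 1,
    )


def normalize_adjacency(a: np.ndarray | PopulationGraph) -> np.ndarray:
    """Renormalized propagation matrix D^{-1/2} (A + I) D^{-1/2}."""
    if isinstance(a, PopulationGraph):
        a = a.A
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise InvalidAdjacencyError("adjacency must be non-negative")
    if not np.allclose(a, a.T, atol=1e-10):
        raise InvalidAdjacencyError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def require_trainable(graph: PopulationGraph) -> None:
    if not np.any(graph.A > 0):
        raise DegenerateGraphError("all-zero adjacency: graph is fully disconnected")


def induce_patient_subgraph(graph: PopulationGraph) -> PopulationGraph:
    """Restrict the graph to patient nodes, weights unchanged, order preserved."""
    mask = graph.patient_mask
    if not np.any(mask):
        raise DegenerateGraphError("no patients in graph")
    idx = np.flatnonzero(mask)
    return PopulationGraph(
        X=graph.X[idx],
        A=graph.A[np.ix_(idx, idx)],
        labels=graph.labels[idx],
        ids=[graph.ids[i] for i in idx],
        patient_mask=graph.patient_mask[idx],
    )
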