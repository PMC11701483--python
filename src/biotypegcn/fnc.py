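"""Functional network connectivity (FNC) features.

A subject's FNC is the Pearson correlation matrix between the time courses
of C intrinsic connectivity components (C = 53 in the NeuroMark layout).
The upper triangle of that matrix, in a fixed row-major order, is the
subject's feature vector of length d = C(C-1)/2 (1378 for C = 53).

This module computes FNC matrices from component time courses, converts
between matrix and vector form, handles the component -> network partition,
and residualizes feature tables on nuisance covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CollinearityError,
    DataShapeError,
    InsufficientSamplesError,
    PartitionError,
    ZeroVarianceError,
)

NETWORK_LABELS = ("SC", "AU", "SM", "VI", "CC", "DM", "CB")
#: NeuroMark 7-network component counts (subcortical, auditory, sensorimotor,
#: visual, cognitive control, default mode, cerebellar).
DEFAULT_NETWORK_SIZES = (5, 2, 9, 9, 17, 7, 4)


def edge_index(n_components: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i, j) pairs with i < j.

    This order is the package-wide canonical edge order; every template,
    overlap and contribution computation depends on it.
    """
    return [(i, j) for i in range(n_components) for j in range(i + 1, n_components)]


def edge_names(n_components: int) -> list[str]:
    """Canonical edge column names ``comp<i>_comp<j>`` (1-based components)."""
    return [f"comp{i + 1}_comp{j + 1}" for i, j in edge_index(n_components)]


def n_edges(n_components: int) -> int:
    return n_components * (n_components - 1) // 2


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of components to functional networks.

    Parameters
    ----------
    network_sizes
        Component count per network, in the order of ``labels``. The default
        is the 53-component, 7-network NeuroMark layout.
    labels
        Network names; one per entry of ``network_sizes``.
    """

    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    labels: tuple[str, ...] = NETWORK_LABELS

    def __post_init__(self):
        if len(self.network_sizes) != len(self.labels):
            raise PartitionError("network_sizes and labels must align")
        if any(s < 0 for s in self.network_sizes):
            raise PartitionError("network sizes must be non-negative")

    @property
    def n_components(self) -> int:
        return int(sum(self.network_sizes))

    @property
    def component_networks(self) -> dict[int, str]:
        """Map component index (0-based) -> network label."""
        out, c = {}, 0
        for label, size in zip(self.labels, self.network_sizes):
            for _ in range(size):
                out[c] = label
                c += 1
        return out

    def network_of(self, component: int) -> str:
        if not 0 <= component < self.n_components:
            raise PartitionError(
                f"component {component} outside partition of {self.n_components} components"
            )
        return self.component_networks[component]

    def to_frame(self):
        import pandas as pd

        cn = self.component_networks
        return pd.DataFrame(
            {"component": sorted(cn), "network": [cn[c] for c in sorted(cn)]}
        )

    @classmethod
    def from_frame(cls, frame) -> "NetworkPartition":
        frame = frame.sort_values("component")
        labels: list[str] = []
        sizes: list[int] = []
        for net in frame["network"]:
            if not labels or net != labels[-1]:
                labels.append(net)
                sizes.append(0)
            sizes[-1] += 1
        return cls(tuple(sizes), tuple(labels))


def compute_fnc(timecourses: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix (C x C) of component time courses (C x T)."""
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2:
        raise DataShapeError("timecourses must be a 2-D components x time array")
    c, t = tc.shape
    if t < 3:
        raise InsufficientSamplesError(f"need at least 3 time points, got {t}")
    sd = tc.std(axis=1)
    constant = sd <= 1e-10 * (np.abs(tc.mean(axis=1)) + 1.0)
    if np.any(constant):
        bad = int(np.flatnonzero(constant)[0])
        raise ZeroVarianceError(f"component {bad} has constant time course")
    r = np.corrcoef(tc)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def vectorize_fnc(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper triangle of a symmetric matrix in canonical row-major order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataShapeError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=atol):
        raise DataShapeError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def unvectorize_fnc(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_fnc`; the diagonal is set to 1."""
    v = np.asarray(vector, dtype=float).ravel()
    d = v.size
    c = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
    if c * (c - 1) // 2 != d:
        raise DataShapeError(f"vector length {d} is not a triangular number")
    m = np.eye(c)
    iu = np.triu_indices(c, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform, an opt-in alternative feature scale."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -0.999999, 0.999999))


def regress_covariates(features: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize each feature column on a covariate design matrix.

    ``design`` must include an intercept column; categorical covariates must
    be pre-encoded as indicators. Returns the least-squares residuals, which
    are orthogonal to every design column.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    z = np.asarray(design, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, q = z.shape
    if x.shape[0] != n:
        raise DataShapeError("features and design have different row counts")
    if n <= q + 1:
        raise DataShapeError(f"need more than q+1={q + 1} rows, got {n}")
    rank = np.linalg.matrix_rank(z)
    if rank < q:
        dependent = _dependent_columns(z)
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {q}); "
            f"dependent columns: {dependent}",
            dependent_columns=dependent,
        )
    beta, *_ = np.linalg.lstsq(z, x, rcond=None)
    return x - z @ beta


def _dependent_columns(z: np.ndarray) -> list[int]:
    """Columns that do not increase the rank when added left to right."""
    dep, cols = [], []
    for j in range(z.shape[1]):
        trial = cols + [z[:, j]]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(cols):
            dep.append(j)
        else:
            cols = trial
    return dep
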