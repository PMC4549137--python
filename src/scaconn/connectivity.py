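"""Whole-brain functional-connectivity matrices and edge vectorization.

Functional connectivity between two regions is the sample Pearson
correlation of their (preprocessed, censored) time courses.  For R regions
the R x R symmetric matrix has R(R-1)/2 unique off-diagonal entries; the
canonical edge order is lexicographic over pairs (i, j) with i < j, which
enumerates the same edge set as the lower triangle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import RoiTimeSeries


@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    region_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        R = self.values.shape[0]
        if self.values.shape != (R, R):
            raise ValueError("connectivity matrix must be square")
        if len(self.region_names) != R:
            raise ValueError("region_names length mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between all region pairs over the kept frames."""
    data = ts.kept_data()
    if data.shape[0] < 3:
        raise ValueError("need at least 3 retained frames")
    sd = data.std(axis=0)
    # relative floor: a residual-of-rounding column is as degenerate as an
    # exactly constant one
    zero_var = np.flatnonzero(sd <= 1e-12 * max(1.0, np.abs(data).max()))
    if zero_var.size:
        names = [ts.region_names[i] for i in zero_var]
        raise ValueError(f"zero-variance region(s): {names}")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(corr, list(ts.region_names))


def edge_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Canonical edge order: (i, j), i < j, lexicographic, 0-based."""
    return [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def edge_names(region_names: list[str]) -> list[str]:
    return [f"{region_names[i]}|{region_names[j]}"
            for i, j in edge_pairs(len(region_names))]


def vectorize_edges(c: ConnectivityMatrix, atol: float = 1e-10) -> np.ndarray:
    """Flatten the unique off-diagonal entries in canonical edge order."""
    m = c.values
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(c.n_regions, k=1)
    return m[iu].copy()


def devectorize_edges(edges: np.ndarray, region_names: list[str]
                      ) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges`; diagonal restored to 1."""
    R = len(region_names)
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (n_edges(R),):
        raise ValueError(f"expected {n_edges(R)} edges for {R} regions")
    m = np.eye(R)
    iu = np.triu_indices(R, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return ConnectivityMatrix(m, list(region_names))


def fisher_z(r):
    """Fisher variance-stabilizing transform, z = atanh(r).

    Optional: raw correlations are the default feature value downstream.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def cohort_edge_table(matrices: dict[str, ConnectivityMatrix]) -> "np.ndarray":
    """Stack per-subject edge vectors into a subjects x edges array.

    Subject order follows the dict insertion order; all subjects must share
    the same region list.
    """
    names = None
    rows = []
    for sid, c in matrices.items():
        if names is None:
            names = c.region_names
        elif c.region_names != names:
            raise ValueError(f"subject {sid!r}: region order mismatch")
        rows.append(vectorize_edges(c))
    return np.vstack(rows)
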