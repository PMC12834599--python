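"""Canonical edge indexing for a parcellated connectome.

The connectome on ``n`` parcels has ``n*(n-1)/2`` unordered edges.  Every
subject-level connectivity vector, every edgewise statistic, and every null
replicate in this package uses the same 0-based lexicographic edge order:
edge ``(i, j)`` with ``i < j`` maps to linear index

    k = i*n - i*(i+1)/2 + (j - i - 1)

which is exactly the row-major upper-triangle order of ``np.triu_indices``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_edges", "edge_pairs", "edge_index", "edge_pair"]


def n_edges(n_parcels: int) -> int:
    """Number of unordered edges among ``n_parcels`` nodes."""
    n = int(n_parcels)
    if n < 2:
        raise ValueError(f"need at least 2 parcels, got {n}")
    return n * (n - 1) // 2


def edge_pairs(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint arrays ``(i, j)`` for all edges in canonical order."""
    if n_parcels < 2:
        raise ValueError(f"need at least 2 parcels, got {n_parcels}")
    return np.triu_indices(n_parcels, k=1)


def edge_index(i, j, n_parcels: int):
    """Linear edge index of parcel pair ``(i, j)``; order-insensitive.

    Accepts scalars or arrays.  Raises on ``i == j`` (no self edges) and on
    out-of-range parcel ids.
    """
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    n = int(n_parcels)
    if np.any(i == j):
        raise ValueError("self edges (i == j) are not indexed")
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise ValueError(f"parcel ids out of range for n={n}")
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    k = lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)
    return k if k.ndim else int(k)


def edge_pair(k, n_parcels: int):
    """Inverse of :func:`edge_index`: endpoints ``(i, j)`` with ``i < j``."""
    k = np.asarray(k, dtype=np.int64)
    n = int(n_parcels)
    m = n_edges(n)
    if np.any((k < 0) | (k >= m)):
        raise ValueError(f"edge index out of range for n={n}")
    # row i ends at cumulative count i*n - i*(i+1)/2 + (n - i - 1)
    row_ends = np.cumsum(np.arange(n - 1, 0, -1))
    i = np.searchsorted(row_ends, k, side="right")
    row_start = row_ends - np.arange(n - 1, 0, -1)
    j = k - row_start[i] + i + 1
    if k.ndim:
        return i, j
    return int(i), int(j)
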