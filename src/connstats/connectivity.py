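"""Fisher-Z functional connectivity from parcellated time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import edge_pairs

__all__ = ["ConnectivityVector", "CollinearParcelsError", "fisher_fc"]


class CollinearParcelsError(Exception):
    """Two parcel series are perfectly (anti)correlated; Fisher Z diverges."""


@dataclass
class ConnectivityVector:
    """One subject's Fisher-Z edge values over the canonical edge order."""

    z: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity values must be finite")


def fisher_fc(series: np.ndarray, mask: np.ndarray | None = None) -> ConnectivityVector:
    """Pairwise Pearson correlation over retained frames, Fisher-Z transformed.

    Parameters
    ----------
    series : ndarray, shape (n_parcels, n_frames)
        Parcellated BOLD series.
    mask : boolean ndarray, optional
        Retained-frame mask from censoring; default keeps all frames.

    Returns
    -------
    ConnectivityVector
        ``z[k] = atanh(r)`` for the k-th canonical edge; the diagonal is
        excluded.  Raises :class:`CollinearParcelsError` if any off-diagonal
        ``|r|`` reaches 1 (e.g. duplicated parcels), since atanh diverges.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (parcels x frames)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (series.shape[1],):
            raise ValueError("mask length must equal frame count")
        series = series[:, mask]
    n_parcels, n_frames = series.shape
    if n_frames < 3:
        raise ValueError(f"need at least 3 retained frames, got {n_frames}")
    spread = np.ptp(series, axis=1)
    if np.any(spread == 0):
        bad = np.flatnonzero(spread == 0)
        raise ValueError(f"constant parcel series among retained frames: {bad.tolist()}")
    r = np.corrcoef(series)
    ii, jj = edge_pairs(n_parcels)
    r_edges = r[ii, jj]
    at_limit = np.abs(r_edges) >= 1.0 - 1e-12
    if np.any(at_limit):
        k = int(np.flatnonzero(at_limit)[0])
        raise CollinearParcelsError(
            f"|r| = 1 for parcel pair ({ii[k]}, {jj[k]}); Fisher Z undefined"
        )
    return ConnectivityVector(z=np.arctanh(r_edges), n_frames_used=n_frames)
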