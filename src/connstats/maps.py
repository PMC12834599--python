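"""Parcel-level summary maps derived from edgewise statistics.

A ``ParcelMap`` holds one scalar per parcel (an RMS effect-magnitude map, a
seed map, or an external reference map such as a receptor-density or arousal
template re-sampled to parcels).  Display thresholding percentiles are
metadata only and are never applied before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import edge_index, edge_pairs, n_edges

__all__ = [
    "ParcelMap",
    "rms_magnitude_map",
    "seed_map",
    "map_correlation",
    "rowwise_fc_correlation_map",
]


@dataclass
class ParcelMap:
    """Scalar value per parcel, aligned with a :class:`~connstats.parcellation.ParcelSet`."""

    values: np.ndarray
    name: str = ""
    display_percentiles: tuple[float, float] = (50.0, 95.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def thresholded(self) -> np.ndarray:
        """Values masked (NaN) outside the display-percentile band.

        Rendering convenience only; statistics always use ``values``.
        """
        lo, hi = np.nanpercentile(np.abs(self.values), self.display_percentiles)
        out = self.values.copy()
        out[(np.abs(out) < lo) | (np.abs(out) > hi)] = np.nan
        return out

    def to_frame(self, parcel_id=None) -> pd.DataFrame:
        if parcel_id is None:
            parcel_id = np.arange(len(self.values))
        return pd.DataFrame({"parcel_id": parcel_id, "value": self.values})


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ParcelMap) else np.asarray(m, dtype=float)


def rms_magnitude_map(t_edges, n_parcels: int, name: str = "rms") -> ParcelMap:
    """Root-mean-square of the edge statistics incident to each parcel.

    The value at parcel ``i`` is ``sqrt(mean over its n-1 incident edges of
    t^2)`` — a per-region magnitude-of-change summary of the full edge
    statistic vector.
    """
    t = np.asarray(t_edges, dtype=float)
    if t.shape != (n_edges(n_parcels),):
        raise ValueError("t_edges length does not match n_parcels")
    if not np.all(np.isfinite(t)):
        raise ValueError("t_edges must be finite")
    ii, jj = edge_pairs(n_parcels)
    sumsq = np.bincount(ii, t**2, minlength=n_parcels) + np.bincount(
        jj, t**2, minlength=n_parcels
    )
    return ParcelMap(np.sqrt(sumsq / (n_parcels - 1)), name=name)


def seed_map(t_edges, seed_parcel: int, n_parcels: int) -> ParcelMap:
    """Edge statistic between one seed parcel and every other parcel.

    The entry at the seed itself is undefined (NaN).
    """
    t = np.asarray(t_edges, dtype=float)
    if t.shape != (n_edges(n_parcels),):
        raise ValueError("t_edges length does not match n_parcels")
    if not 0 <= seed_parcel < n_parcels:
        raise ValueError(f"seed parcel {seed_parcel} out of range")
    others = np.delete(np.arange(n_parcels), seed_parcel)
    vals = np.full(n_parcels, np.nan)
    vals[others] = t[edge_index(np.full(n_parcels - 1, seed_parcel), others, n_parcels)]
    return ParcelMap(vals, name=f"seed-{seed_parcel}")


def map_correlation(map_a, map_b, subset=None) -> float:
    """Pearson correlation of two parcel maps over ``subset`` (default: all).

    Full-range values are used — display thresholds never affect statistics.
    """
    a = _as_values(map_a)
    b = _as_values(map_b)
    if a.shape != b.shape:
        raise ValueError("maps have different lengths")
    if subset is not None:
        a = a[subset]
        b = b[subset]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 parcels with finite values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def rowwise_fc_correlation_map(t_edges_a, t_edges_b, n_parcels: int) -> ParcelMap:
    """Per-parcel correlation between two edge-statistic vectors.

    The value at parcel ``i`` is the Pearson correlation between the two
    vectors of statistics over the ``n-1`` edges incident to ``i`` (one row of
    each FC matrix).  Parcels whose row is constant in either input are
    masked (NaN) rather than raising.
    """
    a = np.asarray(t_edges_a, dtype=float)
    b = np.asarray(t_edges_b, dtype=float)
    m = n_edges(n_parcels)
    if a.shape != (m,) or b.shape != (m,):
        raise ValueError("edge vectors do not match n_parcels")
    n = n_parcels
    # rows[i] = canonical indices of the n-1 edges incident to parcel i
    src = np.repeat(np.arange(n), n - 1)
    dst = np.concatenate([np.delete(np.arange(n), i) for i in range(n)])
    rows = edge_index(src, dst, n).reshape(n, n - 1)
    ra = a[rows]
    rb = b[rows]
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra_c**2).sum(axis=1) * (rb_c**2).sum(axis=1))
    vals = np.full(n, np.nan)
    ok = denom > 0
    vals[ok] = (ra_c * rb_c).sum(axis=1)[ok] / denom[ok]
    return ParcelMap(vals, name="rowwise-corr")
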