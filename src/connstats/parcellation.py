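"""Synthetic parcellations with spherical geometry and network labels.

Emulates a cortical surface parcellation (default 333 cortical parcels split
across two hemispheres, plus 61 subcortical regions, 394 nodes total).  Each
hemisphere's cortical parcels live on their own unit sphere (an inflated
hemisphere), laid out on a Fibonacci lattice so centroids are quasi-uniform.
Networks are assigned as contiguous spherical caps (nearest of a set of seed
directions), which gives parcel maps genuine spatial autocorrelation — the
property rotational null models are designed to respect.  Subcortical parcels
carry no centroid and never enter spin tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelSet",
    "NetworkAssignment",
    "gen_parcellation",
    "DEFAULT_RAW_NETWORKS",
    "DEFAULT_MERGE_SPEC",
]

# Raw resting-state network labels.  The five motor-related networks are kept
# separate here and combined for statistical inference (see DEFAULT_MERGE_SPEC),
# mirroring standard practice for small interdigitated networks.
DEFAULT_RAW_NETWORKS: tuple[str, ...] = (
    "premotor",
    "somatomotor hand",
    "somatomotor mouth",
    "somatomotor foot",
    "somato-cognitive action",
    "AUD",
    "SAL",
    "PMN",
    "lateral visual",
    "medial visual",
    "DMN",
    "DAN",
    "VAN",
    "FPN",
)

DEFAULT_MERGE_SPEC: dict[str, str] = {
    "premotor": "SM",
    "somatomotor hand": "SM",
    "somatomotor mouth": "SM",
    "somatomotor foot": "SM",
    "somato-cognitive action": "SM",
    "SAL": "SAL/PMN",
    "PMN": "SAL/PMN",
    "lateral visual": "VIS",
    "medial visual": "VIS",
    "AUD": "AUD",
    "DMN": "DMN",
    "DAN": "DAN",
    "VAN": "VAN",
    "FPN": "FPN",
}


@dataclass
class ParcelSet:
    """Parcels with ids, hemisphere labels, and unit-sphere centroids.

    ``centroid`` rows are NaN for subcortical parcels (no surface geometry).
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray  # 'left' | 'right' | 'subcortical'
    centroid: np.ndarray  # (n, 3), NaN rows for subcortical

    def __post_init__(self) -> None:
        self.parcel_id = np.asarray(self.parcel_id)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if len(np.unique(self.parcel_id)) != self.n_parcels:
            raise ValueError("parcel ids must be unique")
        cort = self.is_cortical
        norms = np.linalg.norm(self.centroid[cort], axis=1)
        if cort.any() and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cortical centroids must lie on the unit sphere")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    @property
    def is_cortical(self) -> np.ndarray:
        return self.hemisphere != "subcortical"

    def to_frame(self, networks: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "hemisphere": self.hemisphere,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
            }
        )
        if networks is not None:
            df["network"] = networks
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelSet":
        return cls(
            parcel_id=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            centroid=df[["x", "y", "z"]].to_numpy(float),
        )


@dataclass
class NetworkAssignment:
    """Raw network label per parcel plus the raw→merged label mapping."""

    labels: np.ndarray  # raw label per parcel, aligned with a ParcelSet
    merge_spec: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        missing = set(np.unique(self.labels)) - set(self.merge_spec)
        if self.merge_spec and missing:
            raise ValueError(f"merge_spec leaves raw labels unmapped: {sorted(missing)}")

    @property
    def merged_labels(self) -> np.ndarray:
        """Per-parcel label after applying the merge specification."""
        if not self.merge_spec:
            return self.labels.copy()
        return np.array([self.merge_spec[l] for l in self.labels], dtype=object)

    @property
    def networks(self) -> list[str]:
        """Sorted unique merged labels."""
        return sorted(set(self.merged_labels))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-angle spiral lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def gen_parcellation(
    n_cortical: int = 333,
    n_subcortical: int = 61,
    n_networks: int | None = None,
    seed: int | None = None,
    network_names: tuple[str, ...] | None = None,
    merge_spec: dict[str, str] | None = None,
) -> tuple[ParcelSet, NetworkAssignment]:
    """Generate a spherical parcellation with spatially contiguous networks.

    Cortical parcels are split across hemispheres (the left hemisphere gets
    the extra parcel when ``n_cortical`` is odd, as in the 333-parcel default).
    Networks are spherical-cap Voronoi cells of ``n_networks`` quasi-uniform
    seed directions, randomly rotated once per call, identical across
    hemispheres (so networks are bilaterally symmetric).  Subcortical parcels
    are assigned networks round-robin from a seeded shuffle.
    """
    if n_cortical < 2:
        raise ValueError("n_cortical must be at least 2")
    if n_subcortical < 0:
        raise ValueError("n_subcortical must be non-negative")
    if network_names is None:
        network_names = DEFAULT_RAW_NETWORKS
        if merge_spec is None:
            merge_spec = dict(DEFAULT_MERGE_SPEC)
    if n_networks is None:
        n_networks = len(network_names)
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if n_networks > len(network_names):
        raise ValueError(
            f"n_networks={n_networks} exceeds available labels ({len(network_names)})"
        )
    network_names = tuple(network_names[:n_networks])
    if merge_spec is None:
        merge_spec = {name: name for name in network_names}
    else:
        merge_spec = {k: v for k, v in merge_spec.items() if k in network_names}

    rng = np.random.default_rng(seed)
    n_left = (n_cortical + 1) // 2
    n_right = n_cortical - n_left
    # one random orientation per call so lattices differ across seeds
    rot = _random_rotation(rng)
    left = fibonacci_sphere(n_left) @ rot.T
    mirror = np.array([-1.0, 1.0, 1.0])
    right = (fibonacci_sphere(max(n_right, 1)) @ rot.T * mirror)[:n_right]

    seeds_dir = fibonacci_sphere(n_networks) @ _random_rotation(rng).T
    lab_left = np.argmax(left @ seeds_dir.T, axis=1)
    # mirror the seed directions for the right hemisphere so homotopic parcels
    # get the same network
    lab_right = np.argmax(right @ (seeds_dir * mirror).T, axis=1)

    n_total = n_cortical + n_subcortical
    centroid = np.full((n_total, 3), np.nan)
    centroid[:n_left] = left
    centroid[n_left:n_cortical] = right
    hemisphere = np.array(
        ["left"] * n_left + ["right"] * n_right + ["subcortical"] * n_subcortical,
        dtype=object,
    )
    parcels = ParcelSet(
        parcel_id=np.arange(n_total), hemisphere=hemisphere, centroid=centroid
    )

    labels = np.empty(n_total, dtype=object)
    labels[:n_left] = [network_names[k] for k in lab_left]
    labels[n_left:n_cortical] = [network_names[k] for k in lab_right]
    if n_subcortical:
        sub = np.resize(np.arange(n_networks), n_subcortical)
        rng.shuffle(sub)
        labels[n_cortical:] = [network_names[k] for k in sub]
    assignment = NetworkAssignment(labels=labels, merge_spec=merge_spec)
    return parcels, assignment
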