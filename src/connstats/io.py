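"""Readers and writers for the package's tabular artifacts.

Everything round-trips through plain text (TSV/CSV/JSON) except the bootstrap
null t-matrix, which is a compressed ``.npz`` with a JSON sidecar recording
how it was generated.  Optional CIFTI adapters (parcellated time series and
scalars) go through nibabel and are imported lazily.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import ParcelMap
from .parcellation import NetworkAssignment, ParcelSet
from .simulate import SyntheticTruth

__all__ = [
    "write_parcels",
    "read_parcels",
    "write_connectivity",
    "read_connectivity",
    "write_truth",
    "read_truth",
    "write_edge_stats",
    "write_null_t",
    "read_null_t",
    "write_map",
    "read_map",
    "write_thresholded_map",
    "write_nla_report",
    "write_pair_matrix",
    "write_spin_result",
    "read_ptseries",
    "read_pscalar",
]


def write_parcels(path, parcels: ParcelSet, assignment: NetworkAssignment) -> None:
    df = parcels.to_frame(networks=assignment.labels)
    df.to_csv(path, sep="\t", index=False)


def read_parcels(path) -> tuple[ParcelSet, np.ndarray]:
    """Returns the ParcelSet and the raw network label per parcel."""
    df = pd.read_csv(path, sep="\t")
    return ParcelSet.from_frame(df), df["network"].to_numpy(dtype=object)


def write_connectivity(path, Y: np.ndarray, subject_ids) -> None:
    df = pd.DataFrame(Y, columns=[f"e{k}" for k in range(Y.shape[1])])
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)


def read_connectivity(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    ids = df["subject_id"].tolist()
    return df.drop(columns="subject_id").to_numpy(float), ids


def _block_key(k: tuple[str, str]) -> str:
    return f"{k[0]}|{k[1]}"


def write_truth(path, truth: SyntheticTruth, edge_truth: dict | None = None) -> None:
    rec = {
        "beta_stim": {_block_key(k): v for k, v in truth.beta_stim.items()},
        "beta_sleep": {_block_key(k): v for k, v in truth.beta_sleep.items()},
        "beta_interaction": {
            _block_key(k): v for k, v in truth.beta_interaction.items()
        },
        "baseline_within": truth.baseline_within,
        "baseline_between": truth.baseline_between,
        "site_sd": truth.site_sd,
        "family_sd": truth.family_sd,
        "noise_sd": truth.noise_sd,
    }
    if edge_truth is not None:
        rec["edge_truth_summary"] = {
            name: {
                "nonzero_edges": int(np.count_nonzero(v)),
                "p98_abs": float(np.percentile(np.abs(v), 98)),
            }
            for name, v in edge_truth.items()
            if name != "baseline"
        }
    Path(path).write_text(json.dumps(rec, indent=2))


def read_truth(path) -> SyntheticTruth:
    rec = json.loads(Path(path).read_text())

    def unkey(d):
        return {tuple(k.split("|")): v for k, v in d.items()}

    return SyntheticTruth(
        beta_stim=unkey(rec["beta_stim"]),
        beta_sleep=unkey(rec["beta_sleep"]),
        beta_interaction=unkey(rec["beta_interaction"]),
        baseline_within=rec["baseline_within"],
        baseline_between=rec["baseline_between"],
        site_sd=rec["site_sd"],
        family_sd=rec["family_sd"],
        noise_sd=rec["noise_sd"],
    )


def write_edge_stats(path, i, j, beta, se, t, p=None) -> None:
    df = pd.DataFrame(
        {"edge": np.arange(len(beta)), "i": i, "j": j, "beta": beta, "se": se, "t": t}
    )
    if p is not None:
        df["p"] = p
    df.to_csv(path, index=False)


def write_null_t(path, null_t: np.ndarray, meta: dict) -> None:
    path = Path(path)
    np.savez_compressed(path, null_t=null_t.astype(np.float32))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_null_t(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    null_t = np.load(path)["null_t"].astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return null_t, meta


def write_map(path, parcel_map: ParcelMap, parcel_id=None) -> None:
    parcel_map.to_frame(parcel_id).to_csv(path, sep="\t", index=False)


def read_map(path) -> ParcelMap:
    df = pd.read_csv(path, sep="\t")
    return ParcelMap(df["value"].to_numpy(float))


def write_thresholded_map(path, parcel_map: ParcelMap, parcel_id=None) -> None:
    """Rendering hook: percentile-thresholded values for surface viewers."""
    if parcel_id is None:
        parcel_id = np.arange(len(parcel_map))
    pd.DataFrame({"parcel_id": parcel_id, "value": parcel_map.thresholded()}).to_csv(
        path, sep="\t", index=False
    )


def write_nla_report(prefix, result) -> None:
    """NLA tables as CSV plus a JSON summary; ``prefix`` is a path stem."""
    prefix = Path(prefix)
    result.pairs.to_csv(prefix.with_name(prefix.name + "_pairs.csv"), index=False)
    result.whole_networks.to_csv(
        prefix.with_name(prefix.name + "_networks.csv"), index=False
    )
    summary = {
        "alpha": result.alpha,
        "B": result.B,
        "significant_pairs": [
            f"{r.network_a}--{r.network_b}"
            for r in result.pairs[result.pairs["significant"]].itertuples()
        ],
        "significant_networks": result.whole_networks[
            result.whole_networks["significant"]
        ]["network"].tolist(),
    }
    prefix.with_name(prefix.name + "_summary.json").write_text(
        json.dumps(summary, indent=2)
    )


def write_pair_matrix(path, pairs: pd.DataFrame) -> None:
    """Network-by-network grid of pair Welch statistics (CSV rendering)."""
    nets = sorted(set(pairs["network_a"]) | set(pairs["network_b"]))
    grid = pd.DataFrame(np.nan, index=nets, columns=nets)
    for r in pairs.itertuples():
        grid.loc[r.network_a, r.network_b] = r.welch_t
        grid.loc[r.network_b, r.network_a] = r.welch_t
    grid.to_csv(path)


def write_spin_result(prefix, result) -> None:
    prefix = Path(prefix)
    prefix.with_name(prefix.name + ".json").write_text(
        json.dumps(
            {
                "r_obs": result.r_obs,
                "p": result.p,
                "n_rotations": result.n_rotations,
                "mode": result.mode,
            },
            indent=2,
        )
    )
    pd.DataFrame({"r_null": result.r_null}).to_csv(
        prefix.with_name(prefix.name + "_null.csv"), index=False
    )


def read_ptseries(path) -> np.ndarray:
    """Parcellated time series from a CIFTI .ptseries.nii, as parcels x frames."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).T


def read_pscalar(path) -> np.ndarray:
    """Parcellated scalars from a CIFTI .pscalar.nii, as a 1-D array."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).ravel()
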