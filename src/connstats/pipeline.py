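"""End-to-end orchestration: simulate -> connectivity -> fit -> nla -> maps -> spin -> power.

Each stage reads its inputs from, and writes its outputs into, a single run
directory, so stages can be executed all at once (``run``) or individually
on a directory produced earlier.  Every stochastic stage has an explicit
seed derived from the master seed, the configuration is hashed into a
provenance record alongside content hashes of every artifact, and a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .cohort import gen_cohort
from .connectivity import fisher_fc
from .design import build_design
from .edgefit import EdgewiseMarginalModel
from .edges import edge_pairs
from .maps import rms_magnitude_map, seed_map
from .motion import InsufficientFramesError, censor_frames
from .netenrich import merge_networks, run_nla
from .parcellation import gen_parcellation
from .power import (
    ATTENTION_CONTROL_N_NET,
    PowerSpec,
    power_at_effect,
    synthetic_null_welch,
)
from .simulate import default_truth, gen_fc_data, gen_reference_map, gen_timeseries
from .spin import spin_test

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "connectivity", "fit", "nla", "maps", "spin", "power")

log = logging.getLogger("connstats")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full analysis run.

    Defaults follow the reference analysis settings: FD censoring at 0.2 mm
    with a 600-frame minimum, 2,000 bootstrap replicates, 2,000 spin
    rotations, FWER alpha 0.05, clustering on acquisition site.
    """

    out_dir: str = "connstats_run"
    seed: int = 0
    # synthetic cohort
    n_cortical: int = 60
    n_subcortical: int = 6
    n_subjects: int = 300
    n_sites: int = 20
    mean_family_size: float = 1.15
    prevalence_stim: float = 0.058
    truth: dict = field(default_factory=dict)  # SyntheticTruth overrides
    # optional raw time-series emulation
    timeseries: bool = False
    n_frames: int = 700
    tr: float = 0.8
    fd_spike_rate: float = 0.05
    # censoring
    fd_threshold: float = 0.2
    min_frames: int = 600
    # model
    interest: str = "stimulant"
    covariates: list = field(default_factory=lambda: ["age_months", "fd_mean"])
    cluster: str = "site_id"
    small_sample: str = "CR0"
    B: int = 2000
    alpha: float = 0.05
    # cohort filter, e.g. "stimulant == 0" (stratified subgroup runs)
    cohort_filter: str = ""
    # spin
    n_rotations: int = 2000
    # power table
    power_d: list = field(default_factory=lambda: [0.2, 0.5, 0.89])
    power_B: int = 2000

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_stage(stage: str, **info) -> None:
    log.info(json.dumps({"stage": stage, **info}))


def _truth_from_config(cfg: PipelineConfig):
    return default_truth(**cfg.truth) if isinstance(cfg.truth, dict) else cfg.truth


def _stage_simulate(cfg: PipelineConfig, run: Path) -> None:
    parcels, assignment = gen_parcellation(
        cfg.n_cortical, cfg.n_subcortical, seed=cfg.stage_seed("parcellation")
    )
    cohort = gen_cohort(
        cfg.n_subjects,
        n_sites=cfg.n_sites,
        mean_family_size=cfg.mean_family_size,
        prevalence_stim=cfg.prevalence_stim,
        seed=cfg.stage_seed("cohort"),
    )
    truth = _truth_from_config(cfg)
    Y, edge_truth = gen_fc_data(
        cohort, assignment, truth, seed=cfg.stage_seed("fcdata")
    )
    cio.write_parcels(run / "parcels.tsv", parcels, assignment)
    json.dump(
        assignment.merge_spec, open(run / "merge_spec.json", "w"), indent=2
    )
    cohort.to_csv(run / "cohort.csv", index=False)
    cio.write_truth(run / "truth.json", truth, edge_truth)
    if cfg.timeseries:
        ts_dir = run / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(cfg.stage_seed("timeseries"))
        for k, sid in enumerate(cohort["subject_id"]):
            series, fd = gen_timeseries(
                Y[k],
                parcels.n_parcels,
                cfg.n_frames,
                tr=cfg.tr,
                fd_spike_rate=cfg.fd_spike_rate,
                seed=int(rng.integers(2**31)),
            )
            np.savetxt(ts_dir / f"{sid}_series.tsv", series.T, delimiter="\t")
            np.savetxt(ts_dir / f"{sid}_fd.tsv", fd, delimiter="\t")
    else:
        cio.write_connectivity(run / "connectivity.csv", Y, cohort["subject_id"])
    _log_stage("simulate", n_parcels=parcels.n_parcels, n_subjects=len(cohort))


def _stage_connectivity(cfg: PipelineConfig, run: Path) -> None:
    """Censor frames and compute Fisher-Z connectivity from time series."""
    ts_dir = run / "timeseries"
    if not ts_dir.exists():
        if (run / "connectivity.csv").exists():
            _log_stage("connectivity", note="connectivity supplied directly")
            return
        raise FileNotFoundError("no timeseries/ directory and no connectivity.csv")
    cohort = pd.read_csv(run / "cohort.csv")
    rows, kept_ids, excluded = [], [], []
    for sid in cohort["subject_id"]:
        series = np.loadtxt(ts_dir / f"{sid}_series.tsv", delimiter="\t").T
        fd = np.loadtxt(ts_dir / f"{sid}_fd.tsv", delimiter="\t")
        try:
            mask = censor_frames(
                fd, cfg.fd_threshold, cfg.min_frames, subject=str(sid)
            )
        except InsufficientFramesError as err:
            excluded.append(
                {"subject_id": sid, "retained": err.retained, "min_frames": err.min_frames}
            )
            continue
        cv = fisher_fc(series, mask)
        rows.append(cv.z)
        kept_ids.append(sid)
    if not rows:
        raise RuntimeError("all subjects excluded by motion censoring")
    cio.write_connectivity(run / "connectivity.csv", np.array(rows), kept_ids)
    pd.DataFrame(excluded, columns=["subject_id", "retained", "min_frames"]).to_csv(
        run / "exclusions.csv", index=False
    )
    _log_stage("connectivity", kept=len(kept_ids), excluded=len(excluded))


def _load_inputs(run: Path):
    parcels, raw_labels = cio.read_parcels(run / "parcels.tsv")
    merge_spec = json.loads((run / "merge_spec.json").read_text())
    from .parcellation import NetworkAssignment

    assignment = NetworkAssignment(labels=raw_labels, merge_spec=merge_spec)
    cohort = pd.read_csv(run / "cohort.csv")
    Y, ids = cio.read_connectivity(run / "connectivity.csv")
    cohort = cohort.set_index("subject_id").loc[ids].reset_index()
    return parcels, assignment, cohort, Y


def _stage_fit(cfg: PipelineConfig, run: Path) -> None:
    parcels, assignment, cohort, Y = _load_inputs(run)
    if cfg.cohort_filter:
        keep = cohort.eval(cfg.cohort_filter).to_numpy(bool)
        cohort, Y = cohort[keep].reset_index(drop=True), Y[keep]
    design = build_design(
        cohort, list(cfg.covariates), cfg.interest, cluster=cfg.cluster
    )
    model = EdgewiseMarginalModel(
        B=cfg.B,
        small_sample=cfg.small_sample,
        random_state=cfg.stage_seed("bootstrap"),
    ).fit(design, Y)
    ii, jj = edge_pairs(parcels.n_parcels)
    cio.write_edge_stats(
        run / "edge_stats.csv", ii, jj, model.coef_, model.se_, model.t_,
        model.pvalues_,
    )
    cio.write_null_t(
        run / "null_t.npz",
        model.null_t_,
        {
            "B": cfg.B,
            "seed": cfg.stage_seed("bootstrap"),
            "cluster": cfg.cluster,
            "small_sample": cfg.small_sample,
            "interest": cfg.interest,
        },
    )
    _log_stage("fit", B=cfg.B, n_edges=len(model.coef_))


def _read_fit(run: Path):
    stats = pd.read_csv(run / "edge_stats.csv")
    null_t, _ = cio.read_null_t(run / "null_t.npz")
    return stats, null_t


def _stage_nla(cfg: PipelineConfig, run: Path) -> None:
    parcels, assignment, *_ = _load_inputs(run)
    stats, null_t = _read_fit(run)
    merged = merge_networks(assignment)
    result = run_nla((stats["t"].to_numpy(), null_t), merged, alpha=cfg.alpha)
    cio.write_nla_report(run / "nla", result)
    cio.write_pair_matrix(run / "nla_pair_matrix.csv", result.pairs)
    _log_stage(
        "nla",
        significant_pairs=int(result.pairs["significant"].sum()),
        significant_networks=int(result.whole_networks["significant"].sum()),
    )


def _stage_maps(cfg: PipelineConfig, run: Path) -> None:
    parcels, *_ = cio.read_parcels(run / "parcels.tsv"), None
    parcels = parcels[0]
    stats, _ = _read_fit(run)
    t = stats["t"].to_numpy()
    rms = rms_magnitude_map(t, parcels.n_parcels)
    cio.write_map(run / "rms_map.tsv", rms, parcels.parcel_id)
    cio.write_thresholded_map(run / "rms_map_display.tsv", rms, parcels.parcel_id)
    peak = int(np.nanargmax(rms.values))
    cio.write_map(run / "seed_map.tsv", seed_map(t, peak, parcels.n_parcels),
                  parcels.parcel_id)
    json.dump({"peak_parcel": peak}, open(run / "maps_meta.json", "w"))
    _log_stage("maps", peak_parcel=peak)


def _stage_spin(cfg: PipelineConfig, run: Path) -> None:
    parcels, assignment, *_ = _load_inputs(run)
    rms = cio.read_map(run / "rms_map.tsv")
    truth = _truth_from_config(cfg)
    targets = sorted({n for block in truth.beta_stim for n in block})
    merged = merge_networks(assignment)
    reference = gen_reference_map(
        parcels, merged, targets, noise_sd=0.5, seed=cfg.stage_seed("refmap")
    )
    result = spin_test(
        rms, reference, parcels, n_rotations=cfg.n_rotations,
        seed=cfg.stage_seed("spin"),
    )
    cio.write_spin_result(run / "spin", result)
    _log_stage("spin", r_obs=result.r_obs, p=result.p)


def _stage_power(cfg: PipelineConfig, run: Path) -> None:
    nets = list(ATTENTION_CONTROL_N_NET)
    n_nets = [ATTENTION_CONTROL_N_NET[n] for n in nets]
    null = synthetic_null_welch(
        n_nets, B=cfg.power_B, seed=cfg.stage_seed("power")
    )
    rows = []
    for d in cfg.power_d:
        for k, net in enumerate(nets):
            spec = PowerSpec(d=d, n_net=n_nets[k])
            rows.append(
                {
                    "network": net,
                    "d": d,
                    "power": power_at_effect(
                        spec, null, family_n_nets=n_nets, family_index=k
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(run / "power_table.csv", index=False)
    _log_stage("power", B=cfg.power_B)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "connectivity": _stage_connectivity,
    "fit": _stage_fit,
    "nla": _stage_nla,
    "maps": _stage_maps,
    "spin": _stage_spin,
    "power": _stage_power,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> Path:
    """Execute pipeline stages in order; returns the run directory.

    Any stage failure aborts with a stage-tagged error; the provenance record
    is written only after all requested stages complete, so a partial run
    directory is recognizable by its absence.
    """
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run / "log.jsonl")
    handler.setFormatter(logging.Formatter("%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in stages:
            try:
                _STAGE_FUNCS[stage](cfg, run)
            except Exception as err:
                raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        provenance = {
            "package_version": __version__,
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "stages": stages,
            "stage_seeds": {s: cfg.stage_seed(s) for s in stages},
            "artifacts": {
                f.name: _sha256(f)
                for f in sorted(run.iterdir())
                if f.is_file() and f.name not in ("provenance.json", "log.jsonl")
            },
        }
        (run / "provenance.json").write_text(json.dumps(provenance, indent=2))
    finally:
        log.removeHandler(handler)
        handler.close()
    return run
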