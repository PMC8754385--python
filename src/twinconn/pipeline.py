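"""End-to-end orchestration: QC -> task FC -> ACE mapping -> inference.

A run is described by a single INI-style config file. One master seed
deterministically derives a substream per stage (keyed by stage name), so
toggling one stage never shifts another stage's randomness, and a rerun
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .ace import lrsd_ace
from .cohort import TwinCohort, simulate_cohort
from .containers import RoiTimeSeries, load_events, save_events
from .network import threshold_sweep
from .permutation import PermutationScheme, cluster_fwe, elementwise_fwe
from .qc import apply_exclusions, framewise_displacement, high_motion_flag
from .simulate import (
    ACEParams,
    simulate_ace_phenotypes,
    simulate_roi_timeseries,
    simulate_task_events,
)
from .taskfc import contrast_fc_stack

_SECTIONS = {
    "paths": {"data_dir", "out_dir"},
    "stages": {"qc", "fc", "ace", "fwe", "nbs"},
    "qc": {"fd_thresh", "fd_prop", "mad_k"},
    "fc": {"band_low", "band_high", "tr"},
    "ace": {"forming_p"},
    "nbs": {"tau_grid", "n_perm"},
    "run": {"seed"},
}


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed and stage name."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "run"
    qc: bool = True
    fc: bool = True
    ace: bool = True
    fwe: bool = True
    nbs: bool = True
    fd_thresh: float = 0.5
    fd_prop: float = 0.5
    mad_k: float = 3.0
    band_low: float = 0.008
    band_high: float = 0.09
    tr: float = 2.4
    forming_p: float = 0.05
    tau_grid: list = field(default_factory=lambda: [0.25, 0.26, 0.27, 0.28, 0.29, 0.30, 0.31, 0.32])
    n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fd_prop <= 1 or self.fd_thresh <= 0:
            raise ValueError("fd thresholds out of range")
        if not 0 <= self.band_low < self.band_high:
            raise ValueError("band cutoffs out of range")
        if not 0 < self.forming_p < 1:
            raise ValueError("forming_p out of range")
        if any(not 0 <= t <= 1 for t in self.tau_grid):
            raise ValueError("tau grid values must lie in [0, 1]")

    # -- INI round trip --------------------------------------------------
    def save(self, path) -> None:
        import configparser

        cp = configparser.ConfigParser()
        cp["paths"] = {"data_dir": self.data_dir, "out_dir": self.out_dir}
        cp["stages"] = {k: str(getattr(self, k)) for k in _SECTIONS["stages"]}
        cp["qc"] = {k: str(getattr(self, k)) for k in _SECTIONS["qc"]}
        cp["fc"] = {k: str(getattr(self, k)) for k in _SECTIONS["fc"]}
        cp["ace"] = {"forming_p": str(self.forming_p)}
        cp["nbs"] = {
            "tau_grid": ",".join(str(t) for t in self.tau_grid),
            "n_perm": str(self.n_perm),
        }
        cp["run"] = {"seed": str(self.seed)}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def load(cls, path) -> "RunConfig":
        import configparser

        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        kw = {}
        for section in cp.sections():
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section [{section}]")
            for key, val in cp[section].items():
                if key not in _SECTIONS[section]:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                if key in ("data_dir", "out_dir"):
                    kw[key] = val
                elif key in _SECTIONS["stages"]:
                    kw[key] = val.lower() in ("true", "1", "yes")
                elif key == "tau_grid":
                    kw[key] = [float(x) for x in val.split(",") if x.strip()]
                elif key in ("n_perm", "seed"):
                    kw[key] = int(val)
                else:
                    kw[key] = float(val)
        return cls(**kw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_dataset(cfg: RunConfig):
    dd = cfg.data_dir
    cohort = TwinCohort.from_tsv(os.path.join(dd, "cohort.tsv"), require_complete_pairs=False)
    events = load_events(os.path.join(dd, "events.tsv"))
    pheno_path = os.path.join(dd, "phenotypes.tsv")
    pheno = (
        pd.read_csv(pheno_path, sep="\t").set_index("subject_id")
        if os.path.exists(pheno_path)
        else None
    )
    ts, motion = {}, {}
    for sid in cohort.subject_ids:
        ts_path = os.path.join(dd, f"{sid}_ts.tsv")
        mo_path = os.path.join(dd, f"{sid}_motion.tsv")
        if os.path.exists(ts_path):
            ts[sid] = RoiTimeSeries.from_tsv(ts_path, tr=cfg.tr, subject_id=sid)
        if os.path.exists(mo_path):
            motion[sid] = pd.read_csv(mo_path, sep="\t")
    return cohort, events, pheno, ts, motion


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Outputs are written under ``config.out_dir``: exclusion_report.json,
    per-subject FC matrices, ace_map.tsv, fwe.tsv, clusters.json, nbs.tsv
    and manifest.json.
    """
    if (config.fc or config.nbs) and not os.path.exists(
        os.path.join(config.data_dir, "events.tsv")
    ):
        raise ValueError("FC/NBS stages require an events.tsv in data_dir")
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"twinconn": __version__, "numpy": np.__version__},
        "stages": {},
        "warnings": [],
    }
    cohort, events, pheno, ts, motion = _load_dataset(config)

    if config.qc:
        rows = []
        for sid in cohort.subject_ids:
            has_data = sid in ts and sid in motion and (pheno is None or sid in pheno.index)
            hm = (
                high_motion_flag(
                    framewise_displacement(motion[sid]), config.fd_thresh, config.fd_prop
                )
                if sid in motion
                else False
            )
            summary = float(pheno.loc[sid].mean()) if pheno is not None and sid in pheno.index else np.nan
            rows.append(
                {
                    "subject_id": sid,
                    "high_motion": hm,
                    "outlier_summary": summary,
                    "missing": not has_data,
                }
            )
        cohort, report = apply_exclusions(cohort, pd.DataFrame(rows), mad_k=config.mad_k)
        report.to_json(os.path.join(config.out_dir, "exclusion_report.json"))
        manifest["stages"]["qc"] = {
            "n_recruited": report.n_recruited,
            "n_final": report.n_final,
        }

    fc_stack = None
    if config.fc:
        keep_ts = {sid: ts[sid] for sid in cohort.subject_ids if sid in ts}
        fc_stack = contrast_fc_stack(
            keep_ts,
            events,
            motion={sid: motion[sid] for sid in keep_ts},
            band=(config.band_low, config.band_high),
            fd_scrub_thresh=config.fd_thresh,
        )
        fc_stack.save_dir(os.path.join(config.out_dir, "fc"))
        manifest["stages"]["fc"] = {
            "n_subjects": fc_stack.n_subjects,
            "n_nodes": fc_stack.n_nodes,
        }

    if config.ace and pheno is not None:
        sub = pheno.loc[[s for s in cohort.subject_ids if s in pheno.index]]
        ace_map = lrsd_ace(sub, cohort.subset(sub.index))
        ace_map.to_csv(os.path.join(config.out_dir, "ace_map.tsv"), sep="\t")
        manifest["stages"]["ace"] = {"n_elements": len(ace_map)}

    if config.fwe and pheno is not None:
        sub = pheno.loc[[s for s in cohort.subject_ids if s in pheno.index]]
        sub_cohort = cohort.subset(sub.index)
        scheme = PermutationScheme(n_perm=config.n_perm, seed=stage_seed(config.seed, "fwe"))
        fwe = elementwise_fwe(sub, sub_cohort, scheme)
        fwe.to_csv(os.path.join(config.out_dir, "fwe.tsv"), sep="\t")
        # default element adjacency: a chain in element order
        n_el = sub.shape[1]
        from scipy import sparse

        adj = sparse.diags([1.0, 1.0], offsets=[-1, 1], shape=(n_el, n_el)).tocsr()
        clusters = cluster_fwe(sub, sub_cohort, adj, scheme, forming_p=config.forming_p)
        with open(os.path.join(config.out_dir, "clusters.json"), "w") as fh:
            json.dump(
                [
                    {"cluster_id": c.cluster_id, "extent": c.extent, "fwe_p": c.fwe_p,
                     "members": [int(m) for m in c.members]}
                    for c in clusters
                ],
                fh,
                indent=2,
            )
        manifest["stages"]["fwe"] = {
            "n_elements": int(n_el),
            "n_clusters": len(clusters),
        }

    if config.nbs and fc_stack is not None:
        sweep = threshold_sweep(
            fc_stack,
            cohort.subset(fc_stack.subject_ids),
            config.tau_grid,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "nbs"),
        )
        sweep.to_csv(os.path.join(config.out_dir, "nbs.tsv"), sep="\t", index=False)
        manifest["stages"]["nbs"] = {"n_thresholds": len(sweep)}

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def make_demo_dataset(
    outdir,
    seed: int,
    n_mz: int = 40,
    n_dz: int = 40,
    n_nodes: int = 30,
    n_elements: int = 20,
) -> dict:
    """Write a small synthetic dataset exercising every pipeline stage.

    Plants heritable signal on the first 5 phenotype elements and on a
    5-node connected set of FC edges, and injects one high-motion pair and
    one amplitude-outlier pair for the QC stage to catch. Ground truth is
    recorded in ground_truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    cohort = simulate_cohort(n_mz, n_dz, seed=stage_seed(seed, "cohort"))
    cohort.to_tsv(os.path.join(outdir, "cohort.tsv"))
    events = simulate_task_events(seed=stage_seed(seed, "events"))
    save_events(events, os.path.join(outdir, "events.tsv"))

    planted_elems = list(range(5))
    params = [
        ACEParams(0.6, 0.1, 0.3) if k in planted_elems else ACEParams(0.0, 0.2, 0.8)
        for k in range(n_elements)
    ]
    pheno = simulate_ace_phenotypes(cohort, params, seed=stage_seed(seed, "pheno"))

    sids = list(cohort.subject_ids)
    outlier_pair = sids[2:4]  # one full pair becomes an amplitude outlier
    pheno.loc[outlier_pair] += 40.0
    pheno.reset_index().to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False)

    boosted = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)]
    ts, motion = simulate_roi_timeseries(
        cohort,
        events,
        n_nodes=n_nodes,
        tr=2.4,
        condition_edge_boost=1.0,
        pair_share=ACEParams(0.6, 0.1, 0.3),
        seed=stage_seed(seed, "timeseries"),
        boosted_edges=boosted,
    )
    motion_pair = sids[0:2]  # one full pair with pervasive high motion
    for sid in motion_pair:
        m = motion[sid].to_numpy()
        m[:, 0] += np.where(np.arange(len(m)) % 2 == 0, 0.0, 1.0)  # 1 mm alternating jumps
        motion[sid] = pd.DataFrame(m, columns=motion[sid].columns)
    for sid in sids:
        ts[sid].to_tsv(os.path.join(outdir, f"{sid}_ts.tsv"))
        motion[sid].to_csv(os.path.join(outdir, f"{sid}_motion.tsv"), sep="\t", index=False)

    truth = {
        "planted_elements": planted_elems,
        "planted_element_params": {"A": 0.6, "C": 0.1, "E": 0.3},
        "boosted_edges": boosted,
        "high_motion_subjects": motion_pair,
        "outlier_subjects": outlier_pair,
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
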