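"""End-to-end analysis orchestration.

``run_full_analysis`` drives the whole flow on synthetic or simulated
data: generate per-fish activity, compute cosine/dE/dM matrices with their
label-shuffle controls, estimate per-pair manifold capacity and effective
measures (with shuffle control), compare naive against trained groups,
and correlate capacity with a synthetic behavioral discrimination score.
Every stage is seeded from the master seed and logged; outputs are labeled
CSVs plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity import CapacityProtocol, capacity_pair, capacity_pipeline
from .dataset import ActivityDataset
from .geometry import (
    WindowSpec,
    build_manifolds,
    cosine_distance_matrix,
    distance_matrix,
)
from .panel import default_panel
from .stats import (
    compare_groups_mwu,
    discrimination_score,
    generate_behavior_records,
    ols_correlation,
)
from .synthetic import GeometrySpec, generate_imaging_dataset

__all__ = ["ExperimentConfig", "ReportBundle", "run_full_analysis"]


@dataclass
class ExperimentConfig:
    """Configuration of a full analysis run (exactly one data source)."""

    source: str = "synthetic"           # "synthetic" | "simulated" | "file"
    activity_path: str | None = None    # for source = "file"
    n_naive: int = 3                    # virtual fish per group
    n_trained: int = 4
    geometry: dict = field(default_factory=dict)       # GeometrySpec overrides
    simulator: dict = field(default_factory=dict)      # PDpNetwork settings
    window: dict = field(default_factory=dict)         # WindowSpec fields
    distances: dict = field(
        default_factory=lambda: {"n_neurons": 70, "n_repeats": 10,
                                 "n_shuffles": 10}
    )
    capacity: dict = field(
        default_factory=lambda: {
            "n_neurons_subsample": 700, "n_patterns_subsample": 140,
            "n_repeats": 3, "n_gaussian_samples": 50,
        }
    )
    behavior: dict = field(
        default_factory=lambda: {"n_trials": 9, "n_days": 3,
                                 "cs_offset": 0.5, "noise": 1.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.source not in ("synthetic", "simulated", "file"):
            raise ValueError("source must be synthetic, simulated or file")
        if self.source == "file" and not self.activity_path:
            raise ValueError("source 'file' needs activity_path")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables produced by a run, plus the manifest."""

    out_dir: Path
    distance_tables: dict = field(default_factory=dict)
    capacity_table: pd.DataFrame | None = None
    capacity_shuffled: pd.DataFrame | None = None
    group_stats: pd.DataFrame | None = None
    behavior_table: pd.DataFrame | None = None
    behavior_correlation: dict | None = None
    manifest: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr, flush=True)


def _spawn(master: np.random.SeedSequence, n: int) -> list:
    return [int(s % 2**31) for s in master.generate_state(n)]


def _make_datasets(config: ExperimentConfig, master) -> tuple[list, list]:
    """Per-fish activity datasets for the naive and trained groups."""
    if config.source == "file":
        ds = ActivityDataset.load(config.activity_path)
        return [ds], []
    if config.source == "simulated":
        from .network import PDpNetwork
        from .synthetic import generate_mitral_patterns

        sim = dict(config.simulator)
        panel = default_panel()
        pattern = generate_mitral_patterns(
            n_mitral=sim.get("n_mitral", 1500), panel=panel,
            seed=sim.get("pattern_seed", 1),
        )
        presets = sim.get("presets", ["A"])
        n_inst = sim.get("instantiations", 2)
        n_trials = sim.get("n_trials", 4)
        window = sim.get("response_window", 2.0)
        memories = sim.get("memories", ["A1", "A2"])
        naive, trained = [], []
        seeds = _spawn(master, len(presets) * n_inst)
        k = 0
        for preset in presets:
            for _ in range(n_inst):
                net = PDpNetwork(preset=preset, seed=seeds[k])
                naive.append(
                    net.simulate_panel(pattern, panel, n_trials=n_trials,
                                       response_window=window, seed=seeds[k])
                )
                mem = net.store_memories(pattern, memories)
                trained.append(
                    mem.simulate_panel(pattern, panel, n_trials=n_trials,
                                       response_window=window, seed=seeds[k])
                )
                k += 1
        return naive, trained
    # synthetic
    panel = default_panel()
    base = dict(config.geometry)
    naive_seeds = _spawn(master, config.n_naive)
    trained_seeds = _spawn(master, config.n_trained)
    naive = [
        generate_imaging_dataset(GeometrySpec(regime="naive", **base), panel, s)
        for s in naive_seeds
    ]
    trained = [
        generate_imaging_dataset(GeometrySpec(regime="trained", **base), panel, s)
        for s in trained_seeds
    ]
    return naive, trained


def run_full_analysis(config: ExperimentConfig, out_dir) -> ReportBundle:
    """Execute every stage; abort with the stage name on failure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    bundle = ReportBundle(out_dir)
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "data"
    try:
        t0 = time.time()
        naive, trained = _make_datasets(config, master)
        groups = {"naive": naive, "trained": trained}
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] {len(naive)} naive + {len(trained)} trained datasets "
             f"({manifest['stages'][stage]} s)")

        window = WindowSpec(**config.window) if config.window else None

        stage = "cosine"
        t0 = time.time()
        for gname, dsets in groups.items():
            if not dsets:
                continue
            mats = [
                cosine_distance_matrix(ds, "odor-odor").values for ds in dsets
            ]
            mean = sum(mats) / len(mats)
            path = out_dir / f"cosine_{gname}.csv"
            mean.to_csv(path)
            bundle.distance_tables[f"cosine_{gname}"] = mean
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] done ({manifest['stages'][stage]} s)")

        stage = "distances"
        t0 = time.time()
        dist_seeds = _spawn(master, 4 * (len(naive) + len(trained)) + 4)
        si = iter(dist_seeds)
        dp = dict(config.distances)
        n_shuffles = dp.pop("n_shuffles", 10)
        for metric in ("dE", "dM"):
            for gname, dsets in groups.items():
                if not dsets:
                    continue
                mats, smats = [], []
                for ds in dsets:
                    mans = build_manifolds(ds, window)
                    mats.append(
                        distance_matrix(mans, metric, seed=next(si), **dp).values
                    )
                    smats.append(
                        distance_matrix(
                            mans, metric, seed=next(si), shuffle=True,
                            n_shuffles=n_shuffles, **dp
                        ).values
                    )
                mean = sum(mats) / len(mats)
                smean = sum(smats) / len(smats)
                mean.to_csv(out_dir / f"{metric}_{gname}.csv")
                smean.to_csv(out_dir / f"{metric}_{gname}_shuffled.csv")
                bundle.distance_tables[f"{metric}_{gname}"] = mean
                bundle.distance_tables[f"{metric}_{gname}_shuffled"] = smean
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] done ({manifest['stages'][stage]} s)")

        stage = "capacity"
        t0 = time.time()
        proto = CapacityProtocol(**config.capacity)
        proto_sh = CapacityProtocol(**{**config.capacity, "shuffle": True})
        cap_rows, shuf_rows = [], []
        cap_seeds = _spawn(master, 2 * (len(naive) + len(trained)))
        ci = iter(cap_seeds)
        for gname, dsets in groups.items():
            for i, ds in enumerate(dsets):
                fid = f"{gname}{i}"
                t = capacity_pipeline(ds, proto, window, next(ci), fid)
                t["group"] = gname
                cap_rows.append(t)
                ts = capacity_pipeline(ds, proto_sh, window, next(ci), fid)
                ts["group"] = gname
                shuf_rows.append(ts)
        bundle.capacity_table = pd.concat(cap_rows, ignore_index=True)
        bundle.capacity_shuffled = pd.concat(shuf_rows, ignore_index=True)
        bundle.capacity_table.to_csv(out_dir / "capacity.csv", index=False)
        bundle.capacity_shuffled.to_csv(
            out_dir / "capacity_shuffled.csv", index=False
        )
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] done ({manifest['stages'][stage]} s)")

        stage = "stats"
        t0 = time.time()
        rows = []
        cap = bundle.capacity_table
        if (cap["group"] == "naive").any() and (cap["group"] == "trained").any():
            for measure in ("alpha", "radius", "dimension", "center_align",
                            "axes_align", "center_axes_align"):
                res = compare_groups_mwu(
                    cap.loc[cap.group == "naive", measure],
                    cap.loc[cap.group == "trained", measure],
                    "naive", "trained",
                )
                rows.append(
                    {
                        "measure": measure,
                        "naive_mean": float(cap.loc[cap.group == "naive", measure].mean()),
                        "trained_mean": float(cap.loc[cap.group == "trained", measure].mean()),
                        "U": res.statistic,
                        "p": res.p_value,
                        "stars": res.stars,
                    }
                )
        bundle.group_stats = pd.DataFrame(rows)
        bundle.group_stats.to_csv(out_dir / "group_stats.csv", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] done ({manifest['stages'][stage]} s)")

        stage = "behavior"
        t0 = time.time()
        cap = bundle.capacity_table
        trained_ids = sorted(cap.loc[cap.group == "trained", "subject"].unique())
        if len(trained_ids) >= 3:
            bp = dict(config.behavior)
            records = generate_behavior_records(
                len(trained_ids), seed=_spawn(master, 1)[0], **bp
            )
            cs_mask = (
                (cap.odor_a.isin(["A1", "A2"])) & (cap.odor_b.isin(["A1", "A2"]))
            )
            rows = []
            for fid, rec in zip(trained_ids, records):
                sub = cap[(cap.subject == fid) & cs_mask]
                rows.append(
                    {
                        "subject": fid,
                        "discrimination_score": discrimination_score(rec),
                        "alpha_cs": float(sub["alpha"].mean()),
                    }
                )
            bt = pd.DataFrame(rows)
            bundle.behavior_table = bt
            bundle.behavior_correlation = ols_correlation(
                bt["alpha_cs"], bt["discrimination_score"]
            )
            bt.to_csv(out_dir / "behavior.csv", index=False)
            (out_dir / "behavior_correlation.json").write_text(
                json.dumps(bundle.behavior_correlation, indent=1)
            )
        manifest["stages"][stage] = round(time.time() - t0, 2)
        bundle.stages_completed.append(stage)
        _log(f"[{stage}] done ({manifest['stages'][stage]} s)")
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    bundle.manifest = manifest
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
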