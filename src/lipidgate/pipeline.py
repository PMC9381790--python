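"""End-to-end orchestration: config, stages, reproducible report bundles.

A :class:`RunConfig` (YAML-loadable) names the inputs — either a synthetic
preset or trajectory files on disk — and the analysis parameters (6 Å
salt-bridge cutoff, 10 Å proximity cutoff, the [10, 16) Å lift bins, mound
and ladder settings, a frame window such as ``last:0.5`` for the final half
of each replica).  :func:`run` executes a stage (or ``all``) and writes
deterministic TSV/JSON/PDB reports, each carrying the config hash, so two
runs from the same config, inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import domains, homology, lift, saltbridges, synth
from .structio import Trajectory, read_structure, read_trajectory, write_trajectory

__all__ = ["RunConfig", "ConfigError", "run", "window_indices"]

log = logging.getLogger("lipidgate")
STAGES = ("synth", "domains", "lift", "saltbridge", "ladder", "homology", "all")


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation."""


@dataclass
class RunConfig:
    outdir: str = "lipidgate_out"
    seed: int = 0
    # inputs: a synthetic preset ("occupancy" | "ladder" | "flat") or files
    synth_preset: str = "occupancy"
    n_replicas: int = 3
    n_frames: int = 1000
    n_lipids: int = 128
    topology_path: str | None = None
    trajectory_paths: tuple[str, ...] = ()
    # analysis parameters
    cutoff_A: float = 6.0
    proximity_A: float = 10.0
    bin_lo_A: float = 10.0
    bin_hi_A: float = 16.0
    bin_width_A: float = 1.0
    mound_min_height_A: float = 10.0
    mound_radius_A: float = 10.0
    mound_min_size: int = 3
    sustain_frames: int = 2
    frame_window: str = "all"
    residues: str = "charged_gateway"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "trajectory_paths" in data:
            data["trajectory_paths"] = tuple(data["trajectory_paths"])
        return cls(**data)

    def validate(self) -> None:
        problems = []
        for key in ("cutoff_A", "proximity_A", "bin_width_A", "mound_min_height_A",
                    "mound_radius_A"):
            if getattr(self, key) <= 0:
                problems.append(f"{key} must be positive, got {getattr(self, key)}")
        if self.bin_hi_A <= self.bin_lo_A:
            problems.append("bin_hi_A must exceed bin_lo_A")
        if self.mound_min_size < 1:
            problems.append("mound_min_size must be >= 1")
        if self.sustain_frames < 1:
            problems.append("sustain_frames must be >= 1")
        if self.n_replicas < 1:
            problems.append("n_replicas must be >= 1")
        if self.synth_preset not in ("occupancy", "ladder", "flat") and not self.trajectory_paths:
            problems.append(f"unknown synth preset {self.synth_preset!r}")
        try:
            _parse_window(self.frame_window)
        except ValueError as exc:
            problems.append(str(exc))
        if problems:
            raise ConfigError("invalid config: " + "; ".join(problems))

    def config_hash(self) -> str:
        # the output directory is not part of the analysis identity
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_window(spec: str) -> tuple[str, float, float]:
    if spec == "all":
        return ("all", 0.0, 0.0)
    kind, _, rest = spec.partition(":")
    try:
        if kind == "last":
            frac = float(rest)
            if not 0 < frac <= 1:
                raise ValueError
            return ("last", frac, 0.0)
        if kind in ("ns", "frames"):
            a, b = rest.split(":")
            return (kind, float(a), float(b))
    except ValueError:
        pass
    raise ValueError(
        f"bad frame_window {spec!r}; use 'all', 'last:<frac>', 'ns:<a>:<b>' or 'frames:<a>:<b>'"
    )


def window_indices(traj: Trajectory, spec: str) -> list[int]:
    """Frame indices selected by a window spec.

    ``last:0.5`` selects the final half of the frames — the convention used
    to analyse the last 5 µs of a 10 µs run.
    """
    kind, a, b = _parse_window(spec)
    n = len(traj)
    if kind == "all":
        return list(range(n))
    if kind == "last":
        start = n - int(round(n * a))
        return list(range(start, n))
    if kind == "frames":
        return list(range(int(a), min(int(b), n)))
    times = traj.times_ns
    return [i for i in range(n) if a <= times[i] < b]


def _stamp(cfg: RunConfig) -> str:
    return f"# config_hash={cfg.config_hash()}\n"


def _load_replicas(cfg: RunConfig) -> tuple[list[Trajectory], list[synth.GroundTruth | None]]:
    if cfg.trajectory_paths:
        if cfg.topology_path is None:
            raise ConfigError("trajectory_paths given without topology_path")
        topo = read_structure(cfg.topology_path)
        trajs = [read_trajectory(p, topo) for p in cfg.trajectory_paths]
        return trajs, [None] * len(trajs)
    trajs, truths = [], []
    for r in range(cfg.n_replicas):
        spec = _synth_spec(cfg, cfg.seed + r)
        traj, truth = synth.simulate(spec)
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths


def _synth_spec(cfg: RunConfig, seed: int) -> synth.SyntheticSpec:
    if cfg.synth_preset == "occupancy":
        return synth.occupancy_spec(seed=seed, n_frames=cfg.n_frames, n_lipids=cfg.n_lipids)
    if cfg.synth_preset == "ladder":
        return synth.ladder_spec(seed=seed, n_frames=cfg.n_frames, n_lipids=cfg.n_lipids)
    return synth.flat_spec(seed=seed, n_frames=cfg.n_frames, n_lipids=cfg.n_lipids)


def _residue_set(cfg: RunConfig) -> domains.ResidueSet:
    if cfg.residues == "charged_gateway":
        return domains.CHARGED_GATEWAY
    return domains.parse_range_string(cfg.residues, name="residues")


def run(config: RunConfig, stage: str = "all") -> dict[str, Path]:
    """Execute a pipeline stage; returns the written report paths."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    log.info("config hash %s", config.config_hash())
    log.info("config %s", json.dumps(asdict(config), sort_keys=True, default=str))
    outputs: dict[str, Path] = {}
    stages = [s for s in STAGES[:-1]] if stage == "all" else [stage]

    trajs: list[Trajectory] | None = None
    truths: list[synth.GroundTruth | None] | None = None

    def replicas() -> tuple[list[Trajectory], list[synth.GroundTruth | None]]:
        nonlocal trajs, truths
        if trajs is None:
            trajs, truths = _load_replicas(config)
            for i, t in enumerate(trajs):
                w = window_indices(t, config.frame_window)
                log.info("replica %d: %d frames, %d in window %r",
                         i, len(t), len(w), config.frame_window)
        return trajs, truths

    for s in stages:
        if s == "synth":
            ts, tr = replicas()
            if not config.trajectory_paths:
                for i, (t, truth) in enumerate(zip(ts, tr)):
                    p = outdir / f"replica_{i}.xyz"
                    write_trajectory(t, p)
                    outputs[f"trajectory_{i}"] = p
                    if truth is not None:
                        q = outdir / f"truth_{i}.json"
                        synth.write_truth(truth, q)
                        outputs[f"truth_{i}"] = q
        elif s == "domains":
            p = outdir / "domains.tsv"
            lines = [_stamp(config) + "domain\tmembers\tsize"]
            catalog = {
                "gateway": domains.GATEWAY,
                "annulus": domains.ANNULUS,
                "orifice_fig1": domains.ORIFICE_FIG1,
                "orifice_results": domains.ORIFICE_RESULTS,
                "charged_gateway": domains.CHARGED_GATEWAY,
            }
            for name, rs in catalog.items():
                nums = ";".join(str(r) for r in rs.residue_numbers())
                lines.append(f"{name}\t{nums}\t{len(rs)}")
            lines.append(
                "gateway_annulus_union\t-\t"
                f"{domains.union_size(domains.GATEWAY, domains.ANNULUS)}"
            )
            p.write_text("\n".join(lines) + "\n")
            outputs["domains"] = p
        elif s == "lift":
            ts, _ = replicas()
            per = []
            for t in ts:
                w = window_indices(t, config.frame_window)
                edges = np.arange(config.bin_lo_A, config.bin_hi_A + config.bin_width_A / 2,
                                  config.bin_width_A)
                per.append(lift.lift_histogram(t, frame_window=w, bin_edges=edges))
            pooled = per[0]
            counts = np.sum([h.counts for h in per], axis=0)
            p = outdir / "lift_histogram.tsv"
            body = ["bin_lo\tbin_hi\tcount"]
            for lo, hi, c in zip(pooled.bin_edges[:-1], pooled.bin_edges[1:], counts):
                body.append(f"{lo:g}\t{hi:g}\t{int(c)}")
            p.write_text(_stamp(config) + "\n".join(body) + "\n")
            outputs["lift_histogram"] = p
        elif s == "saltbridge":
            ts, _ = replicas()
            w = window_indices(ts[0], config.frame_window)
            table = saltbridges.occupancy(
                ts, _residue_set(config), cutoff_A=config.cutoff_A, frame_window=w)
            p = outdir / "occupancy.tsv"
            with p.open("w") as fh:
                fh.write(_stamp(config))
                table.to_csv(fh, sep="\t", index=False)
            outputs["occupancy"] = p
        elif s == "ladder":
            cfg_l = config if config.synth_preset == "ladder" or config.trajectory_paths \
                else _ladder_variant(config)
            spec = _synth_spec(cfg_l, cfg_l.seed)
            if config.trajectory_paths:
                ts, _ = replicas()
                t = ts[0]
            else:
                t, _ = synth.simulate(spec)
            trace = lift.track_extracted(t, domains.GATEWAY,
                                         min_height_A=config.mound_min_height_A)
            p = outdir / "ladder.json"
            if trace is None:
                payload = {"config_hash": config.config_hash(), "trace": None, "steps": []}
            else:
                report = saltbridges.ladder(trace, t, cutoff_A=config.cutoff_A,
                                            sustain_frames=config.sustain_frames)
                payload = {
                    "config_hash": config.config_hash(),
                    "trace": {"lipid": list(trace.lipid),
                              "n_lifted_frames": trace.n_lifted_frames},
                    "steps": [
                        {"residue": list(st.residue), "first_frame": st.first_frame,
                         "dz_at_onset": st.dz_at_onset}
                        for st in report.steps
                    ],
                    "absent": [list(r) for r in report.absent],
                    "matches_expected_order": report.matches_expected_order,
                }
            p.write_text(json.dumps(payload, indent=1))
            outputs["ladder"] = p
        elif s == "homology":
            p_pdb = outdir / "threaded.pdb"
            p_tsv = outdir / "clash_report.tsv"
            model = _demo_threading()
            from .structio import write_structure

            write_structure(model.structure, p_pdb)
            with p_pdb.open("a") as fh:
                fh.write(f"REMARK config_hash={config.config_hash()}\n")
            p_tsv.write_text(_stamp(config) + homology.clash_report_tsv(model))
            outputs["threaded_model"] = p_pdb
            outputs["clash_report"] = p_tsv
    manifest = outdir / "run_log.json"
    manifest.write_text(json.dumps({
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stage": stage,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }, indent=1, default=str))
    outputs["run_log"] = manifest
    return outputs


def _ladder_variant(config: RunConfig) -> RunConfig:
    import dataclasses

    return dataclasses.replace(config, synth_preset="ladder",
                               n_frames=min(config.n_frames, 400))


def _demo_threading() -> homology.ThreadedModel:
    """A small self-contained threading demonstration on an ideal helix."""
    from .toyfold import ideal_helix

    template = ideal_helix("AKLAVELAKG", chain_id="T")
    amap = homology.map_alignment(("AKLAVKLAKG", "AKLAVELAKG"))
    target_seq = {i + 1: c for i, c in enumerate("AKLAVKLAKG")}
    model = homology.thread_backbone(template, amap, target_seq)
    homology.place_all_side_chains(model)
    return model
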