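"""End-to-end analysis orchestration from a config file.

A run executes, in order: pocket openness -> EF-site expansion -> prong
distances -> beta-scaffold H-bonds -> RMSF -> virtual dihedrals ->
hydrophobic contact panel.  Each stage emits a per-frame CSV and
contributes to a machine-readable JSON summary; a failing stage is
recorded in a status table without silencing the others.  Outputs embed
the SHA-256 hash of the canonical config so every table is traceable to
the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flexibility, hbonds, metrics, packing, rotation
from .structure_io import Selection, Trajectory, read_structure, read_trajectory

__all__ = ["RunConfig", "StageResult", "ReportBundle", "run_analysis", "write_report"]

log = logging.getLogger("tnswitch")


@dataclass
class RunConfig:
    """Everything a reproducible analysis run needs."""

    trajectory: str
    reference_structure: str | None = None
    trajectory_format: str = "multi-model-pdb"
    tnc_chain: str = "A"
    tni_chain: str | None = None
    tnt_chain: str | None = None
    pocket_residues: tuple[int, int] = (16, 48)
    site_starts: tuple[int, int] = (29, 65)
    closed_max: float = 14.5
    semi_closed_max: float = 18.0
    hbond_formed_hn: float = 2.5
    hbond_formed_heavy: float = 3.5
    hbond_min_dwell: int = 5
    contact_cutoff: float = 4.5
    rmsf_residue_range: tuple[int, int] = (5, 80)
    window_last_n: int | None = None  # None -> final quarter of the frames
    start_window_n: int | None = None  # None -> same size as end window
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pocket_residues", "site_starts", "rmsf_residue_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("pocket_residues", "site_starts", "rmsf_residue_range"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        """Collect every problem at once before any stage runs."""
        problems: list[str] = []
        if not Path(self.trajectory).exists():
            problems.append(f"trajectory file not found: {self.trajectory}")
        if self.reference_structure and not Path(self.reference_structure).exists():
            problems.append(
                f"reference structure not found: {self.reference_structure}"
            )
        for name in ("closed_max", "semi_closed_max", "hbond_formed_hn",
                     "hbond_formed_heavy", "contact_cutoff"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.closed_max >= self.semi_closed_max:
            problems.append("closed_max must be below semi_closed_max")
        if self.hbond_min_dwell < 1:
            problems.append("hbond_min_dwell must be >= 1")
        if problems:
            raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))


@dataclass
class StageResult:
    name: str
    status: str  # "ok" | "error"
    seconds: float
    summary: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    events: list = field(default_factory=list)
    error: str = ""


@dataclass
class ReportBundle:
    config: RunConfig
    stages: list[StageResult]
    n_frames: int


def _series_frame(series_map: dict[str, metrics.MetricSeries]) -> pd.DataFrame:
    first = next(iter(series_map.values()))
    df = pd.DataFrame({"frame": first.frame_indices})
    for name, s in series_map.items():
        df[name] = s.values
    return df


def _windows(cfg: RunConfig, n_frames: int):
    n_end = cfg.window_last_n or max(1, n_frames // 4)
    n_start = cfg.start_window_n or n_end
    end = ("last_n_frames", min(n_end, n_frames))
    start = ("frame_range", 0, min(n_start, n_frames) - 1)
    return start, end


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage; individual failures never abort the run."""
    config.validate()
    traj = read_trajectory(config.trajectory, config.trajectory_format)
    if config.reference_structure:
        read_structure(config.reference_structure)  # validated, reserved for fits
    chain = config.tnc_chain
    start_w, end_w = _windows(config, traj.n_frames)
    thresholds = metrics.PocketStateThresholds(config.closed_max, config.semi_closed_max)

    stages: list[StageResult] = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            summary, tables, events = fn()
            res = StageResult(name, "ok", time.perf_counter() - t0, summary, tables, events)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            res = StageResult(name, "error", time.perf_counter() - t0, error=f"{type(exc).__name__}: {exc}")
            log.warning("stage %s failed: %s", name, res.error)
        log.info("stage %-18s %-5s frames=%d wall=%.2fs", name, res.status, traj.n_frames, res.seconds)
        stages.append(res)

    def pocket():
        s = metrics.pocket_openness_series(traj, *config.pocket_residues, chain=chain)
        sm, ssd = metrics.window_stats(s, start_w)
        em, esd = metrics.window_stats(s, end_w)
        summary = {
            "start_window": {"mean": sm, "sd": ssd, "state": metrics.classify_pocket_state(sm, thresholds)},
            "end_window": {"mean": em, "sd": esd, "state": metrics.classify_pocket_state(em, thresholds)},
            "thresholds": {"closed_max": thresholds.closed_max, "semi_closed_max": thresholds.semi_closed_max},
        }
        return summary, {"pocket_openness": _series_frame({"d": s})}, []

    def expansion():
        tables, summary = {}, {}
        for start, sid in zip(config.site_starts, ("I", "II")):
            site = metrics.EFSiteDefinition(sid, start, chain)
            s = metrics.site_expansion_series(traj, site)
            m, sd = metrics.window_stats(s, end_w)
            summary[f"site_{sid}"] = {"end_mean": m, "end_sd": sd}
            tables[f"site_{sid}_expansion"] = _series_frame({"span": s})
        return summary, tables, []

    def prong():
        tables, summary, events = {}, {}, []
        for start, sid in zip(config.site_starts, ("I", "II")):
            site = metrics.EFSiteDefinition(sid, start, chain)
            series = metrics.prong_distance_series(traj, site)
            tables[f"site_{sid}_prong"] = _series_frame(series)
            for key in ("N2-OE", "N9-OE"):
                evts = hbonds.detect_transitions(
                    series[key], config.hbond_formed_heavy, config.hbond_min_dwell
                )
                events += [
                    {"pair": f"site_{sid}_{key}", "kind": e.kind, "frame": e.frame}
                    for e in evts
                ]
                m, sd = metrics.window_stats(series[key], end_w)
                summary[f"site_{sid}_{key}"] = {
                    "end_mean": m,
                    "end_sd": sd,
                    "formed_fraction": float(np.mean(series[key].values <= config.hbond_formed_heavy)),
                }
        return summary, tables, events

    def beta():
        rep = hbonds.beta_scaffold_report(traj, chain, config.hbond_formed_hn)
        tables = {"beta_scaffold": _series_frame({k: v["series"] for k, v in rep.items()})}
        summary, events = {}, []
        for label, entry in rep.items():
            summary[label] = {"formed_fraction": entry["formed_fraction"]}
            evts = hbonds.detect_transitions(
                entry["series"], config.hbond_formed_hn, config.hbond_min_dwell
            )
            events += [{"pair": label, "kind": e.kind, "frame": e.frame} for e in evts]
        return summary, tables, events

    def rmsf():
        sel = Selection(chain=chain, residue_range=config.rmsf_residue_range,
                        atom_names=frozenset({"CA"}))
        prof = flexibility.rmsf_profile(traj, analyze=sel, chain=chain)
        df = pd.DataFrame({"residue": prof.residue_numbers, "rmsf": prof.rmsf})
        return (
            {"mean_rmsf": float(prof.rmsf.mean()), "max_rmsf": float(prof.rmsf.max())},
            {"rmsf": df},
            [],
        )

    def dihedrals():
        tables, summary = {}, {}
        for vd in (rotation.VD1(chain), rotation.VD2(chain)):
            s = rotation.virtual_dihedral_series(traj, vd)
            tables[f"virtual_dihedral_{vd.label}"] = _series_frame({"angle_deg": s})
            sm, _ = metrics.window_stats(s, start_w)
            em, _ = metrics.window_stats(s, end_w)
            delta = (em - sm + 180.0) % 360.0 - 180.0
            summary[vd.label] = {"start_mean": sm, "end_mean": em, "delta_deg": delta}
        return summary, tables, []

    def contacts():
        panel = packing.default_contact_panel(chain, config.contact_cutoff)
        series = {}
        for pair in panel:
            try:
                series[pair.label] = packing.min_heavy_distance_series(traj, pair)
            except (ValueError, KeyError):
                continue  # residue absent or side-chain-less in this topology
        if not series:
            raise ValueError("no contact-panel residue pair is resolvable")
        persistence = {
            label: float(np.mean(s.values <= config.contact_cutoff))
            for label, s in series.items()
        }
        return (
            {"persistence": persistence, "cutoff": config.contact_cutoff},
            {"contact_panel": _series_frame(series)},
            [],
        )

    run_stage("pocket", pocket)
    run_stage("site_expansion", expansion)
    run_stage("prong", prong)
    run_stage("beta_scaffold", beta)
    run_stage("rmsf", rmsf)
    run_stage("virtual_dihedrals", dihedrals)
    run_stage("hydrophobic_panel", contacts)
    return ReportBundle(config, stages, traj.n_frames)


def write_report(bundle: ReportBundle, outdir: str) -> Path:
    """Write metrics/*.csv, summary.json, events.json, run.log and the
    echoed config under ``outdir``."""
    out = Path(outdir)
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)
    chash = bundle.config.config_hash

    events = []
    summary = {
        "config_hash": chash,
        "n_frames": bundle.n_frames,
        "stages": {},
    }
    log_lines = []
    for stage in bundle.stages:
        summary["stages"][stage.name] = {
            "status": stage.status,
            **({"summary": stage.summary} if stage.status == "ok" else {"error": stage.error}),
        }
        log_lines.append(
            f"stage {stage.name}: {stage.status} frames={bundle.n_frames} "
            f"wall={stage.seconds:.2f}s"
        )
        for tname, df in stage.tables.items():
            path = metrics_dir / f"{tname}.csv"
            with open(path, "w", newline="") as fh:
                fh.write(f"# config {chash}\n")
                df.to_csv(fh, index=False)
        events += stage.events

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "events.json").write_text(json.dumps(events, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "config.echo.yaml").write_text(bundle.config.to_yaml())
    return out
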