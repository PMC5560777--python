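"""Configuration-driven orchestration with reproducible, logged runs.

A run is described by a YAML mapping (see ``validate_config``); outputs are
TSV tables plus a JSON manifest recording the config hash, package version
and seed.  Reruns with identical config and inputs produce byte-identical
result tables (the manifest timestamp is the only run-specific field).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .association import association_score_series
from .assays import (
    CurrentTrace,
    FluxTrace,
    ProtocolEvent,
    ba_sensitive_current,
    current_density,
    fractional_inhibition,
    percent_change_vs_basal,
    relative_flux,
)
from .errors import ConfigError, PipgateError
from .gating import detect_dewetting, hbc_diameter, water_density_profile
from .hbonds import DEFAULT_PAIRS, HBondCriteria, hbond_probability, pair_timeseries
from .structures import (
    ResidueRoleMap,
    assign_pockets,
    pocket_ca_rmsd,
    read_structure,
    read_trajectory,
)
from .synthetic import TrajectoryScript, WaterScript, all_bonded_schedule, generate_channel_trajectory

log = logging.getLogger("pipgate")

_ANALYSES = ("hbonds", "association", "gate", "hydration")
_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Normalized run configuration with all defaults materialized."""

    analyses: list = field(default_factory=lambda: list(_ANALYSES))
    structure: str | None = None
    trajectory: str | None = None
    trajectory_format: str | None = None
    simulate: dict | None = None
    roles: dict = field(default_factory=dict)
    criteria: dict = field(
        default_factory=lambda: {
            "distance_cutoff": 3.5,
            "angle_cutoff": 150.0,
            "heavy_atom_cutoff": 3.2,
            "use_hydrogens": True,
        }
    )
    pairs: list = field(default_factory=lambda: list(DEFAULT_PAIRS))
    lipid_resname: str = "PIP"
    association: dict = field(
        default_factory=lambda: {"smooth_window_ns": 10.0, "max_bonds": 2}
    )
    hydration: dict = field(
        default_factory=lambda: {
            "cylinder_radius": 8.0,
            "bin_width": 1.0,
            "window_ns": 10.0,
        }
    )
    dewetting: dict = field(default_factory=lambda: {"threshold_fraction": 0.2})
    output_dir: str = "pipgate_out"
    seed: int = 0
    log_level: str = "INFO"

    def role_map(self) -> ResidueRoleMap:
        kwargs = dict(self.roles)
        if "selectivity_filter_residues" in kwargs:
            kwargs["selectivity_filter_residues"] = tuple(
                kwargs["selectivity_filter_residues"]
            )
        if "pocket_residues" in kwargs:
            kwargs["pocket_residues"] = tuple(kwargs["pocket_residues"])
        return ResidueRoleMap(**kwargs)

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(**self.criteria)


_KNOWN_SUBKEYS = {
    "criteria": {"distance_cutoff", "angle_cutoff", "heavy_atom_cutoff", "use_hydrogens"},
    "association": {"smooth_window_ns", "max_bonds"},
    "hydration": {"cylinder_radius", "bin_width", "window_ns"},
    "dewetting": {"threshold_fraction"},
}


def validate_config(source) -> RunConfig:
    """Normalize a config mapping (or YAML path); reject unknown keys.

    All problems found in one pass are accumulated into a single
    ``ConfigError`` carrying the error list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors: list[str] = []
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    cfg_kwargs = {}
    for f in fields(RunConfig):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name in _KNOWN_SUBKEYS and isinstance(value, dict):
            bad = set(value) - _KNOWN_SUBKEYS[f.name]
            if bad:
                errors.append(f"{f.name}: unknown key(s) {sorted(bad)}")
                value = {k: v for k, v in value.items() if k not in bad}
        cfg_kwargs[f.name] = value
    cfg = RunConfig(**{k: v for k, v in cfg_kwargs.items() if k in known})
    # fill defaults inside sub-dicts
    for sub, defaults in (
        ("criteria", RunConfig().criteria),
        ("association", RunConfig().association),
        ("hydration", RunConfig().hydration),
        ("dewetting", RunConfig().dewetting),
    ):
        merged = dict(defaults)
        merged.update(getattr(cfg, sub))
        setattr(cfg, sub, merged)
    # range checks
    if cfg.criteria["distance_cutoff"] <= 0:
        errors.append("criteria.distance_cutoff must be positive")
    if not (0 < cfg.criteria["angle_cutoff"] <= 180):
        errors.append("criteria.angle_cutoff must be in (0, 180]")
    if cfg.criteria["heavy_atom_cutoff"] <= 0:
        errors.append("criteria.heavy_atom_cutoff must be positive")
    if cfg.hydration["cylinder_radius"] <= 0:
        errors.append("hydration.cylinder_radius must be positive")
    if cfg.hydration["bin_width"] <= 0:
        errors.append("hydration.bin_width must be positive")
    if cfg.association["max_bonds"] < 1:
        errors.append("association.max_bonds must be >= 1")
    if not (0 <= cfg.dewetting["threshold_fraction"] <= 1):
        errors.append("dewetting.threshold_fraction must be in [0, 1]")
    for a in cfg.analyses:
        if a not in _ANALYSES:
            errors.append(f"unknown analysis {a!r}")
    unknown_pairs = [p for p in cfg.pairs if p not in DEFAULT_PAIRS]
    if unknown_pairs:
        errors.append(f"unknown pair label(s) {unknown_pairs}")
    if cfg.simulate is None:
        if cfg.structure is None or cfg.trajectory is None:
            errors.append("either 'simulate' or both 'structure' and 'trajectory' required")
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_inputs(cfg: RunConfig):
    roles = cfg.role_map()
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        n_frames = int(sim.get("n_frames", 100))
        water = None
        if sim.get("n_waters"):
            water = WaterScript(mode="uniform", n_waters=int(sim["n_waters"]))
        script = TrajectoryScript(
            n_frames=n_frames,
            frame_dt_ns=float(sim.get("frame_dt_ns", 1.0)),
            bond_schedule=all_bonded_schedule(n_frames),
            gate_schedule=((0, float(sim.get("gate_start", 10.0))),
                           (max(n_frames - 1, 1), float(sim.get("gate_end", 13.0)))),
            water=water,
            six_prime=sim.get("six_prime", "K"),
            seed=int(sim.get("seed", cfg.seed)),
        )
        _, traj, _ = generate_channel_trajectory(script, roles)
        return traj, roles
    spath, tpath = Path(cfg.structure), Path(cfg.trajectory)
    if not spath.exists():
        raise PipgateError(f"stage load: structure file not found: {spath}")
    if not tpath.exists():
        raise PipgateError(f"stage load: trajectory file not found: {tpath}")
    model = read_structure(spath)
    traj = read_trajectory(model, tpath, cfg.trajectory_format)
    return traj, roles


def run_analysis(config: RunConfig | dict | str | Path) -> dict[str, Path]:
    """Run the configured analyses and write TSV outputs plus a manifest.

    Returns a mapping from output name to path.  Any stage error propagates
    with the stage name and input context prepended.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outputs: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipgateError(f"stage {name!r} failed: {exc}") from exc

    traj, roles = _stage("load", lambda: _load_inputs(cfg))
    criteria = cfg.hbond_criteria()
    pockets = None
    if set(cfg.analyses) & {"hbonds", "association"}:
        pockets = _stage(
            "pockets", lambda: assign_pockets(traj, roles, cfg.lipid_resname)
        )

    if "hbonds" in cfg.analyses:
        def _hbonds():
            rows, summary = [], []
            for label in cfg.pairs:
                series = pair_timeseries(
                    traj, DEFAULT_PAIRS[label], roles, pockets, criteria
                )
                for s in series:
                    for t, c in zip(s.times, s.counts):
                        rows.append((t, label, s.pocket, c))
                probs = [
                    hbond_probability(s, cfg.association["max_bonds"]) for s in series
                ]
                n = len(probs)
                sem = float(np.std(probs, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                summary.append((label, float(np.mean(probs)), sem, n))
            df = pd.DataFrame(rows, columns=["time_ns", "pair", "pocket", "count"])
            path = out_dir / "hbonds.tsv"
            df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs["hbonds"] = path
            sdf = pd.DataFrame(summary, columns=["pair", "mean", "sem", "n_units"])
            spath = out_dir / "hbond_probability.tsv"
            sdf.to_csv(spath, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs["hbond_probability"] = spath
        _stage("hbonds", _hbonds)

    if "association" in cfg.analyses:
        def _assoc():
            series = association_score_series(
                traj, roles, pockets, criteria,
                smooth_window_ns=cfg.association["smooth_window_ns"],
            )
            df = pd.DataFrame(
                {
                    "time_ns": series.times,
                    "raw_score": series.score,
                    "smoothed_score": series.smoothed,
                }
            )
            for label, counts in series.breakdown.items():
                df[label] = counts
            path = out_dir / "association.tsv"
            df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs["association"] = path
        _stage("association", _assoc)

    if "gate" in cfg.analyses:
        def _gate():
            series = hbc_diameter(traj, roles)
            df = pd.DataFrame(
                {
                    "time_ns": series.times,
                    "d_AC": series.d_ac,
                    "d_BD": series.d_bd,
                    "diameter": series.diameter,
                }
            )
            path = out_dir / "gate.tsv"
            df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs["gate"] = path
        _stage("gate", _gate)

    if "hydration" in cfg.analyses:
        def _hydration():
            profile = water_density_profile(
                traj,
                roles,
                cylinder_radius=cfg.hydration["cylinder_radius"],
                bin_width=cfg.hydration["bin_width"],
                window_ns=cfg.hydration["window_ns"],
            )
            try:
                flags = detect_dewetting(
                    profile, cfg.dewetting["threshold_fraction"]
                )
            except PipgateError:
                flags = np.zeros_like(profile.counts, dtype=bool)
            rows = []
            for w in range(profile.counts.shape[0]):
                for z_center, count, flag in zip(
                    profile.z_centers, profile.counts[w], flags[w]
                ):
                    rows.append(
                        (profile.window_edges[w], z_center, count, bool(flag))
                    )
            df = pd.DataFrame(
                rows, columns=["window_start_ns", "z_bin_center", "mean_count", "dewetted"]
            )
            path = out_dir / "hydration.tsv"
            df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs["hydration"] = path
        _stage("hydration", _hydration)

    manifest = {
        "config_hash": _config_hash(cfg),
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "config": asdict(cfg),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = mpath
    return outputs


# ---------------------------------------------------------------------------
# Trace loaders (CSV/TSV with YAML event sidecars)


def _events_from_list(raw_events) -> list[ProtocolEvent]:
    out = []
    for e in raw_events or []:
        out.append(
            ProtocolEvent(
                time=float(e["time"]),
                kind=str(e["kind"]),
                name=e.get("name"),
                duration_ms=(
                    float(e["duration_ms"]) if e.get("duration_ms") is not None else None
                ),
            )
        )
    return out


def load_current_trace(csv_path, events_yaml) -> CurrentTrace:
    """Load a time/current table plus a YAML protocol sidecar."""
    df = pd.read_csv(csv_path, sep=None, engine="python")
    with open(events_yaml) as fh:
        meta = yaml.safe_load(fh) or {}
    return CurrentTrace(
        times=df["time_s"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        holding_mV=float(meta.get("holding_mV", 0.0)),
        capacitance_pF=meta.get("capacitance_pF"),
        events=_events_from_list(meta.get("events")),
    )


def load_flux_trace(csv_path, events_yaml) -> FluxTrace:
    df = pd.read_csv(csv_path, sep=None, engine="python")
    with open(events_yaml) as fh:
        meta = yaml.safe_load(fh) or {}
    return FluxTrace(
        times=df["time_s"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        events=_events_from_list(meta.get("events")),
    )


def analyze_current_trace(trace: CurrentTrace) -> pd.DataFrame:
    """Per-trace electrophysiology metrics as a tidy table."""
    rows = []
    try:
        ba = ba_sensitive_current(trace)
        rows.append(("ba_sensitive_pA", ba))
        if trace.capacitance_pF:
            rows.append(("current_density_pA_per_pF", current_density(ba, trace.capacitance_pF)))
    except PipgateError as exc:
        log.warning("Ba-sensitive current unavailable: %s", exc)
    for e in trace.events:
        if e.kind == "vsp_pulse":
            rows.append(
                (
                    f"fractional_inhibition_{e.duration_ms:g}ms",
                    float(fractional_inhibition(trace, e.duration_ms)),
                )
            )
        elif e.kind == "drug_on" and e.name:
            rows.append(
                (f"percent_change_{e.name}", percent_change_vs_basal(trace, e.name))
            )
    return pd.DataFrame(rows, columns=["metric", "value"])


def analyze_flux_trace(trace: FluxTrace) -> pd.DataFrame:
    return pd.DataFrame(
        [("relative_flux", relative_flux(trace))], columns=["metric", "value"]
    )


def rmsd_report(structure_a, structure_b, roles: ResidueRoleMap | None = None) -> float:
    """Pocket Cα RMSD between two structure files."""
    roles = roles or ResidueRoleMap()
    a = read_structure(structure_a)
    b = read_structure(structure_b)
    return pocket_ca_rmsd(a, b, roles)
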