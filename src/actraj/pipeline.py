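"""Config-driven orchestration of the full per-system trajectory analysis.

A single YAML (or dict) configuration names the trajectory, the domain and
interface selections, the four binding-groove helices, the clustering /
contact / surface parameters and the distance monitors; ``run_analysis`` then
executes every stage in dependency order and writes one CSV table per
observable plus a JSON manifest sufficient to re-run the analysis
bit-identically.

Validation is fail-fast: every selection and monitor is resolved against the
topology before any output directory is created, and all resolution failures
are reported together.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cluster import gromos_cluster, pairwise_rmsd
from .contacts import (
    DistanceMonitor,
    conserved_contact_series,
    distance_series,
    persistence_table,
)
from .helix_geometry import helix_pair_series
from .model_io import (
    SelectionSpec,
    Structure,
    Trajectory,
    read_trajectory,
    resolve_selection,
)
from .superpose import average_structure, rmsd_series, rmsf_profile
from .surface import GapParams, interface_report

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "ConfigValidationError",
    "StageFailureError",
    "validate_config",
    "run_analysis",
    "compare_runs",
    "write_comparison",
]

logger = logging.getLogger("actraj.pipeline")

# analysis defaults: 1.5 Å backbone clustering cutoff, 100 ns dwell filter,
# 5 Å heavy-atom contact cutoff, >0.8 persistence, 400 ns equilibration,
# groove helices 408-420/468-475 (C1) and 910-918/978-988 (C2)
_DEFAULTS: dict = {
    "equilibration_ns": 400.0,
    "t0_ns": 0.0,
    "seed": 0,
    "output_dir": "actraj_out",
    "domains": {"c1": "chain=A", "c2": "chain=B", "gprotein": "chain=G"},
    "helices": {
        "c1_a": "resid=408-420; atoms=calpha",
        "c1_b": "resid=468-475; atoms=calpha",
        "c2_a": "resid=910-918; atoms=calpha",
        "c2_b": "resid=978-988; atoms=calpha",
    },
    "cluster": {"selection": None, "cutoff": 1.5, "min_dwell_ns": 100.0},
    "contacts": {
        "side_a": None,
        "side_b": None,
        "cutoff": 5.0,
        "persistence_threshold": 0.8,
        "reference_frame": 0,
    },
    "interface": {
        "side_a": None,
        "side_b": None,
        "probe": 1.4,
        "slice_dz": 0.1,
        "stride": 10,
        "gap": {"r_min": 1.0, "r_max": 5.0, "grid": 0.5},
    },
    "monitors": [],
}


class ConfigValidationError(ValueError):
    """One or more selections/monitors failed to resolve; lists all failures."""

    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("configuration invalid:\n  " + "\n  ".join(failures))


class StageFailureError(RuntimeError):
    """One or more analysis stages failed; names them."""


def _merge_defaults(user: Mapping, defaults: Mapping) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge_defaults(value, out[key])
        else:
            out[key] = value
    return out


@dataclasses.dataclass
class AnalysisConfig:
    """Normalized analysis configuration with defaults injected."""

    trajectory: str | None
    dt_ns: float
    equilibration_ns: float
    t0_ns: float
    seed: int
    output_dir: str
    domains: dict[str, str]
    helices: dict[str, str]
    cluster: dict
    contacts: dict
    interface: dict
    monitors: list[str]

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        merged = _merge_defaults(dict(data), _DEFAULTS)
        if "dt_ns" not in merged:
            raise ConfigValidationError(["missing required key 'dt_ns'"])
        # cluster selection defaults to domain c2 backbone (the substate-bearing domain)
        if merged["cluster"]["selection"] is None:
            c2 = merged["domains"].get("c2", "chain=B")
            merged["cluster"]["selection"] = f"{c2}; atoms=backbone"
        if merged["contacts"]["side_a"] is None:
            merged["contacts"]["side_a"] = merged["domains"].get("gprotein", "chain=G")
        if merged["contacts"]["side_b"] is None:
            merged["contacts"]["side_b"] = merged["domains"].get("c1", "chain=A")
        if merged["interface"]["side_a"] is None:
            merged["interface"]["side_a"] = merged["domains"].get("c1", "chain=A")
        if merged["interface"]["side_b"] is None:
            merged["interface"]["side_b"] = merged["domains"].get("c2", "chain=B")
        return cls(
            trajectory=merged.get("trajectory"),
            dt_ns=float(merged["dt_ns"]),
            equilibration_ns=float(merged["equilibration_ns"]),
            t0_ns=float(merged["t0_ns"]),
            seed=int(merged["seed"]),
            output_dir=str(merged["output_dir"]),
            domains=dict(merged["domains"]),
            helices=dict(merged["helices"]),
            cluster=dict(merged["cluster"]),
            contacts=dict(merged["contacts"]),
            interface=dict(merged["interface"]),
            monitors=list(merged["monitors"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def equilibration_frames(self) -> int:
        return int(math.floor(self.equilibration_ns / self.dt_ns))


@dataclasses.dataclass
class ValidatedConfig:
    """Configuration with every selection resolved against a topology."""

    config: AnalysisConfig
    domain_specs: dict[str, SelectionSpec]
    helix_specs: dict[str, SelectionSpec]
    cluster_spec: SelectionSpec
    contact_side_a: SelectionSpec
    contact_side_b: SelectionSpec
    interface_side_a: SelectionSpec
    interface_side_b: SelectionSpec
    monitors: list[DistanceMonitor]
    gap_params: GapParams


def validate_config(config: AnalysisConfig, topology: Structure) -> ValidatedConfig:
    """Resolve every selection and monitor; aggregate all failures."""
    failures: list[str] = []

    def _resolve(label: str, text: str) -> SelectionSpec | None:
        try:
            spec = SelectionSpec.parse(text)
            resolve_selection(topology, spec)
            return spec
        except Exception as exc:
            failures.append(f"{label}: {exc}")
            return None

    domain_specs = {k: _resolve(f"domain {k!r}", v) for k, v in config.domains.items()}
    helix_specs = {k: _resolve(f"helix {k!r}", v) for k, v in config.helices.items()}
    cluster_spec = _resolve("cluster.selection", config.cluster["selection"])
    ca = _resolve("contacts.side_a", config.contacts["side_a"])
    cb = _resolve("contacts.side_b", config.contacts["side_b"])
    ia = _resolve("interface.side_a", config.interface["side_a"])
    ib = _resolve("interface.side_b", config.interface["side_b"])

    monitors: list[DistanceMonitor] = []
    for text in config.monitors:
        try:
            mon = DistanceMonitor.parse(text)
            mon.spec_a.resolve(topology)
            mon.spec_b.resolve(topology)
            monitors.append(mon)
        except Exception as exc:
            failures.append(f"monitor {text!r}: {exc}")

    gap = config.interface.get("gap", {})
    try:
        gap_params = GapParams(
            r_min=float(gap.get("r_min", 1.0)),
            r_max=float(gap.get("r_max", 5.0)),
            grid=float(gap.get("grid", 0.5)),
        )
    except Exception as exc:
        failures.append(f"interface.gap: {exc}")
        gap_params = GapParams()

    if failures:
        raise ConfigValidationError(failures)
    return ValidatedConfig(
        config=config,
        domain_specs={k: v for k, v in domain_specs.items() if v is not None},
        helix_specs={k: v for k, v in helix_specs.items() if v is not None},
        cluster_spec=cluster_spec,  # type: ignore[arg-type]
        contact_side_a=ca,  # type: ignore[arg-type]
        contact_side_b=cb,  # type: ignore[arg-type]
        interface_side_a=ia,  # type: ignore[arg-type]
        interface_side_b=ib,  # type: ignore[arg-type]
        monitors=monitors,
        gap_params=gap_params,
    )


@dataclasses.dataclass
class ReportBundle:
    """All analysis tables plus the run manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    output_dir: Path

    @classmethod
    def load(cls, directory: str | Path) -> "ReportBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        tables = {
            p.stem: pd.read_csv(p) for p in sorted(directory.glob("*.csv"))
        }
        return cls(tables=tables, manifest=manifest, output_dir=directory)


_FLOAT_FMT = "%.6f"


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_analysis(
    config: AnalysisConfig,
    trajectory: Trajectory | None = None,
) -> ReportBundle:
    """Run every analysis stage and write the report bundle to disk.

    The first ``floor(equilibration_ns / dt_ns)`` frames are dropped before
    any stage runs. Stages that cannot run on the given input (for example
    clustering on a single frame) are skipped with a logged reason; stage
    errors are collected and re-raised together after independent stages have
    completed, so one failing observable does not suppress the others.
    """
    if trajectory is None:
        if not config.trajectory:
            raise ConfigValidationError(["no trajectory path in config and none supplied"])
        trajectory = read_trajectory(config.trajectory, dt_ns=config.dt_ns, t0_ns=config.t0_ns)

    validated = validate_config(config, trajectory.topology)

    n_skip = config.equilibration_frames
    if n_skip >= trajectory.n_frames:
        raise ConfigValidationError(
            [
                f"equilibration ({n_skip} frames) consumes the whole trajectory "
                f"({trajectory.n_frames} frames)"
            ]
        )
    production = trajectory.sliced(n_skip) if n_skip else trajectory

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    stages: dict[str, str] = {}
    errors: list[str] = []

    def _stage(name: str, fn) -> None:
        try:
            fn()
            stages[name] = "ok"
            logger.info("stage %s: ok", name)
        except Exception as exc:  # stage isolation: record, continue
            stages[name] = f"failed: {exc}"
            errors.append(name)
            logger.error("stage %s failed: %s", name, exc)

    # --- superposition-based observables, per domain -----------------------
    def _rmsd_stage() -> None:
        for name, spec in validated.domain_specs.items():
            if name == "gprotein":
                continue
            bb = SelectionSpec(
                chains=spec.chains, residue_ranges=spec.residue_ranges, atom_class="backbone"
            )
            avg = average_structure(production, bb)
            tables[f"rmsd_{name}"] = rmsd_series(production, bb, reference=avg)

    _stage("rmsd", _rmsd_stage)

    def _rmsf_stage() -> None:
        if production.n_frames < 2:
            stages["rmsf"] = "skipped: fewer than 2 production frames"
            raise _Skip()
        profile = rmsf_profile(production, SelectionSpec(atom_class="backbone"))
        tables["rmsf"] = profile.to_frame()

    _stage_skippable("rmsf", _rmsf_stage, stages, errors)

    # --- clustering --------------------------------------------------------
    def _cluster_stage() -> None:
        if production.n_frames < 2:
            stages["cluster"] = "skipped: fewer than 2 production frames"
            raise _Skip()
        matrix = pairwise_rmsd(production, validated.cluster_spec)
        cs = gromos_cluster(
            matrix,
            cutoff=float(config.cluster["cutoff"]),
            dt_ns=config.dt_ns,
            min_dwell_ns=float(config.cluster["min_dwell_ns"]),
            selection=validated.cluster_spec,
        )
        tables["clusters"] = cs.to_frame(t0_ns=production.t0_ns)
        tables["cluster_summary"] = cs.summary()

    _stage_skippable("cluster", _cluster_stage, stages, errors)

    # --- helix geometry ----------------------------------------------------
    def _helix_stage() -> None:
        for domain in ("c1", "c2"):
            a, b = validated.helix_specs.get(f"{domain}_a"), validated.helix_specs.get(f"{domain}_b")
            if a is None or b is None:
                continue
            series = helix_pair_series(production, a, b)
            tables[f"helix_{domain}"] = series.table

    _stage("helix", _helix_stage)

    # --- contacts ----------------------------------------------------------
    def _contacts_stage() -> None:
        cutoff = float(config.contacts["cutoff"])
        tables["conserved_contacts"] = conserved_contact_series(
            production,
            validated.contact_side_a,
            validated.contact_side_b,
            cutoff=cutoff,
            reference_frame=int(config.contacts["reference_frame"]),
        )
        pt = persistence_table(
            production,
            validated.contact_side_a,
            validated.contact_side_b,
            cutoff=cutoff,
            threshold=float(config.contacts["persistence_threshold"]),
        )
        tables["persistence_pairs"] = pt.pairs_frame()
        tables["persistence_residues"] = pt.residues_frame()

    _stage("contacts", _contacts_stage)

    # --- interface complementarity (strided; SASA/gap are the costly stages)
    def _interface_stage() -> None:
        stride = max(int(config.interface["stride"]), 1)
        rows = []
        for f in range(0, production.n_frames, stride):
            rep = interface_report(
                production.frame_structure(f),
                validated.interface_side_a,
                validated.interface_side_b,
                probe=float(config.interface["probe"]),
                gap_params=validated.gap_params,
                slice_dz=float(config.interface["slice_dz"]),
            )
            rows.append(
                {
                    "frame": f,
                    "time_ns": production.times_ns[f],
                    "asa_A": rep.asa_A,
                    "asa_B": rep.asa_B,
                    "asa_AB": rep.asa_AB,
                    "delta_asa": rep.delta_asa,
                    "interface_area": rep.interface_area,
                    "gap_volume": rep.gap_volume,
                    "gap_index": np.nan if rep.gap_index is None else rep.gap_index,
                }
            )
        tables["interface"] = pd.DataFrame(rows)

    _stage("interface", _interface_stage)

    # --- distance monitors -------------------------------------------------
    def _monitor_stage() -> None:
        if not validated.monitors:
            stages["monitors"] = "skipped: no monitors configured"
            raise _Skip()
        tables["monitors"] = distance_series(production, validated.monitors)

    _stage_skippable("monitors", _monitor_stage, stages, errors)

    manifest = {
        "actraj_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_frames_total": trajectory.n_frames,
        "n_frames_equilibration": n_skip,
        "n_frames_analyzed": production.n_frames,
        "stages": stages,
    }
    for name, df in tables.items():
        _write_table(df, out / f"{name}.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    if errors:
        raise StageFailureError(f"stage(s) failed: {', '.join(errors)} (see manifest)")
    return ReportBundle(tables=tables, manifest=manifest, output_dir=out)


class _Skip(Exception):
    """Internal: stage preconditions unmet; already recorded as skipped."""


def _stage_skippable(name: str, fn, stages: dict, errors: list[str]) -> None:
    try:
        fn()
        stages[name] = "ok"
        logger.info("stage %s: ok", name)
    except _Skip:
        logger.info("stage %s: %s", name, stages.get(name, "skipped"))
    except Exception as exc:
        stages[name] = f"failed: {exc}"
        errors.append(name)
        logger.error("stage %s failed: %s", name, exc)


# ---------------------------------------------------------------------------
# Between-system comparison
# ---------------------------------------------------------------------------


def compare_runs(a: ReportBundle, b: ReportBundle) -> dict[str, pd.DataFrame]:
    """Per-observable deltas (a minus b) between two report bundles.

    Produces mean helix angle/distance shifts, interface statistic shifts, the
    per-residue flexibility difference profile and interface-persistence
    changes -- the between-system quantities these analyses are compared on.
    """
    deltas: dict[str, pd.DataFrame] = {}

    helix_rows = []
    for name in ("helix_c1", "helix_c2"):
        if (name in a.tables) != (name in b.tables):
            raise ValueError(f"bundles disagree on table {name!r}")
        if name in a.tables:
            ta, tb = a.tables[name], b.tables[name]
            helix_rows.append(
                {
                    "observable": name,
                    "angle_mean_a": ta["angle_deg"].mean(),
                    "angle_mean_b": tb["angle_deg"].mean(),
                    "angle_shift": ta["angle_deg"].mean() - tb["angle_deg"].mean(),
                    "distance_mean_a": ta["distance_A"].mean(),
                    "distance_mean_b": tb["distance_A"].mean(),
                    "distance_shift": ta["distance_A"].mean() - tb["distance_A"].mean(),
                }
            )
    if helix_rows:
        deltas["helix_shifts"] = pd.DataFrame(helix_rows)

    if "interface" in a.tables and "interface" in b.tables:
        cols = ["delta_asa", "interface_area", "gap_volume", "gap_index"]
        rows = []
        for col in cols:
            rows.append(
                {
                    "observable": col,
                    "mean_a": a.tables["interface"][col].mean(),
                    "mean_b": b.tables["interface"][col].mean(),
                    "shift": a.tables["interface"][col].mean()
                    - b.tables["interface"][col].mean(),
                }
            )
        deltas["interface_shifts"] = pd.DataFrame(rows)

    if "rmsf" in a.tables and "rmsf" in b.tables:
        ta, tb = a.tables["rmsf"], b.tables["rmsf"]
        merged = ta.merge(tb, on=["chain", "residue"], how="outer", suffixes=("_a", "_b"))
        if merged[["value_a", "value_b"]].isna().any().any():
            raise ValueError("rmsf tables do not share identical residue keys")
        merged["difference"] = merged["value_a"] - merged["value_b"]
        deltas["rmsf_difference"] = merged[["chain", "residue", "difference"]]

    if "persistence_residues" in a.tables and "persistence_residues" in b.tables:
        ta = a.tables["persistence_residues"][["chain", "residue", "frame_fraction"]]
        tb = b.tables["persistence_residues"][["chain", "residue", "frame_fraction"]]
        merged = ta.merge(tb, on=["chain", "residue"], how="outer", suffixes=("_a", "_b")).fillna(
            0.0
        )
        merged["change"] = merged["frame_fraction_a"] - merged["frame_fraction_b"]
        deltas["persistence_changes"] = merged
    return deltas


def write_comparison(deltas: Mapping[str, pd.DataFrame], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in deltas.items():
        _write_table(df, directory / f"{name}.csv")
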