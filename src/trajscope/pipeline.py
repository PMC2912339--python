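"""Pipeline orchestration: config validation and staged analysis runs.

The pipeline wires the stages in their natural dependency order —
superpose/fluctuation → PCA → extreme conformers → domain decomposition,
with the contact and energetics stages independent — and writes one
tab-separated table per stage into the output directory. A failure in one
independent stage is recorded in the run report without aborting the rest.

Configs are YAML; every stage parameter has the module default and is
echoed back into the run report so a run is fully reproducible from its
report alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import contacts, domain_motion, energetics, essential_dynamics, superpose
from .model_io import Selection, Trajectory, read_structure, select

logger = logging.getLogger("trajscope")

_STAGES = ("fluct", "pca", "domains", "hbonds", "channel", "energy")

_DEFAULTS: dict[str, dict] = {
    "fluct": {"equilibration_drop": None},
    "pca": {"equilibration_drop": None, "n_modes": 2},
    "domains": {"window": 5, "min_domain": 20, "cluster_radius": 5.0},
    "hbonds": {"mode": "distance-only", "d_cut": 3.5, "angle_cut": 120.0,
               "donors": None, "acceptors": None},
    "channel": {"set_a": None, "set_b": None, "entrance": None, "frame": 0},
    "energy": {"receptor": None, "ligand": None, "snapshot_stride": 1,
               "entropy_stride": 5, "temperature": 300.0,
               "entropy": "quasiharmonic", "sasa_points": 240},
}


@dataclass
class AnalysisConfig:
    trajectory: Path
    dialect: str = "frame-dump"
    selections: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    output_dir: Path = Path("trajscope_out")
    seed: int = 0


@dataclass
class StageStatus:
    name: str
    ok: bool
    parameters: dict
    outputs: list[str]
    error: str | None = None
    wall_time: float = 0.0


@dataclass
class RunReport:
    stages: list[StageStatus]
    output_dir: Path

    @property
    def ok(self) -> bool:
        return all(s.ok for s in self.stages)


def validate_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a YAML config; defaults filled, unknown keys rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"trajectory", "dialect", "selections", "stages",
                 "output_dir", "seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "trajectory" not in raw:
        raise ValueError("config must name a trajectory")
    base = path.parent
    traj = Path(raw["trajectory"])
    if not traj.is_absolute():
        traj = base / traj
    if not traj.exists():
        raise ValueError(f"trajectory not found: {traj}")
    stages_raw = raw.get("stages", {})
    stages: dict[str, dict] = {}
    for name, params in stages_raw.items():
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}; known: {_STAGES}")
        params = dict(params or {})
        bad = set(params) - set(_DEFAULTS[name])
        if bad:
            raise ValueError(f"stage {name!r}: unknown keys {sorted(bad)}")
        merged = dict(_DEFAULTS[name])
        merged.update(params)
        stages[name] = merged
    out = Path(raw.get("output_dir", "trajscope_out"))
    if not out.is_absolute():
        out = base / out
    return AnalysisConfig(
        trajectory=traj,
        dialect=raw.get("dialect", "frame-dump"),
        selections=dict(raw.get("selections", {})),
        stages=stages,
        output_dir=out,
        seed=int(raw.get("seed", 0)),
    )


def _resolve_selection(cfg: AnalysisConfig, traj: Trajectory, name: str | None,
                       default_all: bool = True) -> Selection:
    if name is None:
        if default_all:
            return Selection(tuple(range(traj.n_atoms)), label="all")
        raise ValueError("a selection name is required")
    if name not in cfg.selections:
        raise ValueError(f"selection {name!r} is not defined in the config")
    return select(traj.topology, cfg.selections[name], label=name)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def _stage_fluct(cfg, traj, params, outdir) -> list[str]:
    sel = _resolve_selection(cfg, traj, params.get("selection"))
    prof = superpose.rmsf(traj, sel, params["equilibration_drop"])
    rows = []
    for k, i in enumerate(sel.asarray()):
        a = traj.topology.atoms[int(i)]
        rows.append([a.residue_id, a.chain_id, float(prof.per_atom_rmsf[k]),
                     float(prof.per_atom_b[k]), float(prof.per_atom_b_normalized[k])])
    out = outdir / "fluct.tsv"
    _write_tsv(out, ["residue_id", "chain", "rmsf", "b", "b_norm"], rows)
    return [str(out)]


def _stage_pca(cfg, traj, params, outdir):
    sel = _resolve_selection(cfg, traj, params.get("selection"))
    model = essential_dynamics.build_covariance(traj, sel,
                                                params["equilibration_drop"])
    k = int(params["n_modes"])
    spec_rows = [
        [i, float(model.eigenvalues[i]), float(model.variance_fraction[i])]
        for i in range(min(10, model.matrix_dim))
    ]
    out1 = outdir / "pca_spectrum.tsv"
    _write_tsv(out1, ["mode", "eigenvalue_A2", "variance_fraction"], spec_rows)
    series = essential_dynamics.project(traj, model, tuple(range(k)))
    out2 = outdir / "pca_projections.tsv"
    _write_tsv(out2, ["frame"] + [f"pc{i + 1}" for i in range(k)],
               [[f] + [float(v) for v in row]
                for f, row in enumerate(series.values)])
    return [str(out1), str(out2)], (model, series)


def _stage_domains(cfg, traj, params, outdir, pca_state):
    model, series = pca_state
    ext = essential_dynamics.extreme_conformers(series, traj, model, mode=0)
    field = domain_motion.local_rotation_field(
        ext["min_coords"], ext["max_coords"], window=int(params["window"]))
    part = domain_motion.partition_domains(
        field, int(params["min_domain"]), float(params["cluster_radius"]))
    rows = []
    for d, dom in enumerate(part.moving_domains):
        hp = domain_motion.hinge_parameters(
            ext["min_coords"], ext["max_coords"], part, moving=d)
        rows.append([
            d + 1, "PC1", float(hp.rotation_angle), float(hp.translation),
            float(hp.closure) if hp.closure is not None else "NA",
            f"{min(part.hinge_residues[d], default=-1)}-"
            f"{max(part.hinge_residues[d], default=-1)}",
        ])
    out = outdir / "domains.tsv"
    _write_tsv(out, ["hinge", "pc", "rotation_deg", "translation_A",
                     "closure_pct", "hinge_residues"], rows)
    return [str(out)]


def _stage_hbonds(cfg, traj, params, outdir):
    donors = _resolve_selection(cfg, traj, params["donors"], default_all=False)
    acceptors = _resolve_selection(cfg, traj, params["acceptors"],
                                   default_all=False)
    series = contacts.hbond_scan(traj, donors, acceptors, params["mode"],
                                 float(params["d_cut"]),
                                 float(params["angle_cut"]))
    rows = [[s.donor, s.acceptor, float(s.distance.mean()), float(s.occupancy)]
            for s in series]
    out = outdir / "hbonds.tsv"
    _write_tsv(out, ["donor", "acceptor", "mean_distance_A", "occupancy"], rows)
    return [str(out)]


def _stage_channel(cfg, traj, params, outdir):
    a = _resolve_selection(cfg, traj, params["set_a"], default_all=False)
    b = _resolve_selection(cfg, traj, params["set_b"], default_all=False)
    ent = _resolve_selection(cfg, traj, params["entrance"], default_all=False)
    m = contacts.channel_metrics(traj.frames[int(params["frame"])], a, b, ent)
    out = outdir / "channel.tsv"
    _write_tsv(out, ["centroid_distance_A", "entrance_area_A2"],
               [[float(m.centroid_distance), float(m.entrance_area)]])
    return [str(out)]


def _stage_energy(cfg, traj, params, outdir):
    rec = _resolve_selection(cfg, traj, params["receptor"], default_all=False)
    lig = _resolve_selection(cfg, traj, params["ligand"], default_all=False)
    method = params["entropy"]
    report = energetics.mmgbsa_binding(
        traj, rec, lig,
        snapshot_stride=int(params["snapshot_stride"]),
        entropy_stride=int(params["entropy_stride"]),
        T=float(params["temperature"]),
        entropy_method=None if method in (None, "none") else method,
        sasa_points=int(params["sasa_points"]),
    )
    rows = [[label, float(mean), float(sd) if sd is not None else "NA"]
            for label, mean, sd in report.rows()]
    out = outdir / "energy.tsv"
    _write_tsv(out, ["component", "mean_kcal_mol", "sd"], rows)
    return [str(out)]


def run_pipeline(cfg: AnalysisConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    PCA extreme conformers feed the domain stage automatically; a failure
    in one independent stage does not abort the others (the domains stage
    does require a successful PCA stage).
    """
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    traj = read_structure(cfg.trajectory, cfg.dialect)
    statuses: list[StageStatus] = []
    pca_state = None
    for name in _STAGES:
        if name not in cfg.stages:
            continue
        params = cfg.stages[name]
        t0 = time.perf_counter()
        try:
            if name == "fluct":
                outputs = _stage_fluct(cfg, traj, params, cfg.output_dir)
            elif name == "pca":
                outputs, pca_state = _stage_pca(cfg, traj, params, cfg.output_dir)
            elif name == "domains":
                if pca_state is None:
                    raise ValueError("domains stage requires the pca stage")
                outputs = _stage_domains(cfg, traj, params, cfg.output_dir,
                                         pca_state)
            elif name == "hbonds":
                outputs = _stage_hbonds(cfg, traj, params, cfg.output_dir)
            elif name == "channel":
                outputs = _stage_channel(cfg, traj, params, cfg.output_dir)
            elif name == "energy":
                outputs = _stage_energy(cfg, traj, params, cfg.output_dir)
            statuses.append(StageStatus(name, True, params, outputs,
                                        wall_time=time.perf_counter() - t0))
            logger.info("stage %s finished", name)
        except Exception as exc:  # noqa: BLE001 — stage isolation is the point
            statuses.append(StageStatus(name, False, params, [], str(exc),
                                        wall_time=time.perf_counter() - t0))
            logger.error("stage %s failed: %s", name, exc)
    return RunReport(stages=statuses, output_dir=cfg.output_dir)
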