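"""Seeded generators of trajectories and complexes with planted ground truth.

Every analysis stage in the package is exercised against data whose "right
answer" is known by construction:

* a two-lobe Cα chain whose moving lobe rotates about a planted hinge axis
  (with optional Gaussian thermal jitter) — the test bed for superposition,
  PCA and domain/hinge analysis;
* an interaction system whose donor–acceptor pair snaps between bonded
  (2.8 Å) and unbonded (6.0 Å) distances on a prescribed or Bernoulli
  schedule, with an optional water particle occupying a site on the same
  schedule — the test bed for H-bond and hydration analyses;
* a randomly packed charged complex with known per-pair interaction
  energies — the test bed for the energetics machinery.

Generators are pure functions of spec + seed, and each trajectory ships a
manifest recording the planted parameters for the test suites to consume.
These fixtures are kinematic, not physical: no force field ever acts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import AtomRecord, Topology, Trajectory

__all__ = [
    "HingeSpec",
    "OccupancySpec",
    "ChargePlan",
    "make_two_domain_chain",
    "make_hinge_trajectory",
    "make_interaction_trajectory",
    "make_charged_complex",
    "write_manifest",
    "read_manifest",
]

CA_STEP = 3.8          # Å, consecutive Cα spacing
BONDED_DISTANCE = 2.8  # Å
UNBONDED_DISTANCE = 6.0


def _jsonify(obj):
    """Tuples → lists, numpy scalars → python, so manifests round-trip JSON."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class HingeSpec:
    """Planted two-domain hinge motion."""

    n_fixed: int = 100
    n_moving: int = 80
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    amplitude: float = 25.0      # degrees, peak-to-peak between extremes
    motion: str = "sinusoid"     # or "two-state"
    noise_sigma: float = 0.0     # Å, isotropic per coordinate
    n_frames: int = 200
    seed: int = 0
    time_step: float = 2.0       # ps

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude < 180.0:
            raise ValueError("amplitude must be in (0, 180) degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.motion not in ("sinusoid", "two-state"):
            raise ValueError(f"unknown motion {self.motion!r}")

    @property
    def pivot_residue(self) -> int:
        return self.n_fixed  # 1-based residue id of the junction

    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, float)
        return a / np.linalg.norm(a)


@dataclass
class OccupancySpec:
    """Planted on/off schedule for an interacting pair and/or a water site."""

    n_frames: int = 200
    p: float | None = None                 # Bernoulli on-probability
    schedule: tuple[int, ...] | None = None  # explicit 0/1 per frame
    seed: int = 0
    time_step: float = 2.0

    def __post_init__(self) -> None:
        if (self.p is None) == (self.schedule is None):
            raise ValueError("give exactly one of p or schedule")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.schedule is not None and len(self.schedule) != self.n_frames:
            raise ValueError("schedule length must equal n_frames")

    def realize(self) -> np.ndarray:
        if self.schedule is not None:
            return np.asarray(self.schedule, dtype=bool)
        rng = np.random.default_rng(self.seed)
        return rng.random(self.n_frames) < self.p


@dataclass
class ChargePlan:
    """Per-atom parameter plan for a charged complex."""

    receptor_charges: tuple[float, ...]
    ligand_charges: tuple[float, ...]
    lj_sigma: float = 3.2        # Å
    lj_epsilon: float = 0.15     # kcal/mol
    born_radius: float = 1.7     # Å
    vdw_radius: float = 1.7      # Å
    mass: float = 12.0


def _compact_lobe(
    n: int, center: np.ndarray, radius: float, rng: np.random.Generator,
    start: np.ndarray,
) -> np.ndarray:
    """Random-coil chain of n beads confined to a sphere around center."""
    pts = np.empty((n, 3))
    pos = start.copy()
    for i in range(n):
        pts[i] = pos
        step = rng.normal(size=3)
        step *= CA_STEP / np.linalg.norm(step)
        cand = pos + step
        # reflect back toward the lobe center when wandering out
        overshoot = np.linalg.norm(cand - center) - radius
        if overshoot > 0:
            pull = (center - cand)
            cand = cand + pull / np.linalg.norm(pull) * min(2 * overshoot, CA_STEP)
        pos = cand
    return pts


def make_two_domain_chain(spec: HingeSpec) -> tuple[Topology, np.ndarray]:
    """Cα-only two-lobe chain joined at the pivot; reproducible under seed.

    The lobes are compact random coils whose centroid separation exceeds
    twice the lobe radius of gyration, so the hinge geometry is unambiguous.
    """
    min_size = 20
    if spec.n_fixed < min_size or spec.n_moving < min_size:
        raise ValueError(f"each lobe needs at least {min_size} residues")
    rng = np.random.default_rng(spec.seed)
    r_fixed = 1.2 * CA_STEP * spec.n_fixed ** (1 / 3)
    r_moving = 1.2 * CA_STEP * spec.n_moving ** (1 / 3)
    sep = 2.6 * max(r_fixed, r_moving)
    c_fixed = np.zeros(3)
    c_moving = np.array([sep, 0.0, 0.0])
    fixed = _compact_lobe(spec.n_fixed, c_fixed, r_fixed, rng,
                          start=c_fixed + np.array([r_fixed / 2, 0, 0]))
    moving = _compact_lobe(spec.n_moving, c_moving, r_moving, rng,
                           start=c_moving - np.array([r_moving / 2, 0, 0]))
    coords = np.vstack([fixed, moving])
    n = spec.n_fixed + spec.n_moving
    atoms = [
        AtomRecord(serial=i + 1, name="CA", residue_name="GLY",
                   residue_id=i + 1, chain_id="A", element="C")
        for i in range(n)
    ]
    return Topology(atoms), coords


def _angle_schedule(spec: HingeSpec) -> np.ndarray:
    t = np.arange(spec.n_frames)
    if spec.motion == "sinusoid":
        # two full periods; extremes at ±amplitude/2 around the reference
        return 0.5 * spec.amplitude * np.sin(2.0 * np.pi * 2.0 * t / spec.n_frames)
    half = spec.n_frames // 2
    sched = np.zeros(spec.n_frames)
    sched[half:] = spec.amplitude
    return sched - spec.amplitude / 2.0


def make_hinge_trajectory(
    top: Topology, ref: np.ndarray, spec: HingeSpec
) -> tuple[Trajectory, dict]:
    """Rotate the moving lobe about the planted axis through the pivot Cα.

    Per frame, the scheduled angle is applied and isotropic Gaussian jitter
    of ``noise_sigma`` Å is added to every coordinate. Returns the
    trajectory and a manifest of the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pivot_xyz = ref[spec.pivot_residue - 1]
    axis = spec.unit_axis()
    angles = _angle_schedule(spec)
    mov = slice(spec.n_fixed, spec.n_fixed + spec.n_moving)
    frames = np.empty((spec.n_frames, ref.shape[0], 3))
    for f, theta in enumerate(angles):
        R = Rotation.from_rotvec(np.radians(theta) * axis).as_matrix()
        frame = ref.copy()
        frame[mov] = (R @ (ref[mov] - pivot_xyz).T).T + pivot_xyz
        if spec.noise_sigma > 0:
            frame += rng.normal(scale=spec.noise_sigma, size=frame.shape)
        frames[f] = frame
    traj = Trajectory(top, frames, time_step=spec.time_step)
    manifest = _jsonify({
        "kind": "hinge",
        "spec": asdict(spec),
        "pivot_residue": spec.pivot_residue,
        "axis": list(axis),
        "axis_point": list(pivot_xyz),
        "angle_schedule_extremes": [float(angles.min()), float(angles.max())],
        "planted_rotation_between_extremes": float(angles.max() - angles.min()),
    })
    return traj, manifest


def make_interaction_trajectory(
    spec: OccupancySpec,
    include_water: bool = True,
) -> tuple[Trajectory, dict]:
    """Donor/acceptor pair toggling 2.8 ↔ 6.0 Å on the planted schedule.

    The topology carries a donor oxygen, an acceptor nitrogen, and (when
    ``include_water``) a water oxygen that occupies a site 5 Å off the pair
    axis on the same schedule (parked 20 Å away when off).
    """
    on = spec.realize()
    atoms = [
        AtomRecord(serial=1, name="O", residue_name="SER", residue_id=1,
                   element="O", mass=16.0),
        AtomRecord(serial=2, name="N", residue_name="LYS", residue_id=2,
                   element="N", mass=14.0),
    ]
    labels = ["protein", "protein"]
    if include_water:
        atoms.append(
            AtomRecord(serial=3, name="OW", residue_name="HOH", residue_id=3,
                       element="O", mass=16.0)
        )
        labels.append("water")
    site = np.array([0.0, 5.0, 0.0])
    parked = np.array([0.0, 20.0, 0.0])
    frames = np.empty((spec.n_frames, len(atoms), 3))
    for f in range(spec.n_frames):
        d = BONDED_DISTANCE if on[f] else UNBONDED_DISTANCE
        frames[f, 0] = (0.0, 0.0, 0.0)
        frames[f, 1] = (d, 0.0, 0.0)
        if include_water:
            frames[f, 2] = site if on[f] else parked
    traj = Trajectory(Topology(atoms, labels), frames, time_step=spec.time_step)
    manifest = _jsonify({
        "kind": "interaction",
        "spec": asdict(spec),
        "schedule": [int(x) for x in on],
        "occupancy": float(on.mean()),
        "water_site": list(site) if include_water else None,
    })
    return traj, manifest


def make_charged_complex(
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    plan: ChargePlan | None = None,
    seed: int = 0,
    min_separation: float = 3.0,
    box: float = 14.0,
) -> tuple[Topology, np.ndarray, dict]:
    """Non-overlapping random packing of a charged receptor + ligand.

    Parameters come from the plan (default: alternating ±0.5 e charges).
    The manifest carries brute-force double-loop reference energies for the
    interface Coulomb and Lennard-Jones terms.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("both molecules need at least one atom")
    n = n_receptor_atoms + n_ligand_atoms
    if plan is None:
        qr = tuple(0.5 * (-1) ** i for i in range(n_receptor_atoms))
        ql = tuple(0.5 * (-1) ** (i + 1) for i in range(n_ligand_atoms))
        plan = ChargePlan(receptor_charges=qr, ligand_charges=ql)
    if len(plan.receptor_charges) != n_receptor_atoms:
        raise ValueError("receptor charge plan length mismatch")
    if len(plan.ligand_charges) != n_ligand_atoms:
        raise ValueError("ligand charge plan length mismatch")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(-box / 2, box / 2, size=3)
        if len(pts) >= n_receptor_atoms:  # ligand offset to one side
            cand[0] += box * 0.8
        if all(np.linalg.norm(cand - p) >= min_separation for p in pts):
            pts.append(cand)
        tries += 1
        if tries > 20000:
            raise RuntimeError("packing failed; enlarge the box")
    coords = np.array(pts)

    charges = list(plan.receptor_charges) + list(plan.ligand_charges)
    atoms = []
    for i in range(n):
        mol = "REC" if i < n_receptor_atoms else "LIG"
        atoms.append(
            AtomRecord(
                serial=i + 1, name=f"C{i + 1}", residue_name=mol,
                residue_id=i + 1 if i < n_receptor_atoms else i + 1,
                chain_id="R" if mol == "REC" else "L",
                charge=charges[i], lj_sigma=plan.lj_sigma,
                lj_epsilon=plan.lj_epsilon, born_radius=plan.born_radius,
                vdw_radius=plan.vdw_radius, mass=plan.mass,
            )
        )
    labels = ["protein"] * n_receptor_atoms + ["guide-RNA"] * n_ligand_atoms
    top = Topology(atoms, labels)

    # brute-force double-loop reference energies (independent of energetics.py)
    from .energetics import COULOMB_K  # the constant, not the implementation

    ele = 0.0
    lj = 0.0
    for i in range(n_receptor_atoms):
        for j in range(n_receptor_atoms, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            ele += COULOMB_K * charges[i] * charges[j] / r
            s6 = (plan.lj_sigma / r) ** 6
            lj += 4.0 * plan.lj_epsilon * (s6**2 - s6)
    manifest = _jsonify({
        "kind": "charged-complex",
        "seed": seed,
        "n_receptor_atoms": n_receptor_atoms,
        "n_ligand_atoms": n_ligand_atoms,
        "plan": asdict(plan),
        "reference_coulomb": ele,
        "reference_lj": lj,
    })
    return top, coords, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
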