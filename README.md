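# trajscope

Trajectory analysis and end-state binding thermodynamics for biomolecular
complexes — built for studying how a protein's quasi-rigid domains move, how
a ligand sits in its binding channel, and what each interaction contributes
to the binding free energy. The motivating system is an Argonaute
protein binding a guide miRNA and its target mRNA: the PAZ domain's
hinge motions open and close the nucleic-acid-binding channel, ordered
waters and a catalytic Mg²⁺ organize the cleavage site, and an
arginine-rich channel dominates the binding energetics. All of the
analyses, however, are generic and work on any stored trajectory.

## What it computes

**Superposition & fluctuations** (`trajscope.superpose`) — weighted Kabsch
superposition; per-frame RMSD against a reference; per-atom RMSF with
B-factors *B* = (8π²/3)·RMSF² and their z-score normalization.

**Essential dynamics** (`trajscope.essential_dynamics`) — the positional
covariance matrix of an *N*-atom selection over *M* frames,

> C = ⟨(r − ⟨r⟩)(r − ⟨r⟩)ᵀ⟩  (3N × 3N),

eigen-decomposed into collective modes; variance fractions λᵢ/Σλ,
projections pᵢ(t) = Vᵢᵀ·(r(t) − ⟨r⟩), and extreme conformers along a mode.

**Domain & hinge motion** (`trajscope.domain_motion`) — a sliding-window
rotation field between two conformers, clustered into quasi-rigid domains;
per-hinge screw decomposition into an effective rotation angle (°),
translation along the axis (Å), and % closure = 100·(n̂·ĉ)², where n̂ is the
rotation axis and ĉ the closure axis.

**Contacts** (`trajscope.contacts`) — H-bond occupancy series (heavy-atom
distance criterion, optional donor–H–acceptor angle), base-pair torsions,
hydration-site maps with molecule-resolved residence episodes, ion
coordination geometry (distances, consecutive-angle sums, planarity), and
channel metrics (centroid distance, projected entrance area).

**Energetics** (`trajscope.energetics`) — single-trajectory MM-GBSA:

> ΔG_bind = ΔE_ele + ΔE_vdw + ΔG_np + ΔG_polar − TΔS

with pairwise Coulomb (k = 332.0636 kcal·Å/mol·e², no cutoff), 12-6
Lennard-Jones, Shrake–Rupley SASA feeding ΔG_np = γ·SASA + β
(γ = 0.00542 kcal/Å²·mol, β = 0.92 kcal/mol, 1.4 Å probe), a
generalized-Born polar term (ε_in = 1, ε_out = 80) that reduces exactly to
the Born-ion closed form, translational/rotational/vibrational entropy
(quasiharmonic or truncated normal-mode), and per-residue decomposition
with fractional-contribution flags.

**Synthetic data** (`trajscope.synthetic_data`) — seeded generators of
two-lobe hinge trajectories, scheduled H-bond/hydration systems and charged
complexes, each shipping a manifest of its planted ground truth. These are
kinematic stand-ins for MD output, used throughout the test suite.

## Worked example

Generate a 200-frame trajectory of a 180-residue two-lobe chain whose
outer lobe swings 25° about a planted hinge (0.1 Å thermal jitter), then
recover the motion:

```python
from trajscope.synthetic_data import (HingeSpec, make_two_domain_chain,
                                      make_hinge_trajectory)
from trajscope.essential_dynamics import (build_covariance, project,
                                          extreme_conformers, variance_captured)
from trajscope.domain_motion import (local_rotation_field, partition_domains,
                                     hinge_parameters)

spec = HingeSpec(n_fixed=100, n_moving=80, amplitude=25.0,
                 noise_sigma=0.1, n_frames=200, seed=1)
top, ref = make_two_domain_chain(spec)
traj, manifest = make_hinge_trajectory(top, ref, spec)

model = build_covariance(traj, equilibration_drop=0)
print(f"top mode captures {100*variance_captured(model, 1):.1f}% of the variance")
series = project(traj, model, (0,))
ext = extreme_conformers(series, traj, model, 0)
part = partition_domains(local_rotation_field(ext["min_coords"], ext["max_coords"]))
hp = hinge_parameters(ext["min_coords"], ext["max_coords"], part, 0)
print(f"hinge rotation {hp.rotation_angle:.1f} deg, "
      f"translation {hp.translation:.2f} A, closure {hp.closure:.0f}%")
```

prints

```
top mode captures 96.1% of the variance
hinge rotation 25.3 deg, translation -0.06 A, closure 25%
```

— the hinge mode dominates the covariance spectrum, and the screw
decomposition of the PC1 extreme conformers recovers the planted 25°
rotation within the documented ±0.5° (the small translation and the mixed
closure score reflect the planted axis, which is neither a pure closing nor
a pure twisting direction for this geometry).

The same pipeline is scriptable from the shell:

```sh
trajscope simulate hinge --out h --seed 1
trajscope pca h.dump
trajscope domains h.dump
trajscope run --config analysis.yaml   # staged runs with a YAML config
```

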