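# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic test beds do and do not emulate, and the
known limitations. Units are fixed globally: Å, ps, kcal/mol, elementary
charges, amu, degrees, kelvin. Residue numbering is 1-based (PDB
convention); internal atom indexing is 0-based; user-facing tables print
PDB numbering.

## Data model and I/O

A trajectory is a topology (ordered atom metadata with optional per-atom
charge, Lennard-Jones σ/ε, intrinsic Born radius, van der Waals radius and
mass) plus a stack of coordinate frames. Two text dialects are supported:
multi-model PDB (one `MODEL`/`ENDMDL` block per frame; metadata from the
first model; atom-count mismatches and unparsable fields are hard errors
naming the model or line) and a frame-dump format (`natoms N` header, then
`frame <t>` records of N×3 floats) that keeps synthetic fixtures cheap.
Both round-trip coordinates at the 3-decimal precision they print.
Alternate locations keep the first conformer; insertion codes are
rejected. Solvent identity is purely label-based (`water`, `ion`, ...);
no bond or topology perception is attempted. Force-field parameters are
assigned from tab-separated tables keyed by (residue name, atom name) with
`*` wildcards; strict mode makes an unmatched atom an error.

The selection language supports atom names, 1-based residue-id ranges,
chain ids, molecule labels, and `and`/`or` with parentheses. Selections
are deterministic, order-preserving index sets.

## Superposition and fluctuations

The weighted Kabsch solver minimizes Σwᵢ|Rxᵢ + t − yᵢ|² via SVD of the
weighted cross-covariance, with the reflection branch rejected through the
determinant sign. Degenerate geometry (fewer than 3 points, collinear
points) is an error rather than a silent fallback.

RMSF uses the iterated mean-structure protocol: frames are fit to the
running mean and the mean recomputed until it shifts < 10⁻⁹ Å RMS
(typically 2–3 cycles; capped at 100). The equilibration drop defaults to
the first 25% of frames wherever a drop parameter is accepted — trajectory
analyses conventionally discard an equilibration transient, and the exact
cut is configurable. B-factors are B = (8π²/3)·RMSF²; the "normalized B"
is the z-score over the analyzed selection (mean 0, unit sample sd), the
standard way to place systems with different absolute mobilities on one
dimensionless axis. Mass-weighting is off by default for Cα-level
analyses.

## Essential dynamics

The positional covariance C = ⟨ΔrΔrᵀ⟩ (3N×3N) is accumulated over
mean-fitted frames of the analyzed selection only (Cα by default — the
covariance of a full atom set is dominated by side-chain noise), with the
population normalization 1/M so that projection variances equal
eigenvalues exactly. The matrix is symmetrized before `eigh`; eigenvalues
in [−10⁻⁸, 0) Å² are clipped to zero and anything more negative is an
error. Eigenvector signs follow a fixed convention (largest-magnitude
component made positive) so projections are reproducible across platforms.
Extreme conformers are the frames attaining the min/max projection on a
mode; interpolants are generated in mode space from the mean structure, so
the t=0 interpolant is the mode-space reconstruction of the min-extreme
frame. A constant (zero-variance) mode is a "degenerate mode" error.

## Domain and hinge decomposition

For two conformers sharing a selection, each residue's sliding window
(default 5 residues; odd) is rigidly fit A→B and converted to a rotation
vector (axis × angle, degrees). Windows straddling a hinge interpolate
between the two bodies' rotations, so the raw field is boxcar-smoothed
along the sequence (default 5 residues) and clustered by *average*-linkage
at a radius (default 5°) in rotation-vector space, followed by
nearest-cluster-center refinement passes; single linkage is deliberately
avoided because the bridge vectors chain the two bodies into one cluster.
Clusters below the minimum domain size (default 20 residues) dissolve into
their nearest surviving cluster. The largest cluster is the fixed domain;
boundary residues between assignments are the hinges. Two practical
consequences, verified by the tests: a hinge rotation smaller than the
cluster radius cannot be separated (choose the radius below the expected
rotation), and noisy data want wider windows — at 0.3 Å jitter a 21-residue
window with 21-residue smoothing recovers 5–25° hinges within ±1.5°.

Hinge parameters come from a screw decomposition: the conformers are
expressed in the fixed domain's frame, the moving domain's residual rigid
transform (R, t) is split into its rotation angle and axis n̂, the
translation along the axis d = n̂·t, and an axis point from the
least-squares solution of (I − R)p = t⊥ (shifted along n̂ to the moving
centroid's plane for a stable report). Residues within `boundary_trim`
(default 3) of a hinge are excluded from both fits — their windows mix the
bodies and bias the angle. The translation is signed by the right-hand
rule of the rotation.

**Closure definition.** The closure axis ĉ is the rotation-axis direction
that maximally changes the interdomain centroid distance under an
infinitesimal rotation about the screw axis point p: with d̂ the unit
vector between domain centroids and r = c_moving − p, that direction is
ĉ = (r × d̂)/|r × d̂|, automatically perpendicular to the centroid line.
Closure% = 100·(n̂·ĉ)². When ĉ degenerates (the axis passes through the
moving centroid, or p lies on the centroid line) no first-order
centroid-distance change exists and closure is reported as 0; rotations
below 0.1° report closure as missing. Pure closing motions score ~100,
pure interdomain twists ~0, and the two sum to ~100 for a shared geometry.

## Contacts

H-bonds default to the heavy-atom distance criterion at 3.5 Å (a 3.0 Å
strict preset is provided; geometric criteria for base-pair analyses are
conventionally stated on heavy-atom distances); the optional
distance+angle mode adds donor–H–acceptor ≥ 120°. Occupancy is the bonded
fraction of frames; pairs never within the cutoff are omitted. Torsions
follow the IUPAC sign convention, validated against MDAnalysis; a
collinear middle bond yields NaN for that frame.

Hydration sites are found by histogramming water-oxygen positions on a
1.0 Å grid inside a spherical region, thresholding cell occupancy (default
0.40 — chosen to retain the ~50%-occupied sites typical of exchangeable
catalytic-site waters) and merging maxima within 1.5 Å. Site occupancy is
then measured as the fraction of frames with any water within the merge
radius of the site; residence episodes track one molecule's continuous
presence, bridging vacancies up to the gap tolerance (default 2 frames)
only when the *same* molecule returns — a molecule swap always starts a
new episode, so a continuously occupied but exchanging site reports
occupancy 1.0 with multiple episodes.

Coordination reports give per-partner mean ± sd distances (sd over
frames), partner–center–partner angles, and two shape measures: the angle
sum over *consecutive* partners (ordered azimuthally about the center;
~360° for a planar shell, less as the center is pulled out of plane) and
the center's distance from the best-fit partner plane. Channel metrics are
the centroid distance of two atom sets and the area of the 2-D convex hull
of the entrance atoms projected perpendicular to the channel axis (auto:
the inter-centroid direction); the convex hull is used because it is
deterministic and parameter-free, at the cost of overestimating concave
entrances.

## Energetics

Interface Coulomb and 12-6 Lennard-Jones sums run over all cross pairs
with no cutoff (k = 332.0636 kcal·Å/mol·e²; Lorentz–Berthelot combining);
atoms closer than 10⁻³ Å are an error. SASA is Shrake–Rupley with a
deterministic golden-spiral lattice (default 960 points for single-shot
calls, 240 inside the snapshot loop; doubling the count moves a 20-atom
total by < 1%), probe 1.4 Å. The nonpolar term is γ·SASA + β with
γ = 0.00542 kcal/Å²·mol and β = 0.92 kcal/mol per species — note the
binding difference therefore carries one uncancelled −β.

The polar term is generalized Born rather than a finite-difference
Poisson–Boltzmann solve: ΔG = −(k/2)(1/ε_in − 1/ε_out)Σᵢⱼ qᵢqⱼ/f_GB with
f_GB = √(r² + RᵢRⱼ·exp(−r²/4RᵢRⱼ)), ε_in = 1, ε_out = 80, self-terms
included so one ion reduces exactly to the Born closed form. Effective
radii use Hawkins–Cramer–Truhlar pairwise descreening with a uniform
scaling factor 0.8 and zero radius offset — an isolated atom keeps its
intrinsic radius, and burial grows the effective radius. A uniform scale
was chosen over per-element tables because the package's inputs are
generic parameter tables; absolute polar energies therefore differ from
any specific force-field GB variant, while the anchors (Born ion,
rigid-transform invariance, single-trajectory cancellation) are exact.

Entropy is reported as T·S. Translation uses Sackur–Tetrode at the 1 M
standard state; rotation the classical rigid rotor (σ = 1) from the
principal moments of inertia; vibration the harmonic-oscillator sum over
mode frequencies. Quasiharmonic frequencies come from the mass-weighted
covariance of superposed snapshots (ωᵢ = √(k_BT/λᵢ), top 3N−6 modes);
the normal-mode path minimizes a pluggable energy function (default:
Coulomb with the ε = 4r distance-dependent dielectric plus LJ) to a
gradient RMS below 5×10⁻⁵ kcal/mol·Å — failure to reach it, or divergence,
is an error — and diagonalizes a central-difference Hessian (h = 10⁻⁴ Å,
exact for quadratic potentials). The normal-mode system can be truncated
to a radius (default 9 Å) around a ligand center, the standard
cost-control for large complexes; it is intended for small systems
(≲500 atoms) because the Hessian is numeric.

The binding report uses the single-trajectory protocol: receptor and
ligand geometries are extracted from each complex snapshot, so
intramolecular terms cancel identically in Δ = complex − receptor − ligand
and ΔE_ele equals the pure interface Coulomb term (asserted numerically).
Means ± sd are over snapshots (sd with ddof = 1). Default snapshot
handling mirrors common practice: every frame for the components, every
5th for entropy, T = 300 K. The ledger rows — ΔE_ele, ΔE_vdw, ΔG_np,
ΔG_polar, ΔE_ele+ΔG_polar, ΔH, TΔS, ΔG_bind — are always recomputed from
the components, never stored, so the identities ΔH = Σ components and
ΔG = ΔH − TΔS hold by construction.

Per-residue decomposition assigns each residue its atoms' interface
Coulomb + LJ + GB cross terms (complex-geometry effective radii; entropy
omitted as conventionally small per residue), averaged over snapshots;
fractions are of the decomposed total and residues above a configurable
threshold (1.4% receptor-side default, 1.5% for ternary-mode analyses) are
flagged. Experimental affinities convert as ΔG = RT·ln(K_d) with
R = 1.9872×10⁻³ kcal/mol·K.

## Synthetic test beds

The generators are pure functions of spec + seed (single RNG stream each)
and emit JSON manifests of their planted truth, which the tests consume
directly.

* **Two-lobe hinge chains**: Cα-only compact random coils (3.8 Å steps
  confined to lobe spheres, centroid separation > 2× lobe radius of
  gyration) with the outer lobe rotated per frame about a planted axis
  through the pivot Cα — a sinusoid spanning ±amplitude/2, or a two-state
  schedule — plus isotropic Gaussian jitter. Defaults (100+80 residues,
  25° amplitude, 200 frames, 2 ps spacing) sit at the scale of the large
  PAZ-domain hinge motions that motivated the package.
* **Interaction systems**: a donor/acceptor pair snapping between 2.8 Å
  (bonded) and 6.0 Å (unbonded) on an explicit or Bernoulli schedule, with
  an optional water occupying a fixed site on the same schedule.
* **Charged complexes**: non-overlapping random packings with planned
  charges/LJ/Born parameters and brute-force double-loop reference
  energies in the manifest.

These fixtures are kinematic: no force field generates them, water has no
physics, and chains have no sequence. Passing tests therefore demonstrate
that the *analyses* recover planted structure at realistic noise levels —
not that any particular biomolecular conclusion is reproduced. Quantities
that depend on real MD ensembles (absolute RMSDs, variance fractions of a
specific protein, absolute binding components) are out of reach by design;
what is checked against published numbers is the exactly reproducible
ledger arithmetic and the closed-form anchors.

## Determinism

Everything downstream of the seeded generators is deterministic: fixed
SASA lattice (no RNG), fixed eigenvector signs, ordered selections, greedy
highest-count-first site merging with deterministic tie-breaks. Two
pipeline runs with the same config and inputs produce byte-identical
tables; the acceptance script's stochastic quantities vary only through
its --seed.

## Known limitations

* The GB term is a generic HCT variant, not a drop-in for any specific
  force field's radii; absolute polar energies shift accordingly.
* The closure axis is this package's fixed, unit-tested definition; other
  domain-motion tools construct theirs from interdomain screw geometry
  differently, so closure percentages are comparable only in kind.
* Hinges rotating less than the cluster radius are undetectable; the
  window/smoothing/radius trio must be chosen against the noise level.
* Entrance areas use convex hulls and overestimate concave openings.
* Normal-mode entropy scales poorly (numeric Hessian, O(n²) energy
  evaluations) and is intended for truncated subsystems.
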