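"""End-state binding thermodynamics (MM-GBSA style) with per-residue decomposition.

The binding free energy of a complex is assembled from snapshot averages of

    ΔG_bind = ΔE_ele + ΔE_vdw + ΔG_np + ΔG_polar − TΔS
            = ΔH − TΔS,

using the single-trajectory protocol: receptor and ligand geometries are
extracted from each complex snapshot, so intramolecular terms cancel exactly
in the Δ and ΔE_ele reduces to the pure interface Coulomb sum.

Components:

* ``coulomb_interface`` / ``lj_interface`` — pairwise Coulomb (k = 332.0636
  kcal·Å/(mol·e²)) and 12-6 Lennard-Jones (Lorentz–Berthelot combining),
  no cutoff.
* ``sasa`` — Shrake–Rupley solvent-accessible surface area with a
  deterministic golden-spiral point lattice (no RNG), probe 1.4 Å.
* ``nonpolar_energy`` — γ·SASA + β with γ = 0.00542 kcal/(Å²·mol),
  β = 0.92 kcal/mol.
* ``gb_polar`` — generalized-Born polar solvation with the canonical
  f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))) interaction kernel and
  effective radii from HCT-style pairwise descreening; reduces exactly to
  the Born-ion closed form for a single atom.
* ``entropy_estimate`` — translational (Sackur–Tetrode at 1 M standard
  state), rotational (classical rigid rotor), and vibrational entropy
  (harmonic-oscillator sum over quasiharmonic or normal-mode frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as const
from scipy.optimize import minimize

from .model_io import Selection, Topology, Trajectory

__all__ = [
    "COULOMB_K",
    "GAS_CONSTANT_KCAL",
    "NonpolarParams",
    "EnergyComponents",
    "EntropyComponents",
    "BindingReport",
    "ResidueContribution",
    "coulomb_interface",
    "lj_interface",
    "sasa",
    "nonpolar_energy",
    "effective_born_radii",
    "gb_polar",
    "mm_energy_fn",
    "entropy_estimate",
    "mmgbsa_binding",
    "assemble_report",
    "decompose_per_residue",
    "experimental_dg",
]

COULOMB_K = 332.0636            # kcal·Å/(mol·e²)
GAS_CONSTANT_KCAL = 1.9872e-3   # kcal/(mol·K)
OVERLAP_TOL = 1e-3              # Å; closer atoms are an error
HCT_SCALE = 0.8                 # uniform descreening scale factor
DEFAULT_EPS_IN = 1.0
DEFAULT_EPS_OUT = 80.0


@dataclass
class NonpolarParams:
    gamma: float = 0.00542   # kcal/(Å²·mol)
    beta: float = 0.92       # kcal/mol
    probe: float = 1.4       # Å

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.probe <= 0:
            raise ValueError("gamma and probe must be positive")


@dataclass
class EnergyComponents:
    ele: float
    vdw: float
    np_: float
    polar: float

    @property
    def enthalpy(self) -> float:
        return self.ele + self.vdw + self.np_ + self.polar


@dataclass
class EntropyComponents:
    trans: float        # all as T·S, kcal/mol, at `temperature`
    rot: float
    vib: float
    temperature: float

    @property
    def total(self) -> float:
        return self.trans + self.rot + self.vib


@dataclass
class BindingReport:
    """The Table-3-shaped ledger of a binding free energy estimate."""

    ele: tuple[float, float]           # (mean, sd) kcal/mol
    vdw: tuple[float, float]
    np_: tuple[float, float]
    polar: tuple[float, float]
    t_ds: tuple[float, float]
    n_snapshots: int
    temperature: float = 300.0

    @property
    def ele_plus_polar(self) -> float:
        return self.ele[0] + self.polar[0]

    @property
    def dh(self) -> float:
        return self.ele[0] + self.vdw[0] + self.np_[0] + self.polar[0]

    @property
    def dg_bind(self) -> float:
        return self.dh - self.t_ds[0]

    def rows(self) -> list[tuple[str, float, float | None]]:
        """Ledger rows with Table-3 style labels."""
        return [
            ("dE_ele", self.ele[0], self.ele[1]),
            ("dE_vdw", self.vdw[0], self.vdw[1]),
            ("dG_np", self.np_[0], self.np_[1]),
            ("dG_polar", self.polar[0], self.polar[1]),
            ("dE_ele+dG_polar", self.ele_plus_polar, None),
            ("dH", self.dh, None),
            ("TdS", self.t_ds[0], self.t_ds[1]),
            ("dG_bind", self.dg_bind, None),
        ]


@dataclass
class ResidueContribution:
    residue_id: int
    chain_id: str
    residue_name: str
    contribution: float        # kcal/mol
    fraction_of_total: float   # %
    flagged: bool


# ---------------------------------------------------------------------------
# pairwise molecular mechanics

def _check_params(top: Topology, idx: np.ndarray, *fields: str) -> None:
    for i in idx:
        a = top.atoms[int(i)]
        for f in fields:
            if getattr(a, f) is None:
                raise ValueError(f"atom {a.serial} ({a.name}) missing {f}")


def _pair_distances(frame: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    diff = frame[ia][:, None, :] - frame[ib][None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r < OVERLAP_TOL):
        raise ValueError("overlapping atoms across the interface")
    return r


def coulomb_interface(
    frame: np.ndarray,
    top: Topology,
    set_a: Selection,
    set_b: Selection,
    eps_interior: float = 1.0,
) -> float:
    """Interface Coulomb energy Σ k·q_i·q_j/(ε·r_ij), kcal/mol, no cutoff."""
    ia, ib = set_a.asarray(), set_b.asarray()
    if set(ia) & set(ib):
        raise ValueError("interface selections must be disjoint")
    _check_params(top, np.concatenate([ia, ib]), "charge")
    q = top.charges()
    r = _pair_distances(frame, ia, ib)
    return float(COULOMB_K / eps_interior * (np.outer(q[ia], q[ib]) / r).sum())


def lj_interface(
    frame: np.ndarray,
    top: Topology,
    set_a: Selection,
    set_b: Selection,
) -> float:
    """Interface 12-6 Lennard-Jones energy, Lorentz–Berthelot combining."""
    ia, ib = set_a.asarray(), set_b.asarray()
    if set(ia) & set(ib):
        raise ValueError("interface selections must be disjoint")
    _check_params(top, np.concatenate([ia, ib]), "lj_sigma", "lj_epsilon")
    sig = np.array([top.atoms[int(i)].lj_sigma for i in range(top.n_atoms)])
    eps = np.array([top.atoms[int(i)].lj_epsilon for i in range(top.n_atoms)])
    r = _pair_distances(frame, ia, ib)
    sij = 0.5 * (sig[ia][:, None] + sig[ib][None, :])
    eij = np.sqrt(eps[ia][:, None] * eps[ib][None, :])
    s6 = (sij / r) ** 6
    return float((4.0 * eij * (s6**2 - s6)).sum())


# ---------------------------------------------------------------------------
# SASA

def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    frame: np.ndarray,
    top: Topology,
    sel: Selection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley per-atom solvent-accessible surface areas (Å²).

    Each atom's sphere of radius (vdW + probe) is sampled on a fixed
    golden-spiral lattice; points inside any neighbor's expanded sphere are
    occluded. Only atoms in ``sel`` contribute to and occlude the surface.
    """
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    idx = sel.asarray() if sel is not None else np.arange(top.n_atoms)
    _check_params(top, idx, "vdw_radius")
    radii = np.array([top.atoms[int(i)].vdw_radius for i in idx]) + probe
    pos = np.asarray(frame, float)[idx]
    unit = _sphere_lattice(n_points)
    areas = np.zeros(len(idx))
    for k in range(len(idx)):
        pts = pos[k] + radii[k] * unit
        accessible = np.ones(n_points, dtype=bool)
        for m in range(len(idx)):
            if m == k:
                continue
            d_atoms = np.linalg.norm(pos[m] - pos[k])
            if d_atoms >= radii[k] + radii[m]:
                continue
            accessible &= (
                np.linalg.norm(pts - pos[m], axis=1) >= radii[m]
            )
            if not accessible.any():
                break
        areas[k] = 4.0 * np.pi * radii[k] ** 2 * accessible.mean()
    return areas


def nonpolar_energy(total_sasa: float, params: NonpolarParams | None = None) -> float:
    """Nonpolar solvation energy γ·SASA + β (kcal/mol)."""
    if total_sasa < 0:
        raise ValueError("SASA must be non-negative")
    p = params or NonpolarParams()
    return p.gamma * total_sasa + p.beta


# ---------------------------------------------------------------------------
# generalized Born

def effective_born_radii(
    frame: np.ndarray,
    top: Topology,
    idx: np.ndarray,
    scale: float = HCT_SCALE,
) -> np.ndarray:
    """Effective Born radii by HCT-style pairwise descreening.

    1/R_i = 1/ρ_i − Σ_j H(r_ij, s·ρ_j), with the Hawkins–Cramer–Truhlar
    overlap integral H; an isolated atom's effective radius equals its
    intrinsic radius ρ_i. A uniform scaling factor ``scale`` (default 0.8)
    stands in for the per-element tables of production force fields.
    """
    rho = np.array([top.atoms[int(i)].born_radius for i in idx], dtype=float)
    if np.any(np.isnan(rho)) or np.any(rho <= 0):
        raise ValueError("all atoms need a positive intrinsic Born radius")
    pos = np.asarray(frame, float)[idx]
    n = len(idx)
    inv_r = 1.0 / rho
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(r, np.inf)
        sj = scale * rho[None, :] * np.ones((n, 1))
        rho_i = rho[:, None] * np.ones((1, n))
        # integration bounds of the HCT overlap integral, case by case
        case_far = r >= rho_i + sj
        case_mid = (~case_far) & (r > np.abs(rho_i - sj))
        case_in = (~case_far) & (~case_mid) & (rho_i < sj - r)
        L = np.where(case_far, r - sj, rho_i)
        U = np.where(case_far | case_mid, r + sj, np.where(case_in, sj - r, np.inf))
        active = (case_far | case_mid | case_in) & (U > L) & np.isfinite(r)
        Ls = np.where(active, L, 1.0)
        Us = np.where(active, U, 1.0)
        rs = np.where(active, r, 1.0)
        term = (
            1.0 / Ls
            - 1.0 / Us
            + (rs - sj**2 / rs) * 0.25 * (1.0 / Us**2 - 1.0 / Ls**2)
            + 0.5 / rs * np.log(Ls / Us)
        )
        inv_r -= 0.5 * np.where(active, term, 0.0).sum(axis=1)
    if np.any(inv_r <= 0):
        raise ValueError("descreening produced a nonpositive inverse Born radius")
    return 1.0 / inv_r


def gb_polar(
    frame: np.ndarray,
    top: Topology,
    sel: Selection | None = None,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    effective_radii: np.ndarray | None = None,
) -> float:
    """Generalized-Born polar solvation energy (kcal/mol).

    ΔG = −(k/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j) with
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); the double sum includes
    the self terms (i = j, f = R_i), so a single ion reduces to the Born
    closed form.
    """
    idx = sel.asarray() if sel is not None else np.arange(top.n_atoms)
    _check_params(top, idx, "charge", "born_radius")
    q = top.charges()[idx]
    if effective_radii is None:
        R = effective_born_radii(frame, top, idx)
    else:
        R = np.asarray(effective_radii, float)
    if np.any(R <= 0):
        raise ValueError("Born radii must be positive")
    pos = np.asarray(frame, float)[idx]
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    RiRj = np.outer(R, R)
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    prefac = -0.5 * COULOMB_K * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefac * (np.outer(q, q) / f).sum())


# ---------------------------------------------------------------------------
# entropy

# unit bridge: kcal/mol per J, and amu·Å² in SI
_J_PER_KCALMOL = const.calorie * 1000.0 / const.Avogadro


def _trans_entropy(total_mass_amu: float, T: float) -> float:
    """Sackur–Tetrode translational entropy at 1 M standard state, as T·S."""
    m = total_mass_amu * const.atomic_mass
    v = 1e-3 / const.Avogadro  # m³ per molecule at 1 mol/L
    lam3 = (2.0 * np.pi * m * const.k * T / const.h**2) ** 1.5
    s = const.k * (np.log(lam3 * v) + 2.5)
    return T * s / _J_PER_KCALMOL


def _rot_entropy(coords: np.ndarray, masses: np.ndarray, T: float) -> float:
    """Classical rigid-rotor rotational entropy (σ = 1), as T·S."""
    m = masses * const.atomic_mass
    x = (coords - (masses[:, None] * coords).sum(0) / masses.sum()) * 1e-10
    I = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        I += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.linalg.eigvalsh(I)
    moments = moments[moments > 1e-60]
    if len(moments) < 2:
        return 0.0  # a point or single atom has no rotational entropy
    if len(moments) == 2:  # linear molecule
        theta = const.hbar**2 / (2.0 * moments.max() * const.k)
        s = const.k * (np.log(T / theta) + 1.0)
    else:
        prod = np.prod(8.0 * np.pi**2 * moments * const.k * T / const.h**2)
        s = const.k * (np.log(np.sqrt(np.pi * prod)) + 1.5)
    return T * s / _J_PER_KCALMOL


def _vib_entropy_from_freqs(freqs_hz: np.ndarray, T: float) -> float:
    """Harmonic-oscillator vibrational entropy over mode frequencies, as T·S."""
    s = 0.0
    for nu in freqs_hz:
        if nu <= 0:
            continue
        x = const.h * nu / (const.k * T)
        if x > 300:  # stiff mode: entropy underflows to zero
            continue
        s += const.k * (x / (np.expm1(x)) - np.log(-np.expm1(-x)))
    return T * s / _J_PER_KCALMOL


def _quasiharmonic_freqs(
    snapshots: np.ndarray, masses: np.ndarray, T: float
) -> np.ndarray:
    """Mode frequencies from the mass-weighted covariance of fitted snapshots.

    Modes with λ ≤ λ_max·1e−9 (the six rigid-body directions and numerical
    zeros) are dropped; ω_i = sqrt(k_B T / λ_i) in mass-weighted coordinates.
    """
    from .superpose import iterated_mean_fit

    fitted, mean = iterated_mean_fit(snapshots)
    M, N = fitted.shape[0], fitted.shape[1]
    w = np.repeat(np.sqrt(masses * const.atomic_mass), 3)
    D = (fitted - mean).reshape(M, 3 * N) * 1e-10 * w  # kg^1/2·m
    C = (D.T @ D) / M
    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > max(lam.max(), 0) * 1e-9 + 1e-300]
    n_internal = max(3 * N - 6, 0)
    lam = np.sort(lam)[::-1][:n_internal]
    return np.sqrt(const.k * T / lam) / (2.0 * np.pi)


def _normal_mode_freqs(
    coords: np.ndarray,
    masses: np.ndarray,
    energy_fn,
    grad_tol: float = 5e-5,
    h: float = 1e-4,
) -> np.ndarray:
    """Frequencies from a numeric Hessian after minimization.

    ``energy_fn(flat_coords) -> kcal/mol``. The structure is minimized until
    the RMS gradient is below ``grad_tol`` kcal/(mol·Å); the mass-weighted
    Hessian's positive eigenvalues (beyond the six rigid-body modes) give
    the frequencies.
    """
    x0 = np.asarray(coords, float).ravel()

    def grad(x):
        g = np.empty_like(x)
        for i in range(len(x)):
            xp = x.copy(); xp[i] += h
            xm = x.copy(); xm[i] -= h
            g[i] = (energy_fn(xp) - energy_fn(xm)) / (2 * h)
        return g

    res = minimize(energy_fn, x0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
    if not np.isfinite(res.fun) or np.max(np.abs(res.x)) > 1e6:
        raise ValueError("minimization diverged; no gradient-tolerance minimum")
    g = grad(res.x)
    if np.sqrt(np.mean(g**2)) > grad_tol:
        raise ValueError(
            f"minimization did not reach gradient RMS {grad_tol}; "
            f"got {np.sqrt(np.mean(g ** 2)):.2e}"
        )
    x = res.x
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        H[i] = (grad(xp) - grad(xm)) / (2 * h)
    H = 0.5 * (H + H.T)
    # kcal/(mol·Å²) → J/m²  (per molecule)
    H_si = H * _J_PER_KCALMOL / 1e-20
    w = np.repeat(1.0 / np.sqrt(masses * const.atomic_mass), 3)
    Hmw = H_si * np.outer(w, w)
    lam = np.linalg.eigvalsh(Hmw)
    n_internal = max(n - 6, 1) if len(masses) > 2 else max(3 * len(masses) - 5, 1)
    lam = np.sort(lam)[::-1][:n_internal]
    lam = lam[lam > 1e-8 * max(lam.max(), 1e-30)]
    return np.sqrt(lam) / (2.0 * np.pi)


def mm_energy_fn(top: Topology, idx: np.ndarray):
    """Pairwise MM energy (kcal/mol) with the ε = 4r distance-dependent
    dielectric Coulomb term plus 12-6 LJ, for normal-mode minimization.

    Returns a callable of the flattened (3n,) coordinate vector in Å.
    """
    _check_params(top, idx, "charge", "lj_sigma", "lj_epsilon")
    q = top.charges()[idx]
    sig = np.array([top.atoms[int(i)].lj_sigma for i in idx])
    eps = np.array([top.atoms[int(i)].lj_epsilon for i in idx])
    n = len(idx)
    iu, ju = np.triu_indices(n, k=1)
    qq = q[iu] * q[ju]
    sij = 0.5 * (sig[iu] + sig[ju])
    eij = np.sqrt(eps[iu] * eps[ju])

    def energy(x: np.ndarray) -> float:
        pos = x.reshape(n, 3)
        d = pos[iu] - pos[ju]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        ele = COULOMB_K * qq / (4.0 * r**2)   # ε = 4r ⇒ q_i q_j / (4 r²)
        s6 = (sij / r) ** 6
        return float((ele + 4.0 * eij * (s6**2 - s6)).sum())

    return energy


def entropy_estimate(
    snapshots: np.ndarray,
    top: Topology,
    sel: Selection | None = None,
    method: str = "quasiharmonic",
    T: float = 300.0,
    truncation_radius: float = 9.0,
    ligand_center: np.ndarray | None = None,
    energy_fn=None,
) -> EntropyComponents:
    """Solute entropy (reported as T·S, kcal/mol) from snapshot geometries.

    ``quasiharmonic`` derives vibrational frequencies from the mass-weighted
    covariance of the snapshots; ``normal-mode`` minimizes the (optionally
    truncated to ``truncation_radius`` Å around ``ligand_center``) system
    under ``energy_fn`` and diagonalizes a numeric Hessian. Translational
    and rotational terms use the closed forms at 1 M standard state.
    """
    if method not in ("quasiharmonic", "normal-mode"):
        raise ValueError(f"unknown entropy method {method!r}")
    X = np.asarray(snapshots, float)
    if X.ndim == 2:
        X = X[None]
    idx = sel.asarray() if sel is not None else np.arange(top.n_atoms)
    X = X[:, idx, :]
    masses = top.masses()[idx]

    if method == "normal-mode" and ligand_center is not None:
        d = np.linalg.norm(X[0] - ligand_center, axis=1)
        keep = d <= truncation_radius
        X = X[:, keep, :]
        masses = masses[keep]

    trans = _trans_entropy(masses.sum(), T)
    rot = _rot_entropy(X[0], masses, T) if X.shape[1] >= 2 else 0.0
    if X.shape[1] < 2:
        vib = 0.0
    elif method == "quasiharmonic":
        if X.shape[0] < 2:
            raise ValueError("quasiharmonic entropy needs at least 2 snapshots")
        freqs = _quasiharmonic_freqs(X, masses, T)
        vib = _vib_entropy_from_freqs(freqs, T)
    else:
        if energy_fn is None:
            raise ValueError("normal-mode entropy requires an energy function")
        freqs = _normal_mode_freqs(X[0], masses, energy_fn)
        vib = _vib_entropy_from_freqs(freqs, T)
    return EntropyComponents(trans=trans, rot=rot, vib=vib, temperature=T)


# ---------------------------------------------------------------------------
# assembly

def _components_for(
    frame: np.ndarray,
    top: Topology,
    receptor: Selection,
    ligand: Selection,
    nonpolar: NonpolarParams,
    sasa_points: int,
) -> EnergyComponents:
    """Δ(complex − receptor − ligand) per component for one snapshot."""
    ele = coulomb_interface(frame, top, receptor, ligand)
    vdw = lj_interface(frame, top, receptor, ligand)

    ir, il = receptor.asarray(), ligand.asarray()
    ic = np.concatenate([ir, il])
    sel_c = Selection(tuple(int(i) for i in ic))
    a_c = sasa(frame, top, sel_c, nonpolar.probe, sasa_points).sum()
    a_r = sasa(frame, top, receptor, nonpolar.probe, sasa_points).sum()
    a_l = sasa(frame, top, ligand, nonpolar.probe, sasa_points).sum()
    np_term = (
        nonpolar_energy(a_c, nonpolar)
        - nonpolar_energy(a_r, nonpolar)
        - nonpolar_energy(a_l, nonpolar)
    )

    polar = (
        gb_polar(frame, top, sel_c)
        - gb_polar(frame, top, receptor)
        - gb_polar(frame, top, ligand)
    )
    return EnergyComponents(ele=ele, vdw=vdw, np_=np_term, polar=polar)


def mmgbsa_binding(
    traj: Trajectory,
    receptor: Selection,
    ligand: Selection,
    snapshot_stride: int = 1,
    entropy_stride: int = 5,
    T: float = 300.0,
    entropy_method: str | None = "quasiharmonic",
    nonpolar: NonpolarParams | None = None,
    sasa_points: int = 240,
) -> BindingReport:
    """Single-trajectory MM-GBSA binding report (Table-3-shaped ledger).

    Per retained snapshot, each component is evaluated for the complex and
    for the receptor/ligand geometries extracted from that same snapshot;
    means ± sd over snapshots are assembled into ΔH − TΔS. Entropy uses
    every ``entropy_stride``-th retained snapshot; ``entropy_method=None``
    skips the entropy term (TΔS = 0).
    """
    if set(receptor.asarray()) & set(ligand.asarray()):
        raise ValueError("receptor and ligand selections overlap")
    nonpolar = nonpolar or NonpolarParams()
    frames = traj.frames[::snapshot_stride]
    comps = [
        _components_for(f, traj.topology, receptor, ligand, nonpolar, sasa_points)
        for f in frames
    ]
    ele = np.array([c.ele for c in comps])
    vdw = np.array([c.vdw for c in comps])
    np_t = np.array([c.np_ for c in comps])
    pol = np.array([c.polar for c in comps])

    if entropy_method is None:
        t_ds = (0.0, 0.0)
    else:
        sub = frames[::entropy_stride]
        if len(sub) < 2 and entropy_method == "quasiharmonic":
            sub = frames
        sc = entropy_estimate(sub, traj.topology,
                              Selection(tuple(int(i) for i in np.concatenate(
                                  [receptor.asarray(), ligand.asarray()]))),
                              method=entropy_method, T=T)
        sr = entropy_estimate(sub, traj.topology, receptor,
                              method=entropy_method, T=T)
        sl = entropy_estimate(sub, traj.topology, ligand,
                              method=entropy_method, T=T)
        t_ds = (sc.total - sr.total - sl.total, 0.0)

    def ms(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0

    return BindingReport(
        ele=ms(ele), vdw=ms(vdw), np_=ms(np_t), polar=ms(pol),
        t_ds=t_ds, n_snapshots=len(frames), temperature=T,
    )


def assemble_report(
    ele: tuple[float, float],
    vdw: tuple[float, float],
    np_: tuple[float, float],
    polar: tuple[float, float],
    t_ds: tuple[float, float],
    n_snapshots: int = 0,
    temperature: float = 300.0,
) -> BindingReport:
    """Assemble a ledger directly from component means ± sd.

    The derived rows (ΔE_ele+ΔG_polar, ΔH, ΔG_bind) are always recomputed
    from the components, never stored — the ledger identities hold by
    construction.
    """
    return BindingReport(ele=ele, vdw=vdw, np_=np_, polar=polar,
                         t_ds=t_ds, n_snapshots=n_snapshots,
                         temperature=temperature)


def decompose_per_residue(
    traj: Trajectory,
    receptor: Selection,
    ligand: Selection,
    threshold_fraction: float = 1.4,
    snapshot_stride: int = 1,
    side: str = "receptor",
) -> list[ResidueContribution]:
    """Per-residue share of the interface interaction energy (MM-GBSA style).

    Each receptor residue's (or ligand nucleotide's, ``side='ligand'``)
    contribution is its atoms' interface Coulomb + LJ + GB cross terms,
    averaged over snapshots; the entropy term is omitted. Residues whose
    fraction of the decomposed total exceeds ``threshold_fraction`` (%) are
    flagged.
    """
    if not 0.0 < threshold_fraction < 100.0:
        raise ValueError("threshold_fraction must be in (0, 100)")
    if side not in ("receptor", "ligand"):
        raise ValueError("side must be 'receptor' or 'ligand'")
    top = traj.topology
    ir, il = receptor.asarray(), ligand.asarray()
    mine, other = (ir, il) if side == "receptor" else (il, ir)
    _check_params(top, np.concatenate([ir, il]),
                  "charge", "lj_sigma", "lj_epsilon", "born_radius")
    q = top.charges()
    sig = np.array([a.lj_sigma for a in top.atoms], dtype=float)
    eps = np.array([a.lj_epsilon for a in top.atoms], dtype=float)

    frames = traj.frames[::snapshot_stride]
    per_atom = np.zeros(len(mine))
    all_idx = np.concatenate([ir, il])
    sel_all = Selection(tuple(int(i) for i in all_idx))
    gb_pref = -0.5 * COULOMB_K * (1.0 / DEFAULT_EPS_IN - 1.0 / DEFAULT_EPS_OUT)
    for frame in frames:
        r = _pair_distances(frame, mine, other)
        ele = COULOMB_K * np.outer(q[mine], q[other]) / r
        sij = 0.5 * (sig[mine][:, None] + sig[other][None, :])
        eij = np.sqrt(eps[mine][:, None] * eps[other][None, :])
        s6 = (sij / r) ** 6
        vdw = 4.0 * eij * (s6**2 - s6)
        # GB cross terms between the two sides (complex effective radii)
        R = effective_born_radii(frame, top, all_idx)
        Rmap = {int(i): R[k] for k, i in enumerate(all_idx)}
        Rm = np.array([Rmap[int(i)] for i in mine])
        Ro = np.array([Rmap[int(i)] for i in other])
        RiRj = np.outer(Rm, Ro)
        f = np.sqrt(r**2 + RiRj * np.exp(-(r**2) / (4.0 * RiRj)))
        gb = 2.0 * gb_pref * np.outer(q[mine], q[other]) / f  # i–j and j–i
        per_atom += (ele + vdw + gb).sum(axis=1)
    per_atom /= len(frames)

    # aggregate to residues
    keys: dict[tuple[str, int, str], float] = {}
    for k, i in enumerate(mine):
        a = top.atoms[int(i)]
        key = (a.chain_id, a.residue_id, a.residue_name)
        keys[key] = keys.get(key, 0.0) + per_atom[k]
    total = sum(keys.values())
    out = []
    for (chain, resid, resname), contrib in sorted(keys.items()):
        frac = 100.0 * contrib / total if total != 0 else 0.0
        out.append(
            ResidueContribution(
                residue_id=resid, chain_id=chain, residue_name=resname,
                contribution=contrib, fraction_of_total=frac,
                flagged=frac > threshold_fraction,
            )
        )
    return out


def experimental_dg(Kd: float, T: float = 300.0) -> float:
    """ΔG_bind = RT·ln(Kd) in kcal/mol (Kd in molar units)."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT_KCAL * T * np.log(Kd)
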