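"""Molecular-mechanics, solvation, entropy and binding-ledger oracles."""

import numpy as np
import pytest
from scipy import constants as const

from trajscope.energetics import (
    COULOMB_K,
    GAS_CONSTANT_KCAL,
    NonpolarParams,
    assemble_report,
    coulomb_interface,
    decompose_per_residue,
    effective_born_radii,
    entropy_estimate,
    experimental_dg,
    gb_polar,
    lj_interface,
    mm_energy_fn,
    mmgbsa_binding,
    nonpolar_energy,
    sasa,
)
from trajscope.model_io import AtomRecord, Selection, Topology, Trajectory
from trajscope.synthetic_data import ChargePlan, make_charged_complex


def sel(*indices):
    return Selection(tuple(indices))


def atoms_with(n, **params):
    return Topology([
        AtomRecord(serial=i + 1, name="C", residue_name="UNK",
                   residue_id=i + 1, **params)
        for i in range(n)
    ])


class TestCoulomb:
    def test_unit_charges_analytic_value(self):
        """±1 e at k/100 Å with ε=1 is exactly −100 kcal/mol."""
        top = atoms_with(2, charge=1.0)
        top.atoms[1].charge = -1.0
        frame = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        e = coulomb_interface(frame, top, sel(0), sel(1))
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_zero_charge_gives_zero(self):
        top = atoms_with(2, charge=0.0)
        top.atoms[0].charge = 1.0
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert coulomb_interface(frame, top, sel(0), sel(1)) == 0.0

    def test_dielectric_linearity(self):
        top = atoms_with(2, charge=1.0)
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        e1 = coulomb_interface(frame, top, sel(0), sel(1), eps_interior=1.0)
        e2 = coulomb_interface(frame, top, sel(0), sel(1), eps_interior=2.0)
        assert e2 == pytest.approx(e1 / 2.0)

    def test_overlapping_atoms_raise(self):
        top = atoms_with(2, charge=1.0)
        frame = np.zeros((2, 3))
        with pytest.raises(ValueError, match="overlap"):
            coulomb_interface(frame, top, sel(0), sel(1))


class TestLennardJones:
    def make_pair(self, r, sigma=3.0, eps=0.2):
        top = atoms_with(2, lj_sigma=sigma, lj_epsilon=eps)
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        return top, frame

    def test_minimum_at_2_to_the_sixth_sigma(self):
        top, frame = self.make_pair(2 ** (1 / 6) * 3.0)
        assert lj_interface(frame, top, sel(0), sel(1)) == pytest.approx(-0.2)

    def test_zero_at_sigma(self):
        top, frame = self.make_pair(3.0)
        assert lj_interface(frame, top, sel(0), sel(1)) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_additivity(self):
        top = atoms_with(3, lj_sigma=3.0, lj_epsilon=0.2)
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 5.0, 0]])
        total = lj_interface(frame, top, sel(0), sel(1, 2))
        parts = (lj_interface(frame, top, sel(0), sel(1))
                 + lj_interface(frame, top, sel(0), sel(2)))
        assert total == pytest.approx(parts, rel=1e-12)


def test_interface_energies_match_generator_double_loop_oracle():
    top, coords, manifest = make_charged_complex(10, 5, seed=11)
    rec = sel(*range(10))
    lig = sel(*range(10, 15))
    assert coulomb_interface(coords, top, rec, lig) == pytest.approx(
        manifest["reference_coulomb"], abs=1e-10
    )
    assert lj_interface(coords, top, rec, lig) == pytest.approx(
        manifest["reference_lj"], abs=1e-10
    )


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        top = atoms_with(1, vdw_radius=2.0)
        areas = sasa(np.zeros((1, 3)), top, probe=1.4, n_points=960)
        assert areas[0] == pytest.approx(4 * np.pi * 3.4**2, rel=0.02)

    def test_buried_atom_has_zero_area(self):
        # central atom caged by 14 overlapping large spheres
        shell = []
        for v in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1]):
            shell.append(np.array(v, float) * 2.0)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shell.append(np.array([sx, sy, sz], float) * 1.4)
        frame = np.vstack([np.zeros(3), shell])
        top = atoms_with(len(frame), vdw_radius=2.0)
        areas = sasa(frame, top, probe=1.4, n_points=240)
        assert areas[0] == 0.0

    def test_distant_atoms_are_additive(self):
        top = atoms_with(2, vdw_radius=1.8)
        frame = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        pair = sasa(frame, top, n_points=240)
        solo = sasa(np.zeros((1, 3)), atoms_with(1, vdw_radius=1.8),
                    n_points=240)
        assert pair.sum() == pytest.approx(2 * solo[0], rel=1e-12)

    def test_two_sphere_overlap_matches_spherical_cap_formula(self):
        """Analytic oracle: equal spheres lose a cap of area 2πa·h each."""
        r, probe, d = 1.7, 1.4, 3.0
        a = r + probe
        h = a - d / 2.0
        expected_each = 4 * np.pi * a**2 - 2 * np.pi * a * h
        top = atoms_with(2, vdw_radius=r)
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa(frame, top, probe=probe, n_points=960)
        assert areas[0] == pytest.approx(expected_each, rel=0.02)
        assert areas[1] == pytest.approx(expected_each, rel=0.02)

    def test_point_doubling_converges_within_1pct(self):
        rng = np.random.default_rng(6)
        frame = rng.uniform(0, 8, size=(20, 3))
        top = atoms_with(20, vdw_radius=1.7)
        a1 = sasa(frame, top, n_points=480).sum()
        a2 = sasa(frame, top, n_points=960).sum()
        assert abs(a2 - a1) / a2 < 0.01

    def test_missing_radius_raises(self):
        top = atoms_with(1)
        with pytest.raises(ValueError, match="vdw_radius"):
            sasa(np.zeros((1, 3)), top)


class TestNonpolar:
    def test_intercept_at_zero_area(self):
        assert nonpolar_energy(0.0) == pytest.approx(0.92)

    def test_linear_form_with_standard_constants(self):
        assert nonpolar_energy(1000.0) == pytest.approx(6.34)

    def test_beta_cancels_once_in_binding_difference(self):
        p = NonpolarParams()
        ac, ar, al = 500.0, 300.0, 250.0
        delta = (nonpolar_energy(ac, p) - nonpolar_energy(ar, p)
                 - nonpolar_energy(al, p))
        assert delta == pytest.approx(p.gamma * (ac - ar - al) - p.beta)

    def test_negative_area_raises(self):
        with pytest.raises(ValueError):
            nonpolar_energy(-1.0)


class TestGeneralizedBorn:
    def test_single_ion_reduces_to_born_closed_form(self):
        top = atoms_with(1, charge=1.0, born_radius=2.0)
        e = gb_polar(np.zeros((1, 3)), top)
        expected = -(COULOMB_K / 2) * (1 - 1 / 80.0) / 2.0
        assert e == pytest.approx(expected, abs=1e-9)
        assert e == pytest.approx(-81.98, abs=0.005)

    def test_isolated_atom_keeps_intrinsic_radius(self):
        top = atoms_with(1, charge=1.0, born_radius=1.5)
        R = effective_born_radii(np.zeros((1, 3)), top, np.array([0]))
        assert R[0] == pytest.approx(1.5)

    def test_neighbor_burial_grows_effective_radius(self):
        # a neighbor displaces solvent, so the effective radius exceeds the
        # intrinsic one, and more so the closer the neighbor
        top = atoms_with(2, charge=0.5, born_radius=1.5)
        near = np.array([[0.0, 0, 0], [3.2, 0, 0]])
        far = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        R_near = effective_born_radii(near, top, np.array([0, 1]))
        R_far = effective_born_radii(far, top, np.array([0, 1]))
        assert np.all(R_near > 1.5)
        assert np.all(R_near > R_far)
        assert np.all(R_far > 1.5)

    def test_zero_charges_give_zero(self):
        top = atoms_with(3, charge=0.0, born_radius=1.5)
        frame = np.random.default_rng(0).uniform(0, 5, (3, 3))
        assert gb_polar(frame, top) == 0.0

    def test_matched_dielectrics_vanish(self):
        top = atoms_with(2, charge=1.0, born_radius=1.5)
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert gb_polar(frame, top, eps_in=80.0, eps_out=80.0) == pytest.approx(0.0)

    def test_invariant_under_rigid_transform(self):
        from scipy.spatial.transform import Rotation

        top = atoms_with(5, charge=0.4, born_radius=1.6)
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 6, (5, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        moved = (R @ frame.T).T + np.array([9.0, -2.0, 4.0])
        assert gb_polar(frame, top) == pytest.approx(gb_polar(moved, top),
                                                     rel=1e-10)

    def test_nonpositive_radius_raises(self):
        top = atoms_with(1, charge=1.0, born_radius=1.5)
        top.atoms[0].born_radius = -1.0
        with pytest.raises(ValueError):
            gb_polar(np.zeros((1, 3)), top)


class TestEntropy:
    def test_single_free_atom_matches_sackur_tetrode(self):
        """Closed-form oracle computed independently from SI constants."""
        mass_amu, T = 40.0, 300.0
        top = atoms_with(1, mass=mass_amu)
        out = entropy_estimate(np.zeros((2, 1, 3)), top, method="quasiharmonic",
                               T=T)
        m = mass_amu * const.atomic_mass
        lam3 = (2 * np.pi * m * const.k * T / const.h**2) ** 1.5
        v = 1e-3 / const.Avogadro
        s_kcal = const.k * (np.log(lam3 * v) + 2.5) * const.Avogadro \
            / (1000.0 * const.calorie)
        assert out.rot == 0.0
        assert out.vib == 0.0
        assert out.trans == pytest.approx(T * s_kcal, rel=1e-9)

    def test_harmonic_diatomic_matches_oscillator_closed_form(self):
        k_force = 100.0  # kcal/mol/Å²
        mass, T = 16.0, 300.0
        top = atoms_with(2, mass=mass, charge=0.0)
        coords = np.array([[[0.0, 0, 0], [1.5, 0, 0]]])

        def energy(x):
            p = x.reshape(2, 3)
            r = np.linalg.norm(p[1] - p[0])
            return 0.5 * k_force * (r - 1.5) ** 2

        out = entropy_estimate(coords, top, method="normal-mode", T=T,
                               energy_fn=energy)
        mu = mass / 2 * const.atomic_mass
        k_si = k_force * 1000.0 * const.calorie / const.Avogadro / 1e-20
        nu = np.sqrt(k_si / mu) / (2 * np.pi)
        x = const.h * nu / (const.k * T)
        s = const.k * (x / np.expm1(x) - np.log(-np.expm1(-x)))
        expected = T * s * const.Avogadro / (1000.0 * const.calorie)
        assert out.vib == pytest.approx(expected, rel=1e-6)

    def test_rigid_snapshots_have_zero_quasiharmonic_vib(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 8, (1, 6, 3))
        snaps = np.repeat(coords, 5, axis=0)
        top = atoms_with(6, mass=12.0)
        out = entropy_estimate(snaps, top, method="quasiharmonic", T=300.0)
        assert out.vib == pytest.approx(0.0, abs=1e-9)
        assert out.rot > 0.0

    def test_totals_identity(self):
        rng = np.random.default_rng(3)
        snaps = rng.uniform(0, 8, (10, 4, 3))
        top = atoms_with(4, mass=14.0)
        out = entropy_estimate(snaps, top, method="quasiharmonic", T=300.0)
        assert out.total == pytest.approx(out.trans + out.rot + out.vib)

    def test_unminimizable_system_raises(self):
        top = atoms_with(2, mass=12.0)
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])

        def bad_energy(x):  # linear potential: no minimum exists
            return float(x[0])

        with pytest.raises(ValueError, match="gradient|diverged"):
            entropy_estimate(coords, top, method="normal-mode",
                             energy_fn=bad_energy)


class TestBindingLedger:
    def test_printed_component_means_assemble_to_printed_totals(self):
        """Published ledger check: the component rows for a protein–RNA
        complex reproduce the printed ΔH, ΔE_ele+ΔG_polar and ΔG_bind."""
        binary = assemble_report(
            ele=(-10765.22, 61.14), vdw=(-330.00, 11.10),
            np_=(-48.51, 0.18), polar=(11002.22, 62.58),
            t_ds=(-123.14, 30.43), n_snapshots=500,
        )
        assert binary.ele_plus_polar == pytest.approx(237.00, abs=0.01)
        assert binary.dh == pytest.approx(-141.51, abs=0.01)
        assert binary.dg_bind == pytest.approx(-18.37, abs=0.01)
        ternary = assemble_report(
            ele=(-1739.81, 40.55), vdw=(-187.51, 9.76),
            np_=(-29.72, 0.56), polar=(1844.13, 35.63),
            t_ds=(-82.99, 25.53), n_snapshots=500,
        )
        # the printed table rounds this row to 104.31; the exact component
        # sum is 104.32
        assert ternary.ele_plus_polar == pytest.approx(104.32, abs=0.015)
        assert ternary.dh == pytest.approx(-112.91, abs=0.01)
        assert ternary.dg_bind == pytest.approx(-29.92, abs=0.01)

    def test_ledger_identities_hold_on_computed_reports(self):
        top, coords, _ = make_charged_complex(8, 4, seed=5)
        traj = Trajectory(top, np.repeat(coords[None], 3, axis=0) +
                          np.random.default_rng(5).normal(
                              scale=0.05, size=(3, 12, 3)))
        rep = mmgbsa_binding(traj, sel(*range(8)), sel(*range(8, 12)),
                             entropy_method=None, sasa_points=120)
        assert rep.dh == pytest.approx(
            rep.ele[0] + rep.vdw[0] + rep.np_[0] + rep.polar[0])
        assert rep.dg_bind == pytest.approx(rep.dh - rep.t_ds[0])
        assert rep.ele_plus_polar == pytest.approx(rep.ele[0] + rep.polar[0])
        assert all(s >= 0 for _, _, s in
                   [r for r in rep.rows() if r[2] is not None])

    def test_neutral_distant_ligand_leaves_only_the_np_intercept(self):
        plan = ChargePlan(
            receptor_charges=tuple([0.3] * 6), ligand_charges=(0.0, 0.0),
            lj_epsilon=0.2,
        )
        top, coords, _ = make_charged_complex(6, 2, plan=plan, seed=8)
        for a in top.atoms[6:]:
            a.lj_epsilon = 0.0
        coords = coords.copy()
        coords[6:] += np.array([500.0, 0.0, 0.0])
        traj = Trajectory(top, coords[None])
        rep = mmgbsa_binding(traj, sel(*range(6)), sel(6, 7),
                             entropy_method=None, sasa_points=120)
        assert rep.ele[0] == pytest.approx(0.0, abs=1e-8)
        assert rep.vdw[0] == pytest.approx(0.0, abs=1e-8)
        assert rep.polar[0] == pytest.approx(0.0, abs=1e-8)
        # per-species γ·SASA+β leaves exactly one −β in the difference
        assert rep.np_[0] == pytest.approx(-NonpolarParams().beta, abs=1e-6)

    def test_single_snapshot_sd_is_zero(self):
        top, coords, _ = make_charged_complex(5, 3, seed=2)
        traj = Trajectory(top, coords[None])
        rep = mmgbsa_binding(traj, sel(*range(5)), sel(5, 6, 7),
                             entropy_method=None, sasa_points=120)
        assert rep.ele[1] == 0.0 and rep.vdw[1] == 0.0

    def test_overlapping_selections_raise(self):
        top, coords, _ = make_charged_complex(5, 3, seed=2)
        traj = Trajectory(top, coords[None])
        with pytest.raises(ValueError, match="overlap"):
            mmgbsa_binding(traj, sel(0, 1, 2), sel(2, 3))

    def test_single_trajectory_delta_ele_is_pure_interface_term(self):
        """Intramolecular terms cancel in Δ, so Δele equals the interface
        Coulomb sum computed independently."""
        top, coords, manifest = make_charged_complex(8, 4, seed=7)
        traj = Trajectory(top, coords[None])
        rep = mmgbsa_binding(traj, sel(*range(8)), sel(*range(8, 12)),
                             entropy_method=None, sasa_points=120)
        assert rep.ele[0] == pytest.approx(manifest["reference_coulomb"],
                                           abs=1e-10)


class TestDecomposition:
    def test_contributions_sum_to_decomposed_total(self):
        top, coords, _ = make_charged_complex(8, 4, seed=4)
        traj = Trajectory(top, coords[None])
        rec, lig = sel(*range(8)), sel(*range(8, 12))
        contribs = decompose_per_residue(traj, rec, lig)
        total = sum(c.contribution for c in contribs)
        fracs = sum(c.fraction_of_total for c in contribs)
        assert fracs == pytest.approx(100.0, rel=1e-6)
        assert total != 0.0

    def test_lone_charged_residue_takes_all(self):
        plan = ChargePlan(
            receptor_charges=(1.0,) + (0.0,) * 5,
            ligand_charges=(-1.0, 0.0),
            lj_epsilon=0.0,
        )
        top, coords, _ = make_charged_complex(6, 2, plan=plan, seed=6)
        traj = Trajectory(top, coords[None])
        contribs = decompose_per_residue(traj, sel(*range(6)), sel(6, 7))
        by_res = {c.residue_id: c for c in contribs}
        assert by_res[1].fraction_of_total == pytest.approx(100.0, abs=1e-6)
        assert by_res[1].flagged

    def test_threshold_out_of_range_raises(self):
        top, coords, _ = make_charged_complex(4, 2, seed=1)
        traj = Trajectory(top, coords[None])
        with pytest.raises(ValueError):
            decompose_per_residue(traj, sel(0, 1, 2, 3), sel(4, 5),
                                  threshold_fraction=101.0)


class TestExperimentalDg:
    def test_kd_of_one_molar_is_zero(self):
        assert experimental_dg(1.0, 300.0) == 0.0

    def test_subnanomolar_kd_closed_form(self):
        expected = GAS_CONSTANT_KCAL * 300.0 * np.log(1e-10)
        assert experimental_dg(1e-10, 300.0) == pytest.approx(expected)
        assert experimental_dg(1e-10, 300.0) == pytest.approx(-13.73, abs=0.005)

    def test_monotone_in_kd(self):
        assert experimental_dg(1e-6) > experimental_dg(1e-9)

    def test_nonpositive_kd_raises(self):
        with pytest.raises(ValueError):
            experimental_dg(0.0)


def test_mm_energy_fn_uses_distance_dependent_dielectric():
    top = atoms_with(2, charge=1.0, lj_sigma=0.1, lj_epsilon=0.0)
    fn = mm_energy_fn(top, np.array([0, 1]))
    x = np.array([0.0, 0, 0, 4.0, 0, 0])
    # ε = 4r ⇒ E = k q₁q₂ / (4 r²)
    assert fn(x) == pytest.approx(COULOMB_K / (4 * 16.0), rel=1e-9)
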