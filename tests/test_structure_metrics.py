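"""Structural descriptors: RDF/KB nulls, planted signals, closed-form checks."""

import math

import numpy as np
import pytest

from somsorb import (
    InvalidInputError,
    clustered_mixture_box,
    ideal_gas_box,
    hydrogen_bonds,
    kb_integral,
    pair_interaction_energy,
    planted_hbond_frame,
    preferential_solvation,
    radial_distribution,
    sasa,
    select,
)
from somsorb.structure_metrics import (
    Frame,
    HBondCriterion,
    RdfProfile,
    delta_coefficient,
)


def _bare_frame(coords, box, species=None, classes=None, **kw):
    n = len(coords)
    return Frame(
        coordinates=np.asarray(coords, dtype=float),
        box=np.asarray(box, dtype=float),
        species=np.asarray(species if species is not None else ["LHA"] * n),
        element_class=np.asarray(classes if classes is not None else ["carbon"] * n),
        **kw,
    )


@pytest.fixture(scope="module")
def ideal_frames():
    return [ideal_gas_box(n=2000, seed=(5, i)) for i in range(5)]


class TestRadialDistribution:
    def test_ideal_gas_is_uniform(self, ideal_frames):
        f = ideal_frames[0]
        sel = select(f, species=("LHA", "water"))
        prof = radial_distribution(ideal_frames, sel, sel, 0.02, 1.5)
        mask = prof.bin_centers >= 0.3
        assert np.abs(prof.g[mask] - 1.0).max() < 0.05

    def test_planted_pair_occupies_single_bin(self):
        d = 0.73
        f = _bare_frame([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]], [4.0, 4.0, 4.0])
        prof = radial_distribution(f, [0], [1], 0.05, 1.5)
        nonzero = np.flatnonzero(prof.g)
        assert len(nonzero) == 1
        c = prof.bin_centers[nonzero[0]]
        assert abs(c - d) <= 0.025 + 1e-12

    def test_neighbor_count_conserved_under_rebinning(self, ideal_frames):
        """The expected neighbour count ∫ 4πr²ρ g dr is a binning-free
        observable: halving resolution must not change it."""
        f = ideal_frames[0]
        sel = select(f, species="water")
        rho = sel.size / f.volume
        counts = {}
        for bw in (0.02, 0.04):
            prof = radial_distribution(f, sel, sel, bw, 1.4)
            # cover [0, r_max] exactly: anchor g(0)=0, carry g to the edge
            r = np.concatenate(([0.0], prof.bin_centers, [1.4]))
            g = np.concatenate(([0.0], prof.g, [prof.g[-1]]))
            counts[bw] = np.trapezoid(4 * np.pi * r**2 * rho * g, r)
        assert counts[0.04] == pytest.approx(counts[0.02], rel=0.01)

    def test_rmax_beyond_half_box_rejected_with_limit(self, ideal_frames):
        sel = select(ideal_frames[0], species="water")
        with pytest.raises(InvalidInputError, match="half the smallest box edge"):
            radial_distribution(ideal_frames[0], sel, sel, 0.02, 2.0)

    def test_invariant_under_rigid_translation(self, ideal_frames):
        f = ideal_frames[0]
        shifted = _bare_frame(
            f.coordinates + np.array([1.7, -0.4, 2.9]), f.box,
            f.species, f.element_class,
        )
        sel = select(f, species="LHA")
        a = radial_distribution(f, sel, sel, 0.05, 1.5)
        b = radial_distribution(shifted, sel, sel, 0.05, 1.5)
        assert np.allclose(a.g, b.g)


class TestKirkwoodBuff:
    def _flat_profile(self, g_value, r_max=1.5, bw=0.02):
        centers = np.arange(bw / 2, r_max, bw)
        return RdfProfile(centers, np.full_like(centers, g_value), bin_width=bw)

    def test_uniform_profile_integrates_to_zero(self):
        prof = self._flat_profile(1.0)
        # the r=0 anchor contributes -1 over a negligible shell
        assert kb_integral(prof, 1.5).G == pytest.approx(0.0, abs=1e-4)

    def test_constant_excess_closed_form(self):
        prof = self._flat_profile(1.25)
        expected = 4.0 / 3.0 * math.pi * 0.5**3 * 0.25
        assert kb_integral(prof, 0.5).G == pytest.approx(expected, rel=5e-3)

    def test_ideal_gas_limit(self, ideal_frames):
        f = ideal_frames[0]
        sel = select(f, species=("LHA", "water"))
        prof = radial_distribution(ideal_frames, sel, sel, 0.02, 1.5)
        assert abs(kb_integral(prof, 1.5).G) < 0.05

    def test_starred_variant_scales_by_fractions(self):
        prof = self._flat_profile(1.25)
        plain = kb_integral(prof, 0.5).G
        starred = kb_integral(prof, 0.5, molar_fractions=(0.2, 0.4), starred=True)
        assert starred.G == pytest.approx(0.08 * plain)
        assert starred.starred

    def test_boundary_beyond_profile_rejected(self):
        prof = self._flat_profile(1.0, r_max=0.5)
        with pytest.raises(InvalidInputError):
            kb_integral(prof, 1.0)


class TestPreferentialSolvation:
    def test_formula_evaluation(self):
        v_corr = 4.0 / 3.0 * math.pi * 1.5**3
        expected = 0.2 * (1.0 - 0.5) / (v_corr + 0.5)
        assert delta_coefficient(0.2, 1.0, 0.5, 1.5) == pytest.approx(expected)
        assert expected == pytest.approx(0.00683, abs=2e-5)

    def test_ideal_mixture_has_no_preference(self):
        deltas = [preferential_solvation(ideal_gas_box(n=2000, seed=(9, i)))
                  for i in range(20)]
        for sp in ("LHA", "water", "calcium"):
            assert abs(np.mean([d[sp] for d in deltas])) < 0.02

    @pytest.mark.parametrize("placement,pos_sp,neg_sp", [
        ("water_patch", "water", "LHA"),
        ("LHA_patch", "LHA", "water"),
    ])
    def test_clustered_box_recovers_planted_signs(self, placement, pos_sp, neg_sp):
        vals = {pos_sp: [], neg_sp: []}
        for i in range(6):
            cb = clustered_mixture_box(sorbate_placement=placement, seed=(13, i))
            d = preferential_solvation(cb.frame)
            for sp in vals:
                vals[sp].append(d[sp])
            assert cb.expected_delta_sign[pos_sp] == 1
        assert np.mean(vals[pos_sp]) > 0
        assert np.mean(vals[neg_sp]) < 0

    def test_invariant_under_particle_relabeling(self):
        cb = clustered_mixture_box(seed=21)
        f = cb.frame
        rng = np.random.default_rng(3)
        perm = rng.permutation(f.n_atoms)
        shuffled = _bare_frame(
            f.coordinates[perm], f.box, f.species[perm], f.element_class[perm]
        )
        a = preferential_solvation(f)
        b = preferential_solvation(shuffled)
        for sp in a:
            assert a[sp] == pytest.approx(b[sp])

    def test_missing_species_rejected(self):
        f = ideal_gas_box(n=100, species_mix={"sorbate": 0.02, "LHA": 0.98}, seed=0)
        with pytest.raises(InvalidInputError):
            preferential_solvation(f, solvent_species=("LHA", "water"))


def _triple(r_ha, angle_deg):
    """D at origin, H along +x, A placed at the given H···A distance and
    D-H···A angle."""
    h = np.array([0.10, 0.0, 0.0])
    theta = math.radians(angle_deg)
    u_hd = np.array([-1.0, 0.0, 0.0])
    w = np.array([0.0, 1.0, 0.0])
    a = h + r_ha * (math.cos(theta) * u_hd + math.sin(theta) * w)
    coords = np.array([[0.0, 0.0, 0.0], h, a]) + 1.0
    return _bare_frame(coords, [3.0, 3.0, 3.0],
                       classes=["heteroatom", "hydrogen", "heteroatom"])


class TestHydrogenBonds:
    def test_ideal_linear_bond(self):
        f = _triple(0.20, 180.0)
        assert hydrogen_bonds(f, [(0, 1)], [2]) == 1

    @pytest.mark.parametrize("r,angle,expected", [
        (0.26, 180.0, 0),   # too far
        (0.20, 134.0, 0),   # too bent
        (0.25, 180.0, 1),   # distance boundary inclusive
        (0.20, 135.0, 1),   # angle boundary inclusive
    ])
    def test_criterion_boundaries(self, r, angle, expected):
        f = _triple(r, angle)
        assert hydrogen_bonds(f, [(0, 1)], [2]) == expected

    def test_minimum_image_bond_across_boundary(self):
        # H near the box face, acceptor just across it
        coords = np.array([[0.05, 1.0, 1.0], [2.95, 1.0, 1.0], [2.75, 1.0, 1.0]])
        f = _bare_frame(coords, [3.0, 3.0, 3.0],
                        classes=["heteroatom", "hydrogen", "heteroatom"])
        assert hydrogen_bonds(f, [(0, 1)], [2]) == 1

    @pytest.mark.parametrize("k,md,ma", [(0, 0, 0), (0, 4, 3), (5, 3, 3), (12, 6, 6)])
    def test_planted_frames_counted_exactly(self, k, md, ma):
        p = planted_hbond_frame(k, md, ma, seed=(41, k, md, ma))
        assert hydrogen_bonds(p.frame, p.donors, p.acceptors) == k

    def test_symmetric_under_storage_order(self):
        p = planted_hbond_frame(6, 3, 3, seed=2)
        f = p.frame
        n = f.n_atoms
        rev = _bare_frame(f.coordinates[::-1], f.box, f.species[::-1],
                          f.element_class[::-1])
        remap = lambda i: n - 1 - i
        donors = [(remap(d), remap(h)) for d, h in reversed(p.donors)]
        acceptors = [remap(a) for a in reversed(p.acceptors)]
        assert hydrogen_bonds(rev, donors, acceptors) == hydrogen_bonds(
            f, p.donors, p.acceptors
        )


def _two_spheres_exposed_area(radius, probe, d):
    """Closed-form SASA of two equal spheres at centre distance d: each
    inflated sphere loses a cap of height R − d/2."""
    R = radius + probe
    if d >= 2 * R:
        return 2 * 4 * math.pi * R**2
    cap = 2 * math.pi * R * (R - d / 2.0)
    return 2 * (4 * math.pi * R**2 - cap)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        f = _bare_frame([[2.0, 2.0, 2.0]], [5.0, 5.0, 5.0],
                        radius=np.array([0.2]))
        res = sasa(f, None, 0.14, 960)
        assert res.total == pytest.approx(4 * math.pi * 0.34**2, rel=0.01)
        assert res.carbon_fraction == 1.0

    def test_enclosed_atom_has_no_surface(self):
        # central atom caged by 14 large overlapping spheres
        centre = np.array([2.5, 2.5, 2.5])
        shell = []
        for dx in (-0.3, 0.3):
            for axis in range(3):
                v = np.zeros(3)
                v[axis] = dx
                shell.append(centre + v)
        for sx in (-0.25, 0.25):
            for sy in (-0.25, 0.25):
                for sz in (-0.25, 0.25):
                    shell.append(centre + [sx, sy, sz])
        coords = np.vstack([centre, shell])
        radii = np.array([0.05] + [0.25] * len(shell))
        f = _bare_frame(coords, [5.0, 5.0, 5.0],
                        classes=["heteroatom"] + ["carbon"] * len(shell),
                        radius=radii)
        res = sasa(f, None, 0.14, 960)
        assert res.heteroatom_fraction == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("d", [0.2, 0.35, 0.5, 0.65])
    def test_two_equal_spheres_match_analytic_area(self, d):
        f = _bare_frame([[2.0, 2.0, 2.0], [2.0 + d, 2.0, 2.0]],
                        [6.0, 6.0, 6.0], radius=np.array([0.2, 0.2]))
        res = sasa(f, None, 0.14, 960)
        assert res.total == pytest.approx(
            _two_spheres_exposed_area(0.2, 0.14, d), rel=0.02
        )

    def test_matches_independent_reference_implementation(self):
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem

        d = 0.25
        top = mdtraj.Topology()
        chain = top.add_chain()
        res_ = top.add_residue("MOL", chain)
        top.add_atom("C1", elem.carbon, res_)
        top.add_atom("C2", elem.carbon, res_)
        xyz = np.array([[[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]])
        traj = mdtraj.Trajectory(xyz, top)
        ref = float(mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                         n_sphere_points=960).sum())
        r_c = 0.17  # carbon radius used by the reference
        f = _bare_frame(xyz[0], [10.0, 10.0, 10.0],
                        radius=np.array([r_c, r_c]))
        mine = sasa(f, None, 0.14, 960)
        assert mine.total == pytest.approx(ref, rel=0.02)

    def test_zero_radius_rejected(self):
        f = _bare_frame([[1.0, 1.0, 1.0]], [3.0, 3.0, 3.0],
                        radius=np.array([0.0]))
        with pytest.raises(InvalidInputError):
            sasa(f)


class TestPairInteractionEnergy:
    def _frame(self, coords, charges, c6, c12, box=(5.0, 5.0, 5.0)):
        n = len(coords)
        return _bare_frame(coords, box,
                           charge=np.asarray(charges, dtype=float),
                           lj_c6=np.asarray(c6, dtype=float),
                           lj_c12=np.asarray(c12, dtype=float))

    def test_zero_charges_give_zero_electrostatics(self):
        f = self._frame([[0, 0, 0], [0.4, 0, 0]], [0, 0], [1e-3] * 2, [1e-6] * 2)
        elec, vdw = pair_interaction_energy(f, [0], [1])
        assert elec == 0.0
        assert vdw != 0.0

    def test_lj_minimum_depth(self):
        c6, c12 = 1e-3, 1e-6
        r_min = (2 * c12 / c6) ** (1 / 6)
        f = self._frame([[0, 0, 0], [r_min, 0, 0]], [0, 0], [c6] * 2, [c12] * 2)
        _, vdw = pair_interaction_energy(f, [0], [1])
        assert vdw == pytest.approx(-(c6**2) / (4 * c12))

    def test_reaction_field_hand_value(self):
        f = self._frame([[0, 0, 0], [0.5, 0, 0]], [1.0, 1.0], [0] * 2, [0] * 2)
        elec, _ = pair_interaction_energy(f, [0], [1], cutoff=1.4, eps_rf=61.0)
        c_rf = (2 * 61 - 2) / (2 * 61 + 1)
        hand = 138.9354 * (1 / 0.5 + c_rf * 0.5**2 / (2 * 1.4**3)
                           - (1 + c_rf / 2) / 1.4)
        assert elec == pytest.approx(hand)

    def test_symmetry_and_overlap_deduplication(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 3, size=(12, 3))
        f = self._frame(coords, rng.normal(size=12) * 0.3,
                        np.full(12, 2e-3), np.full(12, 2e-6), box=(3.0, 3.0, 3.0))
        a, b = np.arange(6), np.arange(6, 12)
        assert pair_interaction_energy(f, a, b) == pytest.approx(
            pair_interaction_energy(f, b, a)
        )
        # overlapping groups: each unordered pair counts once
        full = np.arange(12)
        e_all = pair_interaction_energy(f, full, full)
        e_ab = pair_interaction_energy(f, a, b)
        e_aa = pair_interaction_energy(f, a, a)
        e_bb = pair_interaction_energy(f, b, b)
        assert e_all[0] == pytest.approx(e_ab[0] + e_aa[0] + e_bb[0])
        assert e_all[1] == pytest.approx(e_ab[1] + e_aa[1] + e_bb[1])

    def test_explicit_images_reproduce_minimum_image(self):
        """Doubling the box along x with explicit particle images doubles the
        energy exactly (each pair within the cutoff appears once per copy)."""
        rng = np.random.default_rng(15)
        n = 10
        coords = rng.uniform(0, 3.0, size=(n, 3))
        q = rng.normal(size=n) * 0.2
        f1 = self._frame(coords, q, np.full(n, 1e-3), np.full(n, 1e-6),
                         box=(3.0, 3.0, 3.0))
        doubled = np.vstack([coords, coords + [3.0, 0.0, 0.0]])
        f2 = self._frame(doubled, np.tile(q, 2), np.full(2 * n, 1e-3),
                         np.full(2 * n, 1e-6), box=(6.0, 3.0, 3.0))
        a1, b1 = np.arange(5), np.arange(5, n)
        a2 = np.concatenate([a1, a1 + n])
        b2 = np.concatenate([b1, b1 + n])
        e1 = pair_interaction_energy(f1, a1, b1)
        e2 = pair_interaction_energy(f2, a2, b2)
        assert e2[0] == pytest.approx(2 * e1[0])
        assert e2[1] == pytest.approx(2 * e1[1])

    def test_missing_parameters_rejected(self):
        f = _bare_frame([[0, 0, 0], [1, 0, 0]], [5.0, 5.0, 5.0])
        with pytest.raises(InvalidInputError):
            pair_interaction_energy(f, [0], [1])
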