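import numpy as np
import pytest

from dnatraffic.errors import ParameterError, RankError
from dnatraffic.guided_docking import (
    ContactParams,
    interface_residues,
    min_surface_gap,
    place_on_guide,
    slide_to_contact,
    superpose_kabsch,
)
from dnatraffic.helix_guide import build_guide, build_guide_atoms, step_transform
from dnatraffic.structures_io import AtomRecord, StructureModel, select_dna_segment
from dnatraffic.synthetic_data import (
    ToyComplexSpec,
    make_toy_complex,
    predicted_contact_between,
)

from conftest import duplex_segment, random_atoms


def horn_quaternion_fit(mobile, target):
    """Independent superposition oracle: Horn's quaternion eigenvalue method."""
    m = mobile - mobile.mean(axis=0)
    t = target - target.mean(axis=0)
    s = m.T @ t
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(n)
    w, x, y, z = vecs[:, -1]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    rmsd = np.sqrt(np.mean(np.sum((m @ rot.T - t) ** 2, axis=1)))
    return rot, rmsd


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        tr, rmsd = superpose_kabsch(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tr.translation, 0, atol=1e-10)
        assert rmsd < 1e-10

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        tr, rmsd = superpose_kabsch(pts, pts + [1.0, 2.0, 3.0])
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tr.translation, [1, 2, 3], atol=1e-10)
        assert rmsd < 1e-12

    def test_noisy_rotation_matches_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        mobile = rng.normal(scale=5.0, size=(8, 3))
        angle = 0.8
        axis = np.array([1.0, 2.0, -1.0]) / np.sqrt(6.0)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot_true = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * k @ k
        target = mobile @ rot_true.T + [4.0, -2.0, 7.0]
        target += rng.normal(scale=0.1, size=target.shape)
        tr, rmsd = superpose_kabsch(mobile, target)
        rot_q, rmsd_q = horn_quaternion_fit(mobile, target)
        assert abs(rmsd - rmsd_q) < 1e-9
        np.testing.assert_allclose(tr.rotation, rot_q, atol=1e-9)

    def test_no_reflection_even_for_near_planar_sets(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(10, 3)) * [5.0, 5.0, 1e-4]
        target = -mobile  # improper map; fit must stay a proper rotation
        tr, _ = superpose_kabsch(mobile, target)
        assert np.linalg.det(tr.rotation) > 0.99

    def test_length_mismatch_and_collinear_rejected(self):
        with pytest.raises(ParameterError):
            superpose_kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(RankError):
            superpose_kabsch(line, line)


class TestMinSurfaceGap:
    def _carbon(self, serial, pos):
        return AtomRecord(serial, "C", "C", "GLY", serial, "X", pos, 1.70)

    def test_two_carbons_closed_form(self):
        a = [self._carbon(1, [0.0, 0.0, 0.0])]
        b = [self._carbon(2, [20.0, 0.0, 0.0])]
        gap = min_surface_gap(a, b, ContactParams(probe_radius=1.4))
        assert gap == pytest.approx(20 - 1.70 - 1.70 - 2.8, abs=1e-12)

    def test_coincident_atoms_fully_overlap(self):
        a = [self._carbon(1, [1.0, 1.0, 1.0])]
        b = [self._carbon(2, [1.0, 1.0, 1.0])]
        gap = min_surface_gap(a, b, ContactParams(probe_radius=1.4))
        assert gap == pytest.approx(-(1.70 + 1.70 + 2.8), abs=1e-12)

    def test_grid_equals_brute_force_on_random_clouds(self):
        a = random_atoms(500, seed=10)
        b = random_atoms(500, seed=11, offset=(15.0, 5.0, 0.0))
        params = ContactParams(probe_radius=1.4)
        pa = np.array([x.position for x in a])
        pb = np.array([x.position for x in b])
        ra = np.array([x.vdw_radius for x in a])
        rb = np.array([x.vdw_radius for x in b])
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        brute = (d - ra[:, None] - rb[None, :] - 2.8).min()
        assert min_surface_gap(a, b, params) == pytest.approx(brute, abs=1e-9)

    def test_empty_side_rejected(self):
        with pytest.raises(ParameterError):
            min_surface_gap([], random_atoms(3, seed=0), ContactParams())


class TestInterfaceResidues:
    def test_matches_brute_force_enumeration(self):
        a = random_atoms(120, seed=20)
        b = random_atoms(120, seed=21, offset=(25.0, 0.0, 0.0))
        params = ContactParams()
        margin = 1.0
        got_a, got_b = interface_residues(a, b, params, cutoff_margin=margin)
        exp_a, exp_b = set(), set()
        for x in a:
            for y in b:
                d = np.linalg.norm(x.position - y.position)
                if d - x.vdw_radius - y.vdw_radius - 2.8 <= margin:
                    exp_a.add((x.chain_id, x.residue_number, x.residue_name))
                    exp_b.add((y.chain_id, y.residue_number, y.residue_name))
        assert set(got_a) == exp_a and set(got_b) == exp_b

    def test_margin_monotonicity(self):
        a = random_atoms(80, seed=30)
        b = random_atoms(80, seed=31, offset=(20.0, 0.0, 0.0))
        params = ContactParams()
        small_a, small_b = interface_residues(a, b, params, cutoff_margin=0.0)
        big_a, big_b = interface_residues(a, b, params, cutoff_margin=5.0)
        assert set(small_a) <= set(big_a) and set(small_b) <= set(big_b)


class TestPlaceOnGuide:
    def test_self_alignment_is_identity(self, guide60):
        model = build_guide_atoms(build_guide(12), seed=4)
        placed = place_on_guide(model, duplex_segment(12, 3, 5), guide60,
                                register=2)
        assert placed.alignment_rmsd < 1e-9
        np.testing.assert_allclose(placed.placement.rotation, np.eye(3),
                                   atol=1e-9)

    def test_arbitrary_rigid_motion_is_inverted(self, guide60):
        model = build_guide_atoms(build_guide(12), seed=4)
        rng = np.random.default_rng(9)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = model.transformed(q, np.array([12.0, -3.0, 8.0]))
        placed = place_on_guide(moved, duplex_segment(12, 3, 5), guide60,
                                register=2)
        assert placed.alignment_rmsd < 1e-6
        np.testing.assert_allclose(placed.placed_model().coordinates(),
                                   model.coordinates(), atol=1e-6)

    def test_kinked_flanks_do_not_disturb_segment_fit(self, guide60):
        # segment pairs ideal, flanking DNA bent away: segment RMSD ~0 while
        # a whole-duplex fit would be poor
        n = 15
        model = build_guide_atoms(build_guide(n), seed=6)
        bend = np.array([[1, 0, 0],
                         [0, np.cos(0.5), -np.sin(0.5)],
                         [0, np.sin(0.5), np.cos(0.5)]])
        atoms = []
        for a in model.atoms:
            pair = (a.residue_number - 1 if a.chain_id == "A"
                    else n - a.residue_number)
            if pair < 5:  # bend the first five pairs out of the helix
                moved = bend @ a.position + np.array([0.0, 4.0, -3.0])
                atoms.append(AtomRecord(a.serial, a.atom_name, a.element,
                                        a.residue_name, a.residue_number,
                                        a.chain_id, moved, a.vdw_radius))
            else:
                atoms.append(a)
        kinked = StructureModel(atoms, "kinked")
        placed = place_on_guide(kinked, duplex_segment(n, 7, 5), guide60,
                                register=6)
        assert placed.alignment_rmsd < 1e-6
        with pytest.warns(UserWarning, match="RMSD"):
            whole = place_on_guide(kinked, duplex_segment(n, 1, n), guide60,
                                   register=0)
        assert whole.alignment_rmsd > 2.0

    def test_register_out_of_range(self, guide60):
        model = build_guide_atoms(build_guide(12), seed=4)
        with pytest.raises(ParameterError):
            place_on_guide(model, duplex_segment(12, 3, 5), guide60,
                           register=58)


def _place_toys(guide, toys, reg_a=3, reg_b=15):
    (ma, meta_a), (mb, meta_b) = toys
    seg = duplex_segment(20, 3, 5)
    # duplex residue A:3 is pair 2; register r of the selection puts duplex
    # bp 0 at guide bp r-2
    pa = place_on_guide(ma, seg, guide, register=reg_a + 2)
    pb = place_on_guide(mb, seg, guide, register=reg_b + 2)
    return pa, pb, meta_a, meta_b


class TestSlideToContact:
    def test_sphere_fixture_matches_closed_form_and_exhaustive_scan(
            self, guide60, sphere_toys):
        pa, pb, meta_a, meta_b = _place_toys(guide60, sphere_toys)
        params = ContactParams(probe_radius=1.4)
        res = slide_to_contact(pa, pb, guide60, params, direction=-1,
                               max_steps=30)
        predicted = predicted_contact_between(meta_a, meta_b, 3, 15)
        assert res.first_contact_step == predicted
        # exhaustive oracle: brute-force gap at every step
        stat = pa.placed_atoms(include_dna=False)
        mob = pb.placed_atoms(include_dna=False)
        first = None
        for k in range(31):
            tr = step_transform(guide60, k, sign=-1)
            gap = min(
                np.linalg.norm(tr.apply(m.position) - s.position)
                - m.vdw_radius - s.vdw_radius - 2.8
                for m in mob for s in stat)
            assert gap == pytest.approx(res.gap_trace[k], abs=1e-9)
            if gap <= 0:
                first = k
                break
        assert first == res.first_contact_step

    def test_contact_bracketing_invariant(self, guide60, sphere_toys):
        pa, pb, *_ = _place_toys(guide60, sphere_toys)
        res = slide_to_contact(pa, pb, guide60, ContactParams(), direction=-1,
                               max_steps=30)
        k = res.first_contact_step
        assert res.gap_trace[k] <= 0 < res.gap_trace[k - 1]

    def test_overlapping_start_contacts_at_step_zero(self, guide60, sphere_toys):
        pa, pb, *_ = _place_toys(guide60, sphere_toys, reg_a=10, reg_b=11)
        res = slide_to_contact(pa, pb, guide60, ContactParams(), direction=-1,
                               max_steps=10)
        assert res.first_contact_step == 0

    def test_no_contact_within_range_reported_as_none(self, guide60, sphere_toys):
        pa, pb, *_ = _place_toys(guide60, sphere_toys)
        res = slide_to_contact(pa, pb, guide60, ContactParams(), direction=-1,
                               max_steps=3)
        assert res.first_contact_step is None
        assert len(res.gap_trace) == 4
        assert res.interface_A == [] and res.interface_B == []

    def test_sphere_interfaces_are_the_sphere_residues(self, guide60, sphere_toys):
        pa, pb, *_ = _place_toys(guide60, sphere_toys)
        res = slide_to_contact(pa, pb, guide60, ContactParams(), direction=-1,
                               max_steps=30)
        assert res.interface_A == [("P", 1, "SPH")]
        assert res.interface_B == [("P", 1, "SPH")]

    def test_sliding_preserves_internal_distances(self, guide60):
        spec = ToyComplexSpec(dna_n_bp=20, protein_shape="helix-bundle-stub",
                              protein_radius=5.0, anchor_bp=10, seed=8)
        model, _ = make_toy_complex(spec, guide60)
        placed = place_on_guide(model, duplex_segment(20, 3, 5), guide60,
                                register=5)
        atoms = placed.placed_atoms(include_dna=False)
        pos0 = np.array([a.position for a in atoms])
        tr = step_transform(guide60, 7, sign=-1)
        pos1 = tr.apply(pos0)
        d0 = np.linalg.norm(pos0[:, None] - pos0[None, :], axis=2)
        d1 = np.linalg.norm(pos1[:, None] - pos1[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_gap_trace_reproducible(self, guide60, sphere_toys):
        pa, pb, *_ = _place_toys(guide60, sphere_toys)
        r1 = slide_to_contact(pa, pb, guide60, ContactParams(), -1, 30)
        r2 = slide_to_contact(pa, pb, guide60, ContactParams(), -1, 30)
        assert r1.gap_trace == r2.gap_trace
        assert r1.first_contact_step == r2.first_contact_step

    def test_swapping_mobile_role_gives_same_contact_geometry(self, guide60):
        specs = [ToyComplexSpec(dna_n_bp=20, protein_shape="helix-bundle-stub",
                                protein_radius=5.0, anchor_bp=10, seed=s)
                 for s in (12, 13)]
        toys = [make_toy_complex(s, guide60) for s in specs]
        seg = duplex_segment(20, 3, 5)
        pa = place_on_guide(toys[0][0], seg, guide60, register=5)
        pb = place_on_guide(toys[1][0], seg, guide60, register=17)
        params = ContactParams()
        fwd = slide_to_contact(pa, pb, guide60, params, direction=-1)
        rev = slide_to_contact(pb, pa, guide60, params, direction=1)
        assert fwd.first_contact_step == rev.first_contact_step
        k = fwd.first_contact_step
        a_pos = np.array([x.position for x in pa.placed_atoms(False)])
        b_pos = np.array([x.position for x in pb.placed_atoms(False)])
        d_fwd = np.linalg.norm(
            a_pos[:, None] - step_transform(guide60, k, -1).apply(b_pos)[None, :],
            axis=2)
        d_rev = np.linalg.norm(
            step_transform(guide60, k, 1).apply(a_pos)[:, None] - b_pos[None, :],
            axis=2)
        assert np.abs(d_fwd - d_rev).max() < 1e-6

    def test_mismatched_guides_rejected(self, guide60, sphere_toys):
        other = build_guide(50)
        pa, pb, *_ = _place_toys(guide60, sphere_toys)
        with pytest.raises(ParameterError):
            slide_to_contact(pa, pb, other, ContactParams())
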