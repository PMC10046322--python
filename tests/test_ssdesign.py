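import numpy as np
import pytest

from lidflex.io import RegionDefinition
from lidflex.ssdesign import (
    CA_CB_SG_ANGLE, SS_BOND, DisulfideCandidate, FunctionalSiteFilter,
    apply_criteria, apply_site_filters, model_cystine, place_atom,
    reconstruct_cbeta, scan_all_pairs,
)
from .conftest import make_structure


def _angle(a, b, c):
    u, v = a - b, c - b
    return np.degrees(np.arccos(
        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))


def _dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return np.degrees(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


def ideal_cystine_pair(chi3=-87.0, chi1_i=-60.0, chi1_j=-65.0):
    """Backbone coordinates of two residues whose ideal-geometry S-gammas
    sit exactly on the chi1 scan grid with S-S = 2.04 A and the given chi3.
    Built by explicit internal-to-Cartesian construction."""
    n_i = np.array([0.0, 1.45, 0.0])
    ca_i = np.array([0.0, 0.0, 0.0])
    cb_i = ca_i + 1.53 * np.array([0.94, -0.33, 0.0]) / np.linalg.norm(
        [0.94, -0.33, 0.0])
    sg_i = place_atom(n_i, ca_i, cb_i, 1.81, CA_CB_SG_ANGLE, chi1_i)
    sg_j = place_atom(ca_i, cb_i, sg_i, SS_BOND, 104.0, 70.0)
    cb_j = place_atom(cb_i, sg_i, sg_j, 1.81, 104.0, chi3)
    ca_j = place_atom(sg_i, sg_j, cb_j, 1.53, CA_CB_SG_ANGLE, 160.0)
    n_j = place_atom(sg_j, cb_j, ca_j, 1.45, 109.0, chi1_j)
    atoms = [
        ("A", 10, "ALA", "N", "N", tuple(n_i)),
        ("A", 10, "ALA", "CA", "C", tuple(ca_i)),
        ("A", 10, "ALA", "C", "C", tuple(ca_i + [1.2, 0.9, 0.2])),
        ("A", 10, "ALA", "CB", "C", tuple(cb_i)),
        ("A", 20, "ALA", "N", "N", tuple(n_j)),
        ("A", 20, "ALA", "CA", "C", tuple(ca_j)),
        ("A", 20, "ALA", "C", "C", tuple(ca_j + [1.1, -0.9, 0.3])),
        ("A", 20, "ALA", "CB", "C", tuple(cb_j)),
    ]
    return make_structure(atoms), (sg_i, sg_j)


class TestPlaceAtom:
    def test_respects_internal_coordinates(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.normal(size=(3, 3)) * 3
        d = place_atom(a, b, c, 1.81, 114.6, -60.0)
        assert np.linalg.norm(d - c) == pytest.approx(1.81)
        assert _angle(b, c, d) == pytest.approx(114.6, abs=1e-8)
        assert _dihedral(a, b, c, d) == pytest.approx(-60.0, abs=1e-8)


class TestCbetaReconstruction:
    def test_ideal_geometry(self):
        n = np.array([1.46, 0.0, 0.0])
        ca = np.zeros(3)
        c = np.array([-0.55, 1.40, 0.0])
        cb = reconstruct_cbeta(n, ca, c)
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53)
        assert _angle(n, ca, cb) == pytest.approx(110.5, abs=1e-6)
        assert _angle(c, ca, cb) == pytest.approx(110.5, abs=1e-6)

    def test_l_configuration(self):
        # L-amino acids have a positive N -> C -> CB improper sense
        n = np.array([1.46, 0.0, 0.0])
        ca = np.zeros(3)
        c = np.array([-0.55, 1.40, 0.0])
        cb = reconstruct_cbeta(n, ca, c)
        assert np.dot(np.cross(n - ca, c - ca), cb - ca) < 0


class TestModelCystine:
    def test_recovers_ideal_fixture(self):
        s, (sg_i, sg_j) = ideal_cystine_pair()
        cand = model_cystine(s, 10, 20)
        assert cand.ss_distance == pytest.approx(2.04, abs=0.01)
        assert cand.chi3 == pytest.approx(-87.0, abs=1.0)
        assert cand.angle_i == pytest.approx(114.6, abs=1.0)
        assert cand.angle_j == pytest.approx(114.6, abs=1.0)
        assert cand.passes
        np.testing.assert_allclose(cand.sg_i, sg_i, atol=1e-6)
        np.testing.assert_allclose(cand.sg_j, sg_j, atol=1e-6)

    def test_distant_pair_fails_without_error(self):
        s, _ = ideal_cystine_pair()
        far = s.copy()
        far.coords[4:] += np.array([40.0, 0.0, 0.0])
        cand = model_cystine(far, 10, 20)
        assert not cand.passes
        assert "ss_distance" in cand.fail_reasons
        assert cand.ss_distance > 5.0

    def test_symmetric_in_residue_order(self):
        s, _ = ideal_cystine_pair()
        a = model_cystine(s, 10, 20)
        b = model_cystine(s, 20, 10)
        assert a.ss_distance == pytest.approx(b.ss_distance, abs=1e-9)
        assert abs(a.chi3) == pytest.approx(abs(b.chi3), abs=1e-6)
        assert a.passes == b.passes

    def test_glycine_gets_ideal_cbeta(self):
        s, _ = ideal_cystine_pair()
        gly = make_structure([
            (c, r, "GLY" if r == 10 else rn, an, el, tuple(xyz))
            for c, r, rn, an, el, xyz in zip(
                s.chain_ids, s.res_ids, s.res_names, s.atom_names,
                s.elements, s.coords)
            if not (r == 10 and an == "CB")
        ])
        cand = model_cystine(gly, 10, 20)
        assert cand.ss_distance < 8.0  # geometry modeled, not errored

    def test_missing_backbone_rejected(self):
        s = make_structure([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "N", "N", (5, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (6, 0, 0)),
            ("A", 2, "ALA", "C", "C", (7, 1, 0)),
        ])
        with pytest.raises(ValueError, match="backbone"):
            model_cystine(s, 1, 2)


def candidate(chi3=-87.0, angle_i=114.6, angle_j=114.6, ss=2.04):
    return DisulfideCandidate(res_i=1, res_j=2, chi3=chi3, angle_i=angle_i,
                              angle_j=angle_j, ss_distance=ss)


class TestCriteria:
    def test_both_rotamer_centers_pass(self):
        for chi3 in (-87.0, 97.0):
            ok, reasons = apply_criteria(candidate(chi3=chi3))
            assert ok, reasons

    def test_chi3_zero_fails(self):
        ok, reasons = apply_criteria(candidate(chi3=0.0))
        assert not ok and "chi3" in reasons

    def test_angle_outside_window_fails_with_reason(self):
        ok, reasons = apply_criteria(candidate(angle_i=130.0))
        assert not ok
        assert reasons == ["angle_i"]

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(chi3=-87.0 - 31.0), "chi3"),
        (dict(chi3=97.0 + 31.0), "chi3"),
        (dict(angle_i=114.6 + 11.0), "angle_i"),
        (dict(angle_j=114.6 - 11.0), "angle_j"),
    ])
    def test_one_degree_beyond_window_flips_to_fail(self, kwargs, reason):
        assert apply_criteria(candidate())[0]
        ok, reasons = apply_criteria(candidate(**kwargs))
        assert not ok and reasons == [reason]

    @pytest.mark.parametrize("kwargs", [
        dict(chi3=-87.0 - 29.0), dict(chi3=97.0 + 29.0),
        dict(angle_i=114.6 + 9.0), dict(angle_j=114.6 - 9.0),
    ])
    def test_one_degree_inside_window_still_passes(self, kwargs):
        ok, _ = apply_criteria(candidate(**kwargs))
        assert ok

    def test_circular_chi3_arithmetic(self):
        # -87 - 30 = -117; approached from +243 wraps correctly
        ok, _ = apply_criteria(candidate(chi3=-116.0))
        assert ok

    def test_relaxing_halfwidth_grows_pass_set(self):
        rng = np.random.default_rng(5)
        chi3s = rng.uniform(-180, 180, size=200)
        tight = {c for c in chi3s
                 if apply_criteria(candidate(chi3=c), chi3_halfwidth=20.0)[0]}
        loose = {c for c in chi3s
                 if apply_criteria(candidate(chi3=c), chi3_halfwidth=40.0)[0]}
        assert tight <= loose


class TestSiteFilters:
    def geometry(self, pair_x):
        """Triad residue at origin; candidate pair at x = pair_x."""
        atoms = [("A", 146, "SER", "CA", "C", (0.0, 0.0, 0.0))]
        for k, resid in enumerate((30, 31)):
            atoms.insert(k, ("A", resid, "ALA", "CA", "C",
                             (pair_x, k * 3.8, 0.0)))
        return make_structure(atoms)

    def test_pair_8A_from_triad_rejected(self):
        s = self.geometry(8.0)
        filt = FunctionalSiteFilter(triad_residues=(146,))
        cand = DisulfideCandidate(res_i=30, res_j=31, chi3=-87.0,
                                  angle_i=114.6, angle_j=114.6,
                                  ss_distance=2.04)
        retained, all_ = apply_site_filters([cand], s, filt)
        assert retained == []
        assert any("triad" in r for r in all_[0].rejection_reasons)

    def test_pair_12A_from_triad_retained(self):
        s = self.geometry(12.0)
        filt = FunctionalSiteFilter(triad_residues=(146,))
        cand = DisulfideCandidate(res_i=30, res_j=31, chi3=-87.0,
                                  angle_i=114.6, angle_j=114.6,
                                  ss_distance=2.04)
        retained, _ = apply_site_filters([cand], s, filt)
        assert retained == [cand]

    def test_blacklisted_conserved_residue_rejected(self):
        s = make_structure([
            ("A", 53, "ALA", "CA", "C", (50.0, 0.0, 0.0)),
            ("A", 54, "ALA", "CA", "C", (53.8, 0.0, 0.0)),
            ("A", 146, "SER", "CA", "C", (0.0, 0.0, 0.0)),
        ])
        filt = FunctionalSiteFilter(triad_residues=(146,),
                                    blacklist=(53, 58, 167, 231))
        cand = DisulfideCandidate(res_i=53, res_j=54, chi3=-87.0,
                                  angle_i=114.6, angle_j=114.6,
                                  ss_distance=2.04)
        retained, all_ = apply_site_filters([cand], s, filt)
        assert retained == []
        assert any("conserved" in r for r in all_[0].rejection_reasons)

    def test_region_exclusion_radius(self):
        atoms = [
            ("A", 30, "ALA", "CA", "C", (4.0, 0.0, 0.0)),
            ("A", 31, "ALA", "CA", "C", (4.0, 3.8, 0.0)),
            ("A", 190, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
        ]
        s = make_structure(atoms)
        filt = FunctionalSiteFilter(
            triad_residues=(),
            regions=(RegionDefinition("lid", (190,)),))
        cand = DisulfideCandidate(res_i=30, res_j=31, chi3=-87.0,
                                  angle_i=114.6, angle_j=114.6,
                                  ss_distance=2.04)
        retained, all_ = apply_site_filters([cand], s, filt)
        assert retained == []
        assert any("lid" in r for r in all_[0].rejection_reasons)


class TestScanAllPairs:
    def test_single_engineered_pair_passes(self):
        s, _ = ideal_cystine_pair()
        table = scan_all_pairs(s)
        passing = table[table["verdict"] == "pass"]
        assert len(passing) == 1
        assert {int(passing.iloc[0]["res_i"]),
                int(passing.iloc[0]["res_j"])} == {10, 20}

    def test_all_inside_triad_shell_rejected_with_log(self):
        s, _ = ideal_cystine_pair()
        atoms = [(c, r, rn, an, el, tuple(xyz)) for c, r, rn, an, el, xyz
                 in zip(s.chain_ids, s.res_ids, s.res_names, s.atom_names,
                        s.elements, s.coords)]
        atoms.insert(0, ("A", 5, "SER", "CA", "C", (0.0, 0.0, 2.0)))
        s2 = make_structure(atoms)
        filt = FunctionalSiteFilter(triad_residues=(5,))
        table = scan_all_pairs(s2, site_filter=filt)
        assert (table["verdict"] == "fail").all()
        rejected = table[table["site_rejections"] != ""]
        assert len(rejected) >= 1

    def test_deterministic_output(self):
        s, _ = ideal_cystine_pair()
        a = scan_all_pairs(s)
        b = scan_all_pairs(s)
        assert a.equals(b)
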