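"""Dihedrals, Newman classification, contact census, superposition and chi1."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import dihedral_reference
from radtunnel.geometry import (
    chi1,
    chi1_delta,
    contact_census,
    dihedral,
    newman_assess,
    superpose,
    superpose_structures,
)
from radtunnel.synth import make_site, make_structure_pair


def random_rotation(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [0, 0, 0], [0, 0, 1], [1, 1, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        val = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [-1, 0, 1])
        assert val == pytest.approx(180.0, abs=1e-9)

    def test_matches_independent_formula(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            assert ours == pytest.approx(dihedral_reference(*pts), abs=1e-9)

    def test_invariant_under_reversal_antisymmetric_under_mirror(self, rng):
        """IUPAC torsions keep their sign when the atom order is reversed
        and flip it under mirror reflection."""
        pts = rng.normal(size=(4, 3)) * 3.0
        fwd = dihedral(*pts)
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)

    def test_invariant_under_rigid_motion(self, rng):
        pts = rng.normal(size=(4, 3)) * 3.0
        q = random_rotation(rng)
        t = rng.normal(size=3) * 10.0
        moved = pts @ q.T + t
        assert dihedral(*moved) == pytest.approx(dihedral(*pts), abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(ValueError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestNewman:
    def test_nosl_product_breaks_ca_c(self):
        """Phi = 174.5: carboxyl bond periplanar (favored), Cbeta clinal."""
        r = newman_assess(174.5)
        assert r.zone("Ca-C") == "periplanar"
        assert next(b for b in r.bonds if b.bond == "Ca-C").omega == pytest.approx(24.5)
        assert r.zone("Ca-Cb") == "clinal"
        assert next(b for b in r.bonds if b.bond == "Ca-Cb").omega == pytest.approx(84.5)

    def test_thih_product_allows_ca_cb(self):
        """Phi = 39.6: Cbeta intermediate (allowed, not optimal), carboxyl clinal."""
        r = newman_assess(39.6)
        assert r.zone("Ca-Cb") == "intermediate"
        assert next(b for b in r.bonds if b.bond == "Ca-Cb").omega == pytest.approx(50.4)
        assert r.zone("Ca-C") == "clinal"
        assert next(b for b in r.bonds if b.bond == "Ca-C").omega == pytest.approx(69.6)

    def test_perpendicular_is_periplanar(self):
        r = newman_assess(90.0)
        assert next(b for b in r.bonds if b.bond == "Ca-Cb").omega == pytest.approx(0.0)
        assert r.zone("Ca-Cb") == "periplanar"

    @given(phi=st.floats(-720, 720, allow_nan=False))
    def test_lobe_symmetry(self, phi):
        """Zones are invariant under phi -> phi + 180 (two-lobe orbital)."""
        a = newman_assess(phi)
        b = newman_assess(phi + 180.0)
        for ba, bb in zip(a.bonds, b.bonds):
            assert ba.omega == pytest.approx(bb.omega, abs=1e-9)
            assert ba.zone == bb.zone

    @given(phi=st.floats(-360, 360, allow_nan=False))
    def test_mirror_symmetry(self, phi):
        """Sign flip combined with offset flip mirrors the assessment."""
        a = newman_assess(phi, substituent_offset=120.0)
        b = newman_assess(-phi, substituent_offset=-120.0)
        for ba, bb in zip(a.bonds, b.bonds):
            assert ba.omega == pytest.approx(bb.omega, abs=1e-9)


class TestContactCensus:
    def test_ideal_square_pyramid(self):
        st_, _ = make_site(n_basal=4, jitter=0.0, apical=True)
        c = contact_census(st_, "A:500:OH")
        assert len(c.contacts) == 5
        assert c.geometry == "square-pyramidal"
        assert all(cc.distance <= 3.5 for cc in c.contacts)
        assert {cc.donor_class for cc in c.contacts} == {"hydroxyl"}

    def test_four_basal_without_apical(self):
        st_, _ = make_site(n_basal=4, apical=False)
        c = contact_census(st_, "A:500:OH")
        assert len(c.contacts) == 4
        assert c.geometry == "square-pyramidal"

    def test_isolated_atom_underdetermined(self):
        st_, _ = make_site(n_basal=0, apical=False)
        c = contact_census(st_, "A:500:OH")
        assert len(c.contacts) == 0
        assert c.geometry == "underdetermined"

    def test_two_donors_underdetermined(self):
        st_, _ = make_site(n_basal=2, apical=False)
        assert contact_census(st_, "A:500:OH").geometry == "underdetermined"

    def test_order_independent(self, rng):
        st_, _ = make_site(jitter=0.15, seed=9)
        c1 = contact_census(st_, "A:500:OH")
        perm = rng.permutation(len(st_.atoms))
        st_.atoms = [st_.atoms[i] for i in perm]
        c2 = contact_census(st_, "A:500:OH")
        assert c1.geometry == c2.geometry
        assert [round(c.distance, 6) for c in c1.contacts] == \
            [round(c.distance, 6) for c in c2.contacts]

    def test_ambiguous_selector_rejected(self):
        st_, _ = make_site()
        with pytest.raises(ValueError, match="matched"):
            contact_census(st_, "A:1:OG2")  # no such atom -> 0 matches


class TestSuperpose:
    def test_identical_sets(self, rng):
        x = rng.normal(size=(40, 3)) * 5.0
        r = superpose(x, x)
        assert r.rmsd == pytest.approx(0.0, abs=1e-12)
        assert r.n_used == r.n_total == 40

    def test_rigid_copy_recovers_exactly(self, rng):
        x = rng.normal(size=(60, 3)) * 5.0
        q = random_rotation(rng)
        y = x @ q.T + np.array([3.0, -7.0, 11.0])
        r = superpose(x, y)
        assert r.rmsd < 1e-9
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noised_copy_matches_expectation(self, rng):
        """Isotropic sigma per coordinate gives RMSD ~ sigma*sqrt(3)."""
        sigma = 0.2
        x = rng.normal(size=(500, 3)) * 8.0
        y = x + rng.normal(0.0, sigma, size=x.shape)
        r = superpose(x, y)
        assert r.rmsd == pytest.approx(sigma * math.sqrt(3.0), rel=0.05)

    def test_symmetric_in_arguments(self, rng):
        x = rng.normal(size=(30, 3)) * 4.0
        y = x + rng.normal(0.0, 0.3, size=x.shape)
        assert superpose(x, y).rmsd == pytest.approx(superpose(y, x).rmsd, rel=1e-9)

    def test_invariant_under_prerotation(self, rng):
        x = rng.normal(size=(30, 3)) * 4.0
        y = x + rng.normal(0.0, 0.3, size=x.shape)
        q = random_rotation(rng)
        assert superpose(x, y @ q.T).rmsd == pytest.approx(superpose(x, y).rmsd, abs=1e-9)

    def test_trimming_drops_outliers_and_lowers_rmsd(self, rng):
        x = rng.normal(size=(100, 3)) * 5.0
        y = x + rng.normal(0.0, 0.05, size=x.shape)
        y[:5] += 8.0  # plant gross outliers
        full = superpose(x, y, trim=False)
        trimmed = superpose(x, y, trim=True)
        assert trimmed.rmsd < full.rmsd
        assert trimmed.n_used <= 95
        assert trimmed.n_used >= 70  # retention floor

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestChi1:
    def test_identical_structures_zero_delta(self):
        a, _, truth = make_structure_pair(noise=0.0, chi1_pair=(-60.0, -60.0))
        ser = truth.parameters["serine_residue"]
        assert chi1_delta(a, a, f"A:{ser}") == 0.0

    def test_constructed_rotation_recovered(self):
        a, b, truth = make_structure_pair(noise=0.0, chi1_pair=(-60.0, 50.0))
        ser = truth.parameters["serine_residue"]
        assert chi1(a, "A", ser) == pytest.approx(-60.0, abs=1e-6)
        assert chi1(b, "A", ser) == pytest.approx(50.0, abs=1e-6)
        assert chi1_delta(a, b, f"A:{ser}") == pytest.approx(110.0, abs=1e-6)

    def test_fold_to_half_circle(self):
        a, b, truth = make_structure_pair(noise=0.0, chi1_pair=(-170.0, 170.0))
        ser = truth.parameters["serine_residue"]
        assert chi1_delta(a, b, f"A:{ser}") == pytest.approx(20.0, abs=1e-6)

    def test_missing_atom_named_in_error(self):
        a, b, truth = make_structure_pair()
        ser = truth.parameters["serine_residue"]
        a.atoms = [at for at in a.atoms if not (at.resnum == ser and at.name == "CB")]
        with pytest.raises(ValueError, match="CB"):
            chi1_delta(a, b, f"A:{ser}")

    def test_structure_pair_superposition(self):
        a, b, _ = make_structure_pair(noise=0.0)
        r = superpose_structures(a, b)
        assert r.rmsd < 1e-9
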