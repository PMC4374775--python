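"""Geometry of pi-pi pairs, salt bridges, H-bonds and interface contacts."""

import itertools

import numpy as np
import pytest

from pkmech.interactions import (
    hbonds,
    interface_contacts,
    pi_pi_pairs,
    plane_angle,
    salt_bridges,
)
from pkmech.structure import DomainDefinition, Structure
from pkmech.synthetic import make_fixture_structure
from tests.conftest import random_rotation


def two_rings(d, normal2=(0, 0, 1), offset_dir=(0, 0, 1)):
    off = np.asarray(offset_dir, dtype=float) * d
    return make_fixture_structure(
        [
            ("phe_ring", {"center": (0, 0, 0), "normal": (0, 0, 1)}),
            ("phe_ring", {"center": tuple(off), "normal": normal2}),
        ]
    )


class TestPiPi:
    def test_parallel_stacked_rings(self):
        recs = pi_pi_pairs(two_rings(4.0))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(4.0, abs=1e-9)
        assert recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_rings(self):
        recs = pi_pi_pairs(two_rings(5.0, normal2=(1, 0, 0)))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(5.0, abs=1e-9)
        assert recs[0].angle == pytest.approx(90.0, abs=1e-6)

    def test_beyond_cutoff_not_reported(self):
        assert pi_pi_pairs(two_rings(7.5)) == []

    def test_incomplete_ring_skipped_with_warning(self):
        s = two_rings(4.0)
        pruned = Structure(
            s.atoms[~((s.atoms["resseq"] == 10) & (s.atoms["name"] == "CZ"))]
            .reset_index(drop=True)
        )
        with pytest.warns(UserWarning, match="incomplete aromatic ring"):
            assert pi_pi_pairs(pruned) == []

    def test_angle_always_acute_and_symmetric(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = rng.normal(size=3), rng.normal(size=3)
            a = plane_angle(n1, n2)
            assert 0.0 <= a <= 90.0
            assert a == pytest.approx(plane_angle(n2, n1))
            assert a == pytest.approx(plane_angle(-n1, n2), abs=1e-9)


class TestSaltBridges:
    def test_planted_pair_within_cutoff(self):
        s = make_fixture_structure([("lys_glu_pair", {"distance": 3.0})])
        recs = salt_bridges(s)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.0, abs=1e-9)

    def test_pair_beyond_cutoff(self):
        s = make_fixture_structure([("lys_glu_pair", {"distance": 4.5})])
        assert salt_bridges(s) == []

    def test_planted_pairs_with_decoys_brute_force(self):
        groups = [
            ("lys_glu_pair", {"distance": 3.0, "origin": (0, 0, 0)}),
            ("lys_glu_pair", {"distance": 3.5, "origin": (0, 30, 0)}),
            ("lys_glu_pair", {"distance": 3.9, "origin": (0, 60, 0)}),
            ("lys_glu_pair", {"distance": 5.5, "origin": (0, 90, 0)}),  # decoy
            ("lys_glu_pair", {"distance": 7.0, "origin": (0, 120, 0)}),  # decoy
        ]
        s = make_fixture_structure(groups)
        recs = salt_bridges(s)
        # independent brute force over all basic-N x acidic-O atom pairs
        basic = s.atoms[(s.atoms["resname"] == "LYS") & (s.atoms["name"] == "NZ")]
        acidic = s.atoms[(s.atoms["resname"] == "GLU") & (s.atoms["name"] == "OE1")]
        expected = sum(
            np.linalg.norm(
                b[["x", "y", "z"]].to_numpy(float) - a[["x", "y", "z"]].to_numpy(float)
            )
            <= 4.0
            for (_, b), (_, a) in itertools.product(
                basic.iterrows(), acidic.iterrows()
            )
        )
        assert expected == 3
        assert len(recs) == expected


class TestHbonds:
    def test_backbone_pair_within_cutoff(self):
        s = make_fixture_structure([("backbone_hbond", {"distance": 2.9})])
        recs = hbonds(s)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9, abs=1e-9)

    def test_pair_beyond_cutoff(self):
        s = make_fixture_structure([("backbone_hbond", {"distance": 3.8})])
        assert hbonds(s) == []

    def test_count_matches_brute_force_pair_scan(self):
        groups = [
            ("backbone_hbond", {"distance": 2.8, "origin": (0, 0, 0)}),
            ("backbone_hbond", {"distance": 3.1, "origin": (0, 30, 0)}),
            ("backbone_hbond", {"distance": 3.3, "origin": (0, 60, 0)}),
            ("backbone_hbond", {"distance": 3.6, "origin": (0, 90, 0)}),
        ]
        s = make_fixture_structure(groups)
        cand = s.atoms[s.atoms["element"].isin({"N", "O", "S"})]
        xyz = cand[["x", "y", "z"]].to_numpy(float)
        res = cand["resseq"].to_numpy()
        brute = sum(
            1
            for i in range(len(cand))
            for j in range(i + 1, len(cand))
            if res[i] != res[j]
            and 1.8 <= np.linalg.norm(xyz[i] - xyz[j]) <= 3.4
        )
        assert len(hbonds(s)) == brute == 3


class TestInterfaceContacts:
    @staticmethod
    def _two_domain_fixture(distance, elem_pair=("O", "O")):
        import pandas as pd

        from pkmech.structure import ATOM_COLUMNS

        e1, e2 = elem_pair
        rows = [
            ("A", 10, "", "THR", "OG1" if e1 == "O" else "CB", e1, 0.0, 0.0, 0.0),
            ("A", 100, "", "ASP", "OD1" if e2 == "O" else "CG", e2, distance, 0.0, 0.0),
        ]
        return Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))

    DOM_A = DomainDefinition("A", ((1, 50),))
    DOM_B = DomainDefinition("B", ((51, 150),))

    def test_polar_contact_classified(self):
        s = self._two_domain_fixture(2.60)
        recs = interface_contacts(s, self.DOM_A, self.DOM_B)
        assert len(recs) == 1
        assert recs[0].contact_class == "Polar"
        assert recs[0].distance == pytest.approx(2.60)

    def test_hydrophobic_contact_classified(self):
        s = self._two_domain_fixture(3.88, elem_pair=("C", "C"))
        recs = interface_contacts(s, self.DOM_A, self.DOM_B)
        assert len(recs) == 1
        assert recs[0].contact_class == "Hydrophobic"

    def test_oxygen_pair_beyond_polar_cutoff_is_no_contact(self):
        # 3.5 A O...O: beyond the polar cutoff and no carbon involved
        s = self._two_domain_fixture(3.50)
        assert interface_contacts(s, self.DOM_A, self.DOM_B) == []

    def test_distant_domains_empty(self):
        s = self._two_domain_fixture(25.0)
        assert interface_contacts(s, self.DOM_A, self.DOM_B) == []

    def test_excluded_hinge_removed(self):
        s = self._two_domain_fixture(2.60)
        assert (
            interface_contacts(s, self.DOM_A, self.DOM_B, exclude=((95, 105),))
            == []
        )

    def test_symmetric_in_domain_order(self):
        s = self._two_domain_fixture(2.60)
        ab = interface_contacts(s, self.DOM_A, self.DOM_B)
        ba = interface_contacts(s, self.DOM_B, self.DOM_A)
        assert {(r.partner_1, r.partner_2) for r in ab} == {
            (r.partner_2, r.partner_1) for r in ba
        }

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            interface_contacts(
                self._two_domain_fixture(3.0),
                DomainDefinition("A", ((1, 60),)),
                DomainDefinition("B", ((51, 150),)),
            )


class TestRigidMotionInvariance:
    def test_all_detectors_invariant_under_rotation_translation(self):
        s = make_fixture_structure(
            [
                ("phe_ring", {"center": (0, 0, 0), "normal": (0, 0, 1)}),
                ("phe_ring", {"center": (3.0, 0, 4.0), "normal": (0, 1, 1)}),
                ("lys_glu_pair", {"distance": 3.2, "origin": (40, 0, 0)}),
                ("backbone_hbond", {"distance": 3.0, "origin": (80, 0, 0)}),
            ]
        )
        base_pi = pi_pi_pairs(s)
        base_sb = salt_bridges(s)
        base_hb = hbonds(s)
        rng = np.random.default_rng(12)
        for _ in range(10):
            rot = random_rotation(rng)
            t = rng.normal(scale=50.0, size=3)
            moved = s.transformed(rot, t)
            for rec, ref in zip(pi_pi_pairs(moved), base_pi):
                assert rec.distance == pytest.approx(ref.distance, abs=1e-9)
                assert rec.angle == pytest.approx(ref.angle, abs=1e-6)
            for rec, ref in zip(salt_bridges(moved), base_sb):
                assert rec.distance == pytest.approx(ref.distance, abs=1e-9)
            assert len(hbonds(moved)) == len(base_hb)
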