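"""Geometry tests: contacts, salt bridges, dihedrals, register recovery."""

import math

import numpy as np
import pytest

from sh3prm import geometry as geo
from sh3prm.synthetic import build_backbone, gen_ppii_fixture


def atom(chain, res_name, res_seq, name, element, xyz):
    return geo.AtomRecord(chain, res_name, res_seq, "", name, element, *xyz)


class TestContacts:
    def test_pair_below_cutoff_detected(self):
        a = [atom("A", "ALA", 1, "CB", "C", (0, 0, 0))]
        b = [atom("B", "ALA", 1, "CB", "C", (4.4, 0, 0))]
        (c,) = geo.compute_contacts(a, b)
        assert c.distance == pytest.approx(4.4)

    def test_pair_above_cutoff_ignored(self):
        a = [atom("A", "ALA", 1, "CB", "C", (0, 0, 0))]
        b = [atom("B", "ALA", 1, "CB", "C", (4.6, 0, 0))]
        assert geo.compute_contacts(a, b) == []

    def test_matches_brute_force_all_pairs(self, tmp_path, ppii_register):
        pdb, _ = gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII",
                                  path=tmp_path / "c.pdb")
        chains = geo.read_structure(tmp_path / "c.pdb")
        got = {
            (c.atom_a.res_seq, c.atom_a.atom_name, c.atom_b.res_seq, c.atom_b.atom_name)
            for c in geo.compute_contacts(chains["A"], chains["B"])
        }
        expect = set()
        for a in chains["A"]:
            for b in chains["B"]:
                if np.linalg.norm(a.coord - b.coord) <= 4.5:
                    expect.add((a.res_seq, a.atom_name, b.res_seq, b.atom_name))
        assert got == expect

    def test_contact_symmetry(self, tmp_path, ppii_register):
        gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII", path=tmp_path / "c.pdb")
        chains = geo.read_structure(tmp_path / "c.pdb")
        ab = {(c.atom_a, c.atom_b) for c in geo.compute_contacts(chains["A"], chains["B"])}
        ba = {(c.atom_b, c.atom_a) for c in geo.compute_contacts(chains["B"], chains["A"])}
        assert ab == ba

    def test_same_chain_refused(self):
        a = [atom("A", "ALA", 1, "CB", "C", (0, 0, 0))]
        with pytest.raises(ValueError, match="distinct chains"):
            geo.compute_contacts(a, a)


class TestSaltBridges:
    def test_detected_at_3_5_not_4_5(self):
        lys = atom("A", "LYS", 1, "NZ", "N", (0, 0, 0))
        near = atom("B", "ASP", 1, "OD1", "O", (3.5, 0, 0))
        far = atom("B", "ASP", 2, "OD1", "O", (4.45, 0, 0))
        contacts = geo.compute_contacts([lys], [near, far])
        bridges = geo.detect_salt_bridges(contacts)
        assert [(b.acidic_residue[2], b.distance) for b in bridges] == [(1, pytest.approx(3.5))]

    def test_histidine_excluded_as_donor(self):
        his = atom("A", "HIS", 1, "NE2", "N", (0, 0, 0))
        asp = atom("B", "ASP", 1, "OD1", "O", (3.0, 0, 0))
        assert geo.detect_salt_bridges(geo.compute_contacts([his], [asp])) == []

    def test_planted_bridges_recovered_exactly(self, tmp_path, ppii_register):
        _, truth = gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII",
                                    path=tmp_path / "c.pdb")
        t = truth.structures["fixture"]
        chains = geo.read_structure(tmp_path / "c.pdb")
        bridges = geo.detect_salt_bridges(geo.compute_contacts(chains["A"], chains["B"]))
        got = {(b.basic_residue[2], b.acidic_residue[2]) for b in bridges}
        expect = {(sb["basic_peptide_index"], sb["acidic_res_seq"]) for sb in t["salt_bridges"]}
        assert got == expect

    def test_bridges_are_subset_of_contacts(self, tmp_path, ppii_register):
        gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII", path=tmp_path / "c.pdb")
        chains = geo.read_structure(tmp_path / "c.pdb")
        contacts = geo.compute_contacts(chains["A"], chains["B"])
        contact_residues = {(c.atom_a.residue_key, c.atom_b.residue_key) for c in contacts}
        for b in geo.detect_salt_bridges(contacts):
            assert (b.basic_residue, b.acidic_residue) in contact_residues


class TestDihedrals:
    def test_round_trip_within_one_degree(self):
        for phi, psi in [(-75.0, 145.0), (-60.0, -45.0), (-120.0, 120.0)]:
            coords = build_backbone("AAAAAA", phi, psi)
            atoms = []
            for i, res in enumerate(coords, start=1):
                for name in ("N", "CA", "C"):
                    atoms.append(atom("A", "ALA", i, name, name[0], tuple(res[name])))
            series = geo.compute_dihedrals(atoms)
            for d in series[1:-1]:
                assert abs(d.phi - phi) < 1.0
                assert abs(d.psi - psi) < 1.0

    def test_ppii_flags_true_only_near_ppii(self):
        assert geo.is_ppii([(-75.0, 145.0), (-100.0, 170.0)]) == [True, True]
        assert geo.is_ppii([(-60.0, -45.0), (None, 145.0)]) == [False, False]

    def test_angular_distance_wraps(self):
        assert geo.angular_distance(179.0, -179.0) == pytest.approx(2.0)

    def test_missing_backbone_gives_none_not_crash(self):
        atoms = [
            atom("A", "ALA", 1, "N", "N", (0, 0, 0)),
            atom("A", "ALA", 1, "CA", "C", (1.5, 0, 0)),
            # residue 1 missing C; residue 2 complete
            atom("A", "ALA", 2, "N", "N", (3, 0, 0)),
            atom("A", "ALA", 2, "CA", "C", (4.5, 0, 0)),
            atom("A", "ALA", 2, "C", "C", (5.5, 1, 0)),
        ]
        series = geo.compute_dihedrals(atoms)
        assert series[0].phi is None and series[0].psi is None
        assert series[1].phi is None  # previous C missing


class TestRegisterRecovery:
    def test_twenty_seeded_fixtures_recover_planted_register(self, tmp_path):
        from sh3prm.synthetic import AA20, stream_rng

        for seed in range(20):
            rng = stream_rng(seed, "structure")
            flank = lambda n: "".join(rng.choice([a for a in AA20 if a not in "PKR"], size=n))
            pos2, pos5 = rng.choice(["K", "R"], size=2)
            p0 = int(rng.integers(3, 6))
            peptide = flank(p0 - 2) + flank(1) + "P" + flank(1) + pos2 + "P" + flank(1) + pos5 + flank(3)
            register = {k: p0 + k for k in range(-2, 6)}
            path = tmp_path / f"fix{seed}.pdb"
            _, truth = gen_ppii_fixture(peptide, register, "PPII", path=path)
            t = truth.structures["fixture"]
            chains = geo.read_structure(path)
            reg = geo.assign_register_from_structure(
                chains["B"], chains["A"], aromatic_res_seqs=t["aromatic_res_seqs"]
            )
            planted = {int(k): v for k, v in t["register"].items()}
            assert dict(reg.positions) == planted, seed

    def test_reversed_peptide_raises_mismatch_warning(self, tmp_path, ppii_register):
        # Build the fixture, then reverse the peptide residue order on re-read.
        path = tmp_path / "c.pdb"
        gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII", path=path)
        chains = geo.read_structure(path)
        reversed_atoms = []
        n_res = max(a.res_seq for a in chains["A"])
        for a in sorted(chains["A"], key=lambda a: -a.res_seq):
            reversed_atoms.append(
                geo.AtomRecord(a.chain_id, a.res_name, n_res + 1 - a.res_seq, a.icode,
                               a.atom_name, a.element, a.x, a.y, a.z)
            )
        with pytest.warns(UserWarning, match="disagree"):
            geo.assign_register_from_structure(chains["B"], reversed_atoms)

    def test_peptide_without_motif_warns_and_uses_structure(self):
        # Prolines 3 apart with groove contacts, but no class-II pattern
        # (no positive residue at position 5): structural anchors win, loudly.
        pep = []
        for i, aa in enumerate("GGPAAPAG", start=1):
            name = {"G": "GLY", "P": "PRO", "A": "ALA"}[aa]
            pep.append(atom("A", name, i, "CA", "C", (i * 3.0, 0, 0)))
        sh3 = [
            atom("B", "PHE", 1, "CZ", "C", (9.0, 3.0, 0)),
            atom("B", "PHE", 2, "CZ", "C", (18.0, 3.0, 0)),
        ]
        with pytest.warns(UserWarning, match="class-II motif"):
            reg = geo.assign_register_from_structure(sh3, pep)
        assert reg.positions[0] == 3 and reg.positions[3] == 6

    def test_no_groove_contacts_unassignable(self):
        pep = [
            atom("A", "PRO", i, "CA", "C", (i * 3.0, 0, 0)) for i in range(1, 8)
        ]
        sh3 = [atom("B", "PHE", 1, "CZ", "C", (0, 100, 0))]
        with pytest.raises(ValueError, match="unassignable"):
            geo.assign_register_from_structure(sh3, pep)


class TestRigidInvariance:
    def test_rotation_translation_changes_nothing(self, tmp_path, ppii_register):
        path = tmp_path / "c.pdb"
        gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII", path=path)
        chains = geo.read_structure(path)

        theta = 0.7
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([11.0, -3.0, 5.0])

        def transform(atoms):
            return [
                geo.AtomRecord(a.chain_id, a.res_name, a.res_seq, a.icode, a.atom_name,
                               a.element, *(rot @ a.coord + shift))
                for a in atoms
            ]

        c0 = geo.compute_contacts(chains["A"], chains["B"])
        c1 = geo.compute_contacts(transform(chains["A"]), transform(chains["B"]))
        assert len(c0) == len(c1)
        for x, y in zip(c0, c1):
            assert abs(x.distance - y.distance) < 1e-6

        d0 = geo.compute_dihedrals(chains["A"])
        d1 = geo.compute_dihedrals(transform(chains["A"]))
        for a, b in zip(d0, d1):
            if a.phi is not None:
                assert abs(a.phi - b.phi) < 1e-4
            if a.psi is not None:
                assert abs(a.psi - b.psi) < 1e-4


class TestReadStructure:
    def test_fixture_round_trip_counts(self, tmp_path, ppii_register):
        _, truth = gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII",
                                    path=tmp_path / "c.pdb")
        chains = geo.read_structure(tmp_path / "c.pdb")
        assert geo.chain_sequence(chains["A"]) == "GAPAKPARGG"
        assert len(chains["B"]) == len(truth.structures["fixture"]["aromatic_res_seqs"]) + 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError, match="no atoms"):
            geo.read_structure(p)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      bad.000   0.000   0.000\n")
        with pytest.raises(ValueError, match="line 1"):
            geo.read_structure(p)

    def test_single_chain_refuses_complex_analysis(self, tmp_path, ppii_register):
        pdb, _ = gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII")
        single = "\n".join(
            l for l in pdb.splitlines() if not (l.startswith("ATOM") and l[21] == "B")
        )
        p = tmp_path / "single.pdb"
        p.write_text(single + "\n")
        chains = geo.read_structure(p)
        with pytest.raises(ValueError, match="two chains"):
            geo.analyze_complex(p, "A", "B")

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        def pdb_line(serial, name, altloc, x, occ):
            return (
                f"ATOM  {serial:>5} {name:<4}{altloc}ALA A{1:>4}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{occ:6.2f}{0.0:6.2f}          "
                " C"
            )

        lines = [
            pdb_line(1, " CA", "A", 0.0, 0.40),
            pdb_line(2, " CA", "B", 5.0, 0.60),
            pdb_line(3, " CB", " ", 1.0, 1.00),
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\n")
        chains = geo.read_structure(p)
        ca = [a for a in chains["A"] if a.atom_name == "CA"]
        assert len(ca) == 1 and ca[0].x == pytest.approx(5.0)


def test_analyze_complex_end_to_end(tmp_path, ppii_register):
    path = tmp_path / "c.pdb"
    _, truth = gen_ppii_fixture("GAPAKPARGG", ppii_register, "PPII", path=path)
    t = truth.structures["fixture"]
    report = geo.analyze_complex(path, "B", "A", aromatic_res_seqs=t["aromatic_res_seqs"])
    assert report.structure_register is not None
    assert {int(k): v for k, v in t["register"].items()} == dict(report.structure_register.positions)
    assert len(report.salt_bridges) == 2
    interior = [v for k, v in sorted(report.ppii_flags.items())][1:-1]
    assert all(interior)
    # anchor prolines contact the groove aromatics, positive positions the acidic patch
    assert report.pocket_summary[0]["groove"] > 0
    assert report.pocket_summary[3]["groove"] > 0
    assert report.pocket_summary[2]["acidic"] > 0
    assert report.pocket_summary[5]["acidic"] > 0
    out = tmp_path / "report.json"
    report.to_json(out)
    assert out.exists()
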