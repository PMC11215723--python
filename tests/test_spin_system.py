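import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdmat.spin_system import (
    Group,
    Proton,
    SpinSystem,
    apply_cutoff,
    parse_complex,
    select_saturated,
)
from stdmat.synthetic_fixtures import FixtureSpec, make_spin_fixture, write_pdb


def _make_fixture(tmp_path, template, **params):
    return make_spin_fixture(FixtureSpec(template, params=params), tmp_path / template)


def _system_at_distances(distances, saturated_at=0.0):
    """One ligand proton at the origin-ward end, protein protons along x."""
    protons = [Proton("H1", "LIG", 1, np.array([saturated_at, 0.0, 0.0]), Group.LIGAND)]
    for i, d in enumerate(distances, 1):
        protons.append(
            Proton(f"HP{i}", "SRC", i, np.array([d, 0.0, 0.0]), Group.SATURATED_PROTEIN)
        )
    return SpinSystem(protons)


class TestParseComplex:
    def test_hydrogen_count_matches_file_records(self, tmp_path):
        res = _make_fixture(tmp_path, "methyl_probe")
        n_h_protein = sum(
            1 for line in res["protein"].read_text().splitlines()
            if line.startswith("ATOM") and line[76:78].strip() == "H"
        )
        n_h_ligand = sum(
            1 for line in res["ligand"].read_text().splitlines()
            if line.startswith("ATOM") and line[76:78].strip() == "H"
        )
        system = parse_complex(res["protein"], res["ligand"])
        assert len(system.ligand) == n_h_ligand == 1
        assert len(system.unsaturated) == n_h_protein == 3
        assert {p.atom_name for p in system.unsaturated} == {"HB1", "HB2", "HB3"}

    def test_ligand_protons_tagged_ligand_and_protein_unsaturated(self, tmp_path):
        res = _make_fixture(tmp_path, "mini_complex")
        system = parse_complex(res["protein"], res["ligand"])
        assert all(p.group is Group.LIGAND for p in system.ligand)
        assert not system.saturated

    def test_multi_model_ligand_coordinate_passthrough(self, tmp_path):
        res = _make_fixture(tmp_path, "poses", n_poses=5, native_index=2)
        lines = res["ligand"].read_text().splitlines()
        blocks, current = [], None
        for line in lines:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                blocks.append(current)
            elif line.startswith("ATOM") and line[76:78].strip() == "H":
                current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        system = parse_complex(res["protein"], res["ligand"], model_index=3)
        np.testing.assert_allclose(system.coords(system.ligand), np.array(blocks[3]))

    def test_model_index_out_of_range(self, tmp_path):
        res = _make_fixture(tmp_path, "two_spin")
        with pytest.raises(IndexError, match="model_index"):
            parse_complex(res["protein"], res["ligand"], model_index=4)

    def test_protein_without_hydrogens_is_rejected(self, tmp_path):
        bare = write_pdb(
            [("CA", "GLY", 1, np.zeros(3), "C")], tmp_path / "noH.pdb"
        )
        res = _make_fixture(tmp_path, "two_spin")
        with pytest.raises(ValueError, match="protonate"):
            parse_complex(bare, res["ligand"])

    def test_garbage_pdb_is_rejected(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM  not a valid record at all\n")
        res = _make_fixture(tmp_path, "two_spin")
        with pytest.raises(ValueError, match="unparseable"):
            parse_complex(bad, res["ligand"])

    def test_hydroxyl_proton_flagged_exchangeable(self, tmp_path):
        protein = write_pdb(
            [
                ("OG", "SER", 1, np.array([0.0, 0.0, 0.0]), "O"),
                ("HG", "SER", 1, np.array([0.96, 0.0, 0.0]), "H"),
                ("CB", "SER", 1, np.array([0.0, 1.43, 0.0]), "C"),
                ("HB2", "SER", 1, np.array([1.0, 1.8, 0.0]), "H"),
            ],
            tmp_path / "ser.pdb",
        )
        res = _make_fixture(tmp_path, "two_spin")
        system = parse_complex(protein, res["ligand"])
        flags = {p.atom_name: p.exchangeable for p in system.unsaturated}
        assert flags == {"HG": True, "HB2": False}


class TestSelectSaturated:
    def test_methyl_rule_finds_ala_and_val_protons(self, tmp_path):
        res = _make_fixture(tmp_path, "mini_complex")
        system = select_saturated(parse_complex(res["protein"], res["ligand"]), "methyls")
        names = {(p.residue_name, p.atom_name) for p in system.saturated}
        assert len(system.saturated) == 9
        assert ("VAL", "HG11") in names and ("ALA", "HB3") in names
        assert ("VAL", "HB") not in names  # CH proton, not CH3

    def test_explicit_list_and_unmatched_entry(self, tmp_path):
        res = _make_fixture(tmp_path, "two_spin")
        system = parse_complex(res["protein"], res["ligand"])
        tagged = select_saturated(system, ["1:HS1"])
        assert [p.atom_name for p in tagged.saturated] == ["HS1"]
        with pytest.raises(ValueError, match="HZ9"):
            select_saturated(system, ["1:HZ9"])

    def test_empty_list_gives_unscorable_system(self, tmp_path):
        res = _make_fixture(tmp_path, "two_spin")
        system = select_saturated(parse_complex(res["protein"], res["ligand"]), [])
        assert not system.saturated and not system.scorable

    def test_methyl_rule_on_methyl_free_protein_flags_unscorable(self, tmp_path):
        res = _make_fixture(tmp_path, "two_spin")  # SRC residue: no methyl dict entry
        system = select_saturated(parse_complex(res["protein"], res["ligand"]), "methyls")
        assert not system.scorable


class TestApplyCutoff:
    def test_survivors_match_brute_force_distances(self):
        system = _system_at_distances([5.0, 9.0, 11.0, 13.0])
        pruned = apply_cutoff(system, 10.0)
        assert [p.atom_name for p in pruned.saturated] == ["HP1", "HP2"]

    def test_boundary_proton_is_kept(self):
        pruned = apply_cutoff(_system_at_distances([10.0]), 10.0)
        assert len(pruned.saturated) == 1

    def test_infinite_cutoff_is_identity(self):
        system = _system_at_distances([5.0, 15.0, 40.0])
        assert len(apply_cutoff(system, np.inf)) == len(system)

    def test_ligand_protons_never_removed(self):
        system = _system_at_distances([100.0])
        assert len(apply_cutoff(system, 1.0).ligand) == 1

    @given(
        distances=st.lists(st.floats(1.0, 40.0), min_size=1, max_size=8),
        c1=st.floats(1.0, 40.0),
        c2=st.floats(1.0, 40.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, distances, c1, c2):
        system = _system_at_distances(distances)
        lo, hi = sorted([c1, c2])
        once = apply_cutoff(system, lo)
        assert [p.label for p in apply_cutoff(once, lo).protons] == [
            p.label for p in once.protons
        ]
        survivors_lo = {p.label for p in once.saturated}
        survivors_hi = {p.label for p in apply_cutoff(system, hi).saturated}
        assert survivors_lo <= survivors_hi

    def test_group_partition_is_disjoint_and_covering(self, tmp_path):
        res = _make_fixture(tmp_path, "mini_complex")
        system = apply_cutoff(
            select_saturated(parse_complex(res["protein"], res["ligand"]), "methyls"),
            8.0,
        )
        groups = [system.ligand, system.saturated, system.unsaturated]
        assert sum(map(len, groups)) == len(system)
        labels = [p.label for g in groups for p in g]
        assert len(labels) == len(set(labels))


def test_incomplete_methyl_group_loses_its_label():
    with pytest.raises(ValueError, match="methyl"):
        SpinSystem(
            [
                Proton("HB1", "ALA", 1, np.zeros(3), Group.UNSATURATED_PROTEIN,
                       methyl_id="ALA1:HB"),
            ]
        )
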