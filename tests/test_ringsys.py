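import pytest
from rdkit import Chem

from kinasespace.ringsys import (
    FrequencyTable,
    bicycle_frequency,
    bicycle_prevalence,
    extract_ring_systems,
    ring_system_atom_sets,
    strip_positioned,
)
from kinasespace.synthdata import LibrarySpec, ScaffoldSpec, Substituent, generate_library

from conftest import records_from_smiles
from ring_fixtures import RING_FIXTURES


def canon_systems(systems):
    return sorted((s.unpositioned, s.positioned, s.n_rings) for s in systems)


def canon_expected(expected):
    return sorted((Chem.CanonSmiles(u), Chem.CanonSmiles(p), n) for u, p, n in expected)


@pytest.mark.parametrize("name,smiles,expected", RING_FIXTURES, ids=[f[0] for f in RING_FIXTURES])
def test_hand_decomposed_fixture(name, smiles, expected):
    """Both encodings match hand-derived decompositions for every fixture."""
    assert canon_systems(extract_ring_systems(smiles)) == canon_expected(expected)


class TestExtraction:
    def test_acyclic_molecule_has_no_systems(self):
        assert extract_ring_systems("CCCCCC") == []

    def test_biphenyl_systems_are_separate(self):
        systems = extract_ring_systems("c1ccc(-c2ccccc2)cc1")
        assert len(systems) == 2 and all(s.n_rings == 1 for s in systems)

    def test_spiro_fuses_by_atom_but_not_by_bond(self):
        spiro = "C1CCC2(C1)CCCCC2"
        assert [s.n_rings for s in extract_ring_systems(spiro, fusion="atom")] == [2]
        assert sorted(s.n_rings for s in extract_ring_systems(spiro, fusion="bond")) == [1, 1]

    def test_atom_sets_partition_ring_atoms(self, planted_library):
        records, _ = planted_library
        for rec in records[::6]:
            mol = rec.to_mol()
            systems = ring_system_atom_sets(mol)
            ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
            union = set().union(*systems) if systems else set()
            assert union == ring_atoms
            assert sum(len(s) for s in systems) == len(union)  # disjoint

    def test_oxindole_keeps_carbonyl_positioned_only(self):
        (system,) = extract_ring_systems("O=C1Cc2ccccc2N1")
        assert system.unpositioned == Chem.CanonSmiles("C1Cc2ccccc2N1")
        assert "O" in system.positioned and len(system.retained_exocyclic) == 1


class TestStripProjection:
    def test_positioned_projects_onto_unpositioned(self, planted_library):
        records, _ = planted_library
        for rec in records[::4]:
            for system in extract_ring_systems(rec):
                assert strip_positioned(system.positioned) == system.unpositioned


class TestFrequency:
    def test_three_quinazolines(self):
        records = records_from_smiles(["Cc1ccc2ncncc2c1", "CCc1ccc2ncncc2c1", "OCc1ccc2ncncc2c1"])
        table = bicycle_frequency(records, "unpositioned")
        key = Chem.CanonSmiles("c1ccc2ncncc2c1")
        assert table.entries[key] == (3, 1.0)
        assert table.n_total == 3 and table.n_unique == 1 and table.n_singletons == 0

    def test_positioned_refines_unpositioned(self, planted_library):
        records, _ = planted_library
        unpos = bicycle_frequency(records, "unpositioned")
        pos = bicycle_frequency(records, "positioned")
        assert pos.n_unique >= unpos.n_unique
        assert pos.n_total == unpos.n_total
        # every unpositioned key is the stripped form of some positioned key
        stripped = {strip_positioned(k) for k in pos.entries}
        assert stripped == set(unpos.entries)

    def test_frequencies_normalize(self, planted_library):
        records, _ = planted_library
        table = bicycle_frequency(records, "unpositioned")
        assert sum(f for _, f in table.entries.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(c for c, _ in table.entries.values()) == table.n_total

    def test_empty_table(self):
        table = bicycle_frequency(records_from_smiles(["CCCC", "c1ccccc1"]), "unpositioned")
        assert table.n_total == 0 and table.entries == {}

    def test_deterministic_ranking(self):
        table = FrequencyTable.from_keys(["b", "a", "a", "c", "b"])
        assert [k for k, _, _ in table.top(3)] == ["a", "b", "c"]  # count desc, then lexicographic
        assert table.n_singletons == 1

    def test_planted_counts_with_singleton(self):
        spec = LibrarySpec(
            scaffold_pool=[
                ScaffoldSpec("c1ccc2ncncc2c1", 5, 2),
                ScaffoldSpec("c1ccc2ncccc2c1", 3, 2),
                ScaffoldSpec("c1ncc2[nH]cnc2n1", 1, 2),
            ],
            substituent_pool=[Substituent("C", 1)],
            n_substituents_range=(1, 1),
            seed=21,
        )
        records, truth = generate_library(spec)
        table = bicycle_frequency(records, "unpositioned")
        assert sorted(c for c, _ in table.entries.values()) == [1, 3, 5]
        assert table.n_singletons == truth.expected_bicycle_singletons_unpositioned == 1


class TestPrevalence:
    def test_half(self):
        assert bicycle_prevalence(records_from_smiles(["c1ccc2ccccc2c1", "CCCCCC"])) == 0.5

    def test_acyclic_set(self):
        assert bicycle_prevalence(records_from_smiles(["CC", "CCC"])) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bicycle_prevalence([])

    def test_planted_exact(self, planted_library):
        records, truth = planted_library
        assert bicycle_prevalence(records) == truth.expected_bicycle_prevalence
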