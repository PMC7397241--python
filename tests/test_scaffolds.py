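import pytest
from rdkit import Chem

from kinasespace.scaffolds import (
    bm_scaffold,
    detect_macrocycle,
    diversity_stats,
    graph_framework,
    scaffold_match,
)
from kinasespace.synthdata import (
    LibrarySpec,
    ScaffoldSpec,
    Substituent,
    default_library_spec,
    generate_library,
)

from conftest import records_from_smiles


class TestBMScaffold:
    def test_toluene(self):
        assert bm_scaffold("Cc1ccccc1") == Chem.CanonSmiles("c1ccccc1")

    def test_acyclic_is_empty(self):
        assert bm_scaffold("CCCCCC") == ""

    def test_dimethoxy_anilinoquinazoline(self):
        # both methoxy side chains removed; anilino linker retained
        got = bm_scaffold("COc1cc2ncnc(Nc3ccccc3)c2cc1OC")
        assert got == Chem.CanonSmiles("c1ccc(Nc2ncnc3ccccc23)cc1")

    def test_exocyclic_carbonyl_retained(self):
        # gem-dimethyl side chains removed, lactam C=O kept on the scaffold
        got = bm_scaffold("CC1(C)C(=O)Nc2ccccc21")
        assert got == Chem.CanonSmiles("O=C1Cc2ccccc2N1")

    def test_idempotent(self, planted_library):
        records, _ = planted_library
        for rec in records[::9]:
            bm = bm_scaffold(rec)
            if bm:
                assert bm_scaffold(bm) == bm


class TestGraphFramework:
    def test_pyridine(self):
        assert graph_framework("c1ccncc1") == Chem.CanonSmiles("C1CCCCC1")

    def test_heteroatom_substitution_collapses(self):
        assert graph_framework("c1ccccc1") == graph_framework("c1ccncc1")
        assert graph_framework("c1ccc2ncncc2c1") == graph_framework("c1ccc2ccccc2c1")

    def test_anilinoquinazoline_atom_count(self):
        gf = graph_framework(bm_scaffold("COc1cc2ncnc(Nc3ccccc3)c2cc1OC"))
        mol = Chem.MolFromSmiles(gf)
        assert mol.GetNumAtoms() == 17
        assert all(a.GetAtomicNum() == 6 and a.GetFormalCharge() == 0 for a in mol.GetAtoms())
        assert all(b.GetBondType() == Chem.BondType.SINGLE for b in mol.GetBonds())

    def test_empty_passthrough(self):
        assert graph_framework("") == ""


class TestMacrocycle:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C1CCCCCCCCCCCC1", True),   # 13-ring
            ("C1CCCCCCCCCCC1", False),   # 12-ring boundary: strict > 12
            ("c1ccc2ccccc2c1", False),   # SSSR sees two 6-rings, not the envelope
            ("CCCC", False),
        ],
    )
    def test_boundary(self, smiles, expected):
        assert detect_macrocycle(smiles) is expected


class TestDiversity:
    def test_shared_scaffold(self):
        records = records_from_smiles(
            ["Cc1ccccc1", "CCc1ccccc1", "OCc1ccccc1", "NCc1ccccc1"]
        )
        stats = diversity_stats(records)
        assert stats.n_unique_bm == 1 and stats.pct_unique_bm == 25.0
        assert stats.n_unique_gf == 1
        assert stats.molecules_per_bm == 4.0

    def test_gf_never_exceeds_bm(self, planted_library):
        records, _ = planted_library
        stats = diversity_stats(records)
        assert stats.n_unique_gf <= stats.n_unique_bm <= stats.n_molecules
        assert 0 <= stats.similarity_mean <= 1

    def test_duplicate_pair_similarity(self):
        stats = diversity_stats(records_from_smiles(["c1ccccc1", "c1ccccc1"]))
        assert stats.similarity_mean == 1.0 and stats.similarity_sd == 0.0

    def test_single_molecule_similarity_absent(self):
        stats = diversity_stats(records_from_smiles(["c1ccccc1"]))
        assert stats.similarity_mean is None

    def test_planted_scaffold_count(self):
        spec = LibrarySpec(
            scaffold_pool=[
                ScaffoldSpec("c1ccc2ncncc2c1", 3, 2),
                ScaffoldSpec("c1ccc2ncccc2c1", 3, 2),
                ScaffoldSpec("c1ccncc1", 3, 1),
            ],
            substituent_pool=[Substituent("C", 1), Substituent("OC", 1, carbon_only=True)],
            n_substituents_range=(1, 2),
            seed=4,
        )
        records, truth = generate_library(spec)
        stats = diversity_stats(records)
        assert stats.n_unique_bm == len(truth.expected_bm_counts) == 3


class TestMatch:
    def test_benzene_query(self):
        hits, total = scaffold_match(
            ["c1ccccc1"], records_from_smiles(["Cc1ccccc1", "CCCCCC"]), level="bm"
        )
        assert total == 1 and hits[Chem.CanonSmiles("c1ccccc1")] == 1

    def test_gf_matching_is_superset_of_bm(self, planted_library):
        records, _ = planted_library
        library = records[:40]
        queries_bm = {bm_scaffold(r) for r in records[40:60] if bm_scaffold(r)}
        _, total_bm = scaffold_match(queries_bm, library, level="bm")
        queries_gf = {graph_framework(q) for q in queries_bm}
        _, total_gf = scaffold_match(queries_gf, library, level="gf")
        assert total_gf >= total_bm

    def test_planted_decorated_quinazolines(self):
        spec = LibrarySpec(
            scaffold_pool=[ScaffoldSpec("c1ccc2ncncc2c1", 3, 2)],
            substituent_pool=[Substituent("C", 1)],
            n_substituents_range=(1, 1),
            seed=8,
        )
        records, _ = generate_library(spec)
        hits, total = scaffold_match(["c1ccc2ncncc2c1"], records, level="bm")
        assert total == 3
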