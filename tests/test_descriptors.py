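import numpy as np
import pytest

from kinasespace.descriptors import (
    DescriptorVector,
    LIPINSKI_LIMITS,
    VEBER_LIMITS,
    compute_descriptors,
    derive_guidelines,
    guideline_from_values,
    rule_profile,
    violation_distribution,
)


def vector(**overrides) -> DescriptorVector:
    base = dict(MW=300.0, ClogP=2.0, TPSA=60.0, HBA=4, HBD=2, NRB=4, NHA=20,
                NAR=2, NCA=0, FCSP3=0.3, MQN8=2, MQN10=1)
    base.update(overrides)
    return DescriptorVector(**base)


class TestPanel:
    def test_benzene(self):
        d = compute_descriptors("c1ccccc1")
        assert (d.HBA, d.HBD, d.NRB, d.NAR, d.NCA) == (0, 0, 0, 1, 0)
        assert d.TPSA == 0.0 and d.FCSP3 == 0.0
        assert d.MW == pytest.approx(78.11, abs=0.01)
        assert d.NHA == 6

    def test_hexane(self):
        d = compute_descriptors("CCCCCC")
        assert (d.NAR, d.NRB) == (0, 3) and d.FCSP3 == 1.0

    def test_deterministic(self):
        a, b = compute_descriptors("CC(=O)Nc1ccc(O)cc1"), compute_descriptors("CC(=O)Nc1ccc(O)cc1")
        assert a == b

    def test_invalid_structure_raises(self):
        with pytest.raises(ValueError):
            compute_descriptors("xyz")


class TestRules:
    def test_two_violations(self):
        p = rule_profile(vector(MW=600.0, ClogP=6.0, HBA=3, HBD=1))
        assert p.lipinski_violations == 2
        assert p.lipinski_flags == {"MW": True, "ClogP": True, "HBA": False, "HBD": False}

    def test_compliant_vector(self):
        p = rule_profile(vector())
        assert p.lipinski_violations == 0 and p.veber_violations == 0

    def test_boundary_is_compliant(self):
        # limits are "<=" compliant; violations require strict exceedance
        p = rule_profile(vector(MW=500.0, ClogP=5.0, HBA=10, HBD=5, TPSA=140.0, NRB=10))
        assert p.lipinski_violations == 0 and p.veber_violations == 0

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            d = vector(
                MW=float(rng.uniform(100, 900)), ClogP=float(rng.uniform(-2, 9)),
                HBA=int(rng.integers(0, 16)), HBD=int(rng.integers(0, 9)),
                TPSA=float(rng.uniform(0, 250)), NRB=int(rng.integers(0, 16)),
            )
            p = rule_profile(d)
            expect_lip = sum(getattr(d, k) > v for k, v in LIPINSKI_LIMITS.items())
            expect_veb = sum(getattr(d, k) > v for k, v in VEBER_LIMITS.items())
            assert p.lipinski_violations == expect_lip
            assert p.veber_violations == expect_veb
            assert sum(p.lipinski_flags.values()) == p.lipinski_violations


class TestViolationDistribution:
    def test_small_example(self):
        vectors = [vector(), vector(), vector(MW=600.0), vector(MW=600.0, ClogP=6.0)]
        table = violation_distribution(vectors)
        assert dict(zip(table.violations, table["count"])) == {"0": 2, "1": 1, "2": 1, ">2": 0}
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_all_compliant(self):
        table = violation_distribution([vector()] * 5)
        assert dict(zip(table.violations, table["count"])) == {"0": 5, "1": 0, "2": 0, ">2": 0}

    def test_classes_partition_dataset(self):
        rng = np.random.default_rng(3)
        vectors = [vector(MW=float(rng.uniform(100, 900)), ClogP=float(rng.uniform(-2, 9)))
                   for _ in range(57)]
        assert violation_distribution(vectors)["count"].sum() == 57

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            violation_distribution([])


class TestGuidelines:
    def test_closed_form(self):
        g = guideline_from_values("HBD", [1, 2, 3, 4, 5])
        assert g.mean == pytest.approx(3.0)
        assert g.sd == pytest.approx(1.5811, abs=1e-4)
        assert g.lower == 0.0  # clamped count descriptor
        assert g.upper == pytest.approx(3.0 + 2 * 1.58113883, abs=1e-6)

    def test_constant_column(self):
        g = guideline_from_values("MW", [7.0, 7.0, 7.0])
        assert g.sd == 0.0 and g.lower == g.upper == g.mean == 7.0

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(42)
        values = rng.normal(100, 10, size=10_000)
        g = guideline_from_values("TPSA", values)
        coverage = np.mean((values >= g.lower) & (values <= g.upper))
        assert coverage == pytest.approx(0.954, abs=0.006)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            guideline_from_values("MW", [1.0])

    def test_full_panel(self, planted_library):
        records, _ = planted_library
        vectors = [compute_descriptors(r) for r in records]
        guidelines = derive_guidelines(vectors)
        assert len(guidelines) == 12
        for g in guidelines:
            assert g.lower <= g.mean <= g.upper
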