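"""Hand-decomposed ring-system fixtures.

Each entry: (name, molecule SMILES, expected systems), where each system
is (unpositioned SMILES, positioned SMILES with typed dummies, n_rings).
Expected strings were derived by hand from the encoding rules —
substituents on acyclic bonds replaced by hydrogen (unpositioned) or by a
typed dummy (positioned), exocyclic double-bonded atoms retained in the
positioned form — and are canonicalized before comparison.  System order
within a molecule is not asserted.
"""

RING_FIXTURES = [
    ("toluene", "Cc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("acetophenone", "CC(=O)c1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("oxindole", "O=C1Cc2ccccc2N1", [("C1Cc2ccccc2N1", "O=C1Cc2ccccc2N1", 2)]),
    ("4-bromoanisole", "COc1ccc(Br)cc1", [("c1ccccc1", "[*:1]c1ccc([*:4])cc1", 1)]),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1",
     [("c1ccccc1", "[*:3]c1ccccc1", 1), ("c1ccccc1", "[*:3]c1ccccc1", 1)]),
    ("2-methylnaphthalene", "Cc1ccc2ccccc2c1",
     [("c1ccc2ccccc2c1", "[*:1]c1ccc2ccccc2c1", 2)]),
    ("cyclotridecane", "C1CCCCCCCCCCCC1",
     [("C1CCCCCCCCCCCC1", "C1CCCCCCCCCCCC1", 1)]),
    ("cyclododecane", "C1CCCCCCCCCCC1", [("C1CCCCCCCCCCC1", "C1CCCCCCCCCCC1", 1)]),
    ("quinazoline", "c1ccc2ncncc2c1", [("c1ccc2ncncc2c1", "c1ccc2ncncc2c1", 2)]),
    ("6,7-dimethoxy-N-phenylquinazolin-4-amine", "COc1cc2ncnc(Nc3ccccc3)c2cc1OC",
     [("c1ccc2ncncc2c1", "[*:1]c1ncnc2cc([*:1])c([*:1])cc12", 2),
      ("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("pyridine", "c1ccncc1", [("c1ccncc1", "c1ccncc1", 1)]),
    ("N-methylpyrrole", "Cn1cccc1", [("c1cc[nH]c1", "[*:1]n1cccc1", 1)]),
    ("chlorobenzene", "Clc1ccccc1", [("c1ccccc1", "[*:4]c1ccccc1", 1)]),
    ("fluorobenzene", "Fc1ccccc1", [("c1ccccc1", "[*:4]c1ccccc1", 1)]),
    ("anisole", "COc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("styrene", "C=Cc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("benzaldehyde", "O=Cc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("phenylcyclohexane", "C1CCC(c2ccccc2)CC1",
     [("C1CCCCC1", "[*:3]C1CCCCC1", 1), ("c1ccccc1", "[*:2]c1ccccc1", 1)]),
    ("benzylcyclohexane", "C(c1ccccc1)C1CCCCC1",
     [("c1ccccc1", "[*:1]c1ccccc1", 1), ("C1CCCCC1", "[*:1]C1CCCCC1", 1)]),
    ("2-methylindole", "Cc1cc2ccccc2[nH]1",
     [("c1cc2ccccc2[nH]1", "[*:1]c1cc2ccccc2[nH]1", 2)]),
    ("benzophenone", "O=C(c1ccccc1)c1ccccc1",
     [("c1ccccc1", "[*:1]c1ccccc1", 1), ("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("4,4'-difluorobiphenyl", "Fc1ccc(-c2ccc(F)cc2)cc1",
     [("c1ccccc1", "[*:3]c1ccc([*:4])cc1", 1),
      ("c1ccccc1", "[*:3]c1ccc([*:4])cc1", 1)]),
    ("methylenecyclohexane", "C=C1CCCCC1", [("C1CCCCC1", "C=C1CCCCC1", 1)]),
    ("acetanilide", "CC(=O)Nc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("naphthalene", "c1ccc2ccccc2c1", [("c1ccc2ccccc2c1", "c1ccc2ccccc2c1", 2)]),
    ("spiro[4.5]decane", "C1CCC2(C1)CCCCC2",
     [("C1CCC2(C1)CCCCC2", "C1CCC2(C1)CCCCC2", 2)]),
    ("quinoline", "c1ccc2ncccc2c1", [("c1ccc2ncccc2c1", "c1ccc2ncccc2c1", 2)]),
    ("purine", "c1ncc2[nH]cnc2n1", [("c1ncc2[nH]cnc2n1", "c1ncc2[nH]cnc2n1", 2)]),
    ("benzonitrile", "N#Cc1ccccc1", [("c1ccccc1", "[*:1]c1ccccc1", 1)]),
    ("1-indanone", "O=C1CCc2ccccc21", [("C1Cc2ccccc2C1", "O=C1CCc2ccccc21", 2)]),
    ("tetralin", "C1CCc2ccccc2C1", [("C1CCc2ccccc2C1", "C1CCc2ccccc2C1", 2)]),
    ("1-phenylpyrazole", "c1ccc(-n2cccn2)cc1",
     [("c1ccccc1", "[*:3]c1ccccc1", 1), ("c1cc[nH]n1", "[*:3]n1cccn1", 1)]),
]
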