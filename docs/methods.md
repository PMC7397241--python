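# Methods

`kinasespace` profiles the chemical space of a small-molecule library the way
medicinal-chemistry surveys of kinase-inhibitor space do: physicochemical
descriptors and empirical rule profiles, a correlation-metric PCA, a
principal-moments-of-inertia (PMI) shape map, Bemis–Murcko scaffold and graph
framework diversity, and a ring-system ensemble classification that keeps
typed attachment points. This note records the models, the defaults, and the
choices made where the procedure was genuinely open.

## Standardization and identity

A structure is standardized by (1) keeping the largest organic fragment
(dropping counter-ions such as bromide), (2) neutralizing formal charges where
a neutral form exists (permanently charged centers, e.g. quaternary ammonium,
stay charged), and (3) selecting one canonical tautomer with RDKit's scoring
canonicalizer. Tautomer canonicalization is configured to retain stereocenters
(`tautomerRemoveSp3Stereo = False`): molecular identity for deduplication is
the standard InChIKey of the standardized form, and enantiomers are distinct
entities, so the standardizer must not erase the distinction. The operation is
idempotent, which the test suite asserts on generated libraries. No exact
agreement with any proprietary standardizer is claimed.

## Descriptor panel, rules and guidelines

The 12-descriptor panel: molecular weight (Da), Wildman–Crippen ClogP, TPSA
(Å²), HBA and HBD in the Lipinski N+O / NH+OH counting convention (the
convention the rule of five was stated in — not the valence-based acceptor
definitions), rotatable bonds, heavy atoms, aromatic rings, chiral atoms
(potential tetrahedral stereocenters including unassigned ones, since many
deposited structures lack stereo annotations), fraction of sp³ carbons, and
MQN components 8 and 10. The MQN vector is the published 42-component integer
descriptor; components 8 and 10 (1-based) are the acyclic-nitrogen and
acyclic-oxygen counts. Which components a bare "MQN8/MQN10" label denotes is a
convention; the 1-based index reading is used and fixed here.

Rule violations are strict exceedances (MW = 500.0 is compliant). The
rule-of-five violation distribution reports classes {0, 1, 2, >2}.

Guideline ranges are mean ± k·SD per descriptor with k = 2 by default (a 95.4%
interval under normality), sample SD (n−1 denominator, the dataset being a
sample of the chemical space of interest). Lower bounds of count descriptors
are clamped at 0; a rounded presentation form (integer bounds for counts) is
emitted alongside the raw values.

## PCA

PCA is run on the 10-variable subset (MW, ClogP, TPSA, HBA, HBD, NRB, NAR,
FCSP3, MQN8, MQN10) after centering and unit-variance scaling, i.e. an
eigendecomposition of the correlation matrix, computed via SVD of the
standardized matrix. Scaling uses the sample SD so the score covariance equals
the eigenvalues exactly on training data. Component signs are fixed (largest
|loading| positive) to make repeated fits comparable. Variable contributions
are 100·loading² (columns are orthonormal, so each axis sums to 100%); the
correlation circle plots variable–component correlations, loading·√eigenvalue.
Constant variables are a hard error naming the variable — silently dropping or
jittering them would change the model. Per-class 95% ellipses are Gaussian
confidence ellipses: mean and covariance of the class's (PC1, PC2) scores at
the chi-square 0.95 quantile with 2 degrees of freedom.

## PMI shape analysis

One conformer per molecule: ETKDG distance-geometry embedding (`n_confs = 10`
trials by default, fixed seed) with MMFF94 minimization, keeping the
lowest-energy conformer — the common convention for single-point PMI maps.
Hydrogens are added before embedding and included in the mass-weighted inertia
tensor, taken about the center of mass. Whether unit-mass or mass-weighted
moments are used is a genuine fork; mass-weighted is chosen and fixed. NPR1 =
I1/I3 and NPR2 = I2/I3 of the ascending-sorted moments place molecules in the
triangle with vertices rod (0, 1), disc (0.5, 0.5), sphere (1, 1); diacetylene,
benzene and adamantane are embedded alongside any input as vertex references.
Embedding failures exclude a molecule from the table with a logged reason,
never failing the batch.

## Scaffolds and frameworks

Bemis–Murcko scaffolds (rings plus connecting linkers, side chains removed,
exocyclic double-bonded atoms retained — a lactam scaffold keeps its carbonyl)
come from RDKit's Murcko decomposition; acyclic molecules have an empty
scaffold. The graph framework converts every scaffold atom to carbon and every
bond to single, collapsing heteroatom- and bond-order variants onto one cyclic
skeleton, so unique-framework counts are never larger than unique-scaffold
counts. Macrocycle detection applies the SSSR strictly: some smallest ring
must have more than 12 atoms; fused envelopes (naphthalene's 10-atom
perimeter) do not count. Scaffold equality is string equality of canonical
SMILES, with both sides re-canonicalized before comparison. Diversity
statistics report unique counts, macrocycles, and within-dataset pairwise
Tanimoto similarity on 166-bit MACCS keys (mean and sample SD over all
unordered pairs); the pair population is within-dataset, which is the natural
reading when each dataset is summarized separately.

## Ring-system ensembles

Ring atoms are partitioned into fused systems: SSSR rings sharing at least one
atom merge, so spiro junctions fuse by default (`fusion="bond"` restricts
merging to shared bonds; spiro cases are rare in practice and the choice is
exposed rather than hidden). Rings joined only through acyclic bonds are
separate systems. Two encodings per system:

* **Unpositioned** — all acyclic substituents, including exocyclic
  double-bonded atoms, replaced by hydrogen; aromaticity is re-perceived on
  the bare system (the molecule is kekulized before atom deletion, then
  re-sanitized). This is why an oxindole ring system encodes as non-aromatic
  indoline: removing the carbonyl leaves an sp³ ring carbon.
* **Positioned** — atoms double-bonded to the system are retained unchanged;
  every other first attached atom becomes a typed dummy, serialized as atom
  map 1–4: 1 generic, 2 non-aromatic ring atom, 3 aromatic atom, 4 halogen.
  The rules are applied with precedence retained > halogen > aromatic >
  non-aromatic ring > generic so the classes partition all attachments. "Not
  double bonded" refers to the bond into the ring system: an acyl carbon
  (double-bonded only to its own oxygen) is class 1. Atom maps survive
  canonicalization bit-exactly, which is why they carry the class labels.

Bicycles are systems with exactly two SSSR rings. Frequency tables count one
entry per occurrence (a molecule with two quinazolines contributes two), with
deterministic ranking (count descending, then lexicographic). Singletons are
entries with count 1. Bicycle prevalence is the fraction of molecules with at
least one bicycle.

## Similarity and clustering

Pair statistics (Tanimoto on MACCS keys or Morgan radius-2/2048 fingerprints)
stream over the n(n−1)/2 pairs with a Welford accumulator — no similarity
matrix is materialized — and reproduce the exact two-pass result, which a test
asserts to 1e-12. Butina leader clustering (distance threshold, default 0.6,
Morgan radius-2) is provided for completeness; its assignment is
order-dependent by construction and documented as such.

## Dataset construction

A bioactivity table row qualifies a molecule when the target is flagged as a
kinase, the activity type is IC50/Ki/Kd, and pChEMBL is strictly above the
threshold (default 6, i.e. sub-micromolar). A molecule qualifies if any single
row passes. Kinase membership is a caller-supplied flag, not a live taxonomy
lookup, keeping the stage testable offline. Qualifying molecules are
standardized, deduplicated and filtered against an exclusion list of
InChIKeys.

## Synthetic libraries and what they do (not) show

The generator decorates a pool of cores (quinazoline, quinoline, indole,
purine, oxindole, benzene, pyridine, pyrimidine, plus undecorated 13-membered
macrocycles) with 1–3 substituents drawn from {methyl, methoxy, dimethylamino,
cyclohexyl, phenyl, F, Cl, Br} at ring positions with a free valence. The
defaults plant: 100 molecules per scale unit, 65% carrying a fused bicycle, 2
macrocycles, and at least one exemplar of every positioned-attachment class;
the oxindole core exercises the carbonyl-retention and de-aromatization rules.
The dimethylamino substituent is in the pool so that every PCA panel variable
(including the acyclic-N count MQN8) varies on generated data. Truth tables
(scaffold counts, both bicycle tables, violation classes, macrocycles,
prevalence) are accumulated while each molecule is assembled, from the
construction plan and elementary RDKit calls — not by running the analysis
code they validate.

Planted libraries have known answers by construction, which real libraries do
not: they contain no salts, no stereochemistry, no tautomer ambiguity, no
charged species and only first-shell decoration. Passing planted-truth tests
therefore demonstrates that the decomposition and counting machinery is exact
on clean inputs; it does not validate standardization choices against messy
registry data, which are covered separately by the standardization unit tests.

## Numerical choices and problem sizes

Sample SD (ddof = 1) throughout. PCA requires n > p and errors on missing or
constant columns. Gaussian coverage checks run at n = 10,000 with fixed seeds
(binomial SD of the 95.4% coverage at that n is ≈ 0.2%, so the ±0.6% test band
is comfortably wider than sampling noise). The test suite and the acceptance
script embed conformers with 1–3 trials per molecule on libraries of 50–100
molecules — enough for the shape invariants being checked, since NPR is
insensitive to conformer choice for the small rigid-to-semirigid structures
generated; the library default remains 10 trials. Frequency-table ties break
lexicographically so outputs are reproducible byte-for-byte.

## Known limitations

- Tautomer canonicalization follows RDKit's scoring function; other toolkits
  pick different canonical tautomers, which can shift a scaffold assignment.
- Positioned encodings type only the first attached atom (no second-shell
  environments), by design.
- Butina clustering exposes no cluster-count target; none is asserted beyond
  planted well-separated families.
- The PMI stage selects a single conformer; molecules with several low-energy
  shapes are represented by one point.
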