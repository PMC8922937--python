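# Methods

## Model and assumptions

The package rests on one empirical premise: a molecular fragment tends to
make the same non-covalent interactions whenever it binds the same target
pocket, largely independently of the compound it is embedded in. Under that
premise the binding mode of a compound–target pair without structural data
can be approximated by composing the observed binding modes of the
compound's fragments on that target. The pipeline makes no geometric claim:
all distances, angles, and residue positions are discarded; a binding mode
is only the *set* of (interaction type, ligand functional group, residue
identity) combinations.

### Fragmentation

RECAP tree-leaves decomposition as implemented in rdkit. Only terminal
leaves are kept (no recombined internal nodes), open valences from cleavage
are hydrogen-capped before canonicalisation so fragment identity (canonical
SMILES, InChIKey, MW) is independent of cleavage context. Leaf sets are
version-dependent — rdkit's RECAP rules have changed across releases — so
the rdkit version is recorded in every run's metadata and fingerprint
provenance. Each leaf occurrence is mapped back onto the parent by
substructure matching of the capped core (hydrogen counts and
stereochemistry are ignored during matching, since capping deliberately
changes both); an occurrence with no consistent embedding is dropped, and a
compound none of whose leaves embed is excluded from fragment-level
analysis while remaining available to evaluation subsets. Ambiguous
embeddings are resolved deterministically: prefer the match overlapping
fewest already-claimed atoms, then the lexicographically smallest atom
tuple. A leaf occurring k times in one compound is recorded k times with
disjoint atom maps — each occurrence mediates its own contacts — but counts
once in per-compound multiplicity statistics and in the compound-proportion
denominator.

Atom identifiers are strings; for SMILES-derived ligands they are the atom
indices of the ligand's stored canonical SMILES, and interaction records
must use the same space. Pre-fragmented (abstract) corpora may use any
opaque scheme.

### Fingerprints

The feature triple is normalised (enum interaction type, case-folded group
label, 3-letter residue code) and hashed with CRC-32 modulo 500, plus one.
The hash is pinned (`crc32-mod500`) with golden vectors frozen in the test
suite: reproducibility across platforms and releases is the contract, and
distinct triples may collide (500-bin pigeonhole) by design. Functional
group labels are taken verbatim from the input dialect after case-folding —
no chemistry is re-perceived. Residue *identity* enters the hash; residue
number and chain do not. For water bridges the protein residue is used as
the interacting residue by default (the bridging water reading can be
expressed through the input dialect by labelling the residue `HOH`).

A fragment's per-complex fingerprint uses the records whose ligand atoms
intersect the fragment's atom map (any-atom membership — the profiler
reports single ligand atoms for most interaction types). When a fragment
occurs multiple times in one complex, the complex-level fragment
fingerprint is the union over occurrences, so the pairwise-comparison unit
is the complex throughout. Complexes with no interaction records, and
fragments with empty restricted record sets, carry no information and are
dropped.

### Conservation scoring

mTIS is the mean pairwise Jaccard over complexes within a group; pairs are
unordered, self-pairs excluded (self-similarity would inflate means). The
empty-vs-empty Tanimoto case is defined as 0 and logged — it cannot arise
from a correctly filtered corpus. Grouping contexts: all complexes of a
fragment (`all_targets`); the complexes of one parent compound, emitted
only when it binds ≥ 2 targets, pooled into one record per fragment
(`same_compound_diff_targets`); and the complexes on one target, emitted
per target when ≥ 2 distinct compounds contribute
(`diff_compounds_same_target`) — the context the reconstruction consumes.
All pairs within a group enter the statistics, including same-compound
pairs inside a target group, matching the aggregation unit being structures
rather than compounds.

Filters (defaults): fragment-sized MW window 40 < MW < 300 Da (strict
inequalities), ≥ 5 distinct parent compounds, ≥ 10 distinct targets, both
applied globally per fragment; fragments above 500 complexes are thinned to
one representative complex per (target UniProt, compound InChIKey) pair,
chosen by a single seeded generator with groups visited in sorted order, so
the selection is reproducible and the filter idempotent. The multiplicity
minima are applied globally, not per target: a fragment can pass them while
a given target group has only two compounds, and that group is still
scored.

Threshold comparisons use ≥ uniformly (a fragment with mTIS exactly 0.6
counts as conserved at the 0.6 gate), which makes the 0.6-conserved set a
subset of the 0.5-selected set by construction.

### Reconstruction

Target-based: only structural data of fragments *on the query target* is
used. A fragment is usable when it survived the corpus filters, has
complexes on the target, and its per-target mTIS passes
max(0.5, BM-conservation threshold) — the 0.5 floor defines subset
membership regardless of how permissive the tunable gate is. The compound
proportion counts distinct leaves: usable / all leaves, including leaves
without any data. Statuses record the first failed gate: no fragment with
data at all → `no_fragment_data`; data present but nothing passes the
conservation gate → `below_conservation`; proportion under threshold →
`below_proportion`.

A usable fragment's representative fingerprint is the per-bin activation
frequency over its complexes on the target (a rational with denominator
n_source_fps). In leave-one-out evaluation only this step excludes the
held-out complex; conservation scores and filters are computed once on the
full corpus, since the gates define the fragment subset rather than the
evidence being transferred. Merging representatives takes the union of
active bins and, per bin, the mean frequency **over the representatives in
which the bin is active** (default `merge="active"`): a bin's score should
reflect how often it was observed, not how many unrelated fragments the
compound has. The reading "mean over all representatives" is available as
`merge="all"`; with it, frequencies shrink with fragment count while the
active-bin set is unchanged, so binary-set evaluation is identical under
both.

### Evaluation

Every complex of a fragmentable compound is an evaluation pair: the
original compound-level fingerprint (all records, unrestricted) versus the
leave-one-out reconstruction for its (compound, target). A reconstructed
bin is activated when its frequency is strictly positive (every positive
frequency stems from a real observation); the cutoff is exposed
(`activation_cutoff`) for sensitivity analysis. RSS is the mean pair
similarity over a cell's reconstructed pairs; pairs failing a gate are
tallied separately and excluded from that cell's mean, so counts vary
across the grid. Counts are asserted non-increasing along both threshold
axes after every grid run. Human-readable tables round RSS to two decimals;
machine output keeps full precision.

## Synthetic corpora

The generator emulates exactly the structure the analysis assumes: each
fragment–target pair owns a canonical set of feature triples, each complex
displays an independent thinning of that set (keep-probability
`conservation_p`) plus Poisson noise records from a separate vocabulary.
Canonical triples are rejection-sampled to occupy distinct bins, with noise
bins disjoint from all canonical bins, so truth metadata separates signal
from noise exactly and the analytic limit for the mean pairwise TIS of two
thinnings — p/(2−p) at zero noise — holds at the bin level and checks the
whole encode→compare path.

Default conditions are a realistic miniature of a crystallographic fragment
corpus: 14 targets, 12 fragments, 30 compounds of 2–4 leaves binding 2–5
targets each with 1–3 complexes per pair, canonical sets of 6 interactions,
`conservation_p` 0.8, noise rate 0.5 per complex. These give means of
roughly 7.5 compounds and 12 targets per fragment, matching the typical
multiplicity statistics of fragments in the PDB (means near 7.8 and 12.1).
`conservation_p` accepts a tuple assigned to fragments round-robin to build
conservation blocks for recovery experiments.

Two modes: `abstract` (default test surface) synthesises fragment
membership, atom maps, valid-layout InChIKeys and fragment-sized MWs
directly, decoupling method tests from fragmentation-library versioning;
`chemical` assembles small amides from an acyl × amine vocabulary and runs
the real RECAP rules. What passing tests on synthetic corpora do **not**
show: robustness to crystallographic bias, resolution effects, correlated
binding modes across related targets, profiler mislabelling, or fragments
whose conservation varies by binding-site environment — none of which the
generator emulates.

The bundled worked-example corpus places brivudine (fragmented with real
RECAP) on deoxynucleoside kinase among synthetic companion compounds that
give its uracil and sugar leaves ≥ 5 compounds, > 10 targets and high
per-target conservation, while the bromine-containing leaf stays below the
five-compound minimum — so reconstruction uses 2 of 3 leaves, a compound
proportion of 2/3.

## Numerical and design choices

* Bin vectors are fixed length 500, indexed 1..500; serialisation is a
  500-character 0/1 string, or a sparse `bin:freq` list for frequency
  fingerprints.
* Pairwise TIS matrices are computed by integer matrix product of the
  stacked bin arrays; the 0/0 union case maps to 0.
* All randomness (corpus generation, cap selection) flows from one integer
  seed; group iteration is sorted before any draw, so outputs are
  byte-identical across reruns and platforms.
* Problem sizes in the test-suite simulations (tens of compounds, hundreds
  of complexes, 12–20 seeds for statistical properties) were chosen as the
  smallest scales at which the distributional checks are stable.
* `FragmentationOutcome` keeps non-fragmentable compounds (status
  `non_fragmentable`) so evaluation subsets can retain them even though
  fragment-level analysis cannot use them.

## Known limitations

* Leaf sets depend on the rdkit release; the worked example's
  bromine-containing leaf is `CBr` under the pinned rdkit (2024.09), while
  older rule sets can render the small bromine leaf differently. Identity
  comparisons in tests therefore use connectivity-level InChIKey blocks.
* Hash collisions between distinct triples are accepted, not corrected; at
  500 bins and typical per-complex record counts the effect on Jaccard
  similarities is small but nonzero.
* The per-target conservation context requires ≥ 2 distinct compounds; a
  fragment seen on a target in only one compound can never be used for that
  target, which bounds coverage on sparsely populated targets.
* The pipeline consumes profiler output as ground truth; it does not
  recompute interactions from coordinates and inherits any profiler errors.
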