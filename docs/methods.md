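# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `mgcminer`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code demonstrates.

## Alignment statistics (`align`)

Pairwise comparison uses Smith–Waterman–Gotoh local alignment (the
C implementation behind `Bio.Align.PairwiseAligner`) with BLOSUM62 and
affine gaps in the convention *score(gap of length k) = gap_open +
k·gap_extend*, defaults −11/−1 — the classic protein-search setting. The
empty alignment is admissible, so scores are never negative. Co-optimal
tracebacks are resolved deterministically by taking the engine's first
enumerated alignment; scores are unaffected by this choice, and the test
suite checks score equivalence against exhaustive enumeration of all local
alignments of short words.

Expectation values use the Karlin–Altschul formula *E = K·m·n·e^(−λS)*
with the gapped BLOSUM62/11/1 parameters λ = 0.267, K = 0.041 and **raw**
sequence lengths *m, n* (no edge-effect correction — a documented
simplification relative to production search tools; at the protein lengths
involved it shifts E-values by well under an order of magnitude).
−ln *E* is computed in log space and clamped to [0, 745]; 745 is just
below −ln of the smallest positive double, and hits with *E* > 1 carry no
evidence, so they clamp to 0.

Percent identity is identical columns over **all** alignment columns,
including gapped ones — the choice matters at the 30 % threshold and is
fixed here so that thresholds are unambiguous.

## Marker evaluation (`marker_eval`)

A usable search marker must look similar across distantly related MTB yet
dissimilar from its non-MTB homologs. For each candidate family we
aggregate all-vs-all statistics over **cross-taxon-group pairs only**
(within-group similarity says nothing about reach): minimum and median
identity, minimum and median −ln *E*. The separation margin is

    min within-family −ln E  −  max marker-vs-homolog −ln E,

with the homolog side defaulting to 0 (the *E* = 1 floor) for families
without recorded homologs. Families are ranked lexicographically:
excluded flag (min cross-group identity below a configurable floor,
default 0.15), homolog intrusions ascending, separation margin descending,
minimum identity descending, family name. The aggregation statistic and
ranking are this package's own operationalization — scatter plots in the
literature show the raw quantities but never define an ordering; this one
is deterministic and reproduces the expected qualitative ordering (the
slowest-evolving family with the most distant homologs ranks first) on
synthetic data built with that structure.

Clade structure is assessed on an NJ tree over the family plus its
homologs. Trees built internally are rooted on the homolog side (the edge
whose far side holds the most homologs and fewest markers — homologs are
the natural outgroup); trees supplied pre-rooted are honored as given.
The count is of **maximal marker-only clades** covering all marker leaves;
intrusions are homolog leaves inside counted clades, verified from leaf
sets. Under marker-only clades this count is zero by construction — it is
reported as a diagnostic of the cover, and the interesting signal is the
clade count itself (a family that is genuinely split, as the actin-like
case, yields two clean clades).

## Screening (`screen`)

Retention requires identity **strictly above 0.30** and *E* ≤ 10⁻⁵. The
threshold direction matters: significant hits have small E-values, and a
filter keeping *E* above 10⁻⁵ would admit noise; the implementation
therefore keeps the small-*E* side. A protein gets at most one hit: the
best-scoring reference per family is found, passing families compete by
score, and the winner's family is assigned.

The co-occurrence filter keeps scaffolds with a primary-marker hit
(default mamK) plus at least `min_other_families` = 1 additional
*distinct* family, counted by name (two primary hits never qualify) and
restricted by default to `mam`-category families — how many and which
categories should count is genuinely open, so both are parameters.

Locus calling chains hits whose gene ordinals differ by ≤ 5 (the
`max_gene_gap` default; published MGC regions are contiguous but no
chaining rule is stated, so this is a knob).

## Annotation, QC, ANI (`annotate_qc`)

Locus annotation re-examines **every** gene call in the locus's ordinal
span against the full reference set (mam/mms/mad/man), so genes the
marker screen never looked for can be labeled; failures are `unassigned`.

The quality filter keeps completeness > 45 and contamination < 10, both
strict — a genome at exactly 45.0 or 10.0 is rejected — matching the
wording of the thresholds it reproduces; an override id set keeps
designated genomes (e.g. a 39 %-complete single-cell genome whose MGC is
too informative to drop) with a logged note.

N50 is the largest length L such that scaffolds ≥ L cover at least half
the assembly; GC % is over unambiguous A/C/G/T only, and an assembly with
no unambiguous base raises rather than reporting a number.

Fragment ANI cuts genome A into non-overlapping 1020-bp windows (the
classic fragment length; a scaffold shorter than one window is used
whole, tails are dropped), aligns each window to genome B with blastn-like
local scoring (match 2, mismatch −3, gap 5 + 2k), and averages the
identities of windows passing identity > 0.30 **and** aligned-fraction
≥ 0.70. The coverage floor is what rejects unrelated sequences — random
DNA still produces short, high-scoring local alignments, but never
70 %-coverage ones. With no passing fragment the result is undefined
(`None`). This is a deliberate simplification of minimizer-based
production ANI tools; on mutated-pair benchmarks it tracks the expected
value (2 % mutation → ≈ 98.0) and is symmetric within 1 point.

## Phylogenetics (`phylo`)

Full maximum-likelihood tree search with model selection is replaced by
corrected-distance neighbor joining with nonparametric column bootstrap —
a documented stand-in that is dependency-free, fast at desk scale, and
sufficient for the monophyly and congruence logic; externally built ML
trees can be injected as newick.

- *Progressive alignment*: single-linkage guide tree on pairwise
  global-alignment distances (1 − identity); profiles merged leaf-to-root
  by profile-profile dynamic programming with expected-score columns
  (f₁ᵀ S f₂) and a linear gap penalty of −4 per column. Linear (not
  affine) gaps keep the profile DP exact and vectorizable; for two
  sequences the result scores identically to the optimal global alignment
  under the same penalties, which the tests verify against an independent
  aligner.
- *Trimming*: keep maximal runs of ≥ 5 columns whose modal residue
  frequency is ≥ 0.5, optionally discarding gap-containing columns first —
  a conserved-block filter in the spirit of the classic curation tools,
  with gap positions allowed inside blocks by default. Partition
  provenance (which gene a column came from) survives trimming and
  concatenation exactly.
- *Distances*: Kimura's protein correction *d = −ln(1 − p − 0.2p²)* over
  columns ungapped in both rows; pairs at p ≥ 0.85 (just below the
  formula's pole at p ≈ 0.8541) are set to a ceiling of 5.0 so NJ stays
  finite; a pair with no shared ungapped column is an error naming the
  pair.
- *NJ*: Saitou–Nei agglomeration; ties in the Q criterion break toward
  the pair whose smallest member labels sort first, negative branch
  lengths clamp to 0 with a log entry. On additive matrices the output
  tree reproduces the input distances exactly (tree-metric oracle in the
  tests, plus a cross-check against an independent NJ implementation).
- *Bootstrap*: resample columns with replacement, rebuild the NJ tree,
  support = fraction of replicates containing each original bipartition;
  replicates that destroy all shared columns for some pair are skipped and
  excluded from the denominator. Seeded.
- *Congruence*: restrict both trees to shared leaves, then greedily remove
  the leaf whose removal most reduces the Robinson–Foulds distance until
  it reaches 0; removed leaves are the putative horizontal-transfer
  candidates. Greedy pruning is this package's operationalization of a
  comparison usually done by eye; it is exact for single-leaf transfers
  (verified by constructed regrafts) and heuristic beyond that.

## Composition prediction (`composition`)

"Ordinate a distance matrix" is read as classical scaling (principal
coordinates): eigendecompose −½ J D² J, keep positive axes scaled by
√eigenvalue (negative eigenvalues are counted and dropped), fix signs so
each axis's first nonzero loading is positive. For Euclidean input the
embedding reproduces the distances to machine precision (tested at 1e−8).

Grouping uses alternating k-medoids in the first two principal
coordinates, k = 3 by default (the observed structure: one greigite and
two magnetite groups), with 10 seeded restarts keeping the lowest-cost
partition — a single random initialization can converge to a degenerate
split even on well-separated clusters. Whether the original grouping was
algorithmic is unknown; k-medoids is this package's choice, made for
determinism and robustness to outliers. Each group's label is the
majority composition label of its labeled members — never hard-coded;
ties label the group `unknown` with a warning, and a group without
labeled members leaves its queries `unassigned`. Ids are canonically
sorted internally so input order is irrelevant.

## Synthetic data (`synthetic`)

The generator emulates the features of real mining campaigns that the
pipeline's decisions depend on, with closed-form expectations for tests:

- **Substitution model**: uniform-frequency 20-state model (F81-type),
  rate-normalized so a branch of length *t* under rate *r* yields expected
  site identity 1/20 + (19/20)·e^(−(20/19)rt). Chosen over an empirical
  matrix precisely for this closed form; consequence: simulated proteins
  have uniform composition, which makes E-values slightly conservative
  relative to real proteins.
- **Reference database**: nine essential families evolved on per-family
  Yule trees (depth 1.0) at rates spanning 0.25 (mamK, the intended best
  marker) to 1.3 (mamI, the worst), realistic protein lengths (77–400 aa),
  leaves assigned to four named taxon groups with magnetite/greigite
  labels per group. Homologs per family are a *related* subfamily: one
  rejection-sampled decoy ancestor at the target identity (0.15 for mamK's
  distant actin-like decoys up to 0.45 for mamI's uncomfortably close
  ones), shallowly radiated. Making homologs mutually related matters:
  independent decoys violate four-point additivity (each is close to its
  source marker but maximally far from the other decoys) and scatter
  across the tree.
- **Planted operons**: default study = 20 scaffolds, 5 loci, each a
  consecutive nine-gene operon whose proteins are references mutated at
  exactly 35 % of positions (identity 0.65); ~6 random background genes
  per scaffold; 10 decoy genes on non-locus scaffolds. Decoy genes are
  rejection-sampled at 85 % divergence against the **joint** screen rule:
  at 70–78 % divergence a homolog can still legitimately pass a
  30 %-identity/10⁻⁵-E screen (that is what the screen is designed to
  detect), and short local alignments inflate identity at high divergence,
  so evasion is enforced on the rule itself, not on identity alone.
- **Quality tables**: exactly `quality_n_pass` genomes drawn in the
  passing region (completeness 50–99, contamination 0–9), the rest
  alternately failing on completeness (5–44) or contamination (11–25).
- **Composition scenario**: three clades (stems 0.6, within-clade depth
  0.06, 600 sites, rate 1) giving between-group distances several times
  the within-group spread without saturating; one greigite and two
  magnetite clades, two labeled references per clade.
- **Split-family scenario**: two marker clades each flanked by its own
  homolog subfamily, with divergences (stems 0.4/0.3, 600 sites) chosen to
  keep all pairs below distance saturation so NJ reconstruction is
  reliable across seeds.
- **Determinism**: all randomness flows from one root seed through named
  `SeedSequence` spawns in fixed order (reference db, scaffolds, quality,
  extras); regeneration with the same config is byte-identical.

What passing on this data does **not** show: robustness to fragmented gene
calls, frameshifts, contaminated bins, compositional bias, alignment
uncertainty in real homolog families, or assembly artifacts — the
generator plants clean gene calls and clean operons by design.

## Problem sizes

Default problem sizes (20 scaffolds, ~175 genes, 8 sequences per family,
600-site composition alignments, 100–1000 bootstrap replicates) were
chosen as the smallest at which every qualitative behavior of interest —
ranking, funnel, clade structure, three-group recovery — is stable across
seeds; the full suite and the acceptance script each run in a couple of
minutes on one CPU.

## Known limitations

- No heuristic seeding: alignment is full dynamic programming, suitable
  for desk-scale reference sets, not database-scale search.
- NJ + bootstrap is not an ML tree; branch supports are not comparable to
  ultrafast-bootstrap percentages, and deep, saturated divergences can
  distort topology (mitigated by the saturation ceiling).
- The greedy congruence report can over-prune when multiple overlapping
  transfers conflict.
- Fragment ANI is O(fragment × genome) dynamic programming — fine for the
  multi-kilobase synthetic genomes it is tested on, slow for real
  multi-megabase genomes.
- The e-value model ignores composition and edge effects; thresholds are
  calibrated to the conventions above, not to any specific search tool's
  output.
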