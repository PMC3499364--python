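# Methods

`duoproteome` reimplements, as a tested pipeline, a two-genome comparative
gene-repertoire analysis: orthologous-group (OG) construction from pairwise
protein similarity, identification of species-specific genes with a
data-derived identity threshold, rescue of genes whose homolog is present in
the partner genome but missing from its annotation, and the evidence lines
used to argue that the remaining species-specific genes are authentic. This
note records the model, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## Similarity search

Pairwise similarity uses optimal local alignment (Smith–Waterman with affine
gaps) over BLOSUM62, with gap costs `open + k·extend` for a length-`k` gap
(defaults 11/1, the standard gapped BLOSUM62 setting). `X` is treated as a
neutral residue scoring 0 against everything. Two implementations share one
scoring convention: a Numba-compiled Gotoh kernel computes exact optimal
scores for screening, and Biopython's `PairwiseAligner` produces the
traceback (columns, identities, gap openings, spans) for retained pairs; the
two agree exactly, and the test suite additionally checks the optimum
against an exhaustive search over the alignment space on short sequences.

E-values follow Karlin–Altschul statistics, `E = K·m·n·exp(−λS)`, with the
published gapped BLOSUM62/11/1 parameters λ = 0.267, K = 0.041 and the
subject proteome's total residue count as `n`. Gapped finite-size
corrections are ignored: only threshold crossings matter downstream, and the
thresholds are derived from the same statistic they gate.

The all-vs-all search prefilters pairs with a shared-k-mer index (k = 4,
at least 2 distinct shared k-mers). At the identity range the analysis
uses (orthologs at ≥ 60% identity share hundreds of 4-mers) the prefilter
loses nothing, which the suite verifies against exhaustive runs; an
`--exhaustive` flag disables it. One best hit per (query, subject) pair and
direction is kept (highest bitscore, ties by lower E then lexicographic id).

The protein-vs-genome search aligns queries against all maximal stop-free
six-frame translated segments (ORFs, minimum 30 aa) rather than performing
spliced alignment; the synthetic genomes are intron-free by construction, so
nothing is lost there. On real genomes with introns this is a conservative
divergence from a TBLASTN-style search and would understate rescue.

Hits are exchanged as 12-column BLAST tabular files with two optional
extension columns (query coverage as a fraction; signed subject frame).
Identity uses alignment columns as denominator (BLAST convention); coverage
uses the full query length — "fraction of the protein covered" is read as
query coverage because the query is the protein being classified.

## Ortholog groups

A hit enters the similarity graph when its percent match length (alignment
columns over the shorter sequence, the OrthoMCL `percentMatchCutoff`
semantics) is ≥ 50 and E ≤ 10⁻⁵ (`evalueExponentCutoff = −5`). Inter-species
edges are reciprocal best hits; intra-species edges join pairs whose
similarity exceeds each member's best inter-species similarity (the
in-paralog rule; genes with no inter-species hit qualify with any retained
intra-species partner). Edge weight is the mean of the two directions'
−log₁₀E, capped at 300 to keep E = 0 finite. OrthoMCL's species-wise
normalisation of in-paralog weights is deliberately omitted — a documented
simplification that does not change membership on the graphs this analysis
builds, only within-cluster weights.

The graph is clustered with Markov clustering (MCL), inflation 1.5
(OrthoMCL's default, exposed in config): add self-loops at each node's
maximum incident weight, column-normalise, then iterate expansion (matrix
square) and inflation (entrywise power, renormalise), pruning entries below
10⁻⁶, until the matrix changes by less than 10⁻⁸ (cap 200 iterations, with a
warning flag on non-convergence). The iteration runs per connected component
— the matrix is block-diagonal across components, so this is exact, and it
makes the clustering independent of node order. Clusters are read as
connected components of the converged support (entries above 10⁻⁴; attractor
mass is orders of magnitude larger, and the cutoff stops numerically
residual mass from linking separate attractor systems). Isolated nodes are
singletons.

OG categories: `shared` (genes from both compared species), `singleton`
(size 1), `single_species` otherwise; `conserved` means the same nonzero
gene count from both compared species. Multi-member clusters are counted as
OGs proper and singletons tallied separately, with both conventions in the
summary, because published OG counts from OrthoMCL-style pipelines exclude
singletons. A species' *presumptive species-specific pool* is its genes in
non-shared clusters.

## Species-specific genes

The significant-match identity floor is the 5th percentile (linear
interpolation between order statistics) of the percent identities of
one-to-one orthologs — OGs with exactly one gene from each compared species.
The identity of a 1:1 pair is the mean of the two directions' reported
identities (the directions are symmetric here; `a2b`/`b2a` modes exist for
asymmetric external hit tables). Threshold derivation refuses fewer than 20
values, where a percentile would be noise.

A genome hit is significant iff identity ≥ the derived floor, E ≤ 10⁻⁵,
alignment length ≥ 30 aa, and query coverage ≥ 0.5 — all comparisons
inclusive. A presumptive gene with ≥ 1 significant match in the partner
genome is *rescued* (annotation missing, not the gene); the rest are *final
species-specific*. Rescued + final = presumptive exactly, and per species
(genes in shared OGs) + (presumptive pool) = proteome size; the report
validates both identities before it is written. Overlapping genome hits are
not merged — only existence is used.

## Evidence lines

**Annotation quality.** AED (annotation edit distance) compares a gene
model against the union of its evidence intervals:
`AED = 1 − (SN + SP)/2` with SN = overlap/evidence bases and
SP = overlap/annotation bases; 0 is perfect congruence, 1 no overlap
(including the no-evidence case). Evidence intervals are unioned first so
stacked alignments are not double-counted. Intervals are 0-based half-open
internally (GFF-style 1-based inclusive only at I/O boundaries). Conserved-OG
genes and final species-specific genes are compared with a two-sample
Kolmogorov–Smirnov test; the p-value is asymptotic with effective
n = n₁n₂/(n₁+n₂) — group sizes in this analysis are hundreds, and
small-sample exactness of the D statistic is covered by an ECDF-sweep oracle
in the tests instead.

**Outgroup support.** An OG that lacks one ingroup species but contains the
outgroup indicates gene loss (or missing annotation) rather than a spurious
gene model. Counted over multi-member clusters: OGs with A genes and no B
genes, and how many of those also contain outgroup genes; mirrored for B.

**Functional matches.** Final species-specific genes with ≥ 1 match to
external annotated proteins at E ≤ 10⁻⁵ (existence test only, the
Blast2GO-style criterion). The four-part significant-match criteria can be
applied instead via an option; the E-only test is the default. In synthetic
runs the outgroup proteome stands in as the external protein database.

**GO enrichment.** Per GO term, a one-sided Fisher's exact test (upper
hypergeometric tail) for over-representation of the gene set among term
carriers, significant at p < α = 0.01 with no multiple-testing correction —
mirroring the fixed-significance-level procedure this analysis reports. A
Benjamini–Hochberg flag exists but defaults off. Terms carried only by
genes outside the universe are skipped with a warning.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions under which the pipeline is validated.

- **Ancestral gene set**: 600 random proteins over the 20-letter alphabet
  with Robinson–Robinson background frequencies; lengths lognormal with
  arithmetic mean 250 aa, sd 100 aa (a compact microalgal proteome),
  clamped to ≥ 30 aa.
- **Ortholog divergence**: the configured target is the *pair* identity
  distribution (truncated normal, mean 80, sd 8 — chosen so its lower tail
  gives a meaningful 5th percentile, the quantity the threshold derivation
  estimates). Each lineage independently mutates an exact count of sites
  (substitutions drawn from the background, never equal to the original
  residue), with per-lineage targets derived as
  m_l = 100·√(pair_mean/100) and sd_l = m_l·(pair_sd/pair_mean)/√2, so the
  product of the two ancestor identities reproduces the configured pair
  distribution. Realized identity bookkeeping is exact because indels are
  off by default (a flag enables geometric-length indels; with them the
  bookkeeping is approximate).
- **Losses and duplications**: per-gene loss probability 0.05 per lineage;
  duplication probability 0.05, modelled as *recent* duplication (the copy
  mutated from its evolved sibling at 96% identity) — the in-paralog rule
  captures post-speciation duplicates, and that is also what it means
  biologically.
- **Outgroup**: a third lineage from the same ancestor with pair identity
  ≈ 60% against either ingroup species, loss 0.05, no duplications.
- **Planted specific genes** (40 per side): fresh random sequences with no
  homolog anywhere. **Hidden genes** (30 per side): fresh sequences
  annotated in one proteome whose 95%-identity copy is planted only in the
  partner *genome*. Genes lost in the partner lineage are genuinely
  species-specific (present only in one species); together with planted
  specifics they form the ground-truth positive set for precision/recall,
  while hidden genes are expected to be rescued.
- **Genomes**: every annotated protein and every hidden gene back-translated
  with uniform synonymous codons (standard code) plus a stop, embedded on a
  random strand between 200-bp random spacers. Uniform codon choice is the
  simplest model preserving protein-level identity; translating every
  embedded CDS in frame recovers its protein exactly.
- **AED**: beta draws — shape (3.5, 6.5), mean 0.35, for conserved-side
  categories (shared orthologs, in-paralogs, hidden genes); shape
  (7.3, 2.7), mean 0.73, for operationally specific categories (planted
  specific and lost-in-partner) — reproducing the observed separation
  between conserved and species-specific annotation quality.
- **GO**: 200-term vocabulary, ~Poisson(3) background terms per gene; one
  designated term assigned to planted specific genes at odds 8 over a 0.2
  baseline (the baseline is set high enough that a set of 100 genes gives
  the enrichment test near-complete power, so the power calibration
  measures the test, not the generator's sparsity).
- One protein per gene throughout; for real data the intended convention is
  the longest protein per gene, avoiding double-counting in OGs.

Determinism: a single seed is fanned out to stage seeds via numpy
`SeedSequence` spawning; identical config + seed reproduces every output
byte for byte.

What the generator does *not* emulate: realistic codon usage, introns and
gene structure, rate heterogeneity across sites and genes, domain-level
homology (shared domains between otherwise unrelated genes), genome
rearrangement, and alignment-tool idiosyncrasies. Passing tests therefore
show the pipeline's logic is correct under its stated assumptions, not that
any particular biological dataset would yield particular counts.

## Numerical and degenerate-input choices

- Truncated-normal draws by rejection on (0, 100]; a mean ≤ 0 is a
  configuration error.
- Reciprocal-best ties broken by bitscore, then lower E, then lexicographic
  subject id — determinism under renaming is tested by shuffling inputs.
- −log₁₀E capped at 300; weights are finite and positive by construction.
- `derive_threshold` errors below 20 values; `one_to_one_identities` raises
  a hard error if a 1:1 OG has no stored hit (graph and hit table
  inconsistent — never a silent skip).
- Empty annotation intervals are an error for AED; empty evidence gives
  AED = 1. Empty AED groups or proteomes are errors, not empty outputs.
- KS on identical samples returns D = 0, p = 1; disjoint supports D = 1.
- Genes present in a match table but absent from the presumptive pool are
  ignored with a warning (stale tables), never added to the pool.

## Problem sizes used in validation

The validation suite runs the generator's default conditions (600 ancestral
genes, ~660 annotated genes per species) end to end twice for the
determinism check, a reduced configuration (80 ancestral genes) for
unit-level checks, 200-trial oracle comparisons for the aligner and MCL,
and 100-run calibrations for the enrichment test. These sizes give the
statistical checks comfortable resolution (binomial noise well inside every
asserted band) while keeping a full validation run in minutes on one core.

## Known limitations

- Karlin–Altschul parameters are fixed for BLOSUM62/11/1; other matrices or
  gap costs require supplying λ and K.
- The in-paralog rule without species-wise weight normalisation can, on
  real data with large paralog families, weight clusters differently from
  OrthoMCL; membership effects were not observed on synthetic data.
- Six-frame ORF search cannot rescue genes split across introns or
  frameshifts; on real genomes the rescued counts are a lower bound.
- The enrichment test deliberately applies no multiple-testing correction
  by default (the procedure it mirrors reports a fixed significance level);
  use the BH flag for exploratory scans over large vocabularies.
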