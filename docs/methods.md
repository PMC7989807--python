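# Methods

## The two processing strategies

Both pipelines start from demultiplexed paired-end FASTQ (Phred+33; a
heuristic rejects Phred+64-looking input rather than mis-decoding it) and
apply the same per-read quality control, in this order:

1. **3′ quality trimming** at Phred threshold `trim_q = 15`, using the
   BWA/cutadapt partial-sum rule: subtract the threshold from each quality,
   accumulate running sums from the 3′ end, and cut at the position
   minimising the running sum (ties keep the longer read). This never
   lengthens a read and may empty it.
2. **Truncation and length selection.** Assembly mode rejects pairs with a
   mate shorter than `trunc_len = 229` and cuts both mates to exactly that
   length; gap mode does the same with `min_len = 200`. Gap-mode mates are
   *truncated* to the minimum length rather than merely length-filtered:
   dereplication at 100 % identity is meaningless over ragged lengths, and
   fixed-length mates put the gap junction at one fixed coordinate.
3. **Expected-error and N filtering** on the truncated mates:
   EE = Σ 10^(−Q/10) per mate; a mate with EE > `max_ee = 2.0` or more than
   `max_n = 0` ambiguous bases rejects the pair. The comparison is strict
   (EE exactly 2.0 is kept), matching the documented semantics of the
   expected-error filters this step mirrors. Rejection reasons are
   enumerated (`too_short`, `max_ee`, `max_n`) and counted per stage.

**Assembly joining** scores every ungapped overlap between the forward
mate's 3′ end and the reverse-complemented reverse mate's 5′ end, for
overlap lengths from `min_overlap = 10` up to the shorter mate (staggered,
read-through layouts are excluded by construction since upstream truncation
makes mates shorter than the amplicon). The score is matches − mismatches;
the best-scoring overlap with fractional identity ≥ 0.9 wins, ties going to
the longer overlap. A full maximum-likelihood merger with a statistical
test was not reproduced: at an engineered 10-base overlap the simple score
is the decisive quantity, and both knobs are exposed. Within the overlap a
mismatch takes the base with the higher Phred (keeping that quality, the
forward mate winning exact ties) and a match keeps the higher quality.
Merged amplicons ≥ 448 nt are cut to exactly 448 from the 5′ end; shorter
ones are rejected. With 229-nt mates this leaves exactly
2×229 − 448 = 10 bases of overlap.

**Gap joining** concatenates the forward mate with the reverse-complemented
reverse mate directly — no placeholder characters, which would corrupt
identity computation against ungapped references — and records the junction
(index of the first reverse-contributed base, 200 under defaults, product
length 400). Downstream code treats the junction as metadata.

## Dereplication and denoising

Dereplication is exact-string grouping with abundance (`;size=N` FASTA
annotations for interoperability with abundance-aware downstream tools),
sorted by size descending with lexicographic tie-breaks so output order is
deterministic. The stop-codon filter translates assembly products from the
database's frame offset and discards any unique containing TAA/TAG/TGA
(standard code; the table is configurable). Gap products translate the
forward segment `[frame_offset, junction)` and the reverse segment
`[junction + rev_frame_offset, end)` independently — codons spanning the
junction do not exist by construction — with trailing partial codons
ignored and N-containing codons skipped (neither stop nor non-stop). The
reverse phase is a property of the reference database and truncation
lengths: for a 448-bp amplicon with 200-nt segments the reverse segment
starts at template position 248, so `rev_frame_offset = 1`.

Full error-cloud read correction is deliberately **not** implemented; the
denoising stage provides exactly the two behaviours the pipelines need
from it: chimera removal and singleton removal. A unique is chimeric iff
two earlier uniques, each at least `skew = 2.0` times its abundance (the
standard assumption that chimeras arise after their parents), can be
spliced at some breakpoint to match it within `max_diffs = 0` mismatches,
both parent orders tried, equal lengths only. A candidate already explained
by a *single* earlier unique within `max_diffs` is never chimeric — the
two-parent model must be genuinely needed; without this guard a pair of
parents sharing a suffix would trivially "explain" a sequence identical to
one of them. Singletons (size 1) are then dropped. Abundance is conserved
at every stage except explicit removals, and a run record verifies that
stage counts telescope.

## Cluster assignment

Databases here hold tens to hundreds of references, so assignment is an
exhaustive best-hit search with exact global alignment rather than a
seeded heuristic — exactness beats speed and results are reproducible
bit-for-bit. Scoring is match +1, mismatch −1, gap open −2, gap extend −1
(a k-column gap costs 2 + (k−1)). Identity is match columns over alignment
columns; because several alignments can share the optimal score, the
dynamic programme optimises the lexicographic objective
(score, matches, −columns), packed into one int64 per cell, making the
reported identity a deterministic function of the inputs with no traceback.
Gapped queries are compared junction-aware: each segment is aligned
semi-globally with the reference's end gaps free, and free end-gap columns
are excluded from the identity denominator (identity definitions differ
between tools, so this one is stated explicitly). Ties between references
at equal identity go to the first in database order. Below-threshold
sequences land in a reserved `unassigned` bucket, excluded by default from
relative-abundance rows in the ecology layer. Identities are computed once
and reused across thresholds, which also enforces monotonicity: raising
the threshold only moves abundance into `unassigned`.

## Comparison statistics

Method comparisons run on relative abundances so depth differences cannot
dominate. Bray–Curtis is reported as a **dissimilarity** (0 = identical
communities) even where the field's prose says "similarity"; Pearson is
the plain product-moment correlation of relative-abundance rows, undefined
(reported missing) for zero-variance rows. Rarefied richness uses
Hurlbert's analytic expectation with log-gamma evaluation; a Monte-Carlo
subsampling oracle confirms it within 3 standard errors at 10,000
replicates in the tests. Heatmap export bins relative abundances at 12.5 %
intervals.

## CCA and permutation tests

`cca_fit` implements ter Braak's algorithm: with P = Y/total, row weights
r and column weights c, the standardised matrix is
Q = (P − r cᵀ)/√(r cᵀ); the predictors are weighted-centred, the row
space of Q is projected onto them under row weights, and the SVD of the
fitted matrix gives eigenvalues (squared singular values), constrained
inertia (their sum) and pseudo-F =
(constrained/q) / (residual/(n−q−1)) with q the constraint rank (aliased
columns are dropped with a warning). On a frozen 6×4 fixture the
eigenvalues agree with R's vegan::cca to ≥ 6 decimals.

Permutation tests are **marginal** — one factor at a time, matching a
one-row-per-factor significance table — with 999 permutations by default,
so the attainable p floor is 0.001; p = (1 + #{F\* ≥ F}) / (1 + nperm).
Categorical factors are dummy-coded with a first-level reference and
permute as a block. Samples are sorted by id before permuting, so p-values
are bit-reproducible under input reordering given (seed, nperm). Both the
marginal scheme and the permutation count are configurable defaults, not
facts about any particular dataset.

## Tree comparison

The "Euclidean distance between two trees" is the Kuhner–Felsenstein
branch-score metric: every branch (pendant branches included) is keyed by
the leaf bipartition it induces, trees are compared unrooted (rooting
differences collapse because complementary sides share a canonical key and
degree-2 root edges merge by summation), branch lengths absent from one
tree count as 0, and the distance is the root of the summed squared
differences. Trees with unequal leaf sets are pruned to the intersection
with a warning; fewer than 4 shared leaves is an error. Congruence between
two marker-gene classifications is tabulated as per-lineage purity (the
fraction of strains in the modal partner-gene cluster) with a
strain-weighted overall mean.

## Simulator

The generator defines the study conditions and provides ground truth for
every stage. A stop-free root coding sequence is drawn codon-wise from the
61 non-stop codons; cluster ancestors apply `between_cluster_div`
substitutions per site (third codon positions 3× more likely, a crude
synonymous bias) and leaves apply `within_cluster_div`, resampling up to
100 times to preserve frame-0 stop-freedom. An optional `mutable_region`
confines all substitutions to a template window so tests can place
cluster-diagnostic sites inside or outside the gap pipeline's unsequenced
region. Communities follow a Gaussian niche model on a simulated soil pH
gradient (default span 3.5–8.5, matching the range of soils such surveys
cover): cluster log-abundance = −gradient_strength × (pH − optimum)² plus
lognormal noise, optima evenly spaced. Reads carry linearly decaying mean
Phred (38→28 forward, 38→22 reverse, s.d. 2) with substitution errors at
the per-base rate 10^(−Q/10); chimeras are spliced from two abundance-drawn
templates at a uniform breakpoint before reading, redrawing until the
splice is a genuine chimera so `chimera_rate` is the realised chimeric
fraction. The error model is substitution-only by default (indels
available by flag to exercise frameshift sensitivity); `error_free()`
produces flat-Q40 reads with zero substitutions, since even Q40 implies
10⁻⁴ errors and would break exact template-recovery checks at depth 10⁴.
All randomness flows from one seeded generator; reruns are byte-identical.

What the simulator does **not** emulate: PCR primer artefacts and bias,
platform-specific error motifs, quality-model training on real runs, indel
error profiles (off by default), and length variation among templates.
Passing tests therefore demonstrate algorithmic correctness under the
stated error model, not robustness to every artefact of real sequencing
runs.

## Problem sizes and numerical choices

Default test/verification sizes were chosen as the smallest that exercise
the claims crisply: exact template recovery uses 5 templates at depth
10,000; the gap-information contrast uses 4 clusters × 3 samples at depth
1,500 with divergence 0.02 confined to a 48-bp window; null calibration
uses 1,000 replicates of a 12-sample × 5-cluster community with 199
permutations each. Alignment packs (score, matches, −columns) into int64
with weights 2²⁵/2¹³/1, valid for sequences whose combined length is below
4,096. Rank decisions in CCA use a relative SVD tolerance of 1e-10;
eigenvalue sums match constrained inertia to 1e-10. Degenerate inputs are
errors, not silent results: empty rows/columns in CCA, alignment of empty
sequences, oversampling in rarefaction, all-zero abundance vectors in
Bray–Curtis.
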