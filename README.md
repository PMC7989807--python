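# gapkit

A toolkit for processing Illumina paired-end amplicon sequencing of
functional genes of **any amplicon size** — including genes longer than two
read lengths — together with the downstream community statistics needed to
compare processing strategies and to analyse environmental niche
specialisation.

Short-read platforms produce 2 × 300-bp read pairs. For an amplicon such as
the 448-bp bacterial *amoA* fragment (the marker gene of ammonia-oxidising
bacteria), quality-truncated mates still overlap and can be merged into the
full amplicon (the **assembly** strategy). For longer amplicons such as the
629-bp archaeal *amoA* fragment the mates never meet; the toolkit instead
reverse-complements the reverse mate and concatenates it to the forward
mate, leaving an unsequenced central **gap** whose junction coordinate is
carried as metadata (the **gap** strategy). Both routes then share the same
downstream steps: dereplication at 100 % identity with abundance tracking,
frame-aware stop-codon filtering (gap products translate each segment in
its own frame so no codon spans the junction), two-parent chimera removal
and singleton removal.

The analysis layers are:

- **Cluster assignment** — exhaustive best-hit global alignment
  (Needleman–Wunsch, match +1 / mismatch −1 / gap open −2 / extend −1)
  of each unique sequence against a cluster-labelled reference database,
  with identity = match columns / alignment columns, thresholded at
  0.9 / 0.95 / 0.97 / 1.0; gapped queries are aligned junction-aware with
  free reference end gaps.
- **Community comparison** — per-sample Bray–Curtis dissimilarity
  (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on relative abundances) and Pearson correlation
  against a designated reference method, plus Hurlbert's analytic rarefied
  richness E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)].
- **Niche analysis** — canonical correspondence analysis (ter Braak's
  chi-square standardisation, weighted least squares, SVD) with marginal
  permutation tests per environmental factor (pseudo-F statistic,
  p = (1 + #{F\* ≥ F}) / (1 + nperm)).
- **Tree comparison** — the Kuhner–Felsenstein branch-score (Euclidean)
  distance between Newick trees, and congruence tabulation between two
  marker-gene classifications (e.g. *amoA* vs 16S rRNA lineages of
  *Nitrosospira* strains; the packaged 56-strain table delineates 17 *amoA*
  and 19 16S lineages).
- **Simulation** — a generator producing reference gene families,
  pH-structured communities (Gaussian niche model) and paired reads with
  quality decay, substitution errors and chimeras, with full ground truth
  for every stage.

## Worked example

```python
import numpy as np
from gapkit.simulate import preset, simulate_references, simulate_community, simulate_reads
from gapkit.pipeline import process_sample, PipelineOptions
from gapkit.cluster_assign import build_matrices
from gapkit.community_stats import compare_methods
from gapkit.niche_cca import permutation_test

cfg = preset("bacterial448", n_samples=4, depth=2000, seed=42)
rng = np.random.default_rng(cfg.seed)
refdb = simulate_references(cfg, rng)
community, env = simulate_community(refdb, cfg, rng)
samples = simulate_reads(community, refdb, cfg, rng)

opts = PipelineOptions(rev_frame_offset=refdb.rev_frame_offset)
assembly, gapped = {}, {}
for s in samples:
    assembly[s.sample_id], rec = process_sample(s.reads, "assembly")
    gapped[s.sample_id], _ = process_sample(s.reads, "gap", opts)
print("assembly S1:", len(assembly["S1"]), "uniques,",
      sum(u.size for u in assembly["S1"]), "reads kept of", cfg.depth)

m_asm = build_matrices(assembly, refdb, [0.97])[0.97]
m_gap = build_matrices(gapped, refdb, [0.97])[0.97]
report = compare_methods(m_asm, m_gap, "assembly", "gap")
print(report.table.round(3))

res = permutation_test(m_asm.relative(), env["pH"], n_perm=999, seed=1)
print(f"pH: F = {res.F_observed:.2f}, p = {res.p_value:.3f}")
```

prints

```
assembly S1: 30 uniques, 1460 reads kept of 2000
    pearson_r  bray_curtis
S1        1.0        0.005
S2        1.0        0.003
S3        1.0        0.003
S4        1.0        0.002
pH: F = 3.74, p = 0.039
```

With realistic sequencing error about a quarter of read pairs are lost to
the expected-error filter and merge gate (1460 of 2000 kept); the two
strategies nevertheless agree almost perfectly on community composition
(Bray–Curtis ≤ 0.005, Pearson 1.0) because this simulation places cluster
differences throughout the amplicon, and the pH gradient built into the
community is recovered as a significant CCA factor.

The same flows are available from the shell:

```bash
gapkit simulate --preset bacterial448 --samples 7 --depth 5000 --seed 42 --out sim/
gapkit run --mode assembly --manifest sim/manifest.tsv --out run/
gapkit assign --db sim/refs.fasta --uniques run/ --id 0.9,0.95,0.97,1.0 --out matrices/
gapkit cca --env sim/env.tsv --matrix matrices/counts_id0.97.tsv --nperm 999 --seed 1
gapkit congruence            # packaged 56-strain lineage table
gapkit treedist a.nwk b.nwk
```

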