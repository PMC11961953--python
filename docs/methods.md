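# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `lavapipe`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Repeat-track construction

RepeatMasker `.out` files are parsed with header auto-detection (rows not
starting with a numeric score are treated as header), genomic coordinates
converted from 1-based inclusive to 0-based half-open, and complement ('C')
rows normalised at parse time: strand becomes '−' and the consensus columns
— stored as `(repLeft) repEnd repStart` for complement hits — are reordered
so `repStart ≤ repEnd` always holds. Filters therefore never see
orientation-dependent fields. Full-length selection keeps copies with
`repStart < max_rep_start` (default 100) and `repEnd > min_rep_end`
(default 1200), both strict, against the family's ~1,300 bp consensus; a
copy exactly at a boundary is dropped. Track integration treats overlap as
≥ 1 shared genomic base, strand-agnostic — the strictest reading of
"overlapping" — and only *selected* copies trigger discard of base
annotations; fragmented copies that fail the filter are neither added nor
allowed to evict anything.

## Counting rules

* **Deduplication** keys on (sample, chrom, start, end, strand, mate) and
  keeps the first record. Including `end` and `mate` in the key is the
  conservative reading of BED-level PCR-duplicate removal.
* **Gene counting** uses mate-1 records only. A record overlapping ≥ 1 bp of
  any exon of a gene increments that gene exactly once however many of its
  exons it touches (per-gene exon union); a record spanning exons of k
  distinct genes increments each of the k genes — no ambiguity rule is
  imposed, keeping the result independent of gene order.
* **TE counting** infers each record's transcript orientation from its mate
  number, alignment strand, and the library's strandedness. The default is
  `reverse` (dUTP-type directional kits: mate 1 aligns opposite to the
  transcript). A record counts toward a family only when an overlapping copy
  of that family lies on the inferred orientation's strand; among multiple
  overlapping families, the largest summed overlap wins, ties broken by
  lexicographic family name. Both mates are counted for TEs by default
  (configurable) — the mate-1 restriction is documented only for genes.
* **Multimapper resolution** picks one candidate placement uniformly at
  random from each read's recorded candidate list, driven by a single seeded
  generator in input-row order, so results are reproducible and
  order-defined.
* **TPM** uses exon-union gene lengths; non-degenerate columns sum to 1e6 by
  construction. **RPM** divides by total genome-mapped reads (post-dedup by
  default, configurable), not column sums, since TE counting covers only a
  subset of the genome.

## Differential expression

The DE stack is the classic count pipeline, authored here:

* **TMM factors.** Per-gene M (log2 ratio) and A (mean log2 abundance)
  values versus a reference sample (automatic choice: upper-quartile count
  fraction closest to the mean upper quartile), with genes zero in either
  sample removed. The trim is rank-based and two-sided — 30% from each M
  tail and 5% from each A tail — and the surviving M values are averaged
  with inverse delta-method-variance weights; factors are rescaled to
  geometric mean 1. One test cross-checks the factors against the
  Bioconductor reference implementation via Rscript when available.
* **Common dispersion.** One φ shared across genes, maximising the
  conditional (on each gene's within-group total) NB log-likelihood, which
  for n samples with common mean is the Dirichlet-multinomial law with
  parameters r = 1/φ. The optimum is located on a 25-point log-spaced grid
  over [1e-4, 4] and refined by bounded scalar minimisation between the
  neighbouring grid points; if the optimum sits at the lower bound and the
  Poisson (multinomial) limit fits at least as well, φ = 0 is returned.
  No tagwise shrinkage is attempted — a single dispersion is the smallest
  faithful model for the planted-truth simulations this package targets.
* **Exact test.** Samples are first pseudo-scaled to the geometric mean of
  their TMM-adjusted effective library sizes; the scaled group sums are
  rounded to the nearest integer (the conditional enumeration requires
  integers; at the count depths involved the rounding perturbs totals by
  < 1 part in 10³). Conditioning on t = a + b, the split follows a
  beta-binomial law with sizes n_A/φ and n_B/φ, binomial at φ = 0. The
  two-sided p-value sums probabilities of all outcomes no more likely than
  the observed one, with a 1e-12 log-probability tolerance so exactly
  symmetric outcomes are always included (making a = b yield p = 1
  regardless of rounding noise). The enumeration is vectorised over the
  t + 1 outcomes; total work across genes is proportional to total counts.
* **log2FC** is log2((mean CPM_A + 0.5)/(mean CPM_B + 0.5)) with
  TMM-adjusted CPM; the 0.5 pseudo-count avoids infinities at zero counts.
* **Calls**: up if FDR < 0.05 and log2FC > 1; down if FDR < 0.05 and
  log2FC < −1; both inequalities strict. BH adjustment is delegated to
  statsmodels behind the `bh_fdr` surface.

Numeric parity with any particular release of external DE packages is not a
goal; the algorithms are the published ones.

## Cross-species harmonization

Order of operations: ortholog intersection → per-individual merging →
outlier-sample removal → batch-gene filtering → contrasts. Ortholog
intersection keeps features transferred to every listed genome, optionally
protein-coding only. Merging sums counts and library sizes per individual;
a merged individual's study label is the set of contributing BioProjects.
Outlier detection computes 1 − Pearson correlation of log2(x+1) sample
profiles, clusters with complete linkage, cuts the dendrogram at height 0.8,
and flags everything outside the largest cluster (a tie for largest flags
nothing, with a warning). Batch-gene filtering runs the DE pipeline for
every unordered BioProject pair — restricted to samples of shared species
when the pair shares species, whole projects otherwise; individuals merged
across several projects are excluded from these contrasts — and removes the
union of genes at FDR < 0.05 with no fold-change threshold. Clade-specific
DE contrasts one clade against all remaining samples with the standard
thresholds. "Between each BioProject" admits several designs
(pairwise vs one-vs-rest, within-species vs pooled); the pairwise
shared-species design was chosen because it cannot mistake species
composition differences for batch effects.

## PCA signatures

Expression is log2(x+1)-transformed by default (configurable; clustering
and PCA on raw TPM are also supported) and feature-centered; components come
from the SVD of the sample-by-feature matrix. Scores are U·S, loadings the
orthonormal right singular vectors. A deterministic sign convention — the
largest-magnitude entry of each loading column is made positive — keeps
ranked lists reproducible across linear-algebra backends. Top-loading
extraction supports signed_top, signed_bottom, and absolute modes with
lexicographic tie-breaks; the signature union counts each feature once and
reports the cross-list overlap (Σ list lengths − |union|).

## The simulator

The simulator emulates the statistical structure the analysis assumes, with
full ground truth:

* **Toy genome**: genes of 1–3 exons (exons 200–400 bp, introns 100–300 bp),
  background repeat copies, and target-family TE copies placed
  non-overlapping along 2 chromosomes of 150 kb (all configurable). Exactly
  `round(full_length_fraction × n)` target copies receive consensus
  coordinates passing the full-length filter; the rest violate at least one
  criterion.
* **Alignments**: paired-end coordinate records (no sequences, qualities, or
  error model) with 100 bp reads on 120–300 bp fragments drawn inside
  feature intervals, allocated to features proportionally to log-normal
  intensities with a configurable TE expression share. Strand layout
  follows the configured library type. PCR duplicates are planted as
  identical-placement copies at rate `dup_rate`; multimappers at rate
  `multimap_rate` carry 2–4 candidate placements (the true one plus random
  decoys). Distinct fragments never collide on a placement key — the
  generator resamples colliding coordinates and caps each feature's
  per-sample allocation at half its distinct-start capacity — so
  deduplication removes planted duplicates and nothing else, and the truth
  counters are exact post-dedup expectations. A configurable fraction of TE
  fragments is transcribed antisense to exercise the sense filter.
* **Count matrix**: genes × samples with per-gene log-normal baselines
  (meanlog 4, sdlog 1 — a realistic bulk RNA-seq dynamic range), library
  factors from libraries drawn uniformly on `lib_size_range`, planted
  clade genes at ±`clade_lfc` (alternating directions) in the target clade,
  planted batch genes at `batch_lfc` in the first BioProject, and NB noise
  with dispersion φ (`Var = μ + φμ²`, Poisson at φ = 0). Clade and batch
  gene sets are disjoint by construction. Defaults describe a small but
  study-shaped design: six species in four clades, four individuals per
  species, two BioProjects assigned round-robin within species (so every
  study carries every clade and batch effects are orthogonal to clade),
  φ = 0.1, ~1e6-read libraries, 2,000 genes with 50 clade and 50 batch
  genes at |log2FC| = 2.
* **Ortholog map**: one genome per species; a 5% random fraction of
  unplanted genes fails transfer to one genome, 90% of unplanted genes are
  protein-coding; planted genes always transfer and are coding, so
  harmonization cannot silently discard the truth the recovery metrics
  score.

What passing tests on these simulations do **not** show: robustness to
species-tree covariance beyond clade labels, GC/length biases, spliced or
soft-clipped alignments, incomplete deduplication of near-identical
placements, or dispersion heterogeneity across genes. Those effects are
absent from the generator by design.

## Problem sizes and seeds

The test suite and acceptance script run everything at desk scale: 2,000
genes for calibration and recovery checks, ~20–30 k alignment records for
counting oracles, exhaustive exact-test enumeration for totals ≤ 50, and a
600-gene pipeline for the determinism check. All randomness flows from
explicit seeds (NumPy `SeedSequence`-derived streams per stage), and the
pipeline manifest records no timestamps, so identical configurations
reproduce byte-identical outputs.

## Known limitations

* The exact test's integer rounding of pseudo-counts makes p-values at very
  low totals (t < ~20) mildly discrete; calibration checks run at realistic
  depths.
* Batch filtering with individuals merged across BioProjects excludes those
  individuals from the batch contrasts rather than modelling the mixture.
* `detect_outliers` assumes the majority cluster is the biology of interest;
  with fewer than three samples it refuses to run rather than guess.
* The CLI's `simulate` stage regenerates data from config and seed; it does
  not ingest real BAM/FASTQ (alignments are consumed as coordinate tables;
  a SAM/BAM adapter would be a thin addition via pysam but is out of scope).
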