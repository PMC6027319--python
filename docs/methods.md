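# Methods

`bchrom` detects and characterizes transposable elements (TEs) amplified on a
supernumerary (B) chromosome from short-read data, and ships a synthetic-data
generator that reproduces the study design end to end with known ground
truth. This note records the models, the defaults and why, the numerical
choices, and what passing tests do and do not demonstrate.

## The detection model: coverage ratios

A B chromosome is built largely from sequences homologous to the standard
chromosome set (the A complement). When a B-carrying individual is sequenced
and its reads are aligned to a B-free reference assembly, reads originating
from B-amplified copies have nowhere to go but their homologous A-complement
loci. The per-locus mean depth of a B+ sample therefore rises above the 0B
reference in proportion to the number of B copies homing to that locus.

For locus *i* and sample *s* the statistic is

    r_is = (d_is / d_ir) * (h_r / h_s)

where `d` is mean depth over the annotated interval, `r` the designated 0B
reference sample, and `h` the mean depth over a single-copy anchor gene
(HPRT). The HPRT factor cancels library-size differences: multiplying every
depth of a sample by a constant leaves `r_is` unchanged (property-tested).

* **Qualification threshold tau = 2** ("at least duplicated", inclusive).
  Loci with `r >= 2` carry at least one extra homologous copy; the
  conservative threshold controls false positives from depth noise.
* **Extra copies per element** = sum of `(r - 1)` over qualifying loci.
  Under the homing model the expectation for a locus receiving `k` chrB
  copies in a sample with `b` B chromosomes is `r = 1 + b*k/2` (diploid
  A complement, each B adding half a haplotype's depth), so the per-element
  sum estimates `b/2 * c_B`, the extra copy count. Summing `r` instead of
  `r - 1` is available (`sum_mode="ratio"`) because the published tables do
  not state the convention; only the `r - 1` reading yields 0.00 for a
  non-carrier, which is why it is the default.
* **Low-coverage filter**: loci whose *reference* depth is below 0.25 x the
  reference HPRT depth are excluded before ratios are formed, preventing
  ratio blow-ups at near-zero denominators. The 0.25 fraction is a package
  choice; the filter applies to loci, not samples.
* **Depth counting**: primary mapped alignments only, any MAPQ by default
  (repeat loci legitimately attract MAPQ-0 reads); CIGAR-aware (deletions
  cover the reference, insertions/soft-clips do not). Simple repeats and
  low-complexity annotations are excluded from the TE set.

## The synthetic study

The generator emulates the study conditions the analyses target:

* **A complement**: one contig, 300 kb random background (GC 0.42) carrying
  six TE families — TcMar-Tc1, hAT-Ac, L2, Gypsy, Pao (Bel/Pao), and a
  satellite — inserted in three divergence waves (means 5, 15, 25%, sd 1%),
  ~540 kb total. A unique single-copy HPRT anchor is inserted with its own
  truth interval. Copies are spaced by at least a read length plus 50 bp so
  no read spans two copies and truth intervals never abut.
* **B haplotype**: a `chrB` contig carrying 400 fresh Gypsy copies and 200
  hAT copies (2% divergence, matching recent amplification) interleaved with
  30% non-repetitive background (the B's non-repeat fraction is unknown in
  real taxa; 30% is a knob with no claim of realism). Every chrB copy is
  assigned a homologous A locus of the same element uniformly at random —
  the least-assumption model of where a real aligner would pile its reads.
* **Samples**: a 0B reference (M1-0B), a second 0B female, a 1B and a 2B
  male, sequenced single-end at 20x (diploid A-complement depth), 100 bp
  reads, 0.5% base error. chrB is sampled at `depth * b/2`. chrB reads
  overlapping a copy by >= 20 bp are emitted as alignments on the homolog
  with overhangs soft-clipped; chrB background reads are unmapped.
* **HPRT anchor length**: the demo uses a 4 kb anchor. The anchor's
  mean-depth estimate carries relative noise ~ sqrt(D*L_read/L)/D, which at
  1 kb and 20x is ~7% and propagates multiplicatively into every ratio; at
  4 kb it is ~3.5%, keeping the normalization scale tight relative to the
  +/-15% recovery bands. Standalone `SimulationConfig` defaults keep a 1 kb
  anchor.
* **Divergence model**: `mutate_sequence` samples each site's end state from
  the exact Kimura two-parameter (K2P) transition probabilities at the
  requested distance `d` with transition:transversion rate ratio kappa
  (default 2), so multiple hits are included and the downstream K2P
  estimator is consistent for `d` — the mean estimate over copies recovers
  the configured distance (tested to +/-0.02 up to d = 0.3). Indels are
  optional (rate 0 by default) and are the reason alignment, not naive
  pairing, is used for real data.

Features of real data the generator does **not** model: GC bias, PCR
duplicates, paired-end inserts, platform error profiles, nested/fragmented
insertions, mappability structure, and real aligner behavior (mapping is by
construction). Passing recovery tests therefore shows the *statistics* are
correct under the stated homing model, not that any aligner realizes that
model on a given genome.

## Repeat landscape

Each annotated copy (minus-strand copies reverse-complemented) is globally
aligned to its family consensus (match +1, mismatch -1, gap open -5, extend
-1 — constants fixed here because stored alignments are not available for
synthetic copies). Transition fraction `p` and transversion fraction `q` per
ungapped, non-N column give

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

Copies outside the formula's domain are reported saturated (K capped at
0.50, flagged) and excluded from the landscape and burst calls. Each copy
contributes its interval length to the 1%-wide bin `floor(100K)` of its
family; the matrix is emitted both as bp and as % of genome since published
landscapes use either scale. Burst detection smooths the per-bin totals with
a 3-bin moving average and reports local maxima with prominence >= 10% of
the smoothed maximum — explicit constants standing in for the visual peak
reading used with real genomes. A wave centered on a bin edge (e.g. 5%)
legitimately peaks in either adjacent bin. CpG-adjusted counting (a
transition at a consensus CpG counts 1/10) is available but off by default.

## Comparative read clustering

Equal-sized read samples (without replacement) from a 0B and a 2B individual
are clustered: candidate pairs share an exact canonical 17-mer (k chosen so
random 100 bp reads rarely collide at desk scale), and an edge requires a
best local alignment at >= 90% identity over >= 55% of the shorter read
(the conventional comparative-clustering similarity defaults), reverse
complements included. Clusters are connected components — a deterministic
simplification of hierarchical/community clustering used at genome scale;
singletons are counted separately. Per-cluster enrichment

    E = ((n_2B + psi)/N_2B) / ((n_0B + psi)/N_0B),  psi = 1

estimates relative genomic abundance; candidate B clusters require size >=
50 and E >= 3 (thresholds standing in for manual inspection). Cluster
annotation takes the library element with the best cumulative local
alignment score, ignoring read alignments scoring below 0.25 x read length
(so random background clusters return "Unknown"); ties go to the first
element lexicographically and are flagged.

For the amplified family, E tracks `(c_A + c_B)/c_A` only when the B
haplotype is a small fraction of the sequenced genome — otherwise chrB
inflates the 2B read pool and shrinks every cluster's 2B share by
`G_A/(G_A + G_B*b/2)`. That condition holds in real taxa (a B is a tiny
genome fraction) but not in the compact coverage demo, so the clustering
scenario uses its own configuration (40 A copies, 80 chrB copies, chrB
~10% of the A length) where the nominal expectation is valid within the
test's +/-30% band.

## TE expression

Counting assigns a read overlapping exactly one element's intervals to that
element and splits a read overlapping k elements as 1/k (a transparent
alternative to pseudogenome counting; `unique-only` is available). RPKM =
`count * 1e9 / (library_size * element_bp)`. Differential expression uses a
negative-binomial Wald test: median-of-ratios size factors, one common
method-of-moments dispersion pooled across elements (means > 1 only,
floored at 0), `log2FC = log2((mu_B+ + 0.5)/(mu_B- + 0.5))`, delta-method
variance `(1/mu + phi)/n` per group, two-sided normal p, Benjamini-Hochberg
FDR. Calls: up if `log2FC >= 1.2` and `FDR < 0.05`; down if `log2FC <=
-1.2` and `FDR < 0.05`; else ns — the fold-change rule is applied
symmetrically since published tables contain negative fold changes. This is
a deliberate, documented simplification of GLM machinery: validation is
parameter recovery on simulated truth (type-I control under the null,
detection of fold-4 spikes at n = 6, mu = 200, phi = 0.1), not concordance
with any specific package.

The packaged reference DE table (`bchrom/data/de_table_cichlid_b.tsv`)
carries the published per-tissue calls for the cichlid B system; the
summary operation reproduces its per-tissue counts (brain 15 up / 5 down,
14 of 20 retroelements; muscle 3 up; male gonads 14 DE with 3 up; female
gonads 3 up) directly from the fold-change signs and classes. Note the
table as printed contains two brain rows with |fold change| < 1.2; the
table is shipped as printed and summarized by sign — the 1.2/0.05 rule is
applied only to fold changes this package computes.

## qPCR gene dosage ratio

`GDR = 2^-(Ct_target - Ct_HPRT)`, assuming perfect per-cycle doubling (no
efficiency correction — the plain method). Technical replicates are averaged
on the Ct scale before dCT. The Ct generator writes `Ct = c0 - log2(copies)
+ N(0, sd)` with the normalizer fixed at 2 copies per diploid genome, so
with no noise GDR recovers `copies_target / 2` exactly (tested), and the
B+:B- group fold tracks relative dosage.

## Determinism and problem sizes

Every stochastic step takes a `numpy` Generator; stage seeds derive from a
master seed by CRC32 of the stage name (kept below 2^31). Identical configs
give byte-identical outputs (tested via manifest digests). Problem sizes
used by the tests and the acceptance script — a ~540 kb + ~740 kb chrB demo
genome at 20x (~650 k reads), 3000 reads/origin for clustering recovery,
200-copy bursts of 2 kb copies for landscape recovery, 200-600 element
count tables — were chosen so the whole suite runs comfortably on one CPU
while leaving every recovery band at >= 2 standard errors of margin.

## Known limitations

* The homing model reassigns each chrB copy's reads to a single homolog; a
  real aligner spreads multi-mapped reads across near-identical loci. The
  per-element sums are invariant to that spread, but per-locus ratios on
  real data are noisier than simulated ones.
* Edge soft-clipping and the 20 bp minimum homology overlap shave ~3% off
  expected extra-copy sums; this sits well inside the recovery tolerances
  and is not corrected for.
* Connected-component clustering can chain distinct repeat families through
  rare bridging reads; the spaced-insertion genome avoids junction reads,
  but real tandem/nested insertions would require community detection.
* The NB Wald test with common dispersion is anti-conservative for strongly
  element-specific dispersions; with the simulated dispersion regime the
  null call rate stays at or below the FDR level (tested), but real count
  tables with heavy dispersion heterogeneity deserve a per-element shrinkage
  estimator.
* BAM/CRAM are not parsed; convert with `samtools view -h` first.
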