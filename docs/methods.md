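# Methods

This note documents the models, conventions, parameters and design choices
behind `microclip`, in the order the pipeline runs.

## Coordinates and strand conventions

All genomic coordinates are 0-based, half-open, with explicit strand. The
only 1-based positions in the package are miRNA positions, following the
field's nomenclature (seed = positions 2–8). Cluster and site sequences are
always handled in the sense (transcribed) orientation; on minus-strand
features the diagnostic PAR-CLIP T>C transition appears as A>G in
reference-forward coordinates, which is how the 4SU chemistry presents on
the transcribed strand. Read substitutions are stored reference-forward and
re-oriented at classification time.

## Cluster calling and T-to-C classification

AGO-enriched regions are called as maximal read-coverage islands per
(chromosome, strand), allowing up to `max_gap` zero-coverage bases inside an
island (default 0) and requiring `min_reads` supporting reads (default 5).
This is a deliberately simple, deterministic caller: the discrimination
between genuine and spurious sites is the classifier's job, not the peak
caller's. Kernel-density boundary refinement in the PARalyzer style is out
of scope.

A cluster is a **T-to-C cluster** when at least one sense-strand position
has a conversion fraction

    (# reads with T>C at position) / (coverage at position) >= 20%

supported by at least `min_conversion_reads` converted reads (default 2).
The 20% ratio is the standard medium-stringency definition for this
experiment type; the ratio threshold and the read guard are both exposed in
the API and CLI. The reported `t2c_ratio` is the maximum per-position
conversion fraction without the read guard, so the guard only gates the
categorical call at low coverage (it protects against single sequencing
errors). Raising the threshold can only shrink the T2C set (a tested
monotonicity property).

RPKM for clusters and sites is `reads / (length_kb * mapped_reads_millions)`.
Background (non-RBP control) intervals flag overlapping clusters
non-destructively; exclusion is a downstream choice, so non-T-to-C clusters
can still be studied.

## MRE scanning and the binding-type taxonomy

Cluster sequences are scanned against each mature miRNA at every register
(the site index opposite miRNA position 1). A register qualifies when any
of these seed-side rules fires:

- perfect Watson–Crick seed match at positions 2–7 (6mer core; 7–9mers are
  refinements resolved at classification),
- offset 6mer: perfect WC at positions 3–8,
- centered: ≥11 contiguous pairings starting at position 4 (positions
  4–14), tolerating at most one GU wobble inside the run,
- compensatory rescue: ≥4 consecutive WC pairs within positions 2–8
  together with all four of positions 13–16 paired WC.

The emitted site window spans the full miRNA length plus 2 nt of 5' and
1 nt of 3' slack; windows clipped below `miRNA length − 5` at cluster edges
are not emitted (the duplex cannot be formed), and windows containing
non-ACGT characters are skipped with a warning. Scanning is exhaustive by
construction and is tested against literal brute-force enumeration.

Candidates are co-folded with the miRNA using ViennaRNA's two-strand
minimum-free-energy machinery under hard constraints: intramolecular pairs
are prohibited on both strands and the scan-time seed pairs are enforced.
Dangling-end contributions are disabled (`dangles=0`), a documented model
choice that makes the energy of a structure a pure sum of stack, loop and
helix-end terms and gives the evaluated energy a clean monotonicity
property (removing a WC pair never lowers it). Candidates without a
negative-energy structure are dropped. Asymmetric unpaired runs between
consecutive pairs count as bulges, symmetric runs as internal loops.

Binding types map to a fixed 12-code ordinal table (part of the model
contract; smaller code = stronger seed match):

| code | type | rule |
|------|------|------|
| 1 | 9mer | WC 2–9 + A opposite position 1 |
| 2 | 8mer | WC 2–8 + A opposite position 1 |
| 3 | 7mer-m8 | WC 2–8 |
| 4 | 7mer-A1 | WC 2–7 + A opposite position 1 |
| 5 | 6mer | WC 2–7 |
| 6 | offset 6mer | WC 3–8 |
| 7 | centered (perfect) | ≥11 contiguous pairs from position 4, no GU |
| 8 | centered (imperfect) | as 7 with exactly one GU |
| 9 | 3' supplementary | ≥4 pairs in 13–16 + ≥4 paired seed positions |
| 10 | 3' compensatory | ≥4-WC seed core (imperfect seed) + ≥4 pairs in 13–16 |
| 11 | noncanonical seed | ≥4 contiguous WC in 2–8 |
| 12 | noncanonical | everything else that folds stably |

The strongest (smallest) applicable code wins. Independently of the code, a
boolean `supplementary` flag marks ≥6mer seeds accompanied by ≥4 pairs at
positions 13–16. The target-side adenine check ("A1") reads the site base
opposite position 1 by register geometry, whether or not that base pairs.
Overlapping same-miRNA candidates within 5 nt are deduplicated keeping the
lowest-energy duplex.

The compensatory rescue minimum (all four of 13–16) is this package's
definition; published descriptions of compensatory sites do not fix a
number. Likewise the one-GU tolerance inside "imperfect centered" runs is a
documented choice.

## The 131-descriptor catalogue

`data/feature_catalog.tsv` is the single source of truth for feature names,
canonical order and node membership. Nodes 1–6 partition the 131 features:

1. **Region** (56): CLIP signal (max/site conversion ratios, aggregate
   substitution ratio, signed distances of the strongest conversion to the
   MRE start, relative substitution position, cluster/MRE RPKM, coverage
   ratio), mono- and dinucleotide frequencies, DUST and Shannon complexity
   for MRE and flanks, GC/AT/purine/keto skews, frame-agnostic codon-usage
   bias, nearest-neighbor dH/dS/dG and Tm of the MRE, and mean phastCons
   conservation over the MRE, both flanks, and the seed-bound bases.
2. **Binding vectors** (25): the miRNA-side binary pairing vector padded or
   truncated to a fixed width of 25.
3. **Matches per domain** (13): total and longest-consecutive matches for
   the seed (2–8), central (9–12), 3' supplementary (13–16) and tail
   (17–3') domains, whole-duplex totals/runs/mismatches, and two MRE-side
   aggregates.
4. **Duplex** (13): total and seed-restricted structure energies, bulge and
   internal-loop counts and lengths, GU wobbles, miRNA 3' dangling-end
   length, A:U pair counts (seed, supplementary, total), flank AU content.
5. **Base pairing** (16): A/C/G/T composition of the paired and unpaired
   nucleotides on each side of the duplex.
6. **MRE general** (8): overlap fraction with the cluster, relative MRE
   midpoint within the cluster, the ordinal binding-type code, skews of the
   paired site nucleotides, and paired-length ratios for both strands.

Nodes 7–9 ("feature combination sets") are fixed non-overlapping
recombinations: node 7 = CLIP + duplex (22), node 8 = sequence +
pairing-composition (59), node 9 = conservation + MRE-general + domain
matches (25).

Formula conventions: Shannon index in bits over base frequencies (range
0–2); DUST is the triplet statistic `sum c(c-1)/2 / (k-1)` over 64-nt
windows, normalized by `k/2` so a homopolymer scores 1.0, reported as the
max over windows; GC-skew = (G−C)/(G+C) with 0 imputed (flagged) when the
denominator vanishes, AT-skew analogous, purine-skew = (A+G−C−T)/L,
Ks-skew is read as keto skew (G+T−A−C)/L; codon-usage bias is
`max over 3 frames of 1 − H(triplets)/log2(64)` because MREs carry no frame
annotation; dH/dS come from Biopython's published RNA nearest-neighbor
table with dG at 37 °C and Tm at 50 mM Na+, 0.25 µM strand. Missing
conservation (no track, or no data at a position) imputes 0 with a
per-feature provenance flag. Distances are signed in sense orientation:
negative = conversion upstream (5') of the MRE start.

## The two-layer super learner

Node 1 is a single random forest over the region features. Nodes 2–9 each
stack seven members — two random forests (80 and 120 trees with different
feature subsampling), two gradient-boosted ensembles (depth/learning-rate
variants), two three-hidden-layer feed-forward networks (64/32/16 and
32/16/8 rectifier units, log-loss objective, softmax output) and one
logistic (generalized linear) model — combined by an 8-unit single-hidden-
layer feed-forward network trained on the members' out-of-fold
probabilities (standard stacking hygiene: the combiner never sees in-sample
member outputs). Network regularization is L2 (`alpha`); the widths, the
combiner size and the L2-for-dropout substitution are package choices at
desk scale. Member and ensemble sizes are kept small so a full training run
completes in roughly two minutes on one CPU.

A gradient-boosting meta-learner over the nine node scores forms the second
layer and is fitted on an instance set disjoint from the base-training set
by MRE region; the disjointness is asserted at train time and leakage is
fatal. Ten-fold cross-validation supplies both the out-of-fold stacking
inputs and the recorded per-node/per-member CV metrics. Hyperparameter grid
search is supported over small user-supplied grids (selection by 3-fold
internal AUC) and defaults to single-point grids. One master seed fans out
deterministically to every member, so identical seeds reproduce identical
CV tables and predictions. Models serialize to a versioned archive
directory (config + architecture hash + fitted state) and reload
bit-compatibly.

The T-to-C-only variant retrains the identical architecture on the subset
of instances originating from T-to-C clusters; prediction is unrestricted.
A miRNA–gene pair's score is the maximum over its sites' scores (applied in
the evaluation module).

## PARS structural accessibility

Per-base S1/V1 tag-start counts are normalized per million by library
depth; the structure score is `log2((v1 + c)/(s1 + c))` with pseudocount
c = 5 (the established convention for this assay; configurable). Negative
scores mean single-stranded (accessible) RNA. Sites enter profile analyses
only when both nucleases show signal on at least half (ceil(L/2)) of the
site's bases. Meta-profiles align sites at profile position 0 = the 3' end
of the mRNA site, placed 2 nt downstream of the initiation of direct seed
pairing (the alternative 1-nt convention is a switch); positive positions
run 5'-ward, so the base opposite miRNA seed position j sits at profile
position j + 1. Group means are compared per position against the negative
group with the two-sided Wilcoxon rank-sum test. Expression gating of the
site list (transcript TPM, miRNA read counts) is left to the caller's
filters.

## Functional evaluation

Gene-level collapsing keeps the max-scoring site per (miRNA, gene) with
deterministic position tie-breaks. Median fold-change curves rank gene
predictions by descending score; genes absent from the fold-change table do
not consume top-N slots (maximizing comparability across tools with
different gene universes). The random-gene reference draws 1000 genes
without replacement, 100 resamples, after removing zero-fold-change genes;
the band is the min–max envelope of per-resample means. Group CDF
comparisons report the exact-at-small-n Wilcoxon rank-sum (two-sided) and
the one-sided Kolmogorov–Smirnov test, with "stochastically smaller values"
mapped onto scipy's CDF-phrased alternative. Precision curves match
predictions to validated sites by same-miRNA identity plus ≥1 bp overlap
(configurable), or by (miRNA, gene) at gene level; totals are
non-decreasing as thresholds loosen and correct ≤ total at every threshold.
Perturbation labeling uses strict |log2FC| > 1 for microarray/pSILAC and
|log2FC| > 0.5 restricted to genes above 10 RPKM for RNA-Seq and ribosome
profiling, with direction set by the perturbation type; boundary values are
unlabeled.

## Synthetic data: what it emulates and what it does not

The generators produce every input with full ground truth and byte-level
determinism given a seed.

- **Library**: a random two-chromosome genome with 50 two-kilobase
  single-exon transcripts (alternating strands, CDS + 3'UTR), 100 read
  clusters of 20–80 thirty-nt reads, one crosslink T per cluster converted
  in exactly `round(rate × covering reads)` reads (so the realized maximum
  conversion fraction equals the planted rate), per-cluster rates drawn
  from {0.1, 0.3} around the 20% threshold by default, uniform sequencing
  errors at 0.1%, and perfect 8mer sites embedded in half the clusters at
  sense offset 25 (far enough inside the cluster that the scan window
  covering the miRNA span fits). It emulates coverage islands, conversion
  statistics and planted binding sites — not fragment-length biology,
  crosslink-position preference, PCR duplicates or quality strings.
- **Training instances**: each of the 131 features is a monotone,
  family-consistent transform (ratios in [0,1], energies ≤ 0, binary
  binding vectors, count-like domain matches) of a latent Gaussian;
  positives are shifted by `separation ×` a fixed per-feature weight. The
  binding-vector family doubles the latent shift before binarization
  because thresholding discards most of it and genuine sites pair their
  seed positions near-deterministically; with this the benchmark is
  separable by construction in every node's feature subset at the
  documented separation of 2.0 (null behaviour is recovered at separation
  0 or under label shuffling). The 1:2.5 positive:negative ratio matches
  the real training corpus shape at reduced n: the benchmark corpus is
  n = 1400 → 200/500 base-train, 100/250 meta-train, 100/250 test.
- **PARS counts**: Poisson tags at a common baseline with elevated S1 and
  depressed V1 (factor 1 + effect) at the bases opposite miRNA seed
  positions 2–4 of accessible-group sites.
- **Perturbation**: non-targets ~ Normal(0, σ = 0.4); targets shifted by
  −effect (transfection) or +effect (knockdown), with a small injectable
  zero-fold-change mass to exercise the zero filter.

Because the feature clouds are monotone transforms of shifted Gaussians,
passing the separability and dominance tests demonstrates the learner
machinery (stacking, out-of-fold hygiene, determinism, meta aggregation) —
not real-data discrimination, which depends on feature informativeness that
only real CLIP corpora can establish. The same applies to the end-to-end
functional shift: it verifies the plumbing from reads to repression
statistics on planted truth at desk scale (200 clusters, 15 miRNAs,
~170 candidate sites, 5-fold CV, ~500 genes).

## Numerical and degenerate-input choices

Zero-coverage clusters cannot be classified (they cannot be called in the
first place). Empty groups are omitted from profile and CDF comparisons
with a warning; groups under n = 3 skip statistics. GC/AT skews impute 0
when their denominators vanish. Folding candidates with no negative-energy
structure are dropped rather than clamped. Probability outputs are exact
model outputs (no clipping); the calibration-slope diagnostic clips logits
only inside the test. All randomness flows from explicit seeds; derived
seeds stay below 2^31.

## Known limitations

- The cluster caller is coverage-threshold based; diffuse binding or very
  deep libraries may need `min_reads`/`max_gap` retuning.
- Scan registers whose site window would be clipped below
  `miRNA length − 5` at cluster edges are not candidates; sites within
  ~20 nt of a cluster 5' edge are therefore invisible unless flanking
  sequence is supplied.
- The feature catalogue reconstructs every documented descriptor family
  and is padded to exactly 131 named features, but it is not a
  byte-for-byte reproduction of any published supplementary list.
- Trained-model quality on real data depends on a real training corpus;
  the shipped generators only emulate its shape.
- bigWig conservation input requires the optional pyBigWig dependency; the
  TSV track format needs no extras.
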