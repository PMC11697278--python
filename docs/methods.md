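# Methods

## Coordinates and region bookkeeping

All intervals are 0-based half-open (BED). Bins are non-overlapping
fixed-width windows (default 1000 bp) over a configurable chromosome
universe (default chr1–22 and chrX); a terminal bin shorter than the bin
width is dropped, and a single bp of overlap with a blacklist interval
excludes a bin — the strictest reading of blacklist filtering. Promoters
are the 1000 bp immediately upstream of the strand-aware TSS, clamped at
chromosome bounds; downstream regions mirror them past the gene end.
Counting follows multicov semantics: a read increments every region it
overlaps by ≥ 1 bp, so a boundary-spanning read counts once per region
but never twice within one. Marked duplicates are excluded by default.

Region annotation assigns one primary feature class by maximal bp
overlap; exact ties break by priority upstream > 5'UTR > exon > 3'UTR >
intron > downstream > intergenic, and CpG-island overlap is an overlay
flag rather than a class, since CpG islands are reported alongside genic
classes. How the original annotation tool resolves multi-class overlaps
is not documented; this table is an explicit stand-in. Feature
enrichment is log2(observed/expected) where expected is the merged class
footprint over the genome size and observed is the fraction of regions
assigned to the class (−∞ for classes never observed).

## SES normalization

For one pulldown/input pair over n bins, bins are sorted ascending by OG
count (ties: input count, then position). With p_k and q_k the
cumulative input and OG count fractions over the first k sorted bins,
the background split k\* is the smallest argmax of p_k − q_k (smallest =
the most conservative, largest background). The input scale factor is
Σ_bg OG / Σ_bg input over those background bins and is applied to input
counts. Degenerate inputs (all OG counts equal, or p − q never positive,
which includes exactly proportional libraries) fall back to the global
ratio with a warning.

**Known limitation.** Because the background is selected by the
pulldown's own noisy counts, the factor estimate carries a downward
selection bias of order the pulldown's unshared coefficient of
variation; at 10 reads/bin this is ~20% even when all biological bin
effects are shared with the input, and it shrinks roughly as 1/√depth
(≤ 10% at ~50 reads/bin, ~5% at 100). The recovery study in the
acceptance suite therefore validates the estimator at 50 reads/bin. A
constant factor bias cancels in the percentile-ranked log2 ratios used
for enriched-bin calling and in two-group damage comparisons, so
downstream calls are insensitive to it.

Inter-genotype library factors are each library's total size divided by
the mean size over all libraries (arithmetic mean exactly 1); they enter
the differential tests as fixed normalization factors.

## Enriched-bin calling

Each technical replicate is processed individually: SES fit, then
log2((OG + pc)/(scaled input + pc)) with pseudocount pc = 0.5 on both
sides (avoids ±∞ while preserving ratio order), then selection at the
95th percentile of the ratio (linear interpolation between order
statistics, computed over all retained bins). A bin is kept when it
passes in both technical replicates of at least two of three biological
replicates; surviving bookended bins (zero-gap adjacency only) merge
into regions scored by the mean ratio across replicates and constituent
bins.

## Differential testing

Both damage regions and RNA use the same two-group conditional NB exact
test. Counts are modelled NB with a common dispersion φ estimated by
pooled method of moments on factor-adjusted counts:
φ̂ = Σ (n_g − 1)(v − m) / Σ (n_g − 1) m², summed over regions and groups,
clipped at 0. Group sums S_A, S_B are modelled NB(μF_A, size n_A/φ) —
exact for equal within-group factors (a sum of iid NBs), an approximation
otherwise — and the p-value sums the conditional probabilities of all
splits of S_A + S_B whose probability does not exceed the observed one
(the "minimum-likelihood" two-sided rule, with the same 1 + 1e−7
relative guard scipy's binomial test uses). At φ = 0 this reduces
exactly to the conditional Poisson, i.e. binomial, test. Totals above
5×10⁵ switch to a normal approximation. log2 fold changes compare
factor-adjusted group means with pseudocount 0.5; a group whose raw sum
is zero reports a ±∞ sentinel. Low-count regions (total across samples
< 10) are removed first.

Thresholds follow the study's rules: damage regions pass at p ≤ 0.01 and
|log2FC| strictly greater than 0.5; genes at p ≤ 0.05 and |log2FC| > 1.
No multiple-testing correction gates the calls (a BH-FDR column is
emitted for transparency). For damage, the tested signal is
max(OG − scaled input, 0) per sample, rounded to integers.

## G4 motif scanning

The canonical motif is four runs of ≥ 3 guanines separated by loops of
1–7 arbitrary bases. Matching is greedy: at the leftmost position where
a match can start, the shortest valid match is taken (breadth-first over
run/loop decompositions) and scanning resumes at its end, so spans never
overlap within a strand; the minus strand is scanned on the reverse
complement and mapped back. G-runs are capped at 10 consumed bases; the
surplus of a longer run falls into the following loop, which changes no
span except when a > 10 run abuts an already-maximal loop. Chromosomes
are scanned whole, then non-overlapping 100 bp windows are flagged when
any motif span overlaps them by ≥ 1 bp; windows containing N are removed
first. A per-window motif count is emitted so a probabilistic G4 scorer
could replace the binary rule. The fraction of enriched regions
overlapping a retained window uses any-overlap semantics.

## Promoter concordance

Promoter damage is computed per sample (floored input subtraction,
division by the sample's library factor) and averaged over the six
samples of each genotype; expression is averaged over each genotype's
RNA replicates. Genes must be nonzero in at least three of four
genotypes in both assays. Each retained gene's damage and expression
rows are z-scored (sample sd, n − 1) and concatenated into an 8-vector.

The per-gene sign rule calls a gene positive when damage and expression
z-scores agree in sign in every constrained genotype and negative when
they disagree in every one; a genotype constrains the call only when
both |z| > 0.2 (with continuous data an exact zero never occurs, so "no
signal" is read as a small-magnitude band), and genes with ≥ 2
unconstrained genotypes stay unclassified. With four genotypes the sign
rule alone passes roughly one in seven unrelated genes, so the final
classification also requires cluster support: the 8-vectors are
clustered hierarchically (Euclidean, average linkage) and maximal
dendrogram nodes are selected that have ≥ 40 members, ≥ 50% of members
sign-classified, ≥ 80% one-way consensus among the classified, and hold
≥ 5× more genes than an average ball of the node's rms radius centred on
a random gene (local density enrichment — chance sign-consistent
neighbourhoods are locally uniform, truly co-varying gene groups are
not; the background is estimated from a deterministic subsample of ~400
genes). Sign-matching genes within Euclidean distance 1.3 of a selected
core's centroid receive its class. These gates were sized for studies of
a few thousand genes with correlated sets of ~100; `k`-cluster flat cuts
of the same tree are emitted for reporting but do not affect the
classification, which is therefore independent of `k` (default 8).
Setting `require_cluster_support=False` reports the bare sign rule.

Fold-change concordance extracts genes shared between damage regions
(annotated to genes) and the expression test, reports their Pearson
correlation and per-feature-class overlap fractions, and clusters the
paired fold-change vectors with correlation distance and average
linkage.

## Synthetic data

The generator emulates the study design: 4 genotypes × 2 clones × 3
biological replicates of OG and input libraries, and 2 RNA replicates
per genotype.

**Counts.** Gamma–Poisson: each pulldown/input pair shares a per-region
Gamma(1/φ, φ) rate effect — the input is sequenced from the same DNA
prep, and background pulldown tracks abundance, which is the premise of
SES — so marginal counts are exactly NB(μ, φ) with variance μ + φμ²
while the biological bin effect cancels within a pair. Across pairs the
effect is independent and acts as replicate variability for the
differential tests. An optional global sequence-driven coverage bias
(`bin_effect_cv`, lognormal, default off) is shared by all libraries.
Defaults: background 10 reads per 1 kb of region, dispersion 0.1,
per-sample library factors uniform on (0.7, 1.3), per-pair true SES
factors uniform on (0.6, 1.4).

**Planted structure.** Enriched bins: a fraction (default 1%) of bins
per genotype, preferentially GC-rich when bin GC is known, with the OG
mean multiplied by `enrichment_fold` (default 8). Feature regions carry
a baseline pulldown enrichment (default 4×) so the floored subtraction
leaves a positive damage signal — without it, damage *loss* would vanish
at the floor and be unrecoverable; differential regions (default 5% per
knockout genotype, half gain, half loss) multiply or divide the OG mean
by `der_fold` (default 2).

**Genome.** Random sequence at 41% GC with GC-elevated (65%) CpG
islands, strand-assigned genes whose exons and introns tile the gene
body exactly (first/last exon doubling as UTR tracks), a blacklist
track, and canonical G4 motifs planted at recorded window-aligned
positions. Chance canonical G4 matches elsewhere are scrubbed (a G→T
flip outside planted spans, iterated), so the ground truth is exact: a
genome with zero planted motifs scans clean.

**OG→RNA coupling.** Correlated genes share one promoter-damage pattern
across genotypes — low while OGG1 is present (WT 1.0, MUTYH 1.1) and
high once it is lost (OGG1 3.5, DKO 3.8) — reflecting that OGG1 excises
OG itself while MUTYH removes the adenine misinserted opposite it.
Expression means are scaled by 1 + βz (positive set) or 1 − βz
(negative set), β = 0.6, floored at 0.05, where z is the gene's observed
promoter-damage z-score: a monotone coupling whose expected deviation
from the gene's mean preserves the sign of z (an exponential coupling
would convexly shift the row mean and systematically flip mid-pattern
genotype signs after z-scoring). Separate genes get knockout-specific
expression folds (default 4×) as planted DEGs. RNA baselines are
log-normal (median 100, σ = 0.5) with NB dispersion 0.05.

**Determinism.** Every emitted file draws from its own RNG stream seeded
by (seed, crc32(stream name)), so adding samples never perturbs existing
ones and a fixed seed reproduces every output byte for byte.

**What the synthetic data does not emulate.** Read-level artifacts
(mappability, fragmentation chemistry, adapter content, duplicates),
sequence-dependent damage propensity beyond GC composition, genotype
differences in global damage load, transcript structure in RNA counts,
and correlated placement of enriched bins with G4 windows. Passing
recovery tests therefore demonstrate the statistical machinery recovers
planted structure under the stated count model — not that the pipeline
is robust to alignment-level artifacts in real libraries.

## Problem sizes of the validation studies

The acceptance studies use 10⁴ bins (SES recovery, at 50 reads/bin as
discussed above), 10⁵ bins (enriched-bin recovery), 10⁴ regions (null
type-I error), 2,000 regions of 2 kb (differential recovery — CpG-island
scale, ~20 input reads per region, where a 2-fold damage change at 6 vs
6 samples has ~90% power at p ≤ 0.01), 1,000 random 200-mers (G4 scanner
vs exhaustive enumeration), and 5,000 genes with 100 planted genes per
concordance class, averaged over three replicate studies. The end-to-end
determinism check runs the full pipeline twice on a 2 × 120 kb genome.
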