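# Methods

This note records the models, algorithms and numerical choices behind
`varsync`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Population model and coordinates

The package assumes an inbred or haploid-equivalent population: one
haplotype per sample, genotypes in {0, 1, missing}, one phenotype record per
line. All internal coordinates are 0-based half-open; VCF (1-based,
anchor-base INDELs) and GFF3 (1-based closed) are converted at the
boundary. Internally an insertion is anchored to an explicit insertion
point (the inserted text precedes the reference base at `pos`), which makes
the "same position, same length" marker identity unambiguous.

## Variant synchronization

**Windows.** The reference is split into windows of `window_size` = 50,000
bases overlapping by `window_overlap` = 1,000 (both configurable). Windows
start every `window_size − overlap` bases; the last window is clipped at
the chromosome end. At most two windows cover any base.

**Haplotypes and alignment.** Each sample's chromosome-scale haplotype is
reconstructed once from its calls and sliced per window through the
coordinate map. The built-in engine aligns each haplotype slice to the
reference slice globally with edlib (banded unit-cost edit-distance
alignment returning an exact CIGAR path) and merges the pairwise alignments
into a window MSA by taking, at every insertion point, the union of the
inserted columns. Two properties matter and are tested, not assumed: the
gap-stripped content of every row is exactly the input sequence, and the
row content depends only on the haplotype *sequence*, never on the variant
representation that produced it — which is what collapses alignment
isomorphs. A unit-cost aligner places gaps differently than an affine-gap
aligner would, but any deterministic placement shared by all samples
yields the same synchronized alleles. `mafft --auto` is available as an
external engine behind the same contract.

**Atomic re-calling.** Variants are read off the MSA column by column:
reference base over sample gap → 1-bp deletion; reference gap over sample
base → 1-bp insertion anchored at the preceding consumed reference
position, with an ordinal per anchor; mismatching bases → SNP. Columns
where either base is N emit no SNP (N never counts as a match or a
mismatch). In window overlaps, every reference position is owned by
exactly one window — the one whose center is nearer, ties to the earlier
window — so agreeing duplicates deduplicate and conflicts resolve in one
rule. The nearest-center cut is clamped into the region both windows
actually cover: a short final window drags the raw center midpoint outside
the overlap, and positions seen by only one window must belong to it.
Atomic runs then merge back: consecutive 1-bp deletions into one deletion,
same-anchor insertions in ordinal order into one insertion; SNPs stay
atomic, and adjacent SNPs are never merged into MNPs. An insertion anchored
inside a deleted span remains an independent record.

**Guarantees measured on synthetic data.** Representation invariance (all
generated isomorph representations collapse to one shared allele, 100% of
500 families), exact haplotype round-trips, and idempotence of
re-synchronizing synchronized output. These hold when variants sit away
from window edges; a variant family straddling a window overlap can in
principle split across the ownership cut, which is the price of windowed
alignment. The synthetic populations keep planted variants ≥ 2 kb from
window boundaries, mirroring how the window size is chosen large relative
to variant scale in practice.

## ORFS annotation

A gene's open reading frame state on a sample haplotype (gene span ± 1 kb
flank, reverse-complemented for minus-strand genes) is judged by three
routes:

* **lift-over** — reference exon/CDS boundaries mapped through the
  coordinate map; a boundary inside a deletion maps to the deletion's left
  haplotype edge, and fully deleted intervals vanish;
* **CDS spliced alignment** — the reference spliced CDS aligned to the
  haplotype by a fit-alignment dynamic programme (query consumed fully,
  genome flanks free) with an intron state;
* **protein spliced alignment** — the reference protein aligned codon-wise,
  same machinery with a genome step of 3.

Four criteria are evaluated on each route's model: ATG start and canonical
stop (any of TAA/TAG/TGA — "intact" is read as "a working codon", not
"the reference's codon"); splice pairs equal to the reference pair at the
same intron index, GT-AG, or in the minor whitelist {GC-AG, GG-AG, GT-TG,
GT-CG, CT-AG}; no in-frame premature stop; spliced CDS length divisible
by 3. The state is *interrupted* only if every evaluable route fails at
least one criterion, *missing* if no route is evaluable (alignment score
below 10), else *conserved*. Unevaluable routes are excluded from the
conjunction. The conservative rule is the point: a single variant that an
alternative gene model absorbs must not flag the gene.

**Aligner scoring.** Match +5, mismatch −4, affine gaps open −12 /
extend −4, intron entry penalty −10, intron length ≥ 10 (an upper bound of
30 kb is nominal — gene regions here are far smaller). Two refinements make
the spliced routes honest about reading frames:

* introns may only open at GT donors and close at AG acceptors, with the
  extended splice context scored (−8 per base deviating from the donor
  GTAAG / acceptor TTCAG consensus). Without splice-site modelling, a
  frameshift can be silently absorbed by sliding an intron boundary onto an
  arbitrary dinucleotide; with it, non-consensus introns are expensive
  enough that honest interpretations win. This mirrors how production
  spliced aligners model splice sites with position-specific scores.
* the codon-level route has an explicit frameshift operation (one residue
  consuming 1/2/4/5 genome bases, penalty −28), and a model containing a
  frameshift operation fails the frame criterion regardless of its summed
  exon length. Without it a codon-stepping aligner is structurally blind to
  frame.

The whitelist of minor splice classes applies when *evaluating* candidate
models (so a mutated reference donor, e.g. GT→GC, still passes), not when
the aligner *proposes* new introns.

**Measured accuracy.** On planted truth (frame-shifting CDS INDELs must be
interrupted; in-frame CDS edits and deep-intron edits conserved), measured
concordance is ≥ 99% over ~500 gene × sample pairs. The residual
disagreements are frameshifts for which the protein route finds a coherent
alternative model with canonical splice sites — exactly the rescue the
conservative rule is designed to allow, so they are a property of the
method, not a defect of the implementation. The synthetic genes are short
(three exons, ~100–150 bp CDS) with consensus splice sites; real genes are
longer and their splice-site signal weaker, so real-data concordance
depends on the aligner's splice model in the same way but is not measured
here.

**Trustable calls.** An ORFS call is trustable when every CDS base has
read coverage ≥ 1 and every CDS INDEL is confirmed by both assembly routes;
with no quality inputs the call defaults to trustable so the pipeline runs
from VCFs alone. Trustable-ORFS counts per sample double as a
sequencing-quality score when removing homogeneous lines.

**Alternative reference copies.** When the reference genome itself carries
a non-functional copy of a gene, the query CDS/protein and splice pairs can
be taken from a designated accession's haplotype (`alt_reference`
mapping); reference-like samples are then correctly called interrupted.

## Genotype encoding and filtering

SNPs are encoded at population-biallelic sites only; a sample is missing at
a SNP when its call has read support < 2, is heterozygous, or the position
is covered by one of its deletions (support/heterozygosity rules pass
vacuously without those fields). INDEL marker identity is (position,
length, type): equal-length insertions at one anchor are one marker even if
the inserted text differs, with the most frequent inserted sequence kept as
the allele descriptor. A non-carrier is missing at an INDEL marker when a
different INDEL of its own occupies part of the marker's span (for
insertion markers: a deletion covering the anchor, or a different-length
insertion at the same anchor); carriers stay 1 because overlapping INDELs
are independent records.

Markers are filtered on MAF (over non-missing samples), missing rate,
minor allele count, and exclusion regions; presets `athaliana`
(MAF ≥ 0.1, missing ≤ 0.5, MAC ≥ 5) and `dmelanogaster` (MAF ≥ 0.05,
missing ≤ 0.2, MAC ≥ 8) carry the standard thresholds for those panels.
Identity-by-state uses LD-pruned SNPs (2 kb windows stepping 1 kb,
r² > 0.9 drops the later-position SNP; r² on pairwise-complete
observations) and is the fraction of co-called identical alleles.
Homogeneous groups are connected components of the IBS > 0.9 graph —
transitive closure chosen for determinism, since "group" is otherwise
ambiguous — and each keeps one sample: id-duplicates removed first, then
the highest trustable-ORFS count, ties to the earliest sample.

## Mixed-model association

Variance components of the null model are estimated by REML (ML optional)
over the ratio δ = σe²/σg², profiling on the spectral decomposition of K:
100-point grid on ln δ ∈ [−10, 10] plus bounded refinement between the best
grid neighbours. The Balding–Nichols kinship is
K[i,j] = mean over markers of (g_i − p)(g_j − p)/(p(1−p)) on co-called
markers, symmetrized, with εI (ε = |λ_min| + 1e−9) added if any eigenvalue
is negative. With sample-estimated allele frequencies the off-diagonal
expectation is −1/(n−1), not exactly 0 — a property, not a bug, of
frequency standardization.

Each marker is tested by GLS at the null δ (the standard one-pass
approximation), with samples missing that marker excluded and the reduced
covariance Cholesky factor cached per missingness pattern; the test is a
t-test on the marker coefficient with n − q residual degrees of freedom.
With K = I this reproduces ordinary least squares p-values to numerical
precision (measured < 1e−8 in log10). ORFS markers run through the same
engine coded 0 = conserved, 1 = interrupted.

Thresholds: Bonferroni α/n_tests, with n_tests either per-class or
integrated over SNP+INDEL+ORFS; and a permutation threshold — phenotype
values permuted against sample labels (preserving marker LD), the
genome-wide minimum p recorded per permutation (1000 by default), threshold
at the lower α-quantile. The permutation scan mean-imputes missing
genotypes so all markers can be screened by one rotated weighted regression
per permutation; reported per-marker tests are unaffected. Raw-value
permutation (rather than residual permutation) was chosen for simplicity
and exactness under exchangeability of lines.

Measured calibration: type-I error 0.03–0.07 at α = 0.05 over 2000
structured-null tests; ~5% of fresh null genome-wide minima fall below the
permutation threshold.

## Variance decomposition

Significant markers enter a forward selection in class order SNP → INDEL →
ORFS, within class by ascending association p-value (the order had to be
fixed somehow; ascending p is deterministic and favours the strongest
signal). A candidate perfectly collinear with a selected covariate is
skipped; otherwise it is kept iff the marginal F-test comparing nested
fixed-effect fits — residual sums of squares computed in the rotated,
whitened basis of the null variance components — gives p < 1e−4.
Coefficients are refit jointly after every acceptance. After each class the
explained variance is evaluated in raw space from the fixed-effect fitted
values (random effect excluded): h2 = 1 − RSS/TSS. Because GLS does not
guarantee raw-space RSS monotonicity on tiny samples, the per-class h2
values are clamped to preserve nesting (h2_S ≤ h2_SI ≤ h2_SIO, a warning is
emitted when clamping bites), which keeps the class differences
non-negative and exactly additive: h2_S + h2_I + h2_O = h2_SIO to 1e−12 by
construction. Recovery measured on simulations with planted shares
(0.25 SNP + 0.10 INDEL, n = 200, 50 replicates): mean estimates within
±0.03 of truth.

## Independent loss-of-function detection

Per gene, samples with interrupted, trustable ORFS are collapsed into
haplotype classes by their ORFS-shifting variant signature (identical
signatures are identical by descent, hence one node). An edge joins two
nodes when any variant of one overlaps any of the other in genomic
position: deletions share a reference base; an insertion overlaps via an
identical anchor or an anchor strictly inside a deletion (two insertions at
different anchors never overlap — the footprint of a zero-span event is
its anchor). If all alleles descend from one ancestral lesion, every pair
overlaps and the graph is complete; a gene is flagged independent when it
has > `min_carriers` carriers (default 130, the published scale — synthetic
populations use proportionally smaller values), ≥ 2 nodes, and at least
one missing edge. Classification agrees with brute-force completeness
checking on all graphs of up to 5 nodes.

## Synthetic data

The generator is driven entirely by a `numpy` Generator, so a seed fixes
every output byte. It produces:

* **references** with evenly spaced 3-exon genes (ATG start, canonical
  stop, codon-boundary introns carrying the GTAAG…TTCAG splice consensus,
  no internal stops) alternating strands, plus homopolymer tracts that
  make position-shift isomorphs possible;
* **isomorph families**: scenario (a) — an INDEL placed left-shifted,
  right-shifted or mid-tract within a repeat; scenario (b) — an adjacent
  base swap represented as two SNPs or as insertion + deletion; scenario
  (c) — a 3→2 complex substitution represented as one block replacement or
  as two different SNP + deletion decompositions. All representations of a
  family are verified during generation to edit the reference to one
  string; carriers (intermediate frequency, ≥ 2) cycle through the
  representations. Families and plain shared alleles are kept ≥ 2 kb from
  window edges and outside gene ± flank regions;
* **ORFS truth cases**: frame-shifting CDS INDELs (length 1/2/4/5),
  in-frame CDS edits (3/6/9 — resampled if the edit happens to introduce a
  premature stop, which would be a genuine loss of function mislabelled as
  conserved), and deep-intron SNPs;
* **loss-of-function genes**: two disjoint carrier groups receiving
  frame-shifting INDELs at two non-overlapping CDS positions (independent
  origins) or one shared INDEL (single origin);
* **phenotypes** y = Σ x_c β_c + u + e with per-class variance shares split
  over causal markers, an optional polygenic term drawn from N(0, h²_poly K),
  and the residual taking the remainder of unit variance;
* the **burden-power simulation**: three allele groups of 70 samples
  (functional mean 2.0; two loss-of-function alleles mean 1.0; variance
  1.44 each, i.e. SD 1.2), compared by two-sided Wilcoxon rank-sum tests —
  one INDEL's carriers versus everyone else, versus both loss-of-function
  groups pooled (the ORFS burden test) — repeated 10,000 times by default
  (2,000 in the test suite and acceptance script, which is plenty for the
  direction and exceedance comparisons), with exceedance counted over the
  genome-wide line at −log10 p = 7.8. The group sizes are read as 70 per
  allele group.

What passing tests show: the pipeline's logic — collapse, round-trips,
criteria arithmetic, calibration, recovery — is correct on data matching
its assumptions. What they do not show: robustness to read-level artifacts
(the generator emits clean calls, not reads), to LD structure from real
demography (markers are drawn independently; no coalescent), to genes with
UTRs, alternative isoforms or weak splice sites, or to reference errors.

## Problem sizes and defaults

The test suite and acceptance script run on deliberately small instances —
populations of 6–20 samples on 30–200 kb chromosomes, 500 isomorph
families, ~500 ORFS cases, n = 200 phenotype replicates — sized so the full
suite completes in a few minutes on one CPU while every rate quoted above
is still estimated from hundreds of draws. All defaults
(window 50,000/1,000; filter presets; 1000 permutations; F-test 1e−4;
IBS 0.9; 130 carriers) are the standard values for the study designs this
package targets and are configurable throughout.
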