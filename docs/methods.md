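# Methods

## Scope and model of the data

The package analyses small-RNA sequencing libraries from two compartments —
whole cells and the exosomes they secrete — with the goal of identifying
miRNAs that are differentially sorted, characterising their 3′ isomiR state,
and checking candidate sequence signals for export. All sequence data are
handled in DNA space (T, not U); mature miRNAs quoted in RNA space are
normalized before matching. Coordinates are 0-based half-open internally and
converted to 1-based inclusive GFF3 at file boundaries.

## Synthetic reference and library generator

`build_reference` creates a toy reference world: `n_hairpins` random
hairpins (default 20, 70–90 nt) each carrying a 22-nt mature window with
≥5 nt margins on both sides, embedded verbatim in a single toy chromosome
together with tRNA (~75 nt), rRNA (~120 nt), snRNA (~105 nt), repeat
(~200 nt) and unclassified loci separated by random gaps. Mature sequences
are rejection-sampled until each occurs at exactly one genome locus
(bounded retries, explicit failure naming the constraint); a config switch
instead emits identical hairpin copies for multi-mapper tests. The ≥5 nt
downstream margin guarantees that the hairpin continuation used for
templated/NTA bookkeeping is identical in hairpin and genome context.

`simulate_library` draws each read's source from a multinomial over mature
miRNAs, ncRNA fragment classes, and an unmappable remainder. Defaults are
chosen as a plausible small-RNA library at desk scale: 70 % miRNA-derived
reads, 25 % ncRNA/repeat fragments (16–32 nt), 5 % unmappable; 3′ trim
lengths 0–10 nt with ~70 % intact; tail lengths 0–3 nt with ~80 % untailed
and an A-biased NTA composition; constant quality strings (the pipeline
never uses qualities); a TruSeq-style 3′ adapter appended in full with reads
truncated to a 50-nt read length, so trimming is exercised realistically.
Exosome libraries multiply each miRNA's expected abundance by
2^(export bias); replicate-to-replicate biological variation is modelled as
per-miRNA gamma multipliers with configurable squared-CV (default 0.05 in
the experiment workflow), giving the NB dispersion estimator something real
to estimate.

Two generator choices keep the ground truth identifiable:

- **Templated tails are drawn only for untrimmed molecules and capped at
  2 nt.** After a trim, a templated re-extension is byte-identical to less
  trimming, so no classifier could attribute it; and a +3 templated
  extension would leave the ±2 nt annotation window. The cap is a property
  of the generator, not the classifier.
- **NTA bases are rejection-sampled to differ from the hairpin continuation
  at each tail position.** A "non-templated" base equal to the template
  would in fact be templated; forcing the mismatch makes the truth label
  correct by construction.

What the generator does *not* emulate: sequencing errors (an optional
uniform substitution rate is the only hook), PCR duplicates and UMIs,
5′ NTA, RNA editing, reverse-strand features (off by default), and the
heavy-tailed abundance distributions of real libraries. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated model, not robustness to platform artefacts.

## Read preprocessing

The 3′ adapter is located by minimum unit-cost edit distance
(substitutions, insertions, deletions) over two placement families: the full
adapter aligned starting at any read position, and a proper adapter prefix
(≥3 nt) aligned to the read's 3′ tail. A placement is admissible when its
edit count is at most ⌊error-rate × matched adapter length⌋ (rate 0.1 by
default). Among admissible placements the smallest edit count wins, ties
broken by leftmost start; everything from the match start onward is removed.
With the leftmost rule a full exact occurrence always beats any downstream
suffix overlap at equal edit count, so the common case trims exactly at the
insert boundary. Edit distances are computed with edlib; an independent
pure-Python dynamic-programming oracle re-derives the same decision in the
tests. Reads shorter than 15 nt after trimming are excluded and counted.

## Alignment and annotation

Alignment is exact-substring search against hairpins (forward strand) and
the toy genome (both strands), with an optional Hamming neighbourhood of up
to 2 mismatches via pigeonhole seeding; no indels, matching the semantics of
a short-read aligner's fixed-mismatch mode at desk scale and bit-reproducibly.
All hits in the best (fewest-mismatch) stratum are kept and a read with k
hits contributes weight 1/k to each, so per-read weights sum to 1.

A hit is annotated miRNA iff its interval lies within a mature window
extended ±2 nt (tolerating imprecise precursor processing); otherwise it
takes the class of its containing feature under the priority
miRNA > tRNA > rRNA > snRNA > repeat > other_ncRNA > unannotated. A read
inside a hairpin but outside every mature window is classed `other_ncRNA`
(it is an annotated precursor locus, not an unannotated region); reads
spanning a feature boundary are `unannotated`. Composition summaries report
weighted category fractions over mapped reads plus mapped / unique / multi /
unmapped read fractions; the length × 5′-base profile counts one unit per
read.

## isomiR classification

Reads are confronted hairpin-first: a read maps at round 0 if its full
sequence is an exact hairpin substring; reads that instead match the genome
are set aside as non-miRNA; everything else is trimmed 1 nt from the 3′ end
and remapped, up to 10 rounds, never below the 15-nt floor. The removed
suffix is recorded verbatim. For a read mapping inside an extended mature
window (5′ start within ±2 nt of the canonical start), `trim_len` is the
gap to the canonical 3′ end, and the suffix splits into the longest prefix
matching the hairpin continuation (templated) plus the non-templated
remainder. Because mapping is maximal-prefix, templated tails are only ever
declared beyond the canonical end — the deterministic reading of the
trim-and-remap procedure. Multi-hairpin placements carry 1/k weights,
consistent with alignment.

The NTA profile restricts to reads ≥ 18 nt that fail both hairpin and
genome mapping at full length, allows at most 3 trims, and reports per-tail-
position base composition for miRNAs with ≥ 500 weighted reads in every
compartment. The 544-miRNA high-confidence restriction of real annotation
releases becomes a reference-subset flag; synthetic bundles define their own
subset.

## Differential enrichment

Counts are weighted sums of reads assigned per mature miRNA (fractional
values from multi-mappers are kept). TMM normalization follows the standard
definition exactly: M and A values against a reference sample (the one whose
scaled upper quartile is closest to the mean), genes with zeros excluded,
double trimming (30 % on M, 5 % on A, rank-based), inverse-asymptotic-
variance weights, factors scaled to geometric mean 1; the tests verify
agreement with the Bioconductor implementation to 1e-6. The factors are not
exactly invariant to rescaling one sample's depth (the variance weights
shift slightly); the tests assert invariance to 0.5 %.

Dispersion is estimated by method of moments on normalized counts,
α = max(0, (s² − μ)/μ²), with within-group deviations pooled across
conditions ("pooled") or estimated per condition and maximized
("per-condition"); a lowess trend of the gene-wise estimates on log10 mean
provides a floor, and the final α = max(gene-wise, trend) is deliberately
conservative. Testing uses a sum-conditioned exact NB test when a miRNA's
total normalized count is ≤ 5000: group sums are NB with size n/α, and
conditioning on the grand total gives a two-sided p as the mass of splits no
more likely than the observed one (binomial conditional in the Poisson
limit α = 0). Larger totals use a Wald test on log2 means with NB variance.
Fold changes use a 0.5 pseudocount; multiple testing is Benjamini–Hochberg
(the conventional FDR choice). Calls require |log2FC| ≥ 1 **and**
FDR ≤ 0.001, both boundaries inclusive; positive fold change means
exosome-enriched under the (exosome, cell) contrast convention. This NB
machinery is behaviourally similar to, but intentionally not numerically
identical with, classical DE packages; its guarantees are established by
simulation (type-I calibration at n = 3, power at fourfold changes,
end-to-end recovery) rather than by replicating another tool's p-values.

Per-line enriched sets are partitioned into the standard seven regions
(three uniques, three pairwise-only intersections, one triple); the packaged
category tables parse into the same structure, so published counts and
pipeline output are directly comparable. Sample relationships use Spearman
correlation (average ranks on ties; constant vectors flagged NaN) and PCA of
log2(x+1) feature-centred matrices via SVD, with each component's sign fixed
by its largest-magnitude loading. Both RPM and TMM normalizations are
exposed for these summaries.

## qPCR and reporter arithmetic

Technical replicates are averaged first; any Ct > 30 fails QC and rejects
the measurement. ΔCt = Ct_miRNA − Ct_U6, ΔΔCt = ΔCt_treated − ΔCt_control,
FC = 2^−ΔΔCt (FC > 1 ⇒ enriched in the treated compartment). Standard
curves regress mean Ct on log10(copies/µl) over ≥ 3 dilutions (pM
concentrations converted via Avogadro's number: 1 pM ≈ 6.02 × 10⁵
copies/µl); the amplification efficiency 10^(−1/slope) − 1 is reported, a
flat curve is flagged degenerate, and inversion outside the fitted range
warns of extrapolation. Percent increase is the conventional relative
change ((CP_cond − CP_base)/CP_base) × 100 — the published formula's
parentheses are garbled, and this reading reproduces its stated ≈34 % and
≈8 % values from the printed copy numbers. SEMs propagate first-order
(delta method). Reporter assays normalize luciferase to β-galactosidase and
then to the scrambled-control ratio; fold repression is the reciprocal.

## Motif scanning

Motifs are IUPAC strings matched position-wise after U→T normalization;
all overlapping matches are reported, and 3′-window mode keeps matches
lying entirely within the final k nt. Set enrichment is a 2×2
motif-incidence table with a one-sided hypergeometric tail p. De novo motif
discovery is out of scope by design — the module tests given candidate
signals (GGAG, U/CC) deterministically.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to give tight
statistical bounds at interactive runtimes: 10⁴ reads for isomiR truth
recovery (binomial SE on a 99.9 % target ≈ 0.03 %), 10⁴ null miRNAs for
type-I calibration (3 SE band ±0.65 %), 2 × 10³ for power, and a
4-condition experiment with 120 miRNAs × 12 libraries × 10⁴ reads for
end-to-end recovery. Exact-test enumeration is vectorized over the
conditioned support; log-pmf normalization guards underflow; the
p ≤ p_obs comparison uses a 1e-12 relative guard against ties. Seeds fix
every random draw; identical inputs give byte-identical FASTQ and truth
tables.

## Known limitations

The aligner is exact/Hamming only and desk-scale; genome-scale indexing is
out of scope. The NB test does not implement GLM offsets, covariates, or
fold-change shrinkage. The trim-and-remap procedure cannot distinguish a
templated re-extension from less trimming (inherent to the method, handled
by the maximal-mapping convention), and coincidental template matches put a
ceiling (well above 99.9 % here) on NTA recovery. The generator's gamma
replicate jitter approximates, but is not, a full hierarchical NB model.
Reverse-strand and 5′-modification analyses beyond the ±2 offset histogram
are not implemented.
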