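# Methods

## Scope and design

`hgblkit` implements the analysis chain for three *MYC*-altered DLBCL
groups (DHL/THL, SHL, MCAD): FISH-based subtype assignment, multi-caller
somatic variant consensus filtering with rule-based classification,
minimal-common-region (MCR) detection in segmented copy-number data, an
integrated gene × sample alteration matrix with Fisher/Mann–Whitney group
comparisons, and Kaplan–Meier/log-rank survival by prognosis group. A
synthetic cohort generator supplies inputs with known latent truth; it is
first-class, tested code, not a fixture.

## FISH scoring

Break-apart and fusion probes are scored per case from per-cell patterns.
A valid call needs ≥100 counted cells (`min_cells`); fewer cells raise an
invalid-call error rather than returning a negative. A probe is positive
when the positive-cell fraction is ≥10% (`threshold = 0.10`); the
threshold attained counts as positive. *MYC*-cluster amplification requires
strictly more than 10 *MYC* signals per cell; because no cell-fraction for
that call is separately established, the same 10% positivity fraction is
reused. Subtype assignment is a total function of the four flags;
a hypothetical case with both *MYC*-R and cluster amplification is
classified by its rearrangement (amplification only defines MCAD in the
absence of *MYC*-R). The *MYC/IGH* fusion probe is recorded as an attribute
and does not change the subtype. IHC positivity is strict (>30% of tumor
cells); the Hans tree is: CD10+ → GCB; CD10− BCL6− → non-GCB; CD10− BCL6+
MUM1− → GCB; CD10− BCL6+ MUM1+ → non-GCB.

## Variant filtering and classification

Per-caller calls are merged on the left-aligned (chrom, pos, ref, alt) key
(shared context bases trimmed; multi-allelic VCF records decomposed on
read); annotations must agree across callers or merging fails loudly.
Consensus keeps variants detected by ≥3 of 5 callers (both configurable).
*BCL6* candidates outside the exon 3–10 mask (BED, 0-based half-open) are
removed because only those exons are covered by the assay.

Classification order:

1. population AF ≥ `af_snp` (default 0.01) → **SNP**;
2. `af_likely` (0.001) ≤ AF < `af_snp` without COSMIC/literature somatic
   evidence → **likely SNP** — known somatic hotspot evidence overrides
   this band, since driver mutations can appear in population databases;
3. otherwise, any of four disjunctive somatic criteria makes a
   **mutation**: COSMIC-confirmed somatic; literature-described
   somatic/driver; truncating (frameshift, splice-donor/acceptor, stop
   gained — splice-region variants are deliberately not treated as
   truncating); missense with ≥2 of 4 damaging predictor verdicts;
4. otherwise **likely non-functional**.

The AF band boundaries are package defaults: the classification scheme in
use upstream does not publish them, so they are exposed as parameters.
Only *mutation*-class changes feed downstream analyses. Burden = number of
distinct panel genes with ≥1 selected mutation (explicitly not mutations
per megabase). The summed per-gene frequency (a per-group diagnostic that
can exceed 100%) is available via `cohort_gene_frequency` but is not a
primary output.

## Copy-number analysis

Coordinates are 0-based half-open internally; SEG files (1-based
inclusive) are converted at the I/O boundary only. Gain/loss thresholds
default to ±0.3 log2 ratio (integer CN: ≥3 / ≤1, diploid baseline) because
the upstream array platform's settings are not published; they are
parameters. Sex chromosomes are treated like autosomes (no ploidy
adjustment).

MCR detection per group and direction: each sample's altered segments are
merged, the genome is cut at all segment breakpoints, and maximal runs
with an identical contributing-sample set form a step profile. Two kinds
of regions are reported:

* **peak MCRs** — runs that are strict local maxima of the altered-sample
  count (absent neighbours count as zero) and reach the recurrence
  threshold `min_freq` (default 0.3, the lowest recurrence worth
  reporting at this cohort size);
* **broad MCRs** — maximal blocks of contiguous above-threshold runs
  spanning more than one plateau, reported with the fraction of samples
  whose altered segments cover the *entire* block (emitted only when that
  fraction also reaches the threshold).

This reproduces the "+chr.7 (44%) with a peak at 7p22.3 (56%)" reporting
idiom. Adjacent runs with equal counts but different contributing samples
are *not* merged: merging them would produce regions not contained in any
contributing sample's segment, violating the defining property of a
minimal common region. The implementation is verified against an
independent per-base counting oracle on randomized instances.

Binned alteration frequencies (1 Mb bins by default) count samples with
≥1 bp of altered overlap per bin. Group comparison runs a two-sided Fisher
exact test per bin and direction on altered/not-altered counts; adjacent
significant bins of the same direction merge into regions reported with
their minimum p. Raw p is primary (matching how such comparisons are
conventionally reported at this cohort size); BH q-values are added as a
column. The choice of Fisher per bin is itself a default — the upstream
nonparametric test is not specified.

## Integration and statistics

Gene-level CNA assigns each gene the call covering a strict majority
(>50%) of its span; uncovered span counts as neutral and exact ties
resolve to `none` (conservative). The alteration matrix combines mutation
presence with the gene call into six statuses; "mutated case" for
frequency comparisons means any mutation-containing status.

`fisher_exact_two_sided` sums hypergeometric probabilities ≤ the observed
table's probability (relative tolerance 1e-12), computed with
log-factorials; an all-zero table returns p = 1 by convention.
`mann_whitney_u` enumerates all C(m+n, m) group assignments exactly when
m+n ≤ 12 (ties handled by enumeration) and otherwise uses the normal
approximation with tie and continuity corrections. Kaplan–Meier and the
log-rank test are computed through lifelines. The prognosis dichotomy is:
favorable = complete response to first-course chemotherapy and no relapse
during observation; everything else adverse. Cox regression is out of
scope (off-the-shelf and dependent on unavailable per-patient covariates).

## Synthetic cohort generator

The generator emulates the study conditions per group:

* **Copy number.** Each template region (chromosome, interval, direction,
  frequency) is present in a sample as an independent Bernoulli draw at
  the published group frequency (e.g. DHL/THL +1q25.2 at 0.56, +12p12.2 at
  0.67; SHL gains at 9p/9q and 16p11.2; MCAD +8q24 at 1.0). Chromosome-
  wide alterations and their higher-frequency peaks are encoded as
  disjoint regions separated by a 5 Mb neutral gap so each maps to exactly
  one recoverable MCR with its own frequency. Gain segments draw log2
  ratios in [0.4, 0.7], losses in [−0.7, −0.4], neutral tiling N(0, 0.03).
* **Mutations.** Named genes carry their published per-group frequencies
  (DHL/THL: BCL2 0.89, MYC/KMT2D 0.78, SOCS1 0.67, CREBBP 0.56, MEF2B/
  ARID1B/HIST1H1E 0.44; SHL: MYC 0.83, DTX1 0.67, MEF2B/PIM1 0.50, PAX5
  0.33, BCL2 0; MCAD: DDX3X 1.0, KMT2D/CREBBP/TP53 0.67, MYC 0); filler
  genes share the remainder so the probability sum equals the group mean
  burden (17, 10, and 12 — the MCAD mean is not published; 12 sits between
  the two published means, consistent with a distinct but not silent
  mutational profile). `calibrate_burden` rescales probabilities
  proportionally with iterative clipping at 1.0 until the sum matches the
  target within 1e-9; the group means are calibrated as *means* (whether
  the published values are means or medians is not stated). One variant
  per mutated gene is drawn; consequences follow missense 0.60 /
  frameshift 0.20 / stop-gained 0.12 / splice 0.08 (the qualitative
  ordering of observed consequence classes; configurable). Annotations are
  drawn consistently with truth so every true somatic variant satisfies at
  least one somatic criterion (missense without COSMIC/literature evidence
  gets ≥2 damaging votes). True *BCL6* variants are placed inside the
  exon 3–10 mask. Each caller detects each true variant independently at
  its sensitivity (default 0.9 each); artifacts (Poisson, default rate
  2/sample) carry 1–2 caller flags by construction; germline contamination
  (Poisson, default 3/sample) carries population AF drawn in [0.01, 0.5].
* **FISH.** Per probe, 100–130 cells. Positive probes receive a split-cell
  count fixed at round(f·n) with f ~ U(0.2, 0.8) (deterministically above
  the 10% threshold); negatives use f ~ U(0, 0.05). Amplified cases show
  11–30 signals in a U(0.2, 0.6) fraction of cells, others 2–6 signals.
  The DHL/THL template forces at least one of BCL2-R/BCL6-R alongside
  MYC-R (BCL2-R is set when neither is drawn), slightly raising the
  marginal BCL2-R probability above its nominal 0.7.
* **Clinical.** First-course response (CR/PR/other), relapse after CR,
  exponential survival with prognosis-dependent medians (favorable 60,
  adverse 15 months) under uniform administrative censoring at 24–96
  months, an IPI category, and IHC percentages consistent with a drawn
  cell of origin.

The simulation genome is a miniature: the 13 chromosomes the templates
touch, 100 Mb each, with a coarse cytoband table carrying the band names
needed for labels. Gene intervals (100 kb) are placed so no gene straddles
a template-region boundary; *MYC* sits inside 8q24 (so the constitutive
MCAD gain covers it) and *BCL6* at its exon model on chr3. A 2×5 kb micro
genome backs the per-base MCR oracle tests.

**What the generator does not model:** read-level data, tumor purity and
subclonality, caller-specific error signatures, linkage between CNA and
mutation status within a sample, and inter-gene mutation correlation. A
passing truth-recovery test therefore demonstrates the correctness of the
filtering/classification logic under the stated noise model, not
performance on real sequencing data.

## Numerical and testing choices

Latent truth is always emitted, enabling closure tests: with caller
sensitivity 1.0, artifact and germline injection are *harmless by
construction* (artifacts never reach 3 callers; germline AF ≥ 0.01 is
classified out), so the pipeline must recover subtype labels, mutated-gene
sets and gene-level CNA exactly — any deviation is a defect, not noise.
Calibration checks use 1000 samples per group with a 3-Monte-Carlo-SE
tolerance; binomial recovery checks use explicit binomial envelopes.
Writers order rows deterministically and format floats to 6 significant
digits; all randomness flows from a single integer seed through one
`numpy` generator, making bundles byte-identical for a fixed seed.
Problem sizes in the test suite (cohorts of 13–23 for end-to-end checks,
1000 per group for calibration, 200 random instances for the MCR oracle,
exhaustive 2×2 tables with margins ≤12 for Fisher) were chosen to make
every check exact or tightly concentrated while keeping the default suite
fast.
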