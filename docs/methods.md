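# Methods

`biofilmdge` implements the classical digital gene-expression (DGE) analysis
used for staged *Saccharomyces cerevisiae* biofilm transcriptomes: pooled tag
libraries, one per developmental stage, with no biological replicates. This
note records the statistical model, the choices that were genuinely open, and
what the synthetic study conditions do and do not establish.

## The two-library exact test

For a gene with `x` tags in library 1 (total `N1` uniquely mapped tags) and
`y` tags in library 2 (total `N2`), tag counts are modelled as Poisson: each
gene occupies a small fraction of the library, so its count is well
approximated by a Poisson draw around `λ·N`. The Audic–Claverie construction
places a flat prior on the unknown rate `λ` and marginalizes it, giving the
conditional law of the second count given the first:

    p(y | x) = (N2/N1)^y · (x+y)! / (x!·y!) · (1 + N2/N1)^−(x+y+1)

This is the negative-binomial distribution with size `x+1` and success
probability `N1/(N1+N2)`. The two-sided p-value doubles the smaller tail:
with `S = Σ_{i≤y} p(i|x)`,

    p = min(1, 2S)                    if S ≤ 1/2
    p = min(1, 2(1 − S + p(y|x)))     otherwise.

The upper branch retains the observed point mass `p(y|x)` so both branches
include the observed outcome and agree near `S = 1/2`; the doubled value is
capped at 1.

Numerics: the pmf is evaluated in log-space through log-gamma, and the tail
sum `S` through the negative-binomial CDF identity (a regularized incomplete
beta), which is exact and O(1) per gene rather than O(y) — term-wise
summation would be prohibitive for high-abundance genes at 10⁷-tag depth.
The implementation is verified against an exact-rational (arbitrary
precision) evaluation to 12 significant digits for all `x, y ≤ 50` and
against direct tail summation.

Calibration: the test is exact but discrete, hence mildly conservative for
genes with low counts. At the default study conditions (20 000 genes, 10⁷
tags per library, long-tailed abundances), the realized fraction of null
two-sided p-values ≤ 0.05 is about 0.047, within three binomial standard
errors of the nominal 0.05; at shallower depth the conservativeness grows.

## Multiple testing and DEG calling

Raw p-values are adjusted by a step-up false-discovery-rate procedure. The
default is Benjamini–Yekutieli (`BY`), which is valid under arbitrary
dependence; Benjamini–Hochberg (`BH`) is available by flag and is what most
tag-DGE pipelines of this generation used in practice. Adjusted values are
monotone in rank, clipped at 1, and returned in input order; ties share the
adjustment of their group.

A gene is called differentially expressed when both gates pass, inclusively:
adjusted p ≤ 0.001 **and** |log2 ratio| ≥ 1. Direction follows the sign of
the ratio.

## Quantification

RPKM = 10⁹·C/(N·L), with `C` the gene's uniquely aligned reads, `N` the
library's total uniquely mapped reads and `L` the transcript length in nt.
Fold changes between libraries are computed from library-size-normalized
counts with a pseudocount `c = 1` (configurable):

    log2 ratio = log2( ((y+c)/N2) / ((x+c)/N1) )

so genes observed in only one library remain finite. For large counts this
converges to the log2 RPKM ratio (lengths cancel within a gene); both the
pseudocount ratio and the raw RPKM ratio are reported in the output tables,
since either convention is defensible and they differ only at low counts.

## Read quality control

Three whole-read filters in fixed order, first failure winning: (1) the read
contains a configured adapter as an exact substring; (2) more than 5% of
bases are `N`; (3) more than 30% of bases have Phred quality ≤ 10. The
fraction thresholds are strict (`>`), the Phred cutoff inclusive. Adapter
matching is exact substring because the provenance of the filter gives no
matching rule; adapters are caller-supplied. Reads are kept or dropped
whole; Phred+33 is the default encoding with a +64 switch, since
HiSeq-2000-era data occurs in both.

## Enrichment

Categories are flat gene sets over an annotated universe (no GO DAG
propagation). For a category of size `K` in a universe of `N` genes, with
`n` annotated DEGs of which `k` fall in the category, the p-value is the
hypergeometric upper tail `P(X ≥ k)`, summed in log-space (logsumexp over
log-gamma terms) so extreme tails (down to ~1e-53 in the reference
contingencies) keep full relative precision. The DEG background `n` counts
only DEGs that carry annotation. Only over-representation is tested.
Q-values are BH across exactly the categories tested in one run — with a
different number of tested categories the q-values shift, which is why
reference q-values are treated as report-only while p-values reproduce
exactly. Categories with q ≤ 0.05 are called enriched. Tested categories
are iterated in sorted id order so p-value ties break deterministically.

## qPCR validation

Relative quantification uses the Livak 2^−ΔΔCT method against a reference
gene (default 18S rRNA): technical-replicate Ct values are averaged
arithmetically, the target is normalized to the reference within each
condition, and the conditions differenced. Concordance with sequencing is
the Pearson correlation of log2 fold changes — log2 rather than raw folds,
because a single extreme fold (e.g. 555×) would otherwise dominate the
correlation. No amplification-efficiency (Pfaffl) correction is applied.

## Synthetic study conditions

The generators produce every input the pipeline consumes, so all stages are
testable without downloads.

**Count libraries.** Gene lengths are lognormal (median ≈ 1400 nt, log-sd
0.45, floor 100 nt). Relative abundances are lognormal (log-sd 1.2), giving
the long-tailed dynamic range (~3–4 orders of RPKM) typical of yeast
transcriptomes. Expected tags scale with abundance × length and are
normalized against the **baseline** transcriptome mass: the library's
nominal depth `N` is the normalizing constant recorded in its profile
(total mapped reads is a supplied constant, not the column sum), so a
planted log2 fold change is recovered exactly by N-normalized count ratios.
Renormalizing each perturbed library instead would impose a compositional
shift (~0.45 log2 under the attachment-period plan) on every gene;
real tag data has this compositional ambiguity, and the package does not
attempt to model or correct it. Counts are Poisson, or gamma-mixed Poisson
(one dispersion knob, variance `μ + φμ²`) for deliberately violating the
test's Poisson assumption in robustness checks.

**The staged-biofilm scenario** (6000 genes, one library per stage at
0.9–1.1 × 10⁷ tags) plants the published sentinel fold changes by name
(Flo11 6.8/5.0/18.4× up across attachment, sessile-growth and maturation;
Fbp1 239× and Pck1 555× up at attachment; Hsp12 181/49/13× up; Gut1
6.6/1.4/2.3× up; Bsc1 42/4/3× down; Mig1 26× down; Tec1 2× up; Kss1 3×
down). Non-sentinel DE sets are sized to the published per-comparison
up/down totals (522/1576, 511/1045, 472/455) and annotated-DEG counts
(648/518/376), with effect magnitudes drawn from {1.5, 2, 2.5, 3} log2
units. The annotation universe holds exactly 2143 genes; four categories
match the reference pathway sizes (32, 55, 183, 12) and carry their planted
DEG contingencies exactly (26/32 and 37/55 at attachment; 69/183 and 9/12
at sessile growth; 120/183, 8/12 and 19/55 at maturation); filler
categories partition the remaining universe. Sentinels stay outside the
universe so the contingencies are exact by construction. Because Tec1 is
planted exactly on the |log2| ≥ 1 call boundary, sampling noise legitimately
puts it on either side; no recovery claim is made for it.

**FASTQ fixtures** plant exact per-class contamination counts (adapter
insertion, ≥6% `N` bases, ≥35% low-quality bases), with clean reads clean
by construction, so QC removal counts can be checked against labels
exactly. **Ct tables** lower the target's mean Ct by the planted log2 fold
change (one PCR cycle per doubling), keep the reference constant, and add
independent Gaussian noise per replicate.

**What the synthetic conditions do not show.** One library per stage means
no biological replication — like the design it emulates, the test detects
sampling-level differences, not biological variability; passing tests say
nothing about replicate-aware inference. The generator has no sequence
content beyond what the QC filters inspect, no alignment ambiguity (counts
are generated directly), no compositional shift between libraries, and
Poisson (or single-knob gamma-Poisson) noise only. Real-data fold changes
and DEG totals are therefore emulated inputs, not reproduced results.

## Problem sizes in the test suite

The suite runs the full scenario (6000 genes × 4 libraries), a 20 000-gene
null calibration at 10⁷ tags per library, a 20 000-gene planted-effect
recovery (sensitivity ≥ 0.9, false-discovery proportion ≤ 0.01 at the
default cutoffs with |log2| = 2 effects), 100 repetitions of the six-gene
qPCR panel, and exact-rational cross-checks over all `x, y ≤ 50`; the whole
suite completes in a few seconds on one CPU because the tail computations
are O(1) per gene.

## Known limitations

- No replicate-aware dispersion estimation (edgeR/DESeq-style); the exact
  test treats all extra-Poisson variability as signal.
- Adapter detection is exact substring matching; mismatched or partial
  (read-through) adapters are not detected.
- Enrichment tests over-representation only; depletion is not reported.
- Q-values depend on the set of categories tested in a run and are not
  comparable across runs with different annotation maps.
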