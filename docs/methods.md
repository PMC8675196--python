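# Methods

## Scope and model

`ihrdkit` classifies tumors by the genomic *consequences* of defective
homology-directed repair (HRR) rather than by gene-mutation status alone.
Three readouts are computed per tumor from whole-exome data and combined:
the HRRd-associated mutational signature (CSig3), a genome-wide LOH score,
and a six-feature RBF-SVM ("iHRD"). Variant calling, copy-number inference,
and pathogenicity curation are upstream of this package: it consumes somatic
SNV tables, Sequenza-style allele-specific segments with ploidy/cellularity,
and curated gene-alteration events.

## Trinucleotide catalogs and signature refitting

Catalogs use the canonical 96-context ordering (substitution blocks C>A,
C>G, C>T, T>A, T>C, T>G; within a block the 5' base varies before the 3'
base). Purine-reference SNVs are reverse-complemented onto the pyrimidine
strand. Records that are not single-base substitutions, or whose context is
unresolvable, are counted and reported, never silently dropped.

Refitting solves a non-negative least-squares problem on the L1-normalised
catalog with the simplex bound Σw ≤ 1. Unconstrained NNLS is used first;
the bound is typically inactive (reference columns are themselves
normalised), and only when it is violated is the program re-solved with
SLSQP from the rescaled NNLS point. Post-fit, weights below a cutoff
(default 0.06, the convention of standard refitting tools) are zeroed and
the surviving weights rescaled so their total equals the pre-cutoff total.
No exome-to-genome trinucleotide-frequency renormalisation is applied by
default — catalogs and reference are assumed to share a context frame — but
`fit_signatures(..., context_scaling=...)` accepts a 96-vector of
per-context abundance ratios for users whose reference is on a different
frame; the SNV count used by the reliability and attributed-count rules is
always the raw count.

Signature calls: CSig3(+) requires fitted weight > 0.20 **and** ≥ 50
mutations attributed (weight × n_snvs) **and** a reliable catalog, defined
as more than 50 somatic SNVs. CSig8(+) uses the same weight threshold
without the attributed-count floor — an explicit assumption, since no
published rule exists for that signature; downstream, the iHRD classifier
consumes the CSig8 *weight*, not the call.

### The bundled reference matrix

The package cannot ship the proprietary COSMIC catalogue, so
`synthetic_signature_matrix()` generates a deterministic *synthetic*
30-signature stand-in with the qualitative structure the method relies on:
a spiky C>T-dominated aging-like "CSig1", near-flat "CSig3"/"CSig8"
profiles (the HRRd signature is famously flat; Dirichlet(1) over 96
contexts keeps it identifiable at exome SNV counts), and sparse spiky
profiles elsewhere (Dirichlet(0.3)). Users with a real reference load it
via `ihrdkit.io.read_signature_matrix`; every algorithmic test also runs on
small analytic matrices, so no bundled matrix is load-bearing for
correctness.

Refitting ~30 free signatures to a catalog of only ~100–200 SNVs is an
ill-posed problem: multinomial noise is partly absorbed by spurious
signatures, which biases flat-signature weights downward (about −0.03 at a
true weight of 0.5 under default conditions). This is a property of the
refitting approach itself at exome scale and is accounted for in the
generator calibration below.

## LOH score

Score = (bases in LOH events) / (assessed bases), where an LOH event is a
maximal run of segments with total CN > 0 and minor-allele CN = 0 whose LOH
bases strictly exceed 15 Mb. Homozygous deletions (total CN 0) are assessed
but never LOH. Design choices where the published description is silent:

* **Merging.** Adjacent LOH segments merge before the length test
  (segmentation tools fragment runs); unassessed gaps up to 3 Mb inside a
  run are bridged (configurable), while any assessed non-LOH segment breaks
  the run. Event length and the numerator count LOH bases only, never gap
  bases.
* **Chromosome exclusion.** A chromosome whose event bases reach ≥ 75 % of
  its *assembly* length is dropped from numerator and denominator —
  near-whole-chromosome LOH typically arises through non-HRRd mechanisms.
  "Entire length" is read literally as the assembly length; an
  assessable-length mode is available (`exclusion_basis="assessable"`).
* **Sex chromosomes** are excluded by default (in an all-male cohort, chrX
  hemizygosity would read as spurious LOH).
* Coordinates are 1-based inclusive, matching Sequenza segment output.
* An empty profile, or a denominator of zero after exclusions, is an error,
  never a silent NaN.

## Zygosity, groups, and the HRR-Reference

Per-gene events collapse to BAL (deep deletion; ≥ 2 pathogenic mutations;
or one pathogenic mutation plus copy loss or LOH), MAL (exactly one hit: a
single pathogenic mutation or a monoallelic copy loss), or intact. LOH
without a mutation is *not* counted as a hit (it may be copy-neutral).

Groups are assigned by fixed precedence: HRG-Germ (germline pathogenic
mutation in a core HRR gene — carriers are labelled regardless of a somatic
second hit) > HRG-BAL > FANC-BAL > HRG-MML (≥ 2 core-gene MALs) > HRG-MAL >
ATM/CHEK2 (biallelic sensor loss without core-gene events) > HRG-Intact.
The ordering is a design choice where tracks could overlap: core-gene
events dominate Fanconi-pathway and sensor-gene events.

O-HRGmut(+) requires biallelic loss or a germline pathogenic mutation in
one of the 14 olaparib-approval genes. The HRR-Reference comparator
excludes any tumor with *any* recorded event in an HRR-associated panel
gene (core, Fanconi, sensors, other-interest), any hypermutated tumor
(≥ 20 mut/Mb, boundary inclusive), and any tumor with XRCC2 or NHEJ-gene
alterations; the NHEJ list defaults to {PRKDC, XRCC4, XRCC5, XRCC6, LIG4,
NHEJ1} and is configurable.

## The iHRD classifier

An SVM with Gaussian RBF kernel over six features, in this order: CSig3
weight, CSig8 weight, LOH score, somatic mutation count, ploidy, segment
count. The two count features are log1p-transformed (heavy-tailed;
configurable off), then all features are z-scored. Both transforms are
fitted inside each cross-validation fold — a leakage test asserts that
inflating a held-out sample cannot change fold-internal scaling. (C, γ)
are selected by stratified 5-fold CV over C ∈ {0.1, 1, 10, 100} and γ ∈
{0.01, 0.1, 1/d, 1, 10} with balanced class weights (the canonical training
design is 48 positives versus 190 negatives); the final model refits on all
training data. The decision threshold is the SVM sign. The default seed is
20211208; identical data and seed give byte-identical models.

Reported error rates: `cv_misclassification` is a *nested* stratified CV
(selection inside each outer fold), which is the honest generalisation
estimate; the `cv_misclassification_` attribute of a fitted model is the
inner-CV error of the selected grid point. Both are reported because the
protocol behind published single-number misclassification rates is usually
underspecified.

Models serialise to JSON (scaling parameters, support vectors, dual
coefficients, kernel parameters) and the decision function is evaluated as
an explicit kernel expansion Σᵢ αᵢ K(svᵢ, z) + b, so a round-tripped model
reproduces decision values bit-for-bit.

## Cohort statistics

Mann-Whitney U is exact when the smaller group has ≤ 10 members and the
data are tie-free, otherwise a normal approximation with continuity and tie
correction. Fisher's exact test reports the hypergeometric two-sided
p-value (sum of tables no more probable than observed — the R convention)
and the sample cross-product odds ratio, Haldane-shifted by 0.5 only for
display when a cell is zero; p-values are always exact. Batched tests are
BH-corrected. Co-occurrence matrices test both-genes-MAL exposure against a
binary status per unordered pair (diagonal: single-gene BAL), marking pairs
with zero exposed tumors untestable. The low-expression flag is
log2-expression < gene median − 1 (strict). Time-on-treatment comparisons
report medians *and* means, since published group summaries do not always
say which.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
raw sequencing reality: catalogs are multinomial draws from a true
signature mixture (no sequencing-error model), segment profiles are
piecewise-constant with no subclonality, gene events follow class rules,
and clinical outcome depends only on the true HRRd state. Five truth
classes: HRRd with biallelic core-gene loss, HRRd with multiple monoallelic
losses, cryptic HRRd (no core-gene event; CHD1 loss in half), proficient,
and hypermutated.

Default calibration, fixed once and frozen:

* LOH-score targets: Beta(3.00, 19.54) for HRRd classes (mean 0.133,
  SD 0.07) and Beta(3.19, 24.29) for proficient/hypermutated (mean 0.116,
  SD 0.06). Profiles realise the drawn target within ±0.02 (typically
  ±0.003) by placing >15 Mb LOH runs on random hg19 autosomes, capped at
  70 % per chromosome so the exclusion rule never fires by construction.
* True CSig3 weight of HRRd tumors: Beta(19.03, 19.03) (mean 0.50,
  SD 0.08); zero for proficient and hypermutated tumors. CSig8 is elevated
  (mean 0.25) in 7 % of tumors, background (≈ 0.04) otherwise.
* Mutation counts: negative binomial (NB2, variance μ + αμ²) with α = 0.12
  in non-hypermutated classes and α = 0.3 (left-truncated at 20 mut/Mb) in
  the hypermutated class, over a 30 Mb callable footprint. A single
  cohort-wide α of 0.5 was rejected: at exome scale it gives within-class
  CV > 70 %, and the ≥ 50-attributed-mutations gate of the signature call
  then censors low-count tumors so strongly that the *called*-group burden
  means cannot sit near their calibration anchors. Cohort-level burden
  remains overdispersed through the class mixture.
* Latent burden means 5.25 mut/Mb (HRRd classes) and 3.42 mut/Mb
  (proficient) were set by a one-off simulation so that the
  *pipeline-observable* called-group means land on 5.94 and 3.47 mut/Mb —
  the call conditions on the fitted weight and the attributed-count floor,
  which selects against low-count tumors and against the fitting bias noted
  above, so latent and observed means necessarily differ.
* Class mixture (13.9 % / 5.6 % / 7.7 % HRRd classes, 4.8 % hypermutated,
  68 % proficient) was set the same way so that a 418-tumor cohort is
  called CSig3-positive at ≈ 19.6 %: roughly 70 % of HRRd-class tumors
  survive both call gates, and false-positive calls in proficient tumors
  are negligible (the attributed-count floor requires more SNVs than their
  burden regime provides).
* Ploidy: truncated normal, mean 2.6 (SD 0.5) for HRRd versus 2.1 (SD 0.4)
  otherwise; segment counts normal with means 210/140/150 — chosen as
  realistic for exome segmentations of metastatic prostate tumors; no
  printed value anchors them.
* Clinical model: PSA50 probability 0.75 (HRRd) versus 0.12 (proficient)
  under carboplatin; time on PARPi gamma-distributed (shape 2.2) with means
  440 versus 141 days. Expression of panel genes: N(5, 0.6) in log2 units,
  shifted −1 by copy loss and −2.5 by deep deletion.

What passing tests on this generator do **not** show: robustness to
segmentation noise, subclonal copy number, context-frame mismatches between
catalog and reference, signature misspecification (real tumors contain
processes absent from any reference), or cohort-composition shifts. The
generator validates the pipeline's internal consistency and its behaviour
under the calibrated conditions, not performance on real sequencing data.

## Numerical and degenerate-input conventions

Empty catalogs, empty profiles, all-zero contingency tables,
sample-identifier mismatches, zero-variance training features and
degenerate response cohorts all raise errors naming the offending input.
Weight optimisation tolerances: NNLS is exact; the SLSQP fallback runs to
ftol 1e-14; fitted weights match an independent constrained-least-squares
oracle to < 1e-4. The LOH scorer is integer-exact in the numerator and
denominator. Determinism: every stochastic routine takes an explicit seed
or `numpy` Generator; cohort generation, training and prediction are
reproducible bit-for-bit given identical inputs and seeds.
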