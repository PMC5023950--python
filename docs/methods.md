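# Methods

This note records the models, rule semantics, numerical choices and known
limitations behind `lymphomut`. It documents what the code does and why;
every empirical claim here is one the test suite or `scripts/acceptance.py`
computes itself.

## Somatic filtering

A candidate site is a 2×2 read-count table. The somatic test is Fisher's
exact test on `[[t_alt, t_ref], [n_alt, n_ref]]`, one-sided in the
direction of tumour alt-enrichment — the direction that distinguishes a
somatic variant from shared (germline) or absent signal. The published
description names only "Fisher's Exact Test"; we fix one-sidedness as a
design choice and verify the implementation against an exact
hypergeometric-tail enumeration in the tests.

Boundary semantics are encoded exactly as printed: tumour VAF "≥ 22 %" is
inclusive, normal VAF "< 15 %" strict, "more than 5 reads" strict (≥ 6),
"at least 18" inclusive. Allele frequencies are compared as exact rational
read-count fractions (`Fraction(alt, depth)` against the rational form of
the threshold), never as pre-rounded floats, so 22/100 passes a 22 %
threshold on every platform. Rejection reasons are evaluated in a fixed
order (coverage → allele frequencies → read support → somatic p →
annotations) so rejected outputs are reproducible; a variant failing
several rules reports the first.

Two published ambiguities are kept visible rather than silently resolved:

* The population-SNP exclusion is printed as "excluded if … an SNP with
  MAF < 2 %", which is the opposite of conventional common-polymorphism
  removal. The default excludes annotated SNPs with population frequency
  ≥ 2 %; `literal_maf_rule=True` reproduces the printed direction.
* The tumour-only panel rules include a somatic Fisher p condition although
  no matched normal exists. By default the rule is skipped with a warning;
  `somatic_p_mode="pseudo_normal"` tests tumour counts against an
  error-rate pseudo-normal (default error 1 %) and keeps variants with
  p ≤ 0.1.

## Copy-number segmentation

Coverage arrives as tumour/normal read counts in fixed 100 kb bins. The
per-bin signal is `log2((t/T)/(n/N))` with `T`, `N` the library totals;
bins with a zero count in either sample are masked, not imputed (they carry
no ratio information, and imputation would fabricate markers).

Before segmentation, single-bin spikes are pulled to the local running
median (window 5 bins; a spike deviates from the local median by more than
3 robust s.d., estimated as 1.4826 × MAD of the residuals). The series is
deliberately *not* replaced wholesale by the running median: a
median-filtered series has autocorrelated noise, and the segmentation's
permutation null assumes exchangeable values, so full filtering makes the
test anticonservative and fragments real segments. A full running-median
smoother (`median_smooth`) is still exposed for display tracks.

Segmentation is classic circular binary segmentation: on each segment the
arc `(i, j]` maximizing

    |mean_in − mean_out| / (s · sqrt(1/k + 1/(n−k)))

(`s` the segment's sample s.d., `k` the arc length) is tested against a
within-segment permutation null; the split is accepted at permutation
p ≤ alpha and the search recurses. Defaults: alpha = 0.01, 1,000
permutations, minimum arc width 2 bins. The permutation loop stops early
once enough exceedances guarantee p > alpha; this changes no decision and
keeps flat segments cheap. All permutations come from one seeded generator,
so results are reproducible; a zero-variance (constant) segment is never
split.

Calls use fixed thresholds: gain iff mean ratio > +0.25, loss iff
< −0.25, each requiring *more than eight* supporting markers (≥ 9; the
boundary is strict). Raising the ratio threshold can only move calls toward
neutral (threshold monotonicity, property-tested).

### LOH

The LOH caller is this package's own design (the upstream study reports
LOH tracks without describing the derivation). Informative sites are
germline heterozygotes selected in the normal (VAF in [0.4, 0.6], depth
≥ 20). A segment is in allelic imbalance when ≥ 10 informative sites have
mean |tumour BAF − 0.5| ≥ 0.2; with tumour purity p, a clean single-copy
loss or copy-neutral LOH shifts BAF to roughly 0.5(1 ± p) /
(normalization), ≈ 0.95/0.05 at p = 0.9, so the 0.2 margin tolerates
purities down to ~0.5 at moderate depth. A segment with no informative
sites keeps a *missing* flag — absence of evidence is not evidence of
retention. Copy-neutral LOH is the conjunction of the imbalance flag and a
neutral coverage call.

## Pathway enrichment

M_B is a binary gene × patient matrix; an entry is 1 iff the patient has at
least one qualifying event (non-silent filtered variant, or — when enabled
— a gain/loss segment overlapping the gene's locus; a locus straddling
several segments takes the call of the segment covering the larger
fraction). The signature frequency matrix counts member-gene events per
patient (an optional normalized mode divides by matched signature size —
the published text does not define "frequency", so raw counts are the
default).

The null reassigns gene labels by permuting the rows of M_B. This is the
only permutation scheme that preserves both each patient's total event
count (column sums) and the per-gene event profile multiset exactly, which
is what "does this *set* of genes carry more events than a random set of
the same size" requires. 1,000 permutations by default.

The published "one-sided t-test" sentence admits two arrangements; both are
implemented. Default: Welch two-sample t-test of the observed per-patient
frequencies against all pooled permuted frequencies, alternative "observed
mean greater". `method="perm_mean"` instead ranks the observed mean within
the per-permutation null means ((1+exceedances)/(1+n_perm)). Signatures
with fewer than two matched genes are skipped (a one-gene "set" degenerates
the test); a both-sides-constant comparison returns p = 1 when means are
equal. Benjamini–Hochberg is the standard step-up with monotonicity
enforcement, verified in tests against both a direct-formula oracle and
statsmodels.

Calibration and power are measured, not assumed: under a row-exchangeable
null the raw-p distribution's fraction ≤ 0.05 lands in [0.03, 0.08] over
500 signature-tests, and a planted 10-gene signature with 0.9 per-patient
event probability in a 15-patient × 200-gene cohort attains the minimum
adjusted p ≤ 0.05 in ≥ 90 % of 50 seeded runs (see
`tests/test_acceptance.py`).

## Recurrence and hit accounting

Substitutions are collapsed to the six pyrimidine-context classes by
complementing purine-reference changes; indels are tallied separately;
non-ACGT alleles are skipped with a warning. "Double hit" accounting is a
pure function of (mutation count, locus-deleted flag): ≥ 2 mutations →
double mutation; 1 + deletion → mutation-plus-deletion; biallelic phase is
*not* inferred (two mutations may in principle lie on one allele).
Splice-site variants group with nonsense and frameshift for the
loss-of-function fraction. Reported percentages round half-up to integers
(13/15 → 87 %, 18/26 → 69 %); fractions are also kept unrounded.

## Phenotype scoring

Extent buckets use the printed integer boundaries (<10 → 0, 10–25 → 1,
26–50 → 2, 51–75 → 3, 76–100 → 4); fractional extents are rounded half-up
to integer percent first, so the buckets partition the input space with no
gaps. The composite is extent score × intensity (0–3), attaining exactly
{0,1,2,3,4,6,8,9,12}. A non-interpretable staining (negative with no
internal positive control) is missing, not zero, and a me3/me2 ratio with
me2 = 0 is likewise missing — a zero denominator here means "cannot be
normalized", not "infinitely demethylated".

FISH: nucleus deleted iff orange/green ≤ 0.5 (inclusive — a 1/2 pattern is
the canonical heterozygous deletion); green = 0 nuclei are excluded from
the denominator. The cutoff is mean + 3 × *sample* (n−1) s.d. of per-sample
control deleted-fractions (the published text does not specify population
vs sample s.d.; sample s.d. is the conservative choice at n = 5 controls).
Tumour calls require ≥ 100 evaluable nuclei and exceed the cutoff strictly.

Group comparison defaults to the two-sample rank-sum (Mann–Whitney) test:
the compared entity groups are independent samples, although the source
figure legend names the signed-rank test; a paired signed-rank mode is
available behind `paired=True`. Fully tied input returns p = 1. Spearman's
rho uses average ranks for ties, drops incomplete pairs, needs ≥ 3 pairs
and returns missing for a constant vector.

## Synthetic cohorts

The generator emulates the *count level* of a paired FFPE exome study — no
reads, no subclones, one clone per tumour. Defaults are the study
conditions: 15 patients, tumour purity 0.9 (microdissected tumour areas),
mean depths 195×/213× (tumour/normal), ~57 somatic coding variants per
patient, 100 kb bins, and a driver-gene mutation mix of 6 nonsense : 9
frameshift : 3 splice : 8 missense.

* Somatic variants: a clonal variant with m mutant copies in a region of
  tumour copy number c has expected VAF `p·m / (p·c + 2(1−p))`; reads are
  binomial at Poisson-sampled depth. Mutations in loss regions sit on the
  retained allele (a mutation on the lost allele would be unobservable and
  would vacuously break ground-truth round-trips).
* Germline hets: normal VAF 0.5; tumour BAF follows the same copy
  accounting with the alt allele on a random haplotype — cnLOH shifts it to
  0.5(1 ± p). Artifact sites draw a low VAF (2–12 %) in *both* samples.
* Coverage bins: Poisson with tumour mean `depth × (p·mult + (1−p))`,
  multipliers 0.5/1.0/1.5/1.0 for loss/neutral/gain/cnLOH. The purity
  mixing term is what makes a planted loss read ≈ −0.86 in log2 rather
  than −1 at p = 0.9.
* Phenotypes: IHC extent/intensity and FISH deleted-fractions are drawn
  conditional on the driver hit class (any driver mutation → low driver
  protein and low trimethylation, matching the dominant-phenotype
  observation; deletion-only → reduced protein, preserved trimethylation).
  FISH controls are five samples at 2–6 % background over 400 nuclei each.
* Randomness: one seed; per-patient streams are spawned by patient index,
  so enlarging the cohort never perturbs existing patients.

What the generator does **not** emulate — and hence what green tests do not
show about real data: FFPE artifact spectra (C>T deamination bias),
mappability and GC coverage waves, subclonal structure, contaminating
normal in the "tumour area" beyond a single purity scalar, segmentation
edge effects from centromeres/gaps, or inter-observer IHC variability.

## Problem sizes

The default verification runs use: 8,100-table Fisher enumeration (depths
≤ 12 per sample), 500 null signature-tests at 200 permutations, 50 planted
power runs at 1,000 permutations, a 15-patient cohort on a 3 × 10 Mb
genome (300 bins/patient) for loss recall, and 40 synthetic FISH samples
at 200 nuclei. These sizes give stable pass/fail behaviour at the stated
tolerances while keeping the whole suite fast on a single core.
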