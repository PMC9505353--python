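# Methods

`abomics` implements a cohort-analysis pipeline connecting the genetics of
the ABO blood group with oral-glucose-tolerance-test (OGTT) measures of
insulin homeostasis, gut-microbiome species abundances and plasma
metabolites, and decomposes exposure→trait effects into mediated and
direct components. Because cohort data of this kind are typically not
redistributable, the package ships a synthetic-cohort generator with known
ground truth; every analysis stage is validated by parameter recovery
against it.

## ABO tagging panel and haplotype model

The ABO blood group is determined genetically at the *ABO* locus on
chromosome 9. Five common haplotypes — O1, O2, A1, A2 and B — are tagged
by six SNPs: rs41302905 (T marks O2), rs8176743 (T marks B), rs1053878 (A
marks A2), rs8176645 (delG marks O1, standing in for the rs8176719
frameshift at LD 0.98), and rs2519093 (T) with rs600038 (C, standing in
for rs579459 at LD 0.99) jointly marking A1. O2 is treated as an O1 point
variant: it is defined only by rs41302905-T and carries the O1 pattern at
the remaining sites — a recorded assumption, since O2 differs from O1
functionally by a separate inactivating substitution. Any allele vector
that matches no table row is labelled `unknown` and kept as a residual
haplotype (such residuals are real: admixed cohorts segregate haplotypes
this six-SNP table does not resolve).

Blood types follow standard ABO dominance: A- and B-group haplotypes are
dominant over O; A together with B gives AB.

## EM haplotype-frequency estimation and diplotype posteriors

Unphased genotypes (counted-allele dosages 0/1/2 per SNP) leave phase
ambiguous whenever two or more panel SNPs are heterozygous. Haplotype
frequencies are estimated by maximum likelihood over the
phase-enumeration likelihood

L(f) = Π_i Σ_{(h1,h2) ∈ C(g_i)} f(h1) f(h2) · [2 if h1 ≠ h2]

via EM, starting uniform over every haplotype consistent with at least one
subject (tolerance 1e-8 on the largest frequency change, at most 1000
iterations; the log-likelihood is asserted non-decreasing every
iteration). Subjects with any missing panel SNP are excluded
(complete-case). A degenerate property of EM worth knowing: a *lone*
double-heterozygote has two phasings of equal prior weight, and the
uniform start sits exactly on that saddle; any symmetry-breaking subject
moves EM off it. The package also provides `brute_force_frequencies`, a
direct quasi-Newton maximiser of the same likelihood over a
softmax-parameterised simplex, used as an independent cross-check on
small instances.

Per-subject diplotype posteriors are proportional to f(h1)·f(h2) (doubled
for heterozygous pairs) over consistent pairs. A subject is *unambiguous*
when exactly one consistent pair has nonzero posterior (hard criterion;
an alternative posterior-threshold mode is provided because the boundary
between "ambiguous" and "practically certain" is a judgement call).
Association analyses use the posterior-expected haplotype dosage (soft
assignment, rows summing to 2) rather than the best-guess pair; this
avoids bias from discarding ambiguity but propagates no dosage variance
into the regression — a standard approximation.

Panel diagnostics: folded minor-allele frequency; the exact conditional
(Levene–Haldane) Hardy–Weinberg test summing probabilities of
heterozygote counts no more probable than observed (mid-p off;
monomorphic sites report p = 1); and pairwise LD r² from EM-phased
two-SNP haplotype frequencies (undefined for monomorphic pairs).

## OGTT insulin-homeostasis indices

From glucose (mg/dL), insulin (µU/mL) and C-peptide (ng/mL) at 0/30/120
minutes after a 75 g load:

- Matsuda ISI = 10000 / √(G₀·I₀·Ḡ·Ī). The means are unweighted
  three-point arithmetic means; a time-weighted (AUC/120) option exists
  but is off by default for this three-sample design. The square-root
  form is the standard Matsuda definition.
- secretion = AUC-Ins(0–30) / AUC-Glu(0–30) (early-phase insulin
  response), clearance = AUC-Cpep(0–120) / AUC-Ins(0–120) (hepatic
  extraction proxy; unit constants cancel in log-scale contrasts),
  DI30 = ISI × secretion exactly, so log DI30 = log ISI + log secretion.
- All AUCs are trapezoidal; all indices require strictly positive inputs
  and are natural-log transformed for modelling. A log-scale effect β
  back-transforms to a percent change (exp(β) − 1)·100, reported to one
  decimal.

## Microbiome composition

Species-level relative abundances are prevalence-filtered (retain species
non-zero in ≥ 30% of samples, inclusive) and centred-log-ratio
transformed: CLR(x_i) = ln(x_i / g(x)), with g the geometric mean over
the **full** species-level profile of the sample, computed before
subsetting to the analysis species (a subset-denominator mode exists for
sensitivity checks). Zeros are replaced by a multiplicative pseudocount —
half the smallest non-zero abundance within the sample by default, or a
fixed epsilon — before logs; the choice changes CLR values and is
therefore recorded in the output object. CLR is invariant to global
rescaling of a sample, so percent vs proportion inputs do not matter
after detection. Group distributions are compared per species with the
two-sample Kolmogorov–Smirnov test (asymptotic p-values).

## Association models

Each outcome (log trait, log metabolite, CLR abundance) is fit by one
joint OLS model containing the expected dosages of *all* retained
non-reference haplotypes (frequency ≥ 5%, O1 the omitted reference) plus
age, sex and ten genetic principal components, under additivity. Wald 95%
intervals and p-values use Gaussian critical values (cohort sizes in the
hundreds). Blood-type models use indicator contrasts against type O on
unambiguous subjects. Bonferroni families (4 traits, 13 metabolites, 21
species) are compared strictly at exact 0.05/k; the displayed threshold
is rounded to two significant figures (0.0024 for the species family).
Rank-deficient designs raise an error naming a collinear column.

## Mediation

For exposure X, mediator M, outcome Y (all continuous, linear models, no
exposure×mediator interaction), the Baron–Kenny step regressions are:
total C from Y~X, path A from M~X, and B with direct C′ jointly from
Y~X+M, all covariate-adjusted on shared complete cases; fulfilment is
reported as effect sizes, not thresholded. The quasi-Bayesian Monte-Carlo
estimator draws `n_sim` (default 1000) parameter vectors from each fit's
asymptotic Gaussian; per draw ACME = a·b, ADE = c′, total = a·b + c′, so
ACME + ADE = total holds exactly per draw. Point estimates are MC means;
intervals are 2.5/97.5 percentiles. The proportion mediated defaults to
the point-estimate ratio ACME/total because per-draw ratios blow up near
zero totals; the per-draw mode averages ratios over draws whose total
shares the sign of the point total. A total-effect interval covering zero
flags the proportion unstable. Screening runs mediation only for
candidates whose A and B paths both reach nominal p < 0.05; survivor
estimates use per-candidate seeds derived deterministically from the run
seed.

## Synthetic cohort generator

The generator's defaults are the package's study conditions:

- **Haplotype pool**: {O1 0.68, A1 0.13, A2 0.068, B 0.060, O2 0.062},
  pairs drawn i.i.d. (Hardy–Weinberg). The O2 value is the remainder of
  the four printed common-haplotype frequencies and is a synthetic
  choice, not an observed estimate.
- **OGTT**: target log traits are drawn first — baseline {ISI 4.0,
  secretion 0.25, clearance 0.15}, additive dosage effects, small age
  (−0.005/yr, centred) and sex (−0.10) effects so adjustment is
  exercised, Gaussian noise (sd 0.3, chosen to match the precision
  implied by printed CI widths at a few hundred subjects) — then curves
  are constructed to realise the targets exactly: a fixed glucose curve
  (90/150/120 mg/dL), insulin solved from ISI and secretion (I₀ pinned
  at the midpoint of its feasible interval, which guarantees positive
  solutions for any trait draw), C-peptide = clearance × insulin
  pointwise. DI30 effects are realised by shifting log-ISI, since
  DI30 = ISI·secretion is an identity. This inversion is deliberately
  non-physiological: it trades realistic curve shapes for exact planted
  effects.
- **Mediator**: log(lactate) = a·dosage(A1) + ε, and the outcome trait's
  log target gains c′·X + b·log M with noise sd `noise_sd_y`; the
  planted proportion mediated is a·b/(a·b + c′). Defaults a=0.4, b=0.3,
  c′=0.2, noise sds 0.5 (free parameters; chosen for test power). The
  demo configuration instead mirrors the A1→lactate→ISI story (a=−0.092,
  b=−0.35, c′=0.10, total 0.1322, proportion 0.2436) at n=1000.
- **Microbiome**: per-species zero-inflated log-normals, closed to sum 1;
  default 21 species with zero-inflation spread over 0–0.6. No
  genotype→microbiome effect is planted by default.
- Missing genotypes are off by default; a masking rate is available.

What passing recovery tests on these cohorts does **not** show: the
generator has no LD beyond the haplotype pool, no genotype–covariate
confounding, Gaussian log-trait noise, a shared glucose curve, and
mediators that satisfy sequential ignorability by construction. Results
on real cohorts additionally depend on those features.

## Numerical and design notes

- EM tolerance 1e-8 / max 1000 iterations; the brute-force cross-check
  optimises softmax coordinates with BFGS from four starts.
- Regression p-values and intervals are Gaussian, not t; at n ≥ 200 the
  difference is far below the reported precision.
- The Bonferroni display rounding of 0.05/4 is 0.013 (binary 0.0125
  rounds up at two significant figures); the internal comparison always
  uses the exact quotient.
- `run_all` re-reads every intermediate from disk so file formats are
  exercised end to end; reruns with identical config and seed are
  byte-identical, and a stage failure leaves a `FAILED` marker.
- Problem sizes used by the acceptance script: full enumeration of 2-SNP
  instances (n ≤ 6, ≤ 3 compatible haplotypes; 1482 instances) for the
  EM oracle; n = 5000 for frequency and effect recovery; 10,000 null
  simulations at n = 300 for type-I calibration; 500 cohorts of n = 2000
  for mediation recovery.

## Known limitations

- Haplotype-dosage regression ignores posterior uncertainty in dosages
  (no variance inflation); with this panel's low ambiguity the
  attenuation is negligible, but it is a bias in principle.
- The exact HWE test is two-sided by probability ordering only; no mid-p
  option.
- African-American-specific ABO subtypes are not resolvable by the
  six-SNP table; residual haplotypes surface as `unknown` labels rather
  than being typed.
- Mediation assumes linear, no-interaction structural equations and
  continuous mediators/outcomes; no sensitivity analysis for unmeasured
  mediator–outcome confounding is provided.
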