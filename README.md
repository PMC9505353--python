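# abomics

Tools for studying how the **ABO blood group** relates to **insulin
homeostasis**, and whether gut-microbiome species or plasma metabolites
mediate that relationship. The package is aimed at genetic-epidemiology
cohorts that carry unphased genotypes at the six ABO tag SNPs, oral
glucose tolerance test (OGTT) measurements, MetaPhlAn-style species
profiles and metabolite panels.

It provides, as composable library modules with a thin CLI on top:

- **`abomics.haplotypes`** — the six-SNP ABO tagging panel (O1, O2, A1,
  A2, B), EM estimation of haplotype frequencies from unphased genotypes
  by maximising the phase-enumeration likelihood
  `L(f) = Π_i Σ_{(h1,h2)∼g_i} f(h1)f(h2)·[2 if h1≠h2]`,
  per-subject diplotype posteriors and expected haplotype dosages,
  blood-type assignment by ABO dominance, and MAF / exact
  Hardy–Weinberg / LD r² diagnostics.
- **`abomics.ogtt`** — the four insulin-homeostasis indices from
  0/30/120-min glucose, insulin and C-peptide: Matsuda ISI
  `10000/√(G₀·I₀·Ḡ·Ī)`, early secretion `AUC-Ins₃₀/AUC-Glu₃₀`, clearance
  `AUC-Cpep/AUC-Ins`, disposition index `DI₃₀ = ISI × secretion`; natural
  log transforms and back-transformation of log-scale effects to percent
  changes `(e^β − 1)·100`.
- **`abomics.microbiome`** — 30% prevalence filtering and the centred
  log-ratio transform `CLR(x_i) = ln(x_i/g(x))` with the geometric mean
  taken over the full species-level profile; two-sample
  Kolmogorov–Smirnov group comparisons.
- **`abomics.assoc`** — covariate-adjusted (age, sex, 10 PCs) joint OLS
  of outcomes on haplotype dosages vs the O1 reference under additivity,
  blood-type contrasts vs O, Wald 95% CIs, Bonferroni families
  (0.05/4 traits, 0.05/13 metabolites, 0.05/21 species).
- **`abomics.mediation`** — Baron–Kenny path checks and quasi-Bayesian
  Monte-Carlo mediation: per parameter draw `ACME = a·b`, `ADE = c′`,
  `total = a·b + c′`, proportion mediated `ACME/total`.
- **`abomics.synthetic`** — a ground-truth cohort generator (genotypes
  under Hardy–Weinberg from a labelled haplotype pool, OGTT curves that
  realise planted log-trait effects exactly, zero-inflated compositional
  abundances, metabolites with an explicit exposure→mediator→outcome
  structural path) so every stage has a parameter-recovery test.

## Worked example

Generate the bundled demo cohort (n = 1000; a planted A1→lactate→ISI
mediation path with a = −0.092, b = −0.35, c′ = 0.10, hence total effect
0.1322 and proportion mediated 0.244) and run the analysis stages:

```python
from abomics.assoc import bonferroni_family, haplotype_regression
from abomics.haplotypes import default_panel, diplotype_posteriors, em_haplotype_frequencies
from abomics.mediation import mediate
from abomics.ogtt import back_transform_percent, compute_traits
from abomics.synthetic import demo_config, generate_cohort

cohort = generate_cohort(demo_config())
panel = default_panel()
freqs = em_haplotype_frequencies(cohort.genotypes, panel)
print(freqs.to_frame().head(5).to_string(index=False))
post = diplotype_posteriors(cohort.genotypes, freqs, panel)
print(f"unambiguous diplotypes: {100 * post.fraction_unambiguous:.1f}%")

traits = compute_traits(cohort.ogtt)
res = bonferroni_family(
    haplotype_regression(traits["log_isi"], post.dosages, cohort.covariates),
    family_size=4, family="traits",
)
print(res[["exposure", "beta", "ci_low", "ci_high", "p", "passes_bonferroni"]]
      .round(4).to_string(index=False))
a1 = res.set_index("exposure").loc["A1", "beta"]
print(f"A1 percent change in ISI: {back_transform_percent(a1)}%")

med = mediate(post.dosages["A1"], cohort.mediator_log, traits["log_isi"],
              cohort.covariates, n_sim=1000, seed=1)
print(f"ACME={med.acme:.4f}  ADE={med.ade:.4f}  total={med.total:.4f}  "
      f"proportion mediated={med.proportion:.3f}")
```

prints

```
haplotype  frequency        alleles
       O1   0.661661 C,C,G,delG,C,T
       A1   0.136839    C,C,G,G,T,C
       A2   0.069500    C,C,A,G,C,T
       O2   0.069339 T,C,G,delG,C,T
        B   0.062500    C,T,G,G,C,T
unambiguous diplotypes: 95.7%
exposure    beta  ci_low  ci_high      p  passes_bonferroni
      A1  0.0860  0.0466   0.1255 0.0000               True
      A2 -0.0271 -0.0816   0.0274 0.3303              False
       B -0.0143 -0.0710   0.0424 0.6209              False
      O2 -0.0185 -0.0717   0.0348 0.4967              False
A1 percent change in ISI: 9.0%
ACME=0.0345  ADE=0.0554  total=0.0899  proportion mediated=0.384
```

Reading the output: the EM frequencies recover the generating haplotype
pool (O1 0.68, A1 0.13, …) to sampling error; 95.7% of subjects have a
single diplotype consistent with their genotypes; the joint dosage
regression finds only the planted A1 effect on log-ISI (its β of 0.086
sits 2.3 SE below the planted total of 0.132 — one cohort's sampling
noise), back-transforming to a 9.0% higher ISI per A1 copy; and the
mediation decomposition attributes ~0.38 of that total effect to the
lactate path at this cohort's draw. `ACME + ADE = total` holds exactly
by construction.

The same analysis runs from the shell:

```bash
abomics run-all --out demo_run/ --seed 20220825
```

which writes every intermediate (VCF/CSV/TSV) plus `associations.csv`,
`mediation.csv` and a `manifest.json` with versions, seeds and input
checksums; identical seeds give byte-identical outputs.

## Layout

```
src/abomics/        library modules (+ bundled panel and demo config YAML)
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md     model and design notes
```
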