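# Demonstration synthetic cohort.
#
# The mediation path plants an A1 -> lactate -> ISI chain whose implied
# total effect on log-ISI is c' + a*b = 0.10 + 0.0322 = 0.1322 with
# proportion mediated 0.2436.  Noise scales give the association and
# screening stages realistic but well-powered conditions at n = 1000.
n_subjects: 1000
seed: 20220825
haplotype_freqs:
  O1: 0.68
  A1: 0.13
  A2: 0.068
  B: 0.060
  O2: 0.062
trait_effects: {}
trait_noise_sd: 0.3
covariate_effects:
  age: -0.005
  sex: -0.10
mediation:
  a: -0.092
  b: -0.35
  c_prime: 0.10
  noise_sd_m: 0.31
  noise_sd_y: 0.29
  exposure: A1
  mediator: lactate
  outcome_trait: isi
abundance:
  n_species: 21
covariates:
  age_mean: 60.0
  age_sd: 9.0
  male_fraction: 0.42
  n_pcs: 10
  pc_scale: 1.0
missing_rate: 0.0
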