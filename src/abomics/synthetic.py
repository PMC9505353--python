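"""Synthetic study-cohort generator with known ground truth.

Every downstream stage (haplotype EM, OGTT indices, CLR, association and
mediation models) has a planted-parameter recovery test against cohorts
generated here.  The generator emulates:

* **Genotypes** — each subject receives two haplotypes drawn i.i.d. from a
  labelled frequency pool (Hardy-Weinberg), default the common white-cohort
  pool {O1: 0.68, A1: 0.13, A2: 0.068, B: 0.060, O2: 0.062}; unphased
  counted-allele genotypes follow from the panel allele table.
* **OGTT trajectories** — target log-scale traits are drawn first
  (baseline + additive dosage effects + covariate effects + Gaussian
  noise), then glucose/insulin/C-peptide curves are constructed to realise
  those trait values *exactly* by inverting the index formulas (fixed
  glucose curve, insulin curve solved from ISI and secretion, C-peptide as
  a clearance-scaled insulin curve).
* **Microbiome** — zero-inflated log-normal abundances closed to sum 1.
* **Metabolites** — log-normal levels with an explicit structural mediator
  (default "lactate"): log M = a*X + eps_m and, on the outcome trait,
  log Y += c'*X + b*(log M deviation) + eps_y, so the planted proportion
  mediated is a*b / (a*b + c').
* **Covariates** — age, sex and ten stand-in genetic PCs, with small
  age/sex effects on every log trait so covariate adjustment is exercised.

Identical seeds regenerate bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .haplotypes import TagSNPPanel, default_panel
from .ogtt import OGTT_TIMES, TRAITS

__all__ = [
    "WHITE_HAPLOTYPE_FREQS",
    "METABOLITE_PANEL",
    "TARGET_SPECIES",
    "MediationSpec",
    "AbundanceSpec",
    "CovariateSpec",
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_genotypes",
    "generate_covariates",
    "generate_metabolites",
    "generate_ogtt",
    "generate_microbiome",
    "generate_cohort",
    "demo_config",
]

#: Common-haplotype pool frequencies for the white study cohort.
WHITE_HAPLOTYPE_FREQS = {"O1": 0.68, "A1": 0.13, "A2": 0.068, "B": 0.060, "O2": 0.062}

#: The 13 glucose-metabolism metabolites carried through the pipeline.
METABOLITE_PANEL = (
    "isoleucine",
    "leucine",
    "valine",
    "lactate",
    "glucose",
    "1,5-anhydroglucitol",
    "2-hydroxybutyrate",
    "N-lactoyl phenylalanine",
    "N-lactoyl tyrosine",
    "N-lactoyl valine",
    "N-lactoyl leucine",
    "N-lactoyl isoleucine",
    "metabolonic lactone sulfate",
)

#: The 21 target gut species (Bacteroides / Roseburia / Faecalibacterium /
#: Akkermansia) retained after the 30% prevalence filter.
TARGET_SPECIES = (
    "Bacteroides_caccae",
    "Bacteroides_cellulosilyticus",
    "Bacteroides_dorei",
    "Bacteroides_faecis",
    "Bacteroides_finegoldii",
    "Bacteroides_fragilis",
    "Bacteroides_galacturonicus",
    "Bacteroides_massiliensis",
    "Bacteroides_ovatus",
    "Bacteroides_stercoris",
    "Bacteroides_thetaiotaomicron",
    "Bacteroides_uniformis",
    "Bacteroides_vulgatus",
    "Bacteroides_xylanisolvens",
    "Faecalibacterium_prausnitzii",
    "Roseburia_faecis",
    "Roseburia_hominis",
    "Roseburia_intestinalis",
    "Roseburia_inulinivorans",
    "Roseburia_sp_CAG_471",
    "Akkermansia_muciniphila",
)

#: Typical raw trait baselines (Matsuda units; secretion uU/mL per mg/dL;
#: clearance ng/mL per uU/mL).  DI30 = ISI x secretion is implied.
TRAIT_BASELINES = {"isi": 4.0, "secretion": 0.25, "clearance": 0.15}

#: Fixed synthetic glucose curve (mg/dL at 0/30/120 min) shared by all
#: subjects; insulin and C-peptide are solved per subject from trait targets.
GLUCOSE_CURVE = (90.0, 150.0, 120.0)


@dataclass
class MediationSpec:
    """Planted exposure -> mediator -> outcome structural path (log scale)."""

    a: float = 0.4
    b: float = 0.3
    c_prime: float = 0.2
    noise_sd_m: float = 0.5
    noise_sd_y: float = 0.5
    exposure: str = "A1"
    mediator: str = "lactate"
    outcome_trait: str = "isi"

    def validate(self) -> None:
        if self.noise_sd_m <= 0 or self.noise_sd_y <= 0:
            raise ValueError("mediation noise sds must be positive")
        if self.outcome_trait not in TRAITS:
            raise ValueError(f"unknown outcome trait {self.outcome_trait!r}")

    @property
    def proportion_mediated(self) -> float:
        return self.a * self.b / (self.a * self.b + self.c_prime)


@dataclass
class AbundanceSpec:
    """Zero-inflated log-normal species abundance model."""

    n_species: int = 21
    species_names: tuple[str, ...] | None = None
    zero_inflation: float | tuple[float, ...] = ()
    log_mean: float | tuple[float, ...] = ()
    log_sd: float | tuple[float, ...] = 1.0

    def resolved(self) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")
        if self.species_names is not None:
            names = list(self.species_names)
            if len(names) != self.n_species:
                raise ValueError("species_names length must equal n_species")
        elif self.n_species == len(TARGET_SPECIES):
            names = list(TARGET_SPECIES)
        else:
            names = [f"Species_{k+1}" for k in range(self.n_species)]
        names = [n if n.startswith("s__") else f"s__{n}" for n in names]

        def expand(v, default):
            if isinstance(v, (tuple, list)) and len(v) == 0:
                return default
            arr = np.broadcast_to(np.asarray(v, dtype=float), (self.n_species,)).copy()
            return arr

        zi = expand(self.zero_inflation, np.linspace(0.0, 0.6, self.n_species))
        mu = expand(self.log_mean, np.linspace(-1.5, 1.5, self.n_species))
        sd = expand(self.log_sd, np.full(self.n_species, 1.0))
        if ((zi < 0) | (zi > 1)).any():
            raise ValueError("zero_inflation must lie in [0, 1]")
        if (sd <= 0).any():
            raise ValueError("log_sd must be positive")
        return names, zi, mu, sd


@dataclass
class CovariateSpec:
    """Age / sex / stand-in genetic PC generator settings."""

    age_mean: float = 60.0
    age_sd: float = 9.0
    male_fraction: float = 0.42
    n_pcs: int = 10
    pc_scale: float = 1.0

    def validate(self) -> None:
        if self.age_sd <= 0 or self.pc_scale <= 0:
            raise ValueError("covariate scales must be positive")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort."""

    n_subjects: int = 400
    seed: int = 0
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(WHITE_HAPLOTYPE_FREQS)
    )
    #: {(haplotype, trait): additive log-scale effect per dosage copy}
    trait_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    trait_noise_sd: float | dict[str, float] = 0.3
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.005, "sex": -0.10}
    )
    mediation: MediationSpec | None = field(default_factory=MediationSpec)
    abundance: AbundanceSpec = field(default_factory=AbundanceSpec)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype_freqs sum to {total}, not 1")
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ValueError("haplotype frequencies must be non-negative")
        for (hap, trait), _ in self.trait_effects.items():
            if trait not in TRAITS:
                raise ValueError(f"unknown trait {trait!r} in trait_effects")
        for trait in TRAITS:
            if self.noise_sd(trait) <= 0:
                raise ValueError("trait noise sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mediation is not None:
            self.mediation.validate()
        self.covariates.validate()

    def noise_sd(self, trait: str) -> float:
        if isinstance(self.trait_noise_sd, dict):
            return float(self.trait_noise_sd.get(trait, 0.3))
        return float(self.trait_noise_sd)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["trait_effects"] = {}
        for (hap, trait), eff in self.trait_effects.items():
            raw["trait_effects"].setdefault(hap, {})[trait] = eff
        for key in ("abundance",):
            spec = raw[key]
            for k, v in list(spec.items()):
                if isinstance(v, tuple):
                    spec[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        effects = {}
        for hap, per_trait in (raw.pop("trait_effects", {}) or {}).items():
            for trait, eff in per_trait.items():
                effects[(hap, trait)] = float(eff)
        med = raw.pop("mediation", "default")
        if med == "default":
            med_obj = MediationSpec()
        elif med is None:
            med_obj = None
        elif isinstance(med, MediationSpec):
            med_obj = med
        else:
            med_obj = MediationSpec(**med)
        ab = raw.pop("abundance", {}) or {}
        cov = raw.pop("covariates", {}) or {}
        if not isinstance(ab, AbundanceSpec):
            if "species_names" in ab and ab["species_names"] is not None:
                ab["species_names"] = tuple(ab["species_names"])
            for k in ("zero_inflation", "log_mean", "log_sd"):
                if isinstance(ab.get(k), list):
                    ab[k] = tuple(ab[k])
            ab = AbundanceSpec(**ab)
        if not isinstance(cov, CovariateSpec):
            cov = CovariateSpec(**cov)
        return cls(
            trait_effects=effects, mediation=med_obj, abundance=ab, covariates=cov, **raw
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a cohort."""

    diplotypes: list[tuple[str, str]]
    dosages: pd.DataFrame
    trait_effects: dict[tuple[str, str], float]
    mediation: MediationSpec | None

    @property
    def planted_proportion_mediated(self) -> float | None:
        if self.mediation is None:
            return None
        return self.mediation.proportion_mediated


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([stage, config.seed])


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{k+1:0{width}d}" for k in range(n)]


def generate_genotypes(
    config: CohortConfig, panel: TagSNPPanel | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw diplotypes under Hardy-Weinberg and emit unphased genotypes.

    Haplotype pairs are i.i.d. draws from ``config.haplotype_freqs``;
    per-SNP counted-allele counts follow from the panel allele table.  An
    optional ``missing_rate`` masks genotype entries at random.
    """
    panel = panel or default_panel()
    labels = list(config.haplotype_freqs)
    unknown = [lab for lab in labels if lab not in panel.haplotypes]
    if unknown:
        raise ValueError(f"haplotypes not in panel: {unknown}")
    probs = np.array([config.haplotype_freqs[lab] for lab in labels], dtype=float)
    rng = _rng(config, 1)
    n = config.n_subjects
    idx = rng.choice(len(labels), size=(n, 2), p=probs)
    bits = np.array([panel.bits(lab) for lab in labels], dtype=int)
    geno = bits[idx[:, 0]] + bits[idx[:, 1]]
    subjects = _subject_ids(n)
    genotypes = pd.DataFrame(geno, index=subjects, columns=panel.snp_ids, dtype=float)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.mask(mask)
    diplotypes = [(labels[i], labels[j]) for i, j in idx]
    dosage = np.zeros((n, len(labels)))
    for col in range(2):
        np.add.at(dosage, (np.arange(n), idx[:, col]), 1.0)
    dosages = pd.DataFrame(dosage, index=subjects, columns=labels)
    truth = SyntheticTruth(
        diplotypes=diplotypes,
        dosages=dosages,
        trait_effects=dict(config.trait_effects),
        mediation=config.mediation,
    )
    return genotypes, truth


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Age (years), sex (1 = male) and stand-in genetic PCs."""
    spec = config.covariates
    rng = _rng(config, 2)
    n = config.n_subjects
    data = {
        "age": rng.normal(spec.age_mean, spec.age_sd, size=n),
        "sex": (rng.random(n) < spec.male_fraction).astype(float),
    }
    for k in range(1, spec.n_pcs + 1):
        data[f"PC{k}"] = rng.normal(0.0, spec.pc_scale, size=n)
    return pd.DataFrame(data, index=_subject_ids(n))


def generate_metabolites(
    truth: SyntheticTruth, config: CohortConfig
) -> pd.DataFrame:
    """Metabolite levels with the planted structural mediator.

    All levels are log-normal; the mediator column (default "lactate")
    follows log M = a * dosage(exposure) + eps_m, so downstream log
    transformation recovers the structural equation exactly.  The
    remaining panel metabolites are independent noise.
    """
    rng = _rng(config, 3)
    n = config.n_subjects
    subjects = truth.dosages.index
    levels = {}
    med = config.mediation
    for name in METABOLITE_PANEL:
        log_level = rng.normal(0.0, 0.3, size=n)
        if med is not None and name == med.mediator:
            x = truth.dosages.get(med.exposure, pd.Series(0.0, index=subjects))
            log_level = med.a * x.to_numpy() + rng.normal(0.0, med.noise_sd_m, size=n)
        levels[name] = np.exp(log_level)
    if med is not None and med.mediator not in METABOLITE_PANEL:
        x = truth.dosages.get(med.exposure, pd.Series(0.0, index=subjects))
        levels[med.mediator] = np.exp(
            med.a * x.to_numpy() + rng.normal(0.0, med.noise_sd_m, size=n)
        )
    return pd.DataFrame(levels, index=subjects)


def _solve_curves(isi, secretion, clearance):
    """Invert the index formulas into positive OGTT curves.

    The glucose curve is fixed; insulin solves ISI and secretion exactly
    (one free degree of freedom pinned at the midpoint of its feasible
    range), and C-peptide is the clearance-scaled insulin curve.
    """
    g0, g30, g120 = GLUCOSE_CURVE
    g_mean = (g0 + g30 + g120) / 3.0
    auc_glu_30 = (g0 + g30) / 2.0 * 30.0
    isi = np.asarray(isi, dtype=float)
    secretion = np.asarray(secretion, dtype=float)
    clearance = np.asarray(clearance, dtype=float)
    # ISI fixes I0 * Ibar = K; secretion fixes I0 + I30 = c
    K = (10000.0 / isi) ** 2 / (g0 * g_mean)
    c = secretion * auc_glu_30 / 15.0
    i0 = 0.5 * np.minimum(c, 3.0 * K / c)
    i30 = c - i0
    i120 = 3.0 * K / i0 - c
    insulin = np.stack([i0, i30, i120], axis=-1)
    glucose = np.broadcast_to(GLUCOSE_CURVE, insulin.shape)
    cpeptide = clearance[..., None] * insulin
    return glucose, insulin, cpeptide


def generate_ogtt(
    truth: SyntheticTruth,
    config: CohortConfig,
    covariates: pd.DataFrame | None = None,
    mediator_log: pd.Series | None = None,
) -> pd.DataFrame:
    """OGTT trajectories realising planted log-scale trait targets exactly.

    Per-subject log targets for ISI, secretion and clearance are baseline
    plus dosage-weighted ``trait_effects``, covariate effects, the
    structural mediation terms (when ``mediator_log`` is supplied) and
    Gaussian noise; curves are then solved so the recomputed indices equal
    the targets to machine precision.  A planted DI30 effect is realised
    by shifting the log-ISI target, since DI30 = ISI x secretion is an
    identity with no independent degree of freedom.
    """
    rng = _rng(config, 4)
    n = config.n_subjects
    subjects = truth.dosages.index
    med = config.mediation
    targets = {}
    for trait in ("isi", "secretion", "clearance"):
        mu = np.log(TRAIT_BASELINES[trait]) * np.ones(n)
        for (hap, t), eff in config.trait_effects.items():
            if t != trait:
                continue
            mu += eff * truth.dosages.get(hap, pd.Series(0.0, index=subjects)).to_numpy()
        for (hap, t), eff in config.trait_effects.items():
            if t == "di30" and trait == "isi":
                mu += eff * truth.dosages.get(hap, pd.Series(0.0, index=subjects)).to_numpy()
        if covariates is not None:
            for cov, eff in config.covariate_effects.items():
                if cov not in covariates.columns:
                    continue
                col = covariates[cov].to_numpy(dtype=float)
                if cov == "age":
                    col = col - config.covariates.age_mean
                mu += eff * col
        sd = config.noise_sd(trait)
        if med is not None and trait == med.outcome_trait:
            x = truth.dosages.get(med.exposure, pd.Series(0.0, index=subjects)).to_numpy()
            mu += med.c_prime * x
            if mediator_log is not None:
                mu += med.b * mediator_log.reindex(subjects).to_numpy()
            sd = med.noise_sd_y
        targets[trait] = np.exp(mu + rng.normal(0.0, sd, size=n))
    glucose, insulin, cpeptide = _solve_curves(
        targets["isi"], targets["secretion"], targets["clearance"]
    )
    cols = {}
    for j, t in enumerate(OGTT_TIMES):
        cols[f"glucose_{int(t)}"] = glucose[:, j]
    for j, t in enumerate(OGTT_TIMES):
        cols[f"insulin_{int(t)}"] = insulin[:, j]
    for j, t in enumerate(OGTT_TIMES):
        cols[f"cpeptide_{int(t)}"] = cpeptide[:, j]
    return pd.DataFrame(cols, index=subjects)


def generate_microbiome(config: CohortConfig) -> pd.DataFrame:
    """Zero-inflated log-normal relative abundances closed to sum 1."""
    names, zi, mu, sd = config.abundance.resolved()
    rng = _rng(config, 5)
    n = config.n_subjects
    raw = np.exp(rng.normal(mu, sd, size=(n, len(names))))
    present = rng.random((n, len(names))) >= zi
    raw = raw * present
    # guard: an all-zero sample has no composition; re-draw presence
    for r in np.where(~present.any(axis=1))[0]:
        while not present[r].any():
            present[r] = rng.random(len(names)) >= zi
        raw[r] = np.exp(rng.normal(mu, sd, size=len(names))) * present[r]
    closed = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(closed, index=_subject_ids(n), columns=names)


@dataclass
class SyntheticCohort:
    """All generated inputs for one synthetic cohort plus its truth."""

    config: CohortConfig
    genotypes: pd.DataFrame
    truth: SyntheticTruth
    covariates: pd.DataFrame
    ogtt: pd.DataFrame
    metabolites: pd.DataFrame
    abundances: pd.DataFrame

    @property
    def mediator_log(self) -> pd.Series | None:
        med = self.config.mediation
        if med is None:
            return None
        return np.log(self.metabolites[med.mediator]).rename(med.mediator)


def generate_cohort(
    config: CohortConfig, panel: TagSNPPanel | None = None
) -> SyntheticCohort:
    """Generate the complete set of study inputs from one config/seed."""
    genotypes, truth = generate_genotypes(config, panel)
    covariates = generate_covariates(config)
    metabolites = generate_metabolites(truth, config)
    mediator_log = None
    if config.mediation is not None:
        mediator_log = np.log(metabolites[config.mediation.mediator])
    ogtt = generate_ogtt(truth, config, covariates=covariates, mediator_log=mediator_log)
    abundances = generate_microbiome(config)
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        truth=truth,
        covariates=covariates,
        ogtt=ogtt,
        metabolites=metabolites,
        abundances=abundances,
    )


def demo_config() -> CohortConfig:
    """The bundled demonstration cohort configuration."""
    from importlib import resources

    with resources.as_file(
        resources.files("abomics.data").joinpath("demo_config.yaml")
    ) as p:
        return CohortConfig.from_yaml(p)
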