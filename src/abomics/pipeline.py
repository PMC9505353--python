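"""End-to-end pipeline: simulate -> haplotypes -> traits -> microbiome ->
associate -> mediate, with inspectable CSV intermediates and a JSON manifest.

Every stage reads the previous stage's files back from disk, so a run
exercises the same readers/writers an external dataset would use.  Reruns
with an identical config and seed reproduce byte-identical outputs.  A
stage failure leaves a ``FAILED`` marker next to the partial outputs and
re-raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, io, mediation, microbiome, ogtt
from .haplotypes import (
    TagSNPPanel,
    default_panel,
    diplotype_posteriors,
    em_haplotype_frequencies,
    blood_type,
    panel_diagnostics,
)
from .synthetic import CohortConfig, generate_cohort

FAMILY_SIZES = {"traits": 4, "metabolites": 13, "species": 21}

__all__ = ["RunConfig", "run_all", "FAMILY_SIZES"]


@dataclass
class RunConfig:
    """Settings for a full synthetic-cohort pipeline run."""

    cohort: CohortConfig
    out_dir: Path
    panel: TagSNPPanel | None = None
    family_sizes: dict[str, int] = field(default_factory=lambda: dict(FAMILY_SIZES))
    reference_haplotype: str = "O1"
    freq_floor: float = 0.05
    prevalence: float = 0.30
    alpha: float = 0.05
    n_sim: int = 1000

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if any(v < 1 for v in self.family_sizes.values()):
            raise ValueError("family sizes must be positive")


def run_all(config: RunConfig) -> dict:
    """Run all six stages and return the manifest dictionary."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    panel = config.panel or default_panel()
    stages: list[str] = []
    inputs: dict[str, Path] = {}
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        # -- simulate -------------------------------------------------------
        cohort = generate_cohort(config.cohort, panel)
        io.write_vcf(cohort.genotypes, out / "genotypes.vcf", panel)
        io.write_counts_csv(cohort.genotypes, out / "genotypes.csv")
        io.write_table(cohort.ogtt, out / "ogtt.csv")
        io.write_table(cohort.metabolites, out / "metabolites.csv")
        io.write_table(cohort.covariates, out / "covariates.csv")
        io.write_metaphlan(cohort.abundances, out / "abundances.tsv")
        for name in ("genotypes.csv", "ogtt.csv", "metabolites.csv", "covariates.csv", "abundances.tsv"):
            inputs[name] = out / name
        stages.append("simulate")

        # -- haplotypes -----------------------------------------------------
        genotypes = io.read_counts_csv(out / "genotypes.csv")
        freqs = em_haplotype_frequencies(genotypes, panel)
        freqs.to_frame().to_csv(out / "haplotype_frequencies.csv", index=False)
        post = diplotype_posteriors(genotypes, freqs, panel)
        io.write_table(post.dosages, out / "dosages.csv")
        per_snp, r2 = panel_diagnostics(genotypes, panel)
        per_snp.to_csv(out / "snp_diagnostics.csv")
        r2.to_csv(out / "ld_r2.csv")
        bt = pd.Series(
            {
                s: blood_type(post.best_pair[s])
                for s in post.dosages.index
                if post.unambiguous[s]
            },
            name="blood_type",
        )
        bt.to_frame().to_csv(out / "blood_types.csv", index_label="subject")
        stages.append("haplotypes")

        # -- traits ---------------------------------------------------------
        ogtt_table = io.read_table(out / "ogtt.csv")
        traits = ogtt.compute_traits(ogtt_table)
        io.write_table(traits, out / "traits.csv")
        stages.append("traits")

        # -- microbiome -----------------------------------------------------
        profile = io.read_metaphlan(out / "abundances.tsv")
        filtered, report = microbiome.prevalence_filter(profile, config.prevalence)
        report.to_csv(out / "prevalence_report.csv")
        clr = microbiome.clr_transform(profile, species=list(filtered.columns))
        io.write_table(clr.values, out / "clr.csv")
        stages.append("microbiome")

        # -- associate ------------------------------------------------------
        dosages = io.read_table(out / "dosages.csv")
        covars = io.read_table(out / "covariates.csv")
        traits_tbl = io.read_table(out / "traits.csv")
        metab = io.read_table(out / "metabolites.csv")
        clr_tbl = io.read_table(out / "clr.csv")
        log_metab = np.log(metab)
        families = [
            ("traits", traits_tbl[[c for c in traits_tbl.columns if c.startswith("log_")]]),
            ("metabolites", log_metab),
            ("species", clr_tbl),
        ]
        results = []
        for family, table in families:
            fam_results = []
            for col in table.columns:
                fam_results.append(
                    assoc.haplotype_regression(
                        table[col],
                        dosages,
                        covars,
                        reference=config.reference_haplotype,
                        freq_floor=config.freq_floor,
                    )
                )
            fam = pd.concat(fam_results, ignore_index=True)
            results.append(
                assoc.bonferroni_family(fam, config.family_sizes[family], family)
            )
        assoc_results = pd.concat(results, ignore_index=True)
        assoc_results.to_csv(out / "associations.csv", index=False)
        stages.append("associate")

        # -- mediate --------------------------------------------------------
        # follow up only Bonferroni-significant trait associations, one
        # (strongest) outcome per exposure
        med_spec = config.cohort.mediation
        fam_assoc = assoc_results[
            (assoc_results["family"] == "traits") & assoc_results["passes_bonferroni"]
        ]
        trait_hits = (
            fam_assoc.sort_values("p", kind="mergesort").groupby("exposure", sort=False).head(1)
        )
        mediators = pd.concat([log_metab, clr_tbl], axis=1, join="inner")
        screens = []
        seed = config.cohort.seed
        for _, hit in trait_hits.iterrows():
            exposure = dosages[hit["exposure"]]
            outcome = traits_tbl[hit["outcome"]]
            screened = mediation.mediation_screen(
                exposure,
                mediators,
                outcome,
                covars,
                alpha=config.alpha,
                n_sim=config.n_sim,
                seed=seed,
            )
            screens.append(screened[screened["survived"]])
        if screens:
            mediation_results = pd.concat(screens, ignore_index=True)
        else:
            mediation_results = pd.DataFrame(
                columns=["exposure", "mediator", "outcome", "survived"]
            )
        mediation_results.to_csv(out / "mediation.csv", index=False)
        stages.append("mediate")
        if med_spec is not None:
            pd.DataFrame(
                [
                    {
                        "exposure": med_spec.exposure,
                        "mediator": med_spec.mediator,
                        "outcome_trait": med_spec.outcome_trait,
                        "planted_proportion": med_spec.proportion_mediated,
                    }
                ]
            ).to_csv(out / "planted_truth.csv", index=False)
    except Exception:
        marker.write_text("pipeline failed after stages: " + ", ".join(stages) + "\n")
        raise

    return io.write_manifest(
        out / "manifest.json",
        stages,
        inputs,
        seeds={"cohort": config.cohort.seed},
    )
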