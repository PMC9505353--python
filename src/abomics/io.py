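"""Readers and writers for the pipeline's exchange formats.

Genotypes cross the package boundary as VCF 4.2 (unphased GT, one record
per panel SNP) or as allele-count CSV; OGTT, trait, metabolite, covariate
and dosage tables as headered CSV; abundance profiles as MetaPhlAn-style
TSV (clade rows, ``s__``-prefixed species, percentages or proportions
auto-detected from column sums); configs as YAML; run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import TagSNPPanel, default_panel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_counts_csv",
    "read_counts_csv",
    "write_table",
    "read_table",
    "write_metaphlan",
    "read_metaphlan",
    "file_sha256",
    "write_manifest",
]


def write_vcf(genotypes: pd.DataFrame, path, panel: TagSNPPanel | None = None) -> None:
    """Write counted-allele genotypes as an unphased VCF 4.2 text file.

    Each panel SNP becomes one record with ALT = the counted allele
    (rs8176645's counted delG is encoded as the TG>T deletion).  Counts of
    0/1/2 map to GT 0/0, 0/1, 1/1; missing counts to ./. .
    """
    panel = panel or default_panel()
    path = Path(path)
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=abomics",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for snp in panel.snps:
        if snp.vcf_ref is None or snp.vcf_alt is None:
            raise ValueError(f"panel SNP {snp.id} lacks VCF REF/ALT encoding")
        col = genotypes[snp.id]
        gts = []
        for v in col:
            if pd.isna(v):
                gts.append("./.")
            else:
                gts.append(gt_map[int(v)])
        lines.append(
            "\t".join(
                [snp.chrom, str(snp.pos), snp.id, snp.vcf_ref, snp.vcf_alt, ".", "PASS", ".", "GT"]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path, panel: TagSNPPanel | None = None) -> pd.DataFrame:
    """Read counted-allele counts for the panel SNPs from a VCF.

    Records are matched by SNP id; REF/ALT must agree with the panel's
    encoding in either orientation (the counted allele may sit on REF in
    externally produced files).  Returns subjects x SNPs counts with NaN
    for missing calls.
    """
    from cyvcf2 import VCF

    panel = panel or default_panel()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data = {s.id: [np.nan] * len(samples) for s in panel.snps}
    by_id = {s.id: s for s in panel.snps}
    for variant in vcf:
        snp = by_id.get(variant.ID)
        if snp is None:
            continue
        alt = variant.ALT[0] if variant.ALT else None
        if variant.REF == snp.vcf_ref and alt == snp.vcf_alt:
            counted_is_alt = True
        elif variant.REF == snp.vcf_alt and alt == snp.vcf_ref:
            counted_is_alt = False
        else:
            raise ValueError(
                f"{snp.id}: VCF alleles {variant.REF}>{alt} do not match panel "
                f"encoding {snp.vcf_ref}>{snp.vcf_alt}"
            )
        counts = data[snp.id]
        for k, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                counts[k] = np.nan
            else:
                n_alt = sum(1 for a in alleles if a > 0)
                counts[k] = float(n_alt if counted_is_alt else len(alleles) - n_alt)
    vcf.close()
    return pd.DataFrame(data, index=samples, columns=[s.id for s in panel.snps])


def write_counts_csv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index_label="subject")


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


def write_table(table: pd.DataFrame, path, index_label: str = "subject") -> None:
    table.to_csv(path, index_label=index_label)


def read_table(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_metaphlan(abundances: pd.DataFrame, path) -> None:
    """Write a samples x species table as a MetaPhlAn-style merged TSV.

    Rows are ``s__``-prefixed clades, columns samples, values percentages
    (rows of the input are proportions summing to 1).
    """
    out = abundances.T * 100.0
    out.index = [c if str(c).startswith("s__") else f"s__{c}" for c in out.index]
    out.index.name = "#clade_name"
    out.to_csv(path, sep="\t")


def read_metaphlan(path) -> pd.DataFrame:
    """Read a MetaPhlAn-style TSV into a samples x species proportion table.

    Keeps species-level clades (``s__`` present, no ``t__`` suffix) and
    auto-detects percentages vs proportions from column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    idx = df.index.astype(str)
    keep = idx.str.contains("s__") & ~idx.str.contains("t__")
    df = df.loc[keep]
    if df.empty:
        raise ValueError("no species-level clades found in profile")
    df.index = [name[name.rindex("s__") :] if "s__" in name else name for name in df.index.astype(str)]
    table = df.T.astype(float)
    if table.sum(axis=1).max() > 1.5:  # percentages
        table = table / 100.0
    return table


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stages, inputs, seeds) -> dict:
    """JSON run manifest: package/library versions, seeds, input checksums."""
    import scipy
    import statsmodels

    import abomics

    manifest = {
        "package": {"name": "abomics", "version": abomics.__version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seeds": seeds,
        "stages": stages,
        "inputs": {str(k): file_sha256(v) for k, v in inputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
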