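# Six-SNP ABO tagging panel.
#
# `counted` is the haplotype-tagging allele counted 0/1/2 in genotype
# matrices.  rs8176645 stands in for the rs8176719 O1 frameshift (LD 0.98)
# and rs600038 for rs579459 (LD 0.99); the counted delG allele of rs8176645
# is encoded in VCF as the single-base deletion TG>T.  Positions are nominal
# GRCh37-style coordinates used for writing synthetic VCFs.
snps:
  - id: rs41302905
    counted: T
    other: C
    chrom: "9"
    pos: 136131415
    vcf_ref: C
    vcf_alt: T
  - id: rs8176743
    counted: T
    other: C
    chrom: "9"
    pos: 136131461
    vcf_ref: C
    vcf_alt: T
  - id: rs1053878
    counted: A
    other: G
    chrom: "9"
    pos: 136131651
    vcf_ref: G
    vcf_alt: A
  - id: rs8176645
    counted: delG
    other: G
    chrom: "9"
    pos: 136132908
    vcf_ref: TG
    vcf_alt: T
    tags_for: rs8176719
    ld_with_original: 0.98
  - id: rs2519093
    counted: T
    other: C
    chrom: "9"
    pos: 136141870
    vcf_ref: C
    vcf_alt: T
  - id: rs600038
    counted: C
    other: T
    chrom: "9"
    pos: 136149399
    vcf_ref: T
    vcf_alt: C
    tags_for: rs579459
    ld_with_original: 0.99

# One allele per panel SNP, in the SNP order above.  O2 is an O1 point
# variant defined by rs41302905-T; its remaining alleles follow the O1
# pattern.
haplotypes:
  O1: [C, C, G, delG, C, T]
  O2: [T, C, G, delG, C, T]
  A1: [C, C, G, G, T, C]
  A2: [C, C, A, G, C, T]
  B:  [C, T, G, G, C, T]
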