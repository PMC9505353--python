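"""ABO tag-SNP panel, EM haplotype-frequency estimation, and diplotypes.

The ABO blood group is tagged by six SNPs at the *ABO* locus; each common
haplotype (O1, O2, A1, A2, B) is a fixed allele vector over those SNPs.
Unphased genotypes (per-SNP counts of the tagging allele) leave the pair of
haplotypes carried by a subject ambiguous whenever two or more panel SNPs
are heterozygous.  This module estimates population haplotype frequencies
by expectation-maximisation over the phase-enumeration likelihood, computes
per-subject diplotype posteriors and expected haplotype dosages, maps
diplotypes to serological blood types, and provides the standard panel
diagnostics (minor-allele frequency, exact Hardy-Weinberg test, pairwise
LD r^2 from two-SNP phased frequencies).

Genotype matrices are pandas DataFrames with one row per subject and one
column per panel SNP, holding counts in {0, 1, 2} of the counted
(haplotype-tagging) allele, with NaN for missing calls.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

UNKNOWN = "unknown"

__all__ = [
    "TagSNP",
    "TagSNPPanel",
    "HaplotypeFrequencies",
    "DiplotypePosterior",
    "default_panel",
    "classify_haplotype",
    "em_haplotype_frequencies",
    "brute_force_frequencies",
    "diplotype_posteriors",
    "blood_type",
    "bloodtype_counts",
    "apply_frequency_floor",
    "hwe_exact_test",
    "panel_diagnostics",
    "ld_r_squared",
]


@dataclass(frozen=True)
class TagSNP:
    """A biallelic panel SNP; ``counted`` is the allele counted 0/1/2."""

    id: str
    counted: str
    other: str
    chrom: str = "9"
    pos: int = 0
    vcf_ref: str | None = None
    vcf_alt: str | None = None
    tags_for: str | None = None
    ld_with_original: float | None = None

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.other, self.counted)


@dataclass
class TagSNPPanel:
    """Ordered tag SNPs plus the haplotype-defining allele table.

    ``haplotypes`` maps a haplotype label to one allele per SNP, in panel
    SNP order.  Labels must be unique and allele vectors distinct.
    """

    snps: list[TagSNP]
    haplotypes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")
        seen: dict[tuple[str, ...], str] = {}
        for label, alleles in self.haplotypes.items():
            alleles = tuple(alleles)
            self.haplotypes[label] = alleles
            if len(alleles) != len(self.snps):
                raise ValueError(
                    f"haplotype {label!r} has {len(alleles)} alleles, "
                    f"panel has {len(self.snps)} SNPs"
                )
            for snp, a in zip(self.snps, alleles):
                if a not in snp.alleles:
                    raise ValueError(
                        f"haplotype {label!r}: allele {a!r} not in "
                        f"{snp.id} allele set {snp.alleles}"
                    )
            if alleles in seen:
                raise ValueError(
                    f"haplotypes {seen[alleles]!r} and {label!r} share an allele vector"
                )
            seen[alleles] = label
        self._by_bits = {self.bits(label): label for label in self.haplotypes}

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def bits(self, label: str) -> tuple[int, ...]:
        """Counted-allele indicator vector of a haplotype."""
        alleles = self.haplotypes[label]
        return tuple(int(a == s.counted) for s, a in zip(self.snps, alleles))

    def alleles_for_bits(self, bits: Sequence[int]) -> tuple[str, ...]:
        return tuple(s.counted if b else s.other for s, b in zip(self.snps, bits))

    def classify(self, allele_vector: Sequence[str]) -> str:
        """Match an allele vector against the haplotype table.

        Returns the haplotype label, or ``"unknown"`` when no row matches.
        Raises ``ValueError`` for an allele outside a SNP's allele set or a
        vector of the wrong length.
        """
        if len(allele_vector) != len(self.snps):
            raise ValueError(
                f"expected {len(self.snps)} alleles, got {len(allele_vector)}"
            )
        for snp, a in zip(self.snps, allele_vector):
            if a not in snp.alleles:
                raise ValueError(f"allele {a!r} not in {snp.id} allele set {snp.alleles}")
        return self._by_bits.get(
            tuple(int(a == s.counted) for s, a in zip(self.snps, allele_vector)),
            UNKNOWN,
        )

    def label_for_bits(self, bits: tuple[int, ...]) -> str:
        """Unique label for a haplotype bit vector.

        Known haplotypes keep their panel label; unmatched vectors get a
        label of the form ``unknown[C,C,G,G,C,T]`` so that distinct residual
        haplotypes remain distinguishable in frequency tables.
        """
        label = self._by_bits.get(bits)
        if label is not None:
            return label
        return f"{UNKNOWN}[{','.join(self.alleles_for_bits(bits))}]"

    @classmethod
    def from_yaml(cls, path) -> "TagSNPPanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        subs = raw.get("tag_substitutions", {})
        snps = []
        for entry in raw["snps"]:
            sub = subs.get(entry["id"], {})
            snps.append(
                TagSNP(
                    id=entry["id"],
                    counted=str(entry["counted"]),
                    other=str(entry["other"]),
                    chrom=str(entry.get("chrom", "9")),
                    pos=int(entry.get("pos", 0)),
                    vcf_ref=entry.get("vcf_ref"),
                    vcf_alt=entry.get("vcf_alt"),
                    tags_for=entry.get("tags_for", sub.get("original")),
                    ld_with_original=entry.get("ld_with_original", sub.get("ld")),
                )
            )
        haps = {label: tuple(map(str, v)) for label, v in raw["haplotypes"].items()}
        return cls(snps=snps, haplotypes=haps)


def default_panel() -> TagSNPPanel:
    """The bundled six-SNP ABO tagging panel."""
    with resources.as_file(
        resources.files("abomics.data").joinpath("abo_panel.yaml")
    ) as p:
        return TagSNPPanel.from_yaml(p)


def classify_haplotype(allele_vector: Sequence[str], panel: TagSNPPanel | None = None) -> str:
    """Label an allele vector using the (default) panel's haplotype table."""
    panel = panel or default_panel()
    return panel.classify(allele_vector)


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation
# ---------------------------------------------------------------------------

Bits = tuple[int, ...]


def _consistent_pairs(geno: tuple[int, ...]) -> list[tuple[Bits, Bits]]:
    """All unordered haplotype pairs consistent with an unphased genotype."""
    het = [i for i, g in enumerate(geno) if g == 1]
    base = [1 if g == 2 else 0 for g in geno]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first heterozygous site on haplotype 1 to avoid duplicates
    for assign in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = list(base)
        h2 = list(base)
        h1[het[0]] = 1
        for site, bit in zip(het[1:], assign):
            h1[site] = bit
            h2[site] = 1 - bit
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.append(pair)
    return pairs


def _prepare_patterns(G: np.ndarray):
    """Group genotype rows into patterns with consistent-pair indices."""
    patterns = Counter(map(tuple, G))
    hap_index: dict[Bits, int] = {}
    pattern_pairs = []
    for geno, count in patterns.items():
        idx_pairs = []
        for h1, h2 in _consistent_pairs(geno):
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            idx_pairs.append((hap_index[h1], hap_index[h2]))
        pattern_pairs.append((count, idx_pairs))
    haps = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    return pattern_pairs, haps


def _complete_rows(genotypes: pd.DataFrame, panel: TagSNPPanel | None) -> np.ndarray:
    if panel is not None:
        missing_cols = [s for s in panel.snp_ids if s not in genotypes.columns]
        if missing_cols:
            raise ValueError(f"genotype matrix lacks panel SNPs: {missing_cols}")
        genotypes = genotypes[panel.snp_ids]
    arr = genotypes.to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    if arr.size and not np.isin(arr, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype counts must be 0, 1 or 2")
    return arr.astype(int)


def _phase_loglik(freqs: np.ndarray, pattern_pairs) -> float:
    ll = 0.0
    for count, idx_pairs in pattern_pairs:
        s = 0.0
        for i, j in idx_pairs:
            w = freqs[i] * freqs[j]
            s += 2.0 * w if i != j else w
        ll += count * math.log(max(s, 1e-300))
    return ll


@dataclass
class HaplotypeFrequencies:
    """EM-estimated haplotype frequencies for a cohort.

    ``frequencies`` maps labels (panel labels, plus ``unknown[...]`` for
    residual vectors) to frequencies summing to 1; ``alleles`` gives each
    label's allele vector when a panel was supplied.
    """

    frequencies: dict[str, float]
    alleles: dict[str, tuple[str, ...]]
    log_likelihood: float
    n_iter: int
    converged: bool
    n_subjects: int
    bits: dict[str, Bits] = field(default_factory=dict, repr=False)

    def frequency(self, label: str) -> float:
        return self.frequencies.get(label, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype": label,
                "frequency": f,
                "alleles": ",".join(self.alleles.get(label, ())),
            }
            for label, f in sorted(
                self.frequencies.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(rows)


def _label_freqs(
    freqs: np.ndarray, haps: list[Bits], panel: TagSNPPanel | None
) -> tuple[dict[str, float], dict[str, tuple[str, ...]], dict[str, Bits]]:
    out: dict[str, float] = {}
    alleles: dict[str, tuple[str, ...]] = {}
    bits: dict[str, Bits] = {}
    for h, f in zip(haps, freqs):
        if panel is not None:
            label = panel.label_for_bits(h)
            alleles[label] = panel.alleles_for_bits(h)
        else:
            label = "".join(map(str, h))
        out[label] = float(f)
        bits[label] = h
    return out, alleles, bits


def em_haplotype_frequencies(
    genotypes: pd.DataFrame,
    panel: TagSNPPanel | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFrequencies:
    """Maximum-likelihood haplotype frequencies from unphased genotypes.

    Subjects with any missing panel SNP are excluded (complete-case).  The
    EM starts from a uniform distribution over all haplotypes consistent
    with at least one subject and iterates the standard phase-posterior
    E-step / frequency-counting M-step until the largest frequency change
    falls below ``tol``.  The log-likelihood is asserted non-decreasing at
    every iteration; hitting ``max_iter`` sets ``converged=False`` with a
    warning rather than failing.
    """
    G = _complete_rows(genotypes, panel)
    if G.shape[0] == 0:
        raise ValueError("no subjects with complete genotypes")
    pattern_pairs, haps = _prepare_patterns(G)
    n = G.shape[0]
    k = len(haps)
    freqs = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(k)
        ll = 0.0
        for count, idx_pairs in pattern_pairs:
            ws = []
            for i, j in idx_pairs:
                w = freqs[i] * freqs[j]
                ws.append(2.0 * w if i != j else w)
            s = sum(ws)
            ll += count * math.log(max(s, 1e-300))
            if s <= 0.0:
                continue
            for (i, j), w in zip(idx_pairs, ws):
                post = count * w / s
                counts[i] += post
                counts[j] += post
        if ll < prev_ll - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}) at iteration {it}"
            )
        new = counts / (2.0 * n)
        delta = float(np.max(np.abs(new - freqs)))
        freqs = new
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"haplotype EM did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    frequencies, alleles, bits = _label_freqs(freqs, haps, panel)
    return HaplotypeFrequencies(
        frequencies=frequencies,
        alleles=alleles,
        log_likelihood=_phase_loglik(freqs, pattern_pairs),
        n_iter=it,
        converged=converged,
        n_subjects=n,
        bits=bits,
    )


def brute_force_frequencies(
    genotypes: pd.DataFrame,
    panel: TagSNPPanel | None = None,
    n_starts: int = 4,
    seed: int = 0,
) -> HaplotypeFrequencies:
    """Direct numerical maximisation of the phase-enumeration likelihood.

    Independent of the EM path: the frequency simplex is parameterised by a
    softmax and the log-likelihood maximised with quasi-Newton iterations
    from several starts.  Intended for small instances (few SNPs/subjects)
    as a cross-check of :func:`em_haplotype_frequencies`.
    """
    G = _complete_rows(genotypes, panel)
    if G.shape[0] == 0:
        raise ValueError("no subjects with complete genotypes")
    pattern_pairs, haps = _prepare_patterns(G)
    k = len(haps)
    if k == 1:
        freqs = np.array([1.0])
    else:
        rng = np.random.default_rng(seed)

        def negll(z: np.ndarray) -> float:
            z = z - z.max()
            p = np.exp(z)
            p /= p.sum()
            return -_phase_loglik(p, pattern_pairs)

        best = None
        starts = [np.zeros(k)] + [rng.normal(scale=2.0, size=k) for _ in range(n_starts - 1)]
        for z0 in starts:
            res = optimize.minimize(negll, z0, method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        z = best.x - best.x.max()
        freqs = np.exp(z)
        freqs /= freqs.sum()
    frequencies, alleles, bits = _label_freqs(freqs, haps, panel)
    return HaplotypeFrequencies(
        frequencies=frequencies,
        alleles=alleles,
        log_likelihood=_phase_loglik(freqs, pattern_pairs),
        n_iter=0,
        converged=True,
        n_subjects=G.shape[0],
        bits=bits,
    )


# ---------------------------------------------------------------------------
# Diplotype posteriors and blood types
# ---------------------------------------------------------------------------


@dataclass
class DiplotypePosterior:
    """Per-subject diplotype distributions under given haplotype frequencies.

    ``posteriors`` maps a subject id to ``[((label1, label2), prob), ...]``
    sorted by decreasing probability; ``dosages`` holds posterior-expected
    haplotype counts (rows sum to 2); ``unambiguous`` marks subjects whose
    genotype admits exactly one diplotype with nonzero posterior (or whose
    top posterior reaches the configured threshold).  ``excluded`` lists
    subjects dropped for incomplete or frequency-inconsistent genotypes.
    """

    posteriors: dict
    dosages: pd.DataFrame
    unambiguous: pd.Series
    best_pair: dict
    excluded: list

    @property
    def fraction_unambiguous(self) -> float:
        if len(self.unambiguous) == 0:
            return float("nan")
        return float(self.unambiguous.mean())


def diplotype_posteriors(
    genotypes: pd.DataFrame,
    freqs: HaplotypeFrequencies,
    panel: TagSNPPanel | None = None,
    posterior_threshold: float = 1.0,
) -> DiplotypePosterior:
    """Posterior diplotype distributions and expected haplotype dosages.

    For each subject the posterior over haplotype pairs consistent with the
    genotype is proportional to ``f(h1) * f(h2)``, doubled for heterozygous
    pairs.  With ``posterior_threshold=1.0`` a subject is unambiguous only
    when exactly one consistent pair has nonzero posterior (the hard
    criterion); smaller thresholds flag subjects whose top posterior
    reaches the threshold.
    """
    if panel is not None:
        genotypes = genotypes[panel.snp_ids]
    arr = genotypes.to_numpy(dtype=float)
    labels = sorted(freqs.frequencies)
    bits_to_label = {b: lab for lab, b in freqs.bits.items()}
    freq_by_bits = {b: freqs.frequencies[lab] for lab, b in freqs.bits.items()}

    posteriors: dict = {}
    best: dict = {}
    unamb: dict = {}
    excluded: list = []
    dosage_rows: dict = {}

    for subj, row in zip(genotypes.index, arr):
        if np.isnan(row).any():
            excluded.append(subj)
            continue
        geno = tuple(int(g) for g in row)
        pairs = _consistent_pairs(geno)
        weights = []
        for h1, h2 in pairs:
            f1 = freq_by_bits.get(h1, 0.0)
            f2 = freq_by_bits.get(h2, 0.0)
            w = f1 * f2 * (2.0 if h1 != h2 else 1.0)
            weights.append(w)
        total = sum(weights)
        if total <= 0.0:
            excluded.append(subj)
            continue
        dist = []
        dos = dict.fromkeys(labels, 0.0)
        for (h1, h2), w in zip(pairs, weights):
            p = w / total
            if p == 0.0:
                continue
            lab1 = bits_to_label.get(h1)
            lab2 = bits_to_label.get(h2)
            dist.append(((lab1, lab2), p))
            dos[lab1] += p
            dos[lab2] += p
        dist.sort(key=lambda kv: -kv[1])
        posteriors[subj] = dist
        best[subj] = dist[0][0]
        if posterior_threshold >= 1.0:
            unamb[subj] = len(dist) == 1
        else:
            unamb[subj] = dist[0][1] >= posterior_threshold
        dosage_rows[subj] = dos

    dosages = pd.DataFrame.from_dict(dosage_rows, orient="index", columns=labels)
    dosages = dosages.reindex(columns=labels).fillna(0.0)
    return DiplotypePosterior(
        posteriors=posteriors,
        dosages=dosages,
        unambiguous=pd.Series(unamb, dtype=bool),
        best_pair=best,
        excluded=excluded,
    )


_ABO_GROUP = {"O1": "O", "O2": "O", "A1": "A", "A2": "A", "B": "B"}


def blood_type(diplotype: tuple[str, str]) -> str | None:
    """Serological blood type implied by a diplotype.

    A and B are dominant over O; A together with B gives AB.  Returns
    ``None`` when either haplotype is not one of {O1, O2, A1, A2, B}
    (e.g. an unknown residual haplotype), in which case the subject is
    excluded from blood-type analyses.
    """
    groups = set()
    for h in diplotype:
        g = _ABO_GROUP.get(h)
        if g is None:
            return None
        groups.add(g)
    if {"A", "B"} <= groups:
        return "AB"
    if "A" in groups:
        return "A"
    if "B" in groups:
        return "B"
    return "O"


def bloodtype_counts(diplotypes: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Count subjects per blood type, skipping untypeable diplotypes."""
    counts = {"O": 0, "A": 0, "B": 0, "AB": 0}
    for d in diplotypes:
        bt = blood_type(d)
        if bt is not None:
            counts[bt] += 1
    return counts


def apply_frequency_floor(
    freqs: HaplotypeFrequencies, floor: float = 0.05
) -> list[str]:
    """Labels of haplotypes at or above the retention frequency floor."""
    return [lab for lab, f in freqs.frequencies.items() if f >= floor]


# ---------------------------------------------------------------------------
# Panel diagnostics: MAF, exact HWE, LD r^2
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom_1: int, n_hom_2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the Levene-Haldane probabilities of all heterozygote counts (with
    the observed rare-allele total) no more probable than the observed one.
    Mid-p correction is off.  A monomorphic site returns p = 1.
    """
    for v in (n_het, n_hom_1, n_hom_2):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_1 + n_hom_2
    if n == 0:
        raise ValueError("no genotyped subjects")
    rare = 2 * min(n_hom_1, n_hom_2) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0

    lf = math.lgamma

    def logprob(x: int) -> float:
        # P(n_het = x | n, rare) on the conditional distribution
        return (
            x * math.log(2.0)
            + lf(n + 1)
            - lf((rare - x) // 2 + 1)
            - lf(x + 1)
            - lf(n - (rare + x) // 2 + 1)
            + lf(rare + 1)
            + lf(2 * n - rare + 1)
            - lf(2 * n + 1)
        )

    xs = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = {x: logprob(x) for x in xs}
    obs = logs[n_het]
    p = sum(math.exp(l) for l in logs.values() if l <= obs + 1e-12)
    return min(1.0, p)


def ld_r_squared(col_a: pd.Series, col_b: pd.Series) -> float:
    """Pairwise LD r^2 from EM-phased two-SNP haplotype frequencies.

    Undefined (NaN) when either SNP is monomorphic among complete pairs.
    """
    df = pd.concat([col_a, col_b], axis=1).dropna()
    if df.empty:
        return float("nan")
    arr = df.to_numpy()
    if len(np.unique(arr[:, 0])) < 2 or len(np.unique(arr[:, 1])) < 2:
        return float("nan")
    res = em_haplotype_frequencies(df, panel=None)
    f = {b: res.frequencies[lab] for lab, b in res.bits.items()}
    p_a = f.get((1, 0), 0.0) + f.get((1, 1), 0.0)
    p_b = f.get((0, 1), 0.0) + f.get((1, 1), 0.0)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0.0:
        return float("nan")
    d = f.get((1, 1), 0.0) - p_a * p_b
    return float(d * d / denom)


def panel_diagnostics(
    genotypes: pd.DataFrame, panel: TagSNPPanel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP MAF and exact HWE p, plus the pairwise LD r^2 matrix.

    MAF is the folded counted-allele frequency (always in [0, 0.5]).
    Monomorphic SNPs report MAF 0, HWE p = 1 and missing r^2.
    """
    if panel is not None:
        genotypes = genotypes[panel.snp_ids]
    rows = []
    for snp in genotypes.columns:
        col = genotypes[snp].dropna()
        vals = col.to_numpy(dtype=float)
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError(f"invalid genotype counts at {snp}")
        n = len(vals)
        if n == 0:
            rows.append({"snp": snp, "n": 0, "maf": np.nan, "hwe_p": np.nan})
            continue
        alt = float(vals.sum()) / (2 * n)
        maf = min(alt, 1 - alt)
        n_het = int((vals == 1).sum())
        n_hom_ref = int((vals == 0).sum())
        n_hom_alt = int((vals == 2).sum())
        rows.append(
            {
                "snp": snp,
                "n": n,
                "maf": maf,
                "hwe_p": hwe_exact_test(n_het, n_hom_alt, n_hom_ref),
            }
        )
    per_snp = pd.DataFrame(rows).set_index("snp")

    cols = list(genotypes.columns)
    r2 = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        r2.loc[a, a] = 1.0 if per_snp.loc[a, "maf"] > 0 else np.nan
        for b in cols[i + 1 :]:
            val = ld_r_squared(genotypes[a], genotypes[b])
            r2.loc[a, b] = val
            r2.loc[b, a] = val
    return per_snp, r2
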