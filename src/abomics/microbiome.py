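"""Prevalence filtering, CLR transformation and KS comparison of species tables.

Relative-abundance tables are pandas DataFrames with one row per sample and
one column per species (MetaPhlAn-style ``s__`` names are accepted and
matched after stripping taxonomic prefixes).  Species-level profiles are
zero-heavy, so species are first filtered on the fraction of samples in
which they are non-zero; the retained columns are then centred-log-ratio
(CLR) transformed with the geometric mean of the sample's *full*
species-level composition as denominator, computed before subsetting to the
analysis species.  Zeros are replaced by a multiplicative pseudocount (half
the smallest non-zero abundance within the sample) before taking logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLRTable",
    "prevalence_filter",
    "clr_transform",
    "ks_compare",
    "strip_taxonomy",
]


def strip_taxonomy(name: str) -> str:
    """Species name after the last taxonomic prefix (``...|s__X`` -> ``X``)."""
    tail = name.split("|")[-1]
    if tail.startswith("s__"):
        return tail[3:]
    return tail


def _validate(table: pd.DataFrame, proportions: bool = True) -> None:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty abundance table")
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    if proportions and (arr.sum(axis=1) > 1 + 1e-6).any():
        raise ValueError("sample rows must sum to at most 1 (proportions)")


def prevalence_filter(
    table: pd.DataFrame, min_nonzero_fraction: float = 0.30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain species non-zero in at least the given fraction of samples.

    The threshold is inclusive (a species non-zero in exactly 30% of
    samples is retained at the default).  Returns the filtered table and a
    per-species report with the observed non-zero fraction and retention
    flag.
    """
    if not (0.0 < min_nonzero_fraction <= 1.0):
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    _validate(table)
    nonzero = (table > 0).mean(axis=0)
    retained = nonzero >= min_nonzero_fraction
    report = pd.DataFrame(
        {"nonzero_fraction": nonzero, "retained": retained}
    ).rename_axis("species")
    return table.loc[:, retained], report


@dataclass
class CLRTable:
    """CLR-transformed abundances plus the transform's provenance.

    ``values`` holds the CLR values for the output species; ``pseudocounts``
    records the per-sample zero replacement used; ``denominator_species``
    lists the species over which each sample's geometric mean was taken.
    When the denominator set equals the output set, rows sum to zero.
    """

    values: pd.DataFrame
    pseudocounts: pd.Series
    denominator_species: list
    dropped_samples: list


def clr_transform(
    table: pd.DataFrame,
    species: list[str] | None = None,
    pseudocount: str | float = "half-min",
    denominator: str = "all",
) -> CLRTable:
    """Centred log-ratio transform with a species-level denominator.

    ``CLR(x_i) = ln(x_i / g(x))`` where ``g`` is the geometric mean over
    the denominator set: with ``denominator="all"`` (default) the full
    species-level composition of the sample, computed before subsetting to
    the analysis ``species``; with ``"subset"`` only the output species.
    Zeros are replaced before logs — ``pseudocount="half-min"`` uses half
    the smallest non-zero abundance within each sample, a float uses that
    fixed value.  Samples that are entirely zero are excluded with a
    warning.  CLR is invariant to a global rescaling of a sample's row, so
    rows need not be closed to 1 here.
    """
    _validate(table, proportions=False)
    if species is not None:
        lookup = {strip_taxonomy(c): c for c in table.columns}
        cols = []
        for s in species:
            key = strip_taxonomy(s)
            if key not in lookup:
                raise KeyError(f"species {s!r} not in abundance table")
            cols.append(lookup[key])
    else:
        cols = list(table.columns)
    if denominator not in ("all", "subset"):
        raise ValueError("denominator must be 'all' or 'subset'")
    denom_cols = list(table.columns) if denominator == "all" else cols

    arr = table.to_numpy(dtype=float)
    all_zero = (arr == 0).all(axis=1)
    dropped = list(table.index[all_zero])
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} all-zero sample(s) from CLR",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = table.loc[~all_zero]

    replaced = kept.to_numpy(dtype=float).copy()
    pseudos = np.empty(replaced.shape[0])
    for r in range(replaced.shape[0]):
        row = replaced[r]
        if isinstance(pseudocount, str):
            if pseudocount != "half-min":
                raise ValueError(f"unknown pseudocount rule {pseudocount!r}")
            delta = row[row > 0].min() / 2.0
        else:
            delta = float(pseudocount)
            if delta <= 0:
                raise ValueError("fixed pseudocount must be positive")
        pseudos[r] = delta
        row[row == 0] = delta
    filled = pd.DataFrame(replaced, index=kept.index, columns=kept.columns)

    log_denom = np.log(filled[denom_cols]).mean(axis=1)
    values = np.log(filled[cols]).sub(log_denom, axis=0)
    return CLRTable(
        values=values,
        pseudocounts=pd.Series(pseudos, index=kept.index, name="pseudocount"),
        denominator_species=denom_cols,
        dropped_samples=dropped,
    )


def ks_compare(
    clr_a: pd.DataFrame, clr_b: pd.DataFrame, species: list[str] | None = None
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov comparison per species.

    Returns the KS D statistic and asymptotic p-value for each species
    present in both groups; species with fewer than two observations in
    either group are skipped with a warning.
    """
    if clr_a.shape[0] == 0 or clr_b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if species is None:
        species = [c for c in clr_a.columns if c in clr_b.columns]
    rows = []
    for s in species:
        a = clr_a[s].dropna().to_numpy()
        b = clr_b[s].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"skipping {s!r}: fewer than 2 observations in a group",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        res = stats.ks_2samp(a, b, method="asymp")
        rows.append(
            {
                "species": s,
                "statistic": float(res.statistic),
                "pvalue": float(res.pvalue),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    return pd.DataFrame(rows, columns=["species", "statistic", "pvalue", "n_a", "n_b"])
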