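"""Covariate-adjusted linear association models for haplotype dosages.

Outcomes (log-scale insulin traits, log metabolite levels, CLR species
abundances) are regressed on posterior-expected haplotype dosages with the
most frequent haplotype (O1 by default) as the omitted reference, under an
additive model: all retained non-reference haplotypes enter one joint OLS
fit per outcome together with the covariates (age, sex, ten genetic PCs).
Haplotypes below a 5% frequency floor are dropped before fitting.  Blood
types are modelled with indicator contrasts against type O.  Wald 95%
intervals and p-values use Gaussian critical values.  Multiple testing is
handled by Bonferroni families (strict ``p < 0.05/family_size``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "beta",
    "ci_low",
    "ci_high",
    "p",
    "n",
    "passes_nominal",
]

Z975 = float(stats.norm.ppf(0.975))

__all__ = [
    "RESULT_COLUMNS",
    "haplotype_regression",
    "bloodtype_regression",
    "bonferroni_family",
    "display_threshold",
]


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    # identify a column whose removal restores full column rank
    for col in X.columns:
        sub = X.drop(columns=[col]).to_numpy(dtype=float)
        if np.linalg.matrix_rank(sub) == rank:
            raise ValueError(f"design matrix is rank-deficient; column {col!r} is collinear")
    raise ValueError("design matrix is rank-deficient")


def _wald_rows(fit, terms: list[str], outcome_name: str, n: int) -> pd.DataFrame:
    rows = []
    for term in terms:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        rows.append(
            {
                "exposure": term,
                "outcome": outcome_name,
                "beta": beta,
                "ci_low": beta - Z975 * se,
                "ci_high": beta + Z975 * se,
                "p": p,
                "n": n,
                "passes_nominal": p < 0.05,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _assemble(outcome: pd.Series, exposures: pd.DataFrame, covariates: pd.DataFrame | None):
    parts = [outcome.rename("__outcome__"), exposures]
    if covariates is not None:
        overlap = set(exposures.columns) & set(covariates.columns)
        if overlap:
            raise ValueError(f"exposure/covariate name clash: {sorted(overlap)}")
        parts.append(covariates)
    df = pd.concat(parts, axis=1, join="inner").dropna()
    y = df["__outcome__"]
    X = sm.add_constant(df.drop(columns="__outcome__"), has_constant="add")
    return y, X


def haplotype_regression(
    outcome: pd.Series,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = "O1",
    freq_floor: float = 0.05,
) -> pd.DataFrame:
    """Joint additive regression of an outcome on haplotype dosages.

    ``dosages`` holds posterior-expected haplotype counts (rows summing
    to 2).  Haplotype frequency is estimated as the mean dosage / 2; only
    non-reference haplotypes at or above ``freq_floor`` enter the model.
    Returns one tidy row per retained haplotype with Wald 95% CI and
    Gaussian p-value.
    """
    if reference not in dosages.columns:
        raise ValueError(f"reference haplotype {reference!r} not in dosage columns")
    freqs = dosages.mean(axis=0) / 2.0
    retained = [
        h for h in dosages.columns if h != reference and freqs[h] >= freq_floor
    ]
    if not retained:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    outcome_name = outcome.name if outcome.name is not None else "outcome"
    y, X = _assemble(outcome, dosages[retained], covariates)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return _wald_rows(fit, retained, outcome_name, int(len(y)))


BLOOD_TYPES = ("O", "A", "B", "AB")


def bloodtype_regression(
    outcome: pd.Series,
    blood_types: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: str = "O",
) -> pd.DataFrame:
    """Indicator-coded regression of an outcome on blood type vs ``reference``.

    Intended for subjects with unambiguous diplotypes.  Blood-type groups
    absent from the data are omitted with a warning; if no non-reference
    group is present an empty result is returned.
    """
    bt = blood_types.dropna()
    invalid = set(bt.unique()) - set(BLOOD_TYPES)
    if invalid:
        raise ValueError(f"unrecognised blood types: {sorted(invalid)}")
    contrasts = [t for t in BLOOD_TYPES if t != reference]
    present = []
    for t in contrasts:
        if (bt == t).any():
            present.append(t)
        else:
            warnings.warn(
                f"blood type {t!r} absent; contrast omitted", RuntimeWarning, stacklevel=2
            )
    if not present:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    indicators = pd.DataFrame(
        {t: (bt == t).astype(float) for t in present}, index=bt.index
    )
    outcome_name = outcome.name if outcome.name is not None else "outcome"
    y, X = _assemble(outcome, indicators, covariates)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return _wald_rows(fit, present, outcome_name, int(len(y)))


def display_threshold(family_size: int) -> float:
    """Bonferroni threshold rounded to two significant figures for display."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(f"{0.05 / family_size:.2g}")


def bonferroni_family(
    results: pd.DataFrame, family_size: int, family: str | None = None
) -> pd.DataFrame:
    """Flag results against a Bonferroni family threshold.

    The internal comparison is strict ``p < 0.05 / family_size`` at full
    precision; ``threshold_display`` carries the two-significant-figure
    rounding used in reports only.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = results.copy()
    threshold = 0.05 / family_size
    out["family"] = family if family is not None else f"n={family_size}"
    out["family_size"] = family_size
    out["bonferroni_threshold"] = threshold
    out["threshold_display"] = display_threshold(family_size)
    out["passes_bonferroni"] = out["p"] < threshold
    return out
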