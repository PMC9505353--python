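"""Baron-Kenny diagnostics and Monte-Carlo causal mediation (ACME/ADE).

For an exposure X (a haplotype dosage or blood-type indicator), a candidate
mediator M (a log metabolite level or CLR species abundance) and an outcome
Y (a log insulin trait), the linear no-interaction structural model is

    M = a*X + covariates + eps_m
    Y = c'*X + b*M + covariates + eps_y

The Baron-Kenny four-step check fits the total effect C (Y ~ X), the A path
(M ~ X), and the B and C' paths jointly (Y ~ X + M); fulfilment is judged
on effect sizes, not significance, so all four estimates are reported.

The quasi-Bayesian Monte-Carlo estimator draws parameter vectors from each
fitted model's asymptotic Gaussian, and per draw computes the average
causal mediation effect ACME = a*b, the average direct effect ADE = c',
and the total effect a*b + c' (the identity ACME + ADE = total holds
exactly per draw in this linear setting).  Point estimates are Monte-Carlo
means; intervals are 2.5/97.5 percentiles.  The proportion mediated is the
point-estimate ratio ACME/total by default (per-draw ratios are unstable
near zero totals); a per-draw mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PathEffect",
    "BaronKennyEffects",
    "MediationResult",
    "baron_kenny",
    "mediate_mc",
    "mediate",
    "mediation_screen",
]

_EXPOSURE = "__exposure__"
_MEDIATOR = "__mediator__"


@dataclass(frozen=True)
class PathEffect:
    estimate: float
    se: float
    p: float

    @property
    def ci(self) -> tuple[float, float]:
        z = float(stats.norm.ppf(0.975))
        return (self.estimate - z * self.se, self.estimate + z * self.se)


@dataclass
class BaronKennyEffects:
    """The four Baron-Kenny path estimates and their underlying fits."""

    total: PathEffect          # C : outcome ~ exposure
    to_mediator: PathEffect    # A : mediator ~ exposure
    from_mediator: PathEffect  # B : outcome ~ mediator | exposure
    direct: PathEffect         # C': outcome ~ exposure | mediator
    fit_mediator: object = field(repr=False, default=None)
    fit_outcome: object = field(repr=False, default=None)


def _effect(fit, term: str) -> PathEffect:
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return PathEffect(estimate=beta, se=se, p=p)


def _design(*named: tuple[str, pd.Series], covariates: pd.DataFrame | None):
    parts = [s.rename(name) for name, s in named]
    if covariates is not None:
        parts.append(covariates)
    df = pd.concat(parts, axis=1, join="inner").dropna()
    return df


def baron_kenny(
    exposure: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> BaronKennyEffects:
    """Fit the three regressions behind the Baron-Kenny four-step check.

    Complete cases across exposure, mediator, outcome and covariates are
    used throughout so all paths share one analysis set.  A constant
    mediator raises an error.
    """
    df = _design(
        (_EXPOSURE, exposure),
        (_MEDIATOR, mediator),
        ("__outcome__", outcome),
        covariates=covariates,
    )
    if df.shape[0] < 3:
        raise ValueError("too few complete cases for mediation models")
    if df[_MEDIATOR].nunique() < 2:
        raise ValueError("mediator is constant")
    covar_cols = [c for c in df.columns if c not in (_EXPOSURE, _MEDIATOR, "__outcome__")]
    y = df["__outcome__"]
    X_total = sm.add_constant(df[[_EXPOSURE] + covar_cols], has_constant="add")
    X_med = X_total
    X_full = sm.add_constant(df[[_EXPOSURE, _MEDIATOR] + covar_cols], has_constant="add")
    fit_total = sm.OLS(y, X_total).fit()
    fit_m = sm.OLS(df[_MEDIATOR], X_med).fit()
    fit_y = sm.OLS(y, X_full).fit()
    return BaronKennyEffects(
        total=_effect(fit_total, _EXPOSURE),
        to_mediator=_effect(fit_m, _EXPOSURE),
        from_mediator=_effect(fit_y, _MEDIATOR),
        direct=_effect(fit_y, _EXPOSURE),
        fit_mediator=fit_m,
        fit_outcome=fit_y,
    )


@dataclass
class MediationResult:
    """ACME/ADE/total/proportion with Monte-Carlo intervals."""

    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    proportion: float
    proportion_mode: str
    unstable_proportion: bool
    n_sim: int
    seed: int | None
    effects: BaronKennyEffects | None = field(repr=False, default=None)
    exposure: str | None = None
    mediator: str | None = None
    outcome: str | None = None

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "acme": self.acme,
            "acme_lo": self.acme_ci[0],
            "acme_hi": self.acme_ci[1],
            "ade": self.ade,
            "ade_lo": self.ade_ci[0],
            "ade_hi": self.ade_ci[1],
            "total": self.total,
            "total_lo": self.total_ci[0],
            "total_hi": self.total_ci[1],
            "proportion": self.proportion,
            "unstable_proportion": self.unstable_proportion,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def mediate_mc(
    fit_m,
    fit_y,
    exposure_term: str = _EXPOSURE,
    mediator_term: str = _MEDIATOR,
    n_sim: int = 1000,
    seed: int | None = None,
    proportion_mode: str = "point",
) -> MediationResult:
    """Quasi-Bayesian Monte-Carlo mediation from two fitted linear models.

    ``fit_m`` is the mediator model (``mediator ~ exposure + covariates``)
    and ``fit_y`` the outcome model (``outcome ~ exposure + mediator +
    covariates``); both must share the exposure term.  ``n_sim`` parameter
    vectors are drawn from each fit's asymptotic Gaussian, and per draw
    ACME = a*b, ADE = c', total = a*b + c'.  The same ``seed`` reproduces
    results bit-for-bit.
    """
    if n_sim < 100:
        warnings.warn(
            f"n_sim={n_sim} is small; intervals will be noisy", RuntimeWarning, stacklevel=2
        )
    if proportion_mode not in ("point", "draw"):
        raise ValueError("proportion_mode must be 'point' or 'draw'")
    rng = np.random.default_rng(seed)
    names_m = list(fit_m.params.index)
    names_y = list(fit_y.params.index)
    for term, names, which in (
        (exposure_term, names_m, "mediator model"),
        (exposure_term, names_y, "outcome model"),
        (mediator_term, names_y, "outcome model"),
    ):
        if term not in names:
            raise ValueError(f"term {term!r} missing from {which}")
    draws_m = rng.multivariate_normal(
        fit_m.params.to_numpy(), fit_m.cov_params().to_numpy(), size=n_sim,
        method="cholesky",
    )
    draws_y = rng.multivariate_normal(
        fit_y.params.to_numpy(), fit_y.cov_params().to_numpy(), size=n_sim,
        method="cholesky",
    )
    a = draws_m[:, names_m.index(exposure_term)]
    b = draws_y[:, names_y.index(mediator_term)]
    c_prime = draws_y[:, names_y.index(exposure_term)]
    acme = a * b
    ade = c_prime
    total = acme + ade

    def ci(x: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return (float(lo), float(hi))

    acme_pt, ade_pt, total_pt = float(acme.mean()), float(ade.mean()), float(total.mean())
    total_ci = ci(total)
    unstable = total_ci[0] <= 0.0 <= total_ci[1]
    if proportion_mode == "point":
        proportion = acme_pt / total_pt if total_pt != 0 else float("nan")
    else:
        same_sign = np.sign(total) == np.sign(total_pt)
        if same_sign.any() and total_pt != 0:
            proportion = float(np.mean(acme[same_sign] / total[same_sign]))
        else:
            proportion = acme_pt / total_pt if total_pt != 0 else float("nan")
    return MediationResult(
        acme=acme_pt,
        acme_ci=ci(acme),
        ade=ade_pt,
        ade_ci=ci(ade),
        total=total_pt,
        total_ci=total_ci,
        proportion=proportion,
        proportion_mode=proportion_mode,
        unstable_proportion=bool(unstable),
        n_sim=n_sim,
        seed=seed,
    )


def mediate(
    exposure: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_sim: int = 1000,
    seed: int | None = None,
    proportion_mode: str = "point",
) -> MediationResult:
    """Baron-Kenny fits followed by Monte-Carlo mediation in one call."""
    effects = baron_kenny(exposure, mediator, outcome, covariates)
    res = mediate_mc(
        effects.fit_mediator,
        effects.fit_outcome,
        n_sim=n_sim,
        seed=seed,
        proportion_mode=proportion_mode,
    )
    res.effects = effects
    res.exposure = exposure.name
    res.mediator = mediator.name
    res.outcome = outcome.name
    return res


def mediation_screen(
    exposure: pd.Series,
    mediators: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int | None = None,
    proportion_mode: str = "point",
) -> pd.DataFrame:
    """Screen candidate mediators, then estimate mediation for survivors.

    A candidate survives when both its A path (exposure -> mediator) and
    its B path (mediator -> outcome given exposure) reach nominal
    ``p < alpha``.  Survivors get a Monte-Carlo mediation estimate with a
    per-candidate seed derived deterministically from ``seed``; results
    are ranked by |ACME|.  An empty survivor set returns an empty frame.
    """
    rows = []
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(mediators.shape[1])]
    for k, name in enumerate(mediators.columns):
        effects = baron_kenny(exposure, mediators[name], outcome, covariates)
        survived = effects.to_mediator.p < alpha and effects.from_mediator.p < alpha
        row = {
            "exposure": exposure.name,
            "mediator": name,
            "outcome": outcome.name,
            "a": effects.to_mediator.estimate,
            "a_p": effects.to_mediator.p,
            "b": effects.from_mediator.estimate,
            "b_p": effects.from_mediator.p,
            "survived": survived,
        }
        if survived:
            res = mediate_mc(
                effects.fit_mediator,
                effects.fit_outcome,
                n_sim=n_sim,
                seed=child_seeds[k],
                proportion_mode=proportion_mode,
            )
            row.update(
                {
                    "acme": res.acme,
                    "acme_lo": res.acme_ci[0],
                    "acme_hi": res.acme_ci[1],
                    "ade": res.ade,
                    "ade_lo": res.ade_ci[0],
                    "ade_hi": res.ade_ci[1],
                    "total": res.total,
                    "total_lo": res.total_ci[0],
                    "total_hi": res.total_ci[1],
                    "proportion": res.proportion,
                    "unstable_proportion": res.unstable_proportion,
                    "n_sim": res.n_sim,
                    "seed": res.seed,
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["rank_key"] = out.get("acme", pd.Series(dtype=float)).abs() if "acme" in out else np.nan
    out = out.sort_values(
        by=["survived", "rank_key"], ascending=[False, False], kind="mergesort"
    ).drop(columns="rank_key")
    return out.reset_index(drop=True)
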