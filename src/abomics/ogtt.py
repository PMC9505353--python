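"""Insulin-homeostasis indices from 0/30/120-minute OGTT measurements.

Four indices are derived from glucose (mg/dL), insulin (uU/mL) and
C-peptide (ng/mL) sampled fasting and 30 and 120 minutes after a 75 g oral
glucose load:

* **Matsuda ISI** — whole-body insulin sensitivity,
  ``10000 / sqrt(G0 * I0 * Gbar * Ibar)`` with ``Gbar``/``Ibar`` the
  unweighted arithmetic means of the three samples (a time-weighted-mean
  option exists but is off by default for the three-point design).
* **secretion** — early insulin response, ``AUC-Ins(0-30) / AUC-Glu(0-30)``.
* **clearance** — hepatic insulin extraction proxy,
  ``AUC-Cpep(0-120) / AUC-Ins(0-120)`` (the liver clears insulin but not
  C-peptide).
* **DI30** — disposition index, ``ISI * secretion`` exactly.

All AUCs are trapezoidal.  Indices are natural-log transformed for
modelling; a log-scale effect ``beta`` back-transforms to a percent change
``(exp(beta) - 1) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OGTT_TIMES = (0.0, 30.0, 120.0)
TRAITS = ("isi", "secretion", "clearance", "di30")

ANALYTES = ("glucose", "insulin", "cpeptide")
OGTT_COLUMNS = tuple(f"{a}_{int(t)}" for a in ANALYTES for t in OGTT_TIMES)

__all__ = [
    "OGTT_TIMES",
    "TRAITS",
    "OGTT_COLUMNS",
    "OGTTRecord",
    "InsulinTraits",
    "auc_trapezoid",
    "matsuda_isi",
    "secretion_index",
    "clearance_index",
    "disposition_index",
    "compute_traits",
    "log_transform",
    "percent_change",
    "back_transform_percent",
]


def auc_trapezoid(times, values):
    """Trapezoidal area under a sampled curve (value-units x minutes)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if values.shape[-1] != times.size:
        raise ValueError("values and times length mismatch")
    if np.any(values <= 0):
        raise ValueError("values must be positive")
    return np.trapezoid(values, times, axis=-1)


def _positive(name, *arrays):
    for a in arrays:
        if np.any(np.asarray(a, dtype=float) <= 0):
            raise ValueError(f"{name} requires strictly positive inputs")


def matsuda_isi(glucose, insulin, time_weighted: bool = False):
    """Matsuda whole-body insulin sensitivity index.

    ``glucose`` and ``insulin`` are the (..., 3) arrays of 0/30/120-minute
    values in mg/dL and uU/mL.  With ``time_weighted=True`` the means are
    AUC/120 instead of the unweighted three-point average.
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    _positive("matsuda_isi", g, i)
    if time_weighted:
        times = np.asarray(OGTT_TIMES)
        g_mean = np.trapezoid(g, times, axis=-1) / (times[-1] - times[0])
        i_mean = np.trapezoid(i, times, axis=-1) / (times[-1] - times[0])
    else:
        g_mean = g.mean(axis=-1)
        i_mean = i.mean(axis=-1)
    return 10000.0 / np.sqrt(g[..., 0] * i[..., 0] * g_mean * i_mean)


def secretion_index(glucose, insulin):
    """Early insulin response AUC-Ins(0-30) / AUC-Glu(0-30)."""
    g = np.asarray(glucose, dtype=float)[..., :2]
    i = np.asarray(insulin, dtype=float)[..., :2]
    t = np.asarray(OGTT_TIMES[:2])
    denom = auc_trapezoid(t, g)
    return auc_trapezoid(t, i) / denom


def clearance_index(insulin, cpeptide):
    """Insulin clearance proxy AUC-Cpep(0-120) / AUC-Ins(0-120)."""
    t = np.asarray(OGTT_TIMES)
    denom = auc_trapezoid(t, np.asarray(insulin, dtype=float))
    return auc_trapezoid(t, np.asarray(cpeptide, dtype=float)) / denom


def disposition_index(isi, secretion):
    """Disposition index DI30 = ISI x secretion."""
    return np.asarray(isi, dtype=float) * np.asarray(secretion, dtype=float)


@dataclass(frozen=True)
class InsulinTraits:
    isi: float
    secretion: float
    clearance: float
    di30: float

    @property
    def log_isi(self) -> float:
        return float(np.log(self.isi))

    @property
    def log_secretion(self) -> float:
        return float(np.log(self.secretion))

    @property
    def log_clearance(self) -> float:
        return float(np.log(self.clearance))

    @property
    def log_di30(self) -> float:
        return float(np.log(self.di30))


@dataclass(frozen=True)
class OGTTRecord:
    """One subject's timed OGTT measurements (all strictly positive)."""

    glucose_0: float
    glucose_30: float
    glucose_120: float
    insulin_0: float
    insulin_30: float
    insulin_120: float
    cpeptide_0: float
    cpeptide_30: float
    cpeptide_120: float

    def __post_init__(self) -> None:
        for name in OGTT_COLUMNS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def traits(self) -> InsulinTraits:
        g = (self.glucose_0, self.glucose_30, self.glucose_120)
        i = (self.insulin_0, self.insulin_30, self.insulin_120)
        c = (self.cpeptide_0, self.cpeptide_30, self.cpeptide_120)
        isi = float(matsuda_isi(g, i))
        sec = float(secretion_index(g, i))
        return InsulinTraits(
            isi=isi,
            secretion=sec,
            clearance=float(clearance_index(i, c)),
            di30=float(disposition_index(isi, sec)),
        )


def compute_traits(ogtt: pd.DataFrame, time_weighted: bool = False) -> pd.DataFrame:
    """Per-subject raw and log-scale insulin traits from an OGTT table.

    Expects columns ``{analyte}_{minute}`` for glucose, insulin and
    cpeptide at minutes 0, 30 and 120.
    """
    missing = [c for c in OGTT_COLUMNS if c not in ogtt.columns]
    if missing:
        raise ValueError(f"OGTT table lacks columns: {missing}")
    g = ogtt[[f"glucose_{int(t)}" for t in OGTT_TIMES]].to_numpy(dtype=float)
    i = ogtt[[f"insulin_{int(t)}" for t in OGTT_TIMES]].to_numpy(dtype=float)
    c = ogtt[[f"cpeptide_{int(t)}" for t in OGTT_TIMES]].to_numpy(dtype=float)
    _positive("compute_traits", g, i, c)
    isi = matsuda_isi(g, i, time_weighted=time_weighted)
    sec = secretion_index(g, i)
    clr = clearance_index(i, c)
    di = disposition_index(isi, sec)
    out = pd.DataFrame(
        {"isi": isi, "secretion": sec, "clearance": clr, "di30": di},
        index=ogtt.index,
    )
    return pd.concat([out, log_transform(out)], axis=1)


def log_transform(traits: pd.DataFrame) -> pd.DataFrame:
    """Natural-log columns ``log_<trait>`` for strictly positive traits."""
    if (traits <= 0).any().any():
        raise ValueError("traits must be strictly positive for log transform")
    return np.log(traits).rename(columns=lambda c: f"log_{c}")


def percent_change(beta):
    """Unrounded percent change implied by a natural-log-scale effect."""
    return np.expm1(beta) * 100.0


def back_transform_percent(beta) -> float:
    """Percent change from a log-scale beta, reported to one decimal."""
    return float(np.round(percent_change(beta), 1))
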