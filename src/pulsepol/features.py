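"""Pulse-shape statistics and feature-vector assembly.

Eight statistics summarize each per-sample trace X of one pulse (population
moments, dividing by N throughout):

========  ==========================================  =========================
XPeak     max(X) - min(X)                             peak-to-peak value
Xvar      (1/N) sum (X_i - mu)^2                      variance
Xstd      sqrt(Xvar)                                  standard deviation
Xrms      sqrt((1/N) sum X_i^2)                       root mean square
Xsk       (1/N) sum (X_i - mu)^3 / Xstd^3             skewness
Xku       (1/N) sum (X_i - mu)^4 / Xstd^4             kurtosis (not excess)
S         Xrms / mu                                   waveform factor
L         XPeak / mu^2                                clearance factor
========  ==========================================  =========================

The clearance factor divides the peak-to-peak value by the *squared mean*;
this is deliberate (it is the definition this pipeline standardizes on) and
differs from the conventional crest-type factor — a conventional variant
``XPeak / rms`` is available behind ``clearance="conventional"``.

Two feature vectors per particle are supported:

* pulse-average (PAC): the 6 averages (Ibar, qbar, ubar, vbar, DOP, F);
* pulse feature-enhanced (PFEC): those 6 plus the 8 statistics of each of
  the four Stokes-domain traces I, q, u, v — 38 features in a fixed,
  documented column order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pulse_processing import StokesTrace

__all__ = [
    "PulseStatistics",
    "pulse_statistics",
    "pfec_vector",
    "pac_vector",
    "feature_frame",
    "PAC_COLUMNS",
    "PFEC_COLUMNS",
    "STAT_NAMES",
]

STAT_NAMES = ("peak", "var", "std", "rms", "sk", "ku", "S", "L")
TRACE_NAMES = ("I", "q", "u", "v")
PAC_COLUMNS = ("I_mean", "q_mean", "u_mean", "v_mean", "DOP", "F")
PFEC_COLUMNS = PAC_COLUMNS + tuple(
    f"{trace}_{stat}" for trace in TRACE_NAMES for stat in STAT_NAMES
)

# Imputation limits for statistics undefined on degenerate traces: a constant
# signal has no standardized shape, so skewness takes its symmetric limit 0
# and kurtosis the Gaussian reference value 3; S -> 1 (constant positive
# signal) and L -> 0 are the exact constant-signal limits.
_IMPUTED = {"sk": 0.0, "ku": 3.0, "S": 1.0, "L": 0.0}


@dataclass(frozen=True)
class PulseStatistics:
    """The eight per-trace statistics; NaN marks a defined-missing value."""

    peak: float
    var: float
    std: float
    rms: float
    sk: float
    ku: float
    S: float
    L: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.peak, self.var, self.std, self.rms, self.sk, self.ku, self.S, self.L)


def pulse_statistics(X, clearance: str = "printed") -> PulseStatistics:
    """Compute the eight pulse statistics of one per-sample trace.

    Moments are population moments (divide by N).  On traces with zero
    standard deviation, skewness and kurtosis are returned as NaN
    (defined-missing); likewise the waveform and clearance factors when the
    mean is zero.  ``clearance="conventional"`` divides the peak-to-peak
    value by the RMS instead of the squared mean.
    """
    x = np.asarray(X, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("trace must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if clearance not in ("printed", "conventional"):
        raise ValueError(f"unknown clearance mode {clearance!r}")

    mu = float(np.mean(x))
    d = x - mu
    peak = float(np.max(x) - np.min(x))
    var = float(np.mean(d * d))
    std = math.sqrt(var)
    rms = math.sqrt(float(np.mean(x * x)))
    if std > 0:
        sk = float(np.mean(d**3)) / std**3
        ku = float(np.mean(d**4)) / std**4
    else:
        sk = ku = float("nan")
    if mu != 0:
        S = rms / mu
        L = peak / mu**2 if clearance == "printed" else (peak / rms if rms > 0 else float("nan"))
    else:
        S = float("nan")
        L = peak / rms if (clearance == "conventional" and rms > 0) else float("nan")
    return PulseStatistics(peak=peak, var=var, std=std, rms=rms, sk=sk, ku=ku, S=S, L=L)


def _averages_block(trace: StokesTrace) -> list[float]:
    Ib, qb, ub, vb = trace.means
    return [Ib, qb, ub, vb, trace.dop, trace.F]


def pfec_vector(
    trace: StokesTrace, impute: bool = True, clearance: str = "printed"
) -> np.ndarray:
    """The 38-dimensional pulse feature-enhanced vector for one particle.

    Order: the 6 averages (Ibar, qbar, ubar, vbar, DOP, F) followed by the
    8 statistics of each of the I, q, u, v traces (see ``PFEC_COLUMNS``).
    Defined-missing statistics are imputed with their degenerate-trace
    limits unless ``impute=False`` (NaN sentinels then pass through).
    """
    if trace.n_samples < 2:
        raise ValueError("need at least 2 in-pulse samples for pulse statistics")
    values = _averages_block(trace)
    for name in TRACE_NAMES:
        st = pulse_statistics(trace.traces()[name], clearance=clearance)
        for stat, v in zip(STAT_NAMES, st.as_tuple()):
            if impute and not np.isfinite(v):
                v = _IMPUTED.get(stat, 0.0)
            values.append(v)
    return np.asarray(values, dtype=float)


def pac_vector(trace: StokesTrace) -> np.ndarray:
    """The 6-dimensional pulse-average vector (Ibar, qbar, ubar, vbar, DOP, F)."""
    return np.asarray(_averages_block(trace), dtype=float)


def feature_frame(
    traces: list[StokesTrace],
    mode: str = "pfec",
    labels=None,
    clearance: str = "printed",
) -> pd.DataFrame:
    """Featurize a list of Stokes traces into a table, one row per particle.

    ``mode`` is ``"pfec"`` (38 columns) or ``"pac"`` (6 columns); a
    ``label`` column is attached when ``labels`` is given, and a
    ``qc_imputed`` column counts imputed entries per row in PFEC mode.
    """
    mode = mode.lower()
    if mode not in ("pfec", "pac"):
        raise ValueError(f"unknown feature mode {mode!r}")
    rows, imputed = [], []
    for t in traces:
        if mode == "pac":
            rows.append(pac_vector(t))
        else:
            raw = pfec_vector(t, impute=False, clearance=clearance)
            n_missing = int(np.sum(~np.isfinite(raw)))
            imputed.append(n_missing)
            rows.append(pfec_vector(t, impute=True, clearance=clearance))
    columns = PFEC_COLUMNS if mode == "pfec" else PAC_COLUMNS
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(columns)))
    df = pd.DataFrame(data, columns=list(columns))
    if mode == "pfec":
        df["qc_imputed"] = imputed
    if labels is not None:
        if len(labels) != len(traces):
            raise ValueError("labels length must match traces")
        df["label"] = list(labels)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a table (excludes label and QC columns)."""
    return [c for c in df.columns if c in PFEC_COLUMNS]
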