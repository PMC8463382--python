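"""Cluster-lability kinetics from 458-nm absorbance decay traces.

Loss of the protein-bound [2Fe-2S] cluster bleaches the characteristic
458-nm absorption band, so a decaying trace reports cluster release.
Each normalized trace is fit with a first-order-plus-plateau model
``A(t) = c + (1 - c) exp(-k t)`` and with a flat (no-release) model; the
winner by small-sample AIC (AICc) plus a minimum-total-loss rule
classifies the trace as labile or stable.  The underlying measurements
are qualitative in origin (release vs no release at 310-318 K); the rate
fit and the 0.2-total-loss labile rule are this toolkit's
operationalization, and reports label them as such.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = [
    "DecayTrace",
    "LabilityFit",
    "normalize_trace",
    "fit_decay",
    "temperature_panel",
    "read_traces_csv",
]

LOSS_THRESHOLD = 0.2        # minimum fitted total loss for a "labile" call
NORMALIZE_POINTS = 3        # leading points averaged for normalization


@dataclass
class DecayTrace:
    """Absorbance vs time at a stated wavelength and temperature."""

    time_min: np.ndarray
    absorbance: np.ndarray
    temperature_K: float
    label: str = ""
    wavelength_nm: float = 458.0
    normalized: bool = False

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.time_min.shape != self.absorbance.shape:
            raise ValueError("time and absorbance differ in length")
        if len(self.time_min) < 5:
            raise ValueError("need at least 5 points to fit")
        if not (np.diff(self.time_min) > 0).all():
            raise ValueError("time points must be strictly increasing")


@dataclass
class LabilityFit:
    """Result of the flat-vs-first-order model comparison for one trace."""

    model: str                   # "flat" | "first-order"
    k: float                     # 1/min
    k_stderr: float
    plateau: float               # plateau fraction c
    total_loss: float            # (1 - c)(1 - exp(-k t_end))
    classification: str          # "stable" | "labile"
    aicc_flat: float
    aicc_exp: float
    converged: bool = True


def normalize_trace(trace: DecayTrace) -> DecayTrace:
    """Divide by the mean of the first NORMALIZE_POINTS points (robust to
    single-point noise at t = 0); result is a fraction-of-initial trace."""
    a0 = float(trace.absorbance[:NORMALIZE_POINTS].mean())
    if a0 <= 0:
        raise ValueError("non-positive initial absorbance; cannot normalize")
    return replace(trace, absorbance=trace.absorbance / a0, normalized=True)


def _aicc(rss: float, n: int, p: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * p
    if n - p - 1 > 0:
        aic += 2 * p * (p + 1) / (n - p - 1)
    return aic


def fit_decay(trace: DecayTrace) -> LabilityFit:
    """Fit flat and first-order-plus-plateau models; classify the trace.

    Labile iff the exponential model wins on AICc *and* the fitted total
    loss over the observation window is at least ``LOSS_THRESHOLD``.
    Non-convergence of the exponential fit falls back to the flat model
    with ``converged=False``.
    """
    if not trace.normalized:
        trace = normalize_trace(trace)
    t = trace.time_min
    y = trace.absorbance
    n = len(t)

    rss_flat = float(((y - y.mean()) ** 2).sum())
    aicc_flat = _aicc(rss_flat, n, 1)

    # free amplitude a0 absorbs the residual scale left by the leading-
    # window normalization (for fast decays the first-3-point mean sits
    # below the true t=0 absorbance, which would otherwise bias k)
    def model(tt, a0, c, k):
        return a0 * (c + (1 - c) * np.exp(-k * tt))

    converged = True
    try:
        span = max(t[-1] - t[0], 1e-9)
        loss0 = max(1e-3, min(0.999, 1.0 - y[-1]))
        k0 = max(1e-4, -np.log(max(1e-3, 1 - loss0 * 0.63)) / span)
        popt, pcov = curve_fit(model, t, y, p0=[1.0, 1 - loss0, k0],
                               bounds=([0.5, 0.0, 0.0], [1.5, 1.0, np.inf]),
                               maxfev=10000)
        c_hat, k_hat = float(popt[1]), float(popt[2])
        k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        rss_exp = float(((y - model(t, *popt)) ** 2).sum())
        aicc_exp = _aicc(rss_exp, n, 3)
    except (RuntimeError, ValueError):
        converged = False
        c_hat, k_hat, k_se = 1.0, 0.0, np.nan
        aicc_exp = np.inf

    total_loss = (1 - c_hat) * (1 - np.exp(-k_hat * (t[-1] - t[0])))
    exp_wins = converged and aicc_exp < aicc_flat
    labile = exp_wins and total_loss >= LOSS_THRESHOLD
    return LabilityFit(
        model="first-order" if exp_wins else "flat",
        k=k_hat if exp_wins else 0.0,
        k_stderr=k_se if exp_wins else np.nan,
        plateau=c_hat if exp_wins else float(y.mean()),
        total_loss=total_loss if exp_wins else 0.0,
        classification="labile" if labile else "stable",
        aicc_flat=aicc_flat, aicc_exp=aicc_exp, converged=converged)


def temperature_panel(traces: list[DecayTrace]) -> dict:
    """Fit every trace and assemble the per-temperature lability report.

    Returns {"table": DataFrame, "monotone_rate_in_T": {label: bool}}.
    The monotone flag is true for a sample label when the Spearman rank
    correlation of (temperature, fitted k) equals 1 across >= 2
    temperatures.  Duplicate (temperature, label) combinations error.
    """
    temps = {float(tr.temperature_K) for tr in traces}
    if len(temps) < 2:
        raise ValueError("panel needs at least 2 temperatures")
    seen = set()
    rows = []
    for tr in traces:
        key = (float(tr.temperature_K), tr.label)
        if key in seen:
            raise ValueError(f"duplicate temperature+label {key}")
        seen.add(key)
        fit = fit_decay(tr)
        rows.append({"label": tr.label, "temperature_K": tr.temperature_K,
                     "k_per_min": fit.k, "k_stderr": fit.k_stderr,
                     "plateau": fit.plateau, "total_loss": fit.total_loss,
                     "model": fit.model, "classification": fit.classification,
                     "AICc_flat": fit.aicc_flat, "AICc_exp": fit.aicc_exp})
    table = pd.DataFrame(rows).sort_values(
        ["label", "temperature_K"]).reset_index(drop=True)

    monotone = {}
    for label, grp in table.groupby("label"):
        if len(grp) < 2 or grp["k_per_min"].nunique() < 2:
            monotone[label] = False
            continue
        rho = spearmanr(grp["temperature_K"], grp["k_per_min"]).statistic
        monotone[label] = bool(np.isclose(rho, 1.0))
    return {"table": table, "monotone_rate_in_T": monotone}


def read_traces_csv(path) -> list[DecayTrace]:
    """Read traces from CSV with columns time_min, A458, temperature_K,
    label; one trace per (temperature_K, label) group."""
    df = pd.read_csv(path)
    required = {"time_min", "A458", "temperature_K", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traces CSV missing columns {sorted(missing)}")
    traces = []
    for (temp, label), grp in df.groupby(["temperature_K", "label"]):
        grp = grp.sort_values("time_min")
        traces.append(DecayTrace(time_min=grp["time_min"].to_numpy(),
                                 absorbance=grp["A458"].to_numpy(),
                                 temperature_K=float(temp), label=str(label)))
    return traces
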