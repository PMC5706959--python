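"""Thioflavin-T aggregation-kinetics analysis.

A normalized fluorescence time course is fit to a four-parameter logistic

    F(t) = F_inf + (F0 - F_inf) / (1 + exp(k (t - t50)))

(an increasing sigmoid for k > 0, F_inf > F0) and the lag time is the
tangent construction at the midpoint,

    t_lag = t50 - 2/k ,

i.e. the intersection of the tangent at t50 with the F = F0 baseline.
Replicate lag times are averaged per condition and expressed as fold
change relative to the matched untreated control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "KineticTrace",
    "LogisticFit",
    "LagResult",
    "normalize_trace",
    "normalize_plate",
    "eval_logistic",
    "fit_logistic",
    "lag_time",
    "analyze_trace",
    "summarize_conditions",
    "CENSOR_MAX_F",
]

#: A trace whose smoothed rise stays below this fraction of the reference
#: dynamic range is treated as "no fibrillation observed" (censored).
CENSOR_MAX_F = 0.1


def _smoothed_rise(f: np.ndarray, window: int = 15) -> float:
    """Dynamic range of a moving-average-smoothed signal.

    Smoothing suppresses read noise so a flat well's apparent range
    (extreme spread of hundreds of noise draws) does not mimic a rise.
    """
    w = max(1, min(window, f.size // 4))
    sm = np.convolve(f, np.ones(w) / w, mode="valid") if w > 1 else f
    return float(sm.max() - sm.min())


def _noise_sigma(f: np.ndarray) -> float:
    """Robust read-noise estimate from first differences (MAD-based)."""
    d = np.diff(f)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


@dataclass
class KineticTrace:
    """One well's time course. ``F`` is normalized fluorescence once
    :func:`normalize_trace` has run; ``condition`` carries the well metadata."""

    times: np.ndarray              # minutes, strictly increasing
    F: np.ndarray                  # dimensionless after normalization
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.shape != self.F.shape:
            raise ValueError("times and F must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class LogisticFit:
    F0: float
    Finf: float
    k: float                      # per minute, > 0 for an accepted fit
    t50: float                    # minutes
    rmse: float = 0.0
    converged: bool = True
    n_points: int = 0
    extrapolated: bool = False    # t50 outside the observed window


@dataclass
class LagResult:
    t_lag: float | None           # minutes; None when censored
    censored: bool = False
    lower_bound: float | None = None   # run length, for censored wells
    negative_flag: bool = False   # transition faster than lag resolution
    fold_change: float | None = None


def normalize_trace(
    raw: KineticTrace, background: KineticTrace | float = 0.0
) -> KineticTrace:
    """Background-correct and min-max normalize a raw trace to [0, 1]."""
    if isinstance(background, KineticTrace):
        if raw.times.shape != background.times.shape or not np.allclose(
            raw.times, background.times
        ):
            raise ValueError("background time grid does not match the trace")
        bg = background.F
    else:
        bg = float(background)
    corrected = raw.F - bg
    lo, hi = corrected.min(), corrected.max()
    if hi == lo:
        raise ValueError("zero dynamic range after background correction")
    return KineticTrace(
        times=raw.times.copy(),
        F=(corrected - lo) / (hi - lo),
        condition=dict(raw.condition),
    )


def normalize_plate(
    run, background: float | np.ndarray = 0.0
) -> dict[str, KineticTrace]:
    """Normalize every well of a :class:`~memtrap.io_formats.PlateRun`.

    Normalization is per-well, but the censoring scale is plate-wide: a
    well whose corrected dynamic range is below :data:`CENSOR_MAX_F` of
    the largest range on the plate (the de-facto positive control) is
    scaled by that reference range instead, so it stays flat (< 0.1) and
    is picked up as censored downstream.
    """
    corrected = {w: f - background for w, f in run.wells.items()}
    rises = {w: _smoothed_rise(c) for w, c in corrected.items()}
    ref_rise = max(rises.values())
    if ref_rise <= 0:
        raise ValueError("zero dynamic range across the whole plate")
    traces: dict[str, KineticTrace] = {}
    for w, c in corrected.items():
        cond = dict(run.meta.get(w, {}))
        cond["well"] = w
        if rises[w] < CENSOR_MAX_F * ref_rise:
            # flat well: scale by the plate reference so it stays flat
            f = (c - c.min()) / ref_rise
            cond["normalization"] = "plate-reference (flat well)"
        else:
            rng = float(c.max() - c.min())
            f = (c - c.min()) / rng
            cond["normalization"] = "per-well"
        traces[w] = KineticTrace(times=run.times.copy(), F=f, condition=cond)
    return traces


def eval_logistic(
    t: np.ndarray | float,
    F0: float,
    Finf: float,
    k: float,
    t50: float,
) -> np.ndarray | float:
    """Evaluate the logistic overflow-safely (saturates to F0 / Finf)."""
    # 1/(1+e^x) = expit(-x); expit underflows gracefully at |x| ~ 700+
    return Finf + (F0 - Finf) * expit(-k * (np.asarray(t, float) - t50))


def _initial_guess(trace: KineticTrace) -> LogisticFit:
    """Deterministic data-driven starting values: F0/Finf from the 5th/95th
    percentiles, t50 from the half-range crossing, k from the max slope."""
    t, f = trace.times, trace.F
    f0 = float(np.percentile(f, 5))
    finf = float(np.percentile(f, 95))
    half = 0.5 * (f0 + finf)
    above = np.nonzero(f >= half)[0]
    t50 = float(t[above[0]]) if above.size else float(t[len(t) // 2])
    slopes = np.gradient(f, t)
    max_slope = float(np.max(slopes))
    rng = max(finf - f0, 1e-12)
    k = 4.0 * max_slope / rng if max_slope > 0 else 1.0 / max(trace.span, 1.0)
    return LogisticFit(F0=f0, Finf=finf, k=min(max(k, 1e-5), 10.0), t50=t50)


def fit_logistic(
    trace: KineticTrace, init: LogisticFit | None = None
) -> LogisticFit | None:
    """Least-squares logistic fit of a normalized trace.

    Returns ``None`` for a censored trace (no sigmoid transition observed:
    max F below :data:`CENSOR_MAX_F`). Deterministic given identical input
    and init.
    """
    t, f = trace.times, trace.F
    if t.size < 8:
        raise ValueError("need at least 8 data points spanning the transition")
    # censor: no sigmoid transition — the smoothed rise neither clears the
    # normalized-range floor nor exceeds 5x the baseline read noise
    if _smoothed_rise(f) < max(CENSOR_MAX_F, 5.0 * _noise_sigma(f)):
        return None
    if init is None:
        init = _initial_guess(trace)
    span = trace.span
    params = lmfit.Parameters()
    params.add("F0", value=init.F0, min=-0.2, max=1.2)
    params.add("Finf", value=init.Finf, min=-0.2, max=1.2)
    params.add("k", value=init.k, min=1e-6, max=10.0)
    params.add("t50", value=init.t50, min=t[0] - span, max=t[-1] + span)

    def residual(p):
        return eval_logistic(t, p["F0"].value, p["Finf"].value,
                             p["k"].value, p["t50"].value) - f

    out = lmfit.minimize(
        residual, params, method="leastsq", xtol=1e-14, ftol=1e-14, max_nfev=5000
    )
    p = out.params
    resid = residual(p)
    fit = LogisticFit(
        F0=float(p["F0"].value),
        Finf=float(p["Finf"].value),
        k=float(p["k"].value),
        t50=float(p["t50"].value),
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=bool(out.success),
        n_points=int(t.size),
    )
    fit.extrapolated = not (t[0] <= fit.t50 <= t[-1])
    return fit


def lag_time(fit: LogisticFit | None, run_length: float | None = None) -> LagResult:
    """Lag time from the tangent construction, t_lag = t50 - 2/k.

    A ``None`` fit (censored trace) yields a censored result whose lower
    bound is the run length.
    """
    if fit is None:
        return LagResult(t_lag=None, censored=True, lower_bound=run_length)
    if fit.k <= 0:
        raise ValueError(f"lag time undefined for k = {fit.k} <= 0")
    t_lag = fit.t50 - 2.0 / fit.k
    return LagResult(t_lag=float(t_lag), negative_flag=t_lag < 0)


def analyze_trace(
    trace: KineticTrace, init: LogisticFit | None = None
) -> tuple[LogisticFit | None, LagResult]:
    """Fit one normalized trace and extract its lag time (censoring-aware)."""
    fit = fit_logistic(trace, init=init)
    return fit, lag_time(fit, run_length=float(trace.times[-1]))


_GROUP_KEYS = ("nanodisc_id", "nanodisc_equiv", "pH", "temperature_C")
_MATCH_KEYS = ("pH", "temperature_C")


def _condition_key(cond: dict) -> tuple:
    return tuple(cond.get(k) for k in _GROUP_KEYS)


def _is_control(cond: dict) -> bool:
    return float(cond.get("nanodisc_equiv", 0) or 0) == 0.0


def summarize_conditions(
    results: Sequence[tuple[LagResult, dict]],
) -> pd.DataFrame:
    """Aggregate replicate lag times per condition and compute fold changes.

    Every treated condition must have a matched untreated control
    (``nanodisc_equiv == 0``) in the same buffer/temperature group. Censored
    replicates are excluded from means, counted separately, and a condition
    that is entirely censored reports a lower-bound fold change
    ``> run_length / mean(control)``.
    """
    by_cond: dict[tuple, list[LagResult]] = {}
    conds: dict[tuple, dict] = {}
    for lag, cond in results:
        key = _condition_key(cond)
        by_cond.setdefault(key, []).append(lag)
        conds[key] = cond

    control_mean: dict[tuple, float] = {}
    for key, lags in by_cond.items():
        if _is_control(conds[key]):
            vals = [r.t_lag for r in lags if not r.censored]
            if vals:
                match = tuple(conds[key].get(k) for k in _MATCH_KEYS)
                control_mean[match] = float(np.mean(vals))

    rows = []
    for key, lags in sorted(by_cond.items(), key=lambda kv: str(kv[0])):
        cond = conds[key]
        vals = [r.t_lag for r in lags if not r.censored]
        n_cens = sum(r.censored for r in lags)
        match = tuple(cond.get(k) for k in _MATCH_KEYS)
        if not _is_control(cond) and match not in control_mean:
            raise ValueError(
                f"no untreated control for group pH={match[0]}, T={match[1]}"
            )
        mean = float(np.mean(vals)) if vals else math.nan
        if len(vals) >= 2:
            sd = float(np.std(vals, ddof=1))
        else:
            sd = math.nan
            if len(vals) == 1:
                warnings.warn(
                    f"condition {key}: single replicate, sd undefined", stacklevel=2
                )
        fold: float | None = None
        fold_bound: str | None = None
        ctrl = control_mean.get(match)
        if ctrl is not None and ctrl > 0:
            if vals:
                fold = mean / ctrl
            elif n_cens:
                bounds = [r.lower_bound for r in lags if r.lower_bound is not None]
                if bounds:
                    fold_bound = f"> {min(bounds) / ctrl:.6g}"
        rows.append(
            {
                "nanodisc_id": cond.get("nanodisc_id"),
                "nanodisc_equiv": cond.get("nanodisc_equiv"),
                "pH": cond.get("pH"),
                "temperature_C": cond.get("temperature_C"),
                "n_replicates": len(lags),
                "n_censored": n_cens,
                "mean_t_lag_min": mean,
                "sd_t_lag_min": sd,
                "fold_change": fold,
                "fold_change_bound": fold_bound,
            }
        )
    return pd.DataFrame(rows)
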