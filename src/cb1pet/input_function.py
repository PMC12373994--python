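"""Arterial input-function construction with metabolite correction.

Blood-sample tables (discrete arterial draws, plus an optional continuous
early segment) are turned into a metabolite-corrected plasma input function:
the fraction of plasma radioactivity attributable to unmetabolized parent
tracer is fitted with a monotone "inverted gamma" curve and the total plasma
activity curve is multiplied by the fitted parent-fraction curve point by
point.  The resulting :class:`InputFunction` carries an explicit
interpolation contract (piecewise linear between samples, zero before the
first sample, mono-exponential tail beyond the last) so that the kinetic
estimators can evaluate running integrals of the input consistently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from scipy.special import gammaincc

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "BloodSampleTable",
    "ParentFractionFit",
    "InputFunction",
    "parent_fraction_curve",
    "fit_parent_fraction",
    "build_input_function",
    "integrate_input",
]


def parent_fraction_curve(t, p_inf, alpha, theta):
    """Inverted-gamma parent-fraction model.

    p(t) = p_inf + (1 - p_inf) * Q(alpha, t / theta)

    where Q is the regularized upper incomplete gamma function (the survival
    function of a gamma law with shape ``alpha`` and scale ``theta``).  By
    construction p(0) = 1, p is non-increasing and p(t) -> p_inf.
    """
    t = np.asarray(t, dtype=float)
    return p_inf + (1.0 - p_inf) * gammaincc(alpha, np.maximum(t, 0.0) / theta)


@dataclass
class BloodSampleTable:
    """Arterial blood samples for one scan.

    ``plasma_activity`` may be NaN where only whole-blood counts exist (the
    early continuous segment); ``parent_fraction`` is NaN except at HPLC
    measurement times.  ``extraction_efficiency`` (optional, NaN where not
    measured) divides the parent fraction before fitting.
    """

    time: np.ndarray                      # min post-injection
    wholeblood_activity: np.ndarray       # kBq/mL
    plasma_activity: np.ndarray           # kBq/mL, NaN allowed
    parent_fraction: np.ndarray           # unitless in [0,1], NaN allowed
    extraction_efficiency: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.wholeblood_activity = np.asarray(self.wholeblood_activity, dtype=float)
        self.plasma_activity = np.asarray(self.plasma_activity, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        if self.extraction_efficiency is not None:
            self.extraction_efficiency = np.asarray(self.extraction_efficiency, dtype=float)
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        for name in ("wholeblood_activity", "plasma_activity"):
            arr = getattr(self, name)
            if arr.shape != self.time.shape:
                raise ValidationError(f"{name} must match the time grid")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError(f"{name} must be non-negative")
        pf = self.parent_fraction[np.isfinite(self.parent_fraction)]
        if np.any((pf < 0) | (pf > 1)):
            raise ValidationError("parent fractions must lie in [0, 1]")

    # -- CSV dialect shared with the synthetic generator ---------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_min": self.time,
                "wholeblood_kBq_mL": self.wholeblood_activity,
                "plasma_kBq_mL": self.plasma_activity,
                "parent_fraction": self.parent_fraction,
            }
        )
        if self.extraction_efficiency is not None:
            df["extraction_efficiency"] = self.extraction_efficiency
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BloodSampleTable":
        df = pd.read_csv(path)
        eff = df["extraction_efficiency"].to_numpy() if "extraction_efficiency" in df else None
        return cls(
            time=df["time_min"].to_numpy(),
            wholeblood_activity=df["wholeblood_kBq_mL"].to_numpy(),
            plasma_activity=df["plasma_kBq_mL"].to_numpy(),
            parent_fraction=df["parent_fraction"].to_numpy(),
            extraction_efficiency=eff,
        )


@dataclass
class ParentFractionFit:
    """Fitted parent-fraction curve p(t)."""

    p_inf: float
    alpha: float
    theta: float
    fit_residual_rms: float
    method: str = "gamma_survival"          # or "monotone_spline" fallback
    _spline: Callable | None = field(default=None, repr=False, compare=False)

    def __call__(self, t):
        if self.method == "monotone_spline":
            t = np.asarray(t, dtype=float)
            return np.clip(self._spline(np.maximum(t, 0.0)), 0.0, 1.0)
        return parent_fraction_curve(t, self.p_inf, self.alpha, self.theta)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "p_inf": self.p_inf,
                    "alpha": self.alpha,
                    "theta": self.theta,
                    "fit_residual_rms": self.fit_residual_rms,
                    "method": self.method,
                },
                fh,
                indent=2,
            )


def fit_parent_fraction(samples: BloodSampleTable, p0=(0.2, 1.5, 20.0)) -> ParentFractionFit:
    """Least-squares fit of the inverted-gamma parent-fraction model.

    Measurements are divided by their extraction efficiencies where supplied
    before fitting.  Requires at least 4 parent-fraction measurements.  If the
    parametric fit fails to converge, falls back to a monotone (PCHIP) spline
    through the measurements, flagged in ``method``.
    """
    mask = np.isfinite(samples.parent_fraction)
    t = samples.time[mask]
    p = samples.parent_fraction[mask].copy()
    if samples.extraction_efficiency is not None:
        eff = samples.extraction_efficiency[mask]
        ok = np.isfinite(eff)
        if np.any((eff[ok] <= 0) | (eff[ok] > 1)):
            raise ValidationError("extraction efficiencies must lie in (0, 1]")
        p[ok] = np.clip(p[ok] / eff[ok], 0.0, 1.0)
    if t.size < 4:
        raise InsufficientDataError(
            f"parent-fraction fit needs >= 4 measurements, got {t.size}"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                parent_fraction_curve,
                t,
                p,
                p0=p0,
                bounds=([0.0, 1e-3, 1e-3], [1.0, 50.0, 500.0]),
                maxfev=20000,
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        resid = p - parent_fraction_curve(t, *popt)
        return ParentFractionFit(
            p_inf=float(popt[0]),
            alpha=float(popt[1]),
            theta=float(popt[2]),
            fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
    except RuntimeError:
        # monotone fallback: non-increasing envelope through (0, 1) and the data
        tt = np.concatenate([[0.0], t])
        pp = np.concatenate([[1.0], np.minimum.accumulate(np.clip(p, 0.0, 1.0))])
        spline = PchipInterpolator(tt, pp, extrapolate=False)
        tail = float(pp[-1])
        t_end = float(tt[-1])

        def curve(x):
            x = np.asarray(x, dtype=float)
            out = np.where(x >= t_end, tail, spline(np.clip(x, 0.0, t_end)))
            return out

        resid = p - curve(t)
        return ParentFractionFit(
            p_inf=tail,
            alpha=float("nan"),
            theta=float("nan"),
            fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
            method="monotone_spline",
            _spline=curve,
        )


class InputFunction:
    """Metabolite-corrected arterial plasma input C_p(t).

    Interpolation contract: piecewise linear between grid points, identically
    zero before the first point, and a mono-exponential tail fitted to the
    last three points beyond the last sample (held constant if the tail is
    non-decaying).  The running integral is exact under this contract.
    """

    def __init__(self, time: np.ndarray, corrected_plasma: np.ndarray):
        time = np.asarray(time, dtype=float)
        values = np.asarray(corrected_plasma, dtype=float)
        if time.ndim != 1 or np.any(np.diff(time) <= 0):
            raise ValidationError("input-function grid must be strictly increasing")
        if values.shape != time.shape:
            raise ValidationError("grid and values must have the same length")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("input-function values must be finite and >= 0")
        self.time = time
        self.values = values
        # cumulative integral at the grid nodes (zero-order start at t=0)
        seg = 0.5 * (values[1:] + values[:-1]) * np.diff(time)
        if time[0] > 0:
            # linear rise from the declared zero at first sample is NOT assumed:
            # contract says zero before the first point, so no area before it.
            pass
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        # mono-exponential tail from the last three points
        self._tail_lambda = 0.0
        if time.size >= 3:
            t3, v3 = time[-3:], values[-3:]
            if np.all(v3 > 0):
                slope = np.polyfit(t3, np.log(v3), 1)[0]
                if slope < 0:
                    self._tail_lambda = -slope

    def __call__(self, t):
        scalar = np.isscalar(t) or np.asarray(t).ndim == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.interp(t, self.time, self.values, left=0.0)
        beyond = t > self.time[-1]
        if np.any(beyond):
            dt = t[beyond] - self.time[-1]
            out[beyond] = self.values[-1] * np.exp(-self._tail_lambda * dt)
        return float(out[0]) if scalar else out

    def integrate(self, t):
        """Running integral of C_p from 0 to ``t`` (kBq·min/mL)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValidationError("integration endpoint must be >= 0")
        if np.any(t > 2.0 * self.time[-1]):
            warnings.warn(
                "integrating input function beyond twice the last sample time; "
                "tail extrapolation may be unreliable",
                stacklevel=2,
            )
        out = np.empty_like(t)
        inside = t <= self.time[-1]
        if np.any(inside):
            ti = t[inside]
            idx = np.searchsorted(self.time, ti, side="right") - 1
            idx = np.clip(idx, 0, self.time.size - 1)
            base = self._cum[idx]
            # area of the partial linear segment (zero before first sample)
            vt = np.interp(ti, self.time, self.values, left=0.0)
            frac = np.where(
                ti <= self.time[0],
                0.0,
                0.5 * (self.values[idx] + vt) * (ti - self.time[idx]),
            )
            out[inside] = base + frac
        if np.any(~inside):
            dt = t[~inside] - self.time[-1]
            lam, v = self._tail_lambda, self.values[-1]
            if lam > 0:
                tail = v / lam * (1.0 - np.exp(-lam * dt))
            else:
                tail = v * dt
            out[~inside] = self._cum[-1] + tail
        return out if out.size > 1 else float(out[0])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"time_min": self.time.tolist(), "corrected_plasma_kBq_mL": self.values.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "InputFunction":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["time_min"]), np.asarray(d["corrected_plasma_kBq_mL"]))


def build_input_function(
    samples: BloodSampleTable, pf: ParentFractionFit
) -> InputFunction:
    """Metabolite-corrected input: plasma activity × fitted parent fraction.

    Where plasma activity is missing (continuous early whole-blood segment),
    it is derived as whole blood × plasma-to-whole-blood ratio, with the
    ratio taken as the median over samples carrying both measurements.
    """
    plasma = samples.plasma_activity.copy()
    missing = ~np.isfinite(plasma)
    if np.any(missing):
        both = np.isfinite(samples.plasma_activity) & np.isfinite(samples.wholeblood_activity)
        both &= samples.wholeblood_activity > 0
        if not np.any(both):
            raise ValidationError(
                "cannot derive plasma activity: no samples with both plasma and whole blood"
            )
        ratio = float(
            np.median(samples.plasma_activity[both] / samples.wholeblood_activity[both])
        )
        plasma[missing] = samples.wholeblood_activity[missing] * ratio
    if np.any(~np.isfinite(plasma)) or np.any(plasma < 0):
        raise ValidationError("plasma activities must be finite and non-negative")
    corrected = plasma * np.clip(pf(samples.time), 0.0, 1.0)
    return InputFunction(samples.time, corrected)


def integrate_input(input_fn: InputFunction, t) -> float:
    """∫₀ᵗ C_p(s) ds under the input function's interpolation contract."""
    return input_fn.integrate(t)
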