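"""Regional V_T estimation by multilinear analysis-1 (MA1) and composites.

The total volume of distribution V_T of a reversible tracer is the
equilibrium tissue-to-plasma concentration ratio.  MA1 linearizes the
compartmental solution for frames with midpoint later than t*:

    C_T(t) = -V_T/b * ∫₀ᵗ C_p(s) ds  +  1/b * ∫₀ᵗ C_T(s) ds

and estimates (β₁, β₂) = (-V_T/b, 1/b) by weighted linear least squares, so
V_T = -β₁/β₂.  The Logan graphical method is provided as an internal
cross-check, not as a primary estimator.  Whole-brain availability is a
volume-weighted composite of the four cortical lobes and the cerebellum.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateFitError,
    EmptyCompositeError,
    InsufficientDataError,
    ValidationError,
)
from .input_function import InputFunction

__all__ = [
    "TimeActivityCurve",
    "VTEstimate",
    "ma1_vt",
    "logan_vt",
    "composite_whole_brain",
    "default_region_weights",
    "read_tacs",
    "write_tacs",
]

#: regions entering the whole-brain composite
COMPOSITE_REGIONS = ("frontal", "temporal", "parietal", "occipital", "cerebellum")


@dataclass
class TimeActivityCurve:
    """Regional PET activity per reconstructed frame."""

    region: str
    frame_start: np.ndarray      # min
    frame_end: np.ndarray        # min
    activity: np.ndarray         # kBq/mL
    frame_weight: np.ndarray | None = None   # default ∝ frame duration

    def __post_init__(self):
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_end = np.asarray(self.frame_end, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if not (self.frame_start.shape == self.frame_end.shape == self.activity.shape):
            raise ValidationError("frame arrays must have identical shapes")
        if np.any(self.frame_end <= self.frame_start):
            raise ValidationError("frame_end must exceed frame_start")
        if np.any(self.frame_start[1:] < self.frame_end[:-1] - 1e-9):
            raise ValidationError("frames must be ordered and non-overlapping")
        if np.any(~np.isfinite(self.activity)):
            raise ValidationError("activities must be finite")
        if self.frame_weight is None:
            self.frame_weight = self.durations.copy()
        else:
            self.frame_weight = np.asarray(self.frame_weight, dtype=float)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start


@dataclass
class VTEstimate:
    """One regional V_T estimate with fit diagnostics.

    Non-positive or non-finite V_T values are retained but flagged invalid;
    composites and regressions exclude them.
    """

    region: str
    vt: float
    b: float                     # MA1 nuisance coefficient (min); Logan: intercept
    n_frames_used: int
    condition_number: float
    residual_rms: float
    method: str = "MA1"

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.vt) and self.vt > 0)


def _tissue_running_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal ∫₀ᵗ C_T at frame midpoints, with C_T(0) = 0."""
    t = np.concatenate([[0.0], tac.midpoints])
    v = np.concatenate([[0.0], tac.activity])
    seg = 0.5 * (v[1:] + v[:-1]) * np.diff(t)
    return np.cumsum(seg)


def ma1_vt(
    tac: TimeActivityCurve, input_fn: InputFunction, t_star: float = 30.0
) -> VTEstimate:
    """MA1 estimate of V_T from frames with midpoint > t*.

    Weighted least squares of frame activity on the running plasma and
    tissue integrals (weights default to frame durations).
    """
    mids = tac.midpoints
    mask = mids > t_star
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"MA1 needs >= 3 frames beyond t*={t_star} min, got {int(mask.sum())}"
        )
    int_cp = np.atleast_1d(input_fn.integrate(mids))
    int_ct = _tissue_running_integral(tac)
    X = np.column_stack([int_cp[mask], int_ct[mask]])
    y = tac.activity[mask]
    w = np.sqrt(tac.frame_weight[mask])
    Xw, yw = X * w[:, None], y * w
    beta, _, _, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    if abs(beta[1]) < 1e-12:
        raise DegenerateFitError("MA1 fit degenerate: 1/b coefficient ~ 0")
    vt = -beta[0] / beta[1]
    resid = y - X @ beta
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    return VTEstimate(
        region=tac.region,
        vt=float(vt),
        b=float(1.0 / beta[1]),
        n_frames_used=int(mask.sum()),
        condition_number=cond,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        method="MA1",
    )


def logan_vt(
    tac: TimeActivityCurve, input_fn: InputFunction, t_star: float = 30.0
) -> VTEstimate:
    """Logan graphical V_T: slope of ∫C_T/C_T versus ∫C_p/C_T beyond t*.

    Internal cross-check for MA1; shares the integral conventions above.
    """
    mids = tac.midpoints
    mask = mids > t_star
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"Logan needs >= 3 frames beyond t*={t_star} min, got {int(mask.sum())}"
        )
    ct = tac.activity[mask]
    if np.any(ct <= 0):
        raise DegenerateFitError("Logan fit degenerate: non-positive activity beyond t*")
    x = np.atleast_1d(input_fn.integrate(mids))[mask] / ct
    ygr = _tissue_running_integral(tac)[mask] / ct
    X = np.column_stack([x, np.ones_like(x)])
    beta, _, _, sv = np.linalg.lstsq(X, ygr, rcond=None)
    resid = ygr - X @ beta
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    return VTEstimate(
        region=tac.region,
        vt=float(beta[0]),
        b=float(beta[1]),
        n_frames_used=int(mask.sum()),
        condition_number=cond,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        method="Logan",
    )


def default_region_weights() -> dict[str, float]:
    """Relative volumes of the four lobes and cerebellum (atlas-derived table)."""
    with resources.files("cb1pet.data").joinpath("lobe_weights.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["region"], df["weight"]))


def composite_whole_brain(
    estimates: Mapping[str, VTEstimate] | list[VTEstimate],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Volume-weighted composite V_T: Σ wᵢ·vtᵢ / Σ wᵢ over valid estimates.

    ``weights`` must cover every valid supplied region (extra entries are
    ignored); defaults to the shipped lobe/cerebellum relative volumes.
    """
    if weights is None:
        weights = default_region_weights()
    if not isinstance(estimates, Mapping):
        estimates = {e.region: e for e in estimates}
    valid = {r: e for r, e in estimates.items() if e.valid}
    if not valid:
        raise EmptyCompositeError("no valid regional V_T estimates for composite")
    missing = set(valid) - set(weights)
    if missing:
        raise ValidationError(f"no composite weight defined for regions: {sorted(missing)}")
    w = np.array([weights[r] for r in valid])
    if np.any(w <= 0):
        raise ValidationError("composite weights must be positive")
    v = np.array([e.vt for e in valid.values()])
    return float(np.sum(w * v) / np.sum(w))


# -- TAC CSV dialect ---------------------------------------------------------

def write_tacs(tacs: list[TimeActivityCurve], path) -> None:
    frames = []
    for tac in tacs:
        frames.append(
            pd.DataFrame(
                {
                    "region": tac.region,
                    "frame_start_min": tac.frame_start,
                    "frame_end_min": tac.frame_end,
                    "activity_kBq_mL": tac.activity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tacs(path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(path)
    out = {}
    for region, g in df.groupby("region", sort=False):
        out[str(region)] = TimeActivityCurve(
            region=str(region),
            frame_start=g["frame_start_min"].to_numpy(),
            frame_end=g["frame_end_min"].to_numpy(),
            activity=g["activity_kBq_mL"].to_numpy(),
        )
    return out
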