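"""Synthetic study generator: cohort, tracer kinetics, blood and TAC data.

Emulates the structure of a CB1R PET study of PTSD: three groups (PTSD,
trauma-exposed controls, healthy controls) with group-specific demographics,
CAPS-5 symptom-cluster scores for the trauma-exposed subjects, regional
ground-truth V_T values with configurable linear effects of demographic and
symptom predictors, a Feng-type arterial input model with inverted-gamma
parent-fraction kinetics, and noisy two-tissue-compartment time-activity
curves on a 33-frame, 120-min schedule.  Everything is deterministic given
the configured seed, and ground truth is exported alongside the data so the
estimation chain can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, ValidationError
from .input_function import InputFunction, parent_fraction_curve
from .kinetics import COMPOSITE_REGIONS, TimeActivityCurve, default_region_weights

__all__ = [
    "KineticParams",
    "FengParams",
    "InputFunctionModel",
    "FrameSchedule",
    "CohortConfig",
    "analytic_vt",
    "kinetic_params_for_vt",
    "simulate_tac",
    "simulate_blood",
    "generate_cohort",
    "DEFAULT_DRAW_TIMES",
    "DEFAULT_HPLC_TIMES",
    "CLUSTER_ITEMS",
    "DSM5_FROM_8",
]

#: discrete arterial draw schedule (min post-injection)
DEFAULT_DRAW_TIMES = (3, 5, 7, 10, 15, 20, 30, 45, 60, 75, 90, 105, 120)
#: HPLC metabolite-analysis times (min)
DEFAULT_HPLC_TIMES = (5, 15, 30, 60, 90, 120)

#: 8-factor CAPS-5 clusters with their item counts (20 items total, 0-4 each)
CLUSTER_ITEMS = {
    "internal_intrusion": 3,
    "external_intrusion": 2,
    "avoidance": 2,
    "negative_affect": 4,
    "anhedonia": 3,
    "externalizing": 2,
    "anxious_arousal": 2,
    "dysphoric_arousal": 2,
}

#: DSM-5 clusters as sums of the 8-factor clusters (keeps totals consistent)
DSM5_FROM_8 = {
    "dsm5_b_intrusion": ("internal_intrusion", "external_intrusion"),
    "dsm5_c_avoidance": ("avoidance",),
    "dsm5_d_mood_cognition": ("negative_affect", "anhedonia"),
    "dsm5_e_arousal": ("externalizing", "anxious_arousal", "dysphoric_arousal"),
}


# ---------------------------------------------------------------------------
# kinetic ground truth
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Two-tissue-compartment rate constants.

    K1 [mL·cm⁻³·min⁻¹] plasma-to-tissue delivery; k2 [min⁻¹] efflux;
    k3/k4 [min⁻¹] exchange with the specifically bound pool; vB blood-volume
    fraction.  k3 = 0 reduces to the one-tissue model.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 <= 0:
            raise ConfigurationError("require K1 >= 0 and k2 > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ConfigurationError("k3 and k4 must be >= 0")
        if not 0.0 <= self.vB < 1.0:
            raise ConfigurationError("vB must lie in [0, 1)")


def analytic_vt(params: KineticParams) -> float:
    """Closed-form V_T = (K1/k2)·(1 + k3/k4); k3 = 0 gives K1/k2."""
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 == 0:
        raise ConfigurationError("k3 > 0 with k4 = 0: V_T undefined (irreversible binding)")
    return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)


def kinetic_params_for_vt(
    vt: float, K1: float = 0.1, k3: float = 0.05, k4: float = 0.05, vB: float = 0.0
) -> KineticParams:
    """Rate constants with a prescribed analytic V_T (k2 solved for)."""
    if vt <= 0:
        raise ConfigurationError("target V_T must be positive")
    k2 = K1 * (1.0 + (k3 / k4 if k3 > 0 else 0.0)) / vt
    return KineticParams(K1=K1, k2=k2, k3=k3, k4=k4, vB=vB)


# ---------------------------------------------------------------------------
# arterial input model
# ---------------------------------------------------------------------------

@dataclass
class FengParams:
    """Feng-type arterial curve: linear upslope times a fast exponential plus
    two slower exponentials, C(τ) = (A1·τ − A2 − A3)e^(−λ1 τ) + A2 e^(−λ2 τ)
    + A3 e^(−λ3 τ) for τ = t − delay ≥ 0 (zero before the delay)."""

    A1: float = 300.0     # kBq/mL/min
    A2: float = 15.0      # kBq/mL
    A3: float = 12.0      # kBq/mL
    l1: float = 4.0       # min⁻¹
    l2: float = 0.25      # min⁻¹
    l3: float = 0.012     # min⁻¹

    def __call__(self, t):
        tau = np.maximum(np.asarray(t, dtype=float), 0.0)
        c = (
            (self.A1 * tau - self.A2 - self.A3) * np.exp(-self.l1 * tau)
            + self.A2 * np.exp(-self.l2 * tau)
            + self.A3 * np.exp(-self.l3 * tau)
        )
        return np.maximum(c, 0.0)


@dataclass
class InputFunctionModel:
    """Ground-truth arterial model: total plasma curve, parent fraction,
    and plasma-to-whole-blood ratio."""

    feng: FengParams = field(default_factory=FengParams)
    delay: float = 0.5                       # min
    pf_p_inf: float = 0.12                   # terminal parent fraction
    pf_alpha: float = 1.5                    # shape
    pf_theta: float = 20.0                   # scale, min
    plasma_to_wholeblood_ratio: float = 1.3

    def __post_init__(self):
        if not 0.0 <= self.pf_p_inf <= 1.0:
            raise ConfigurationError("terminal parent fraction must lie in [0, 1]")
        if self.pf_alpha <= 0 or self.pf_theta <= 0:
            raise ConfigurationError("parent-fraction shape/scale must be > 0")

    def total_plasma(self, t):
        return self.feng(np.asarray(t, dtype=float) - self.delay)

    def parent_fraction(self, t):
        return parent_fraction_curve(t, self.pf_p_inf, self.pf_alpha, self.pf_theta)

    def parent_plasma(self, t):
        """Metabolite-corrected (parent-only) plasma concentration."""
        return self.total_plasma(t) * self.parent_fraction(t)

    def wholeblood(self, t):
        return self.total_plasma(t) / self.plasma_to_wholeblood_ratio

    def to_input_function(self, t_end: float = 120.0, dt: float = 0.05) -> InputFunction:
        """Densely sampled true metabolite-corrected input."""
        grid = np.arange(0.0, t_end + dt / 2, dt)
        return InputFunction(grid, self.parent_plasma(grid))


# ---------------------------------------------------------------------------
# frame schedule
# ---------------------------------------------------------------------------

@dataclass
class FrameSchedule:
    """PET frame timing (min); default is 33 frames spanning 0-120 min:
    6×30 s, 3×60 s, 2×120 s, 22×300 s."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self):
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_end = np.asarray(self.frame_end, dtype=float)
        if np.any(self.frame_end <= self.frame_start) or np.any(
            np.diff(self.frame_start) <= 0
        ):
            raise ConfigurationError("frames must be increasing and non-degenerate")
        if np.any(self.frame_start[1:] < self.frame_end[:-1] - 1e-9):
            raise ConfigurationError("frames must not overlap")

    @classmethod
    def default(cls) -> "FrameSchedule":
        durations = np.concatenate(
            [np.full(6, 0.5), np.full(3, 1.0), np.full(2, 2.0), np.full(22, 5.0)]
        )
        ends = np.cumsum(durations)
        return cls(frame_start=ends - durations, frame_end=ends)

    @property
    def midpoints(self):
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self):
        return self.frame_end - self.frame_start

    @property
    def n_frames(self):
        return self.frame_start.size


# ---------------------------------------------------------------------------
# TAC simulation
# ---------------------------------------------------------------------------

def simulate_tac(
    params: KineticParams,
    input_fn,
    schedule: FrameSchedule | None = None,
    noise_scale: float = 0.0,
    seed: int | None = None,
    region: str = "region",
    wholeblood_fn=None,
) -> TimeActivityCurve:
    """Simulate a framed time-activity curve from two-tissue kinetics.

    Solves dC1/dt = K1·Cp − (k2+k3)·C1 + k4·C2, dC2/dt = k3·C1 − k4·C2 with
    ``input_fn`` as Cp (any callable, e.g. an :class:`InputFunction`), plus
    the running tissue integral so frame averages are exact.  Frame activity
    is (1−vB)·mean(C1+C2) + vB·mean(C_wholeblood); additive Gaussian noise
    has SD = noise_scale·sqrt(activity / frame duration), the usual
    count-statistics surrogate (longer frames are less noisy).
    """
    if schedule is None:
        schedule = FrameSchedule.default()
    t_end = float(schedule.frame_end[-1])

    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    def rhs(t, yv):
        cp = input_fn(t)
        c1, c2 = yv[0], yv[1]
        return (
            K1 * cp - (k2 + k3) * c1 + k4 * c2,
            k3 * c1 - k4 * c2,
            c1 + c2,
        )

    t_nodes = np.unique(np.concatenate([[0.0], schedule.frame_start, schedule.frame_end]))
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0, 0.0, 0.0],
        t_eval=t_nodes,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        max_step=0.25,
    )
    if not sol.success:
        raise ArithmeticError(f"tissue ODE solver failed: {sol.message}")
    cum = dict(zip(sol.t, sol.y[2]))
    dur = schedule.durations
    tissue_mean = np.array(
        [
            (cum[e] - cum[s]) / (e - s)
            for s, e in zip(schedule.frame_start, schedule.frame_end)
        ]
    )
    activity = (1.0 - params.vB) * tissue_mean
    if params.vB > 0:
        if wholeblood_fn is None:
            raise ConfigurationError("vB > 0 requires a whole-blood curve")
        # frame-average whole blood by fine trapezoid
        wb = np.array(
            [
                np.trapezoid(wholeblood_fn(np.linspace(s, e, 21)), np.linspace(s, e, 21))
                / (e - s)
                for s, e in zip(schedule.frame_start, schedule.frame_end)
            ]
        )
        activity = activity + params.vB * wb
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.maximum(activity, 0.0) / dur)
        activity = activity + rng.normal(0.0, 1.0, size=activity.size) * sd
    return TimeActivityCurve(
        region=region,
        frame_start=schedule.frame_start.copy(),
        frame_end=schedule.frame_end.copy(),
        activity=activity,
    )


# ---------------------------------------------------------------------------
# blood sampling
# ---------------------------------------------------------------------------

def simulate_blood(
    input_model: InputFunctionModel,
    draw_times=DEFAULT_DRAW_TIMES,
    hplc_times=DEFAULT_HPLC_TIMES,
    noise_scale: float = 0.0,
    pf_noise: float = 0.0,
    seed: int | None = None,
    continuous_dt: float | None = None,
):
    """Simulate the arterial sampling protocol.

    Returns a :class:`~cb1pet.input_function.BloodSampleTable` with whole-blood
    and plasma activity at the discrete draw times (optionally preceded by a
    continuous whole-blood-only segment up to 7 min at spacing
    ``continuous_dt``) and parent-fraction measurements at the HPLC times.
    ``noise_scale`` is the fractional SD on activities; ``pf_noise`` the
    absolute SD on parent fractions (clipped to [0, 1]).
    """
    from .input_function import BloodSampleTable

    draw_times = np.asarray(draw_times, dtype=float)
    hplc_times = np.asarray(hplc_times, dtype=float)
    if np.any(draw_times <= 0) or np.any(draw_times > 120):
        raise ValidationError("draw times must lie in (0, 120] min")
    if not np.all(np.isin(hplc_times, draw_times)):
        raise ValidationError("HPLC times must be a subset of the draw times")
    times = draw_times
    continuous_mask = np.zeros(times.size, dtype=bool)
    if continuous_dt is not None:
        early = np.arange(continuous_dt, 7.0 + 1e-9, continuous_dt)
        early = early[~np.isin(early, draw_times)]
        times = np.sort(np.concatenate([early, draw_times]))
        continuous_mask = np.isin(times, early)
    rng = np.random.default_rng(seed)
    plasma = input_model.total_plasma(times)
    wholeblood = plasma / input_model.plasma_to_wholeblood_ratio
    if noise_scale > 0:
        plasma = plasma * (1.0 + rng.normal(0.0, noise_scale, times.size))
        wholeblood = wholeblood * (1.0 + rng.normal(0.0, noise_scale, times.size))
        plasma = np.maximum(plasma, 0.0)
        wholeblood = np.maximum(wholeblood, 0.0)
    # continuous detector measures whole blood only
    plasma = np.where(continuous_mask, np.nan, plasma)
    pf = np.full(times.size, np.nan)
    at_hplc = np.isin(times, hplc_times)
    pf_true = input_model.parent_fraction(times[at_hplc])
    if pf_noise > 0:
        pf_true = pf_true + rng.normal(0.0, pf_noise, pf_true.size)
    pf[at_hplc] = np.clip(pf_true, 0.0, 1.0)
    return BloodSampleTable(
        time=times,
        wholeblood_activity=wholeblood,
        plasma_activity=plasma,
        parent_fraction=pf,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _default_baselines() -> dict[str, float]:
    return {
        "amygdala": 1.40,
        "hippocampus": 1.30,
        "frontal": 1.20,
        "temporal": 1.25,
        "parietal": 1.15,
        "occipital": 1.10,
        "cerebellum": 1.00,
    }


@dataclass
class CohortConfig:
    """Study-cohort generator configuration.

    Defaults reproduce the study structure: n = 19 PTSD / 27 TC / 16 HC;
    group-specific male fractions (10/19, 25/27, 9/16), ages (42.6±13.0,
    45.8±13.9, 29.4±8.2 y) and BMI (30.1±5.8, 29.7±6.0, 25.8±4.9 kg/m²);
    CAPS-5 totals 38.4±9.3 (PTSD) and 8.7±6.9 (TC), absent for HC, with two
    TC subjects missing CAPS so the symptom-analysis subset has n = 44.
    ``effect_sizes`` maps predictor names (group/sex indicators ``ptsd``,
    ``tc``, ``female``; raw ``age``, ``bmi``, ``caps_total``; any 8-factor
    cluster name) to V_T units per predictor unit; the default plants an
    anhedonia slope of 0.014 V_T units per CAPS point.
    """

    n_ptsd: int = 19
    n_tc: int = 27
    n_hc: int = 16
    male_prob_by_group: dict = field(
        default_factory=lambda: {"PTSD": 10 / 19, "TC": 25 / 27, "HC": 9 / 16}
    )
    age_mean_sd_by_group: dict = field(
        default_factory=lambda: {
            "PTSD": (42.58, 13.03),
            "TC": (45.78, 13.90),
            "HC": (29.37, 8.16),
        }
    )
    bmi_mean_sd_by_group: dict = field(
        default_factory=lambda: {
            "PTSD": (30.133, 5.79),
            "TC": (29.74, 6.04),
            "HC": (25.76, 4.88),
        }
    )
    caps_mean_sd: dict = field(
        default_factory=lambda: {"PTSD": (38.42, 9.34), "TC": (8.72, 6.91)}
    )
    cluster_correlation: float = 0.6
    n_tc_missing_caps: int = 2
    effect_sizes: dict = field(default_factory=lambda: {"anhedonia": 0.014})
    baseline_vt_by_region: dict = field(default_factory=_default_baselines)
    residual_scale: float = 0.25     # V_T units; Student-t residual scale
    residual_df: float = 5.0
    outlier_fraction: float = 0.05
    outlier_shift: float = 4.0       # gross-outlier shift in residual_scale units
    region_noise: float = 0.0        # extra per-region jitter SD (V_T units)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ptsd, self.n_tc, self.n_hc) < 0:
            raise ConfigurationError("group sizes must be >= 0")
        for g, p in self.male_prob_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"male probability for {g} must be in [0, 1]")
        for d in (self.age_mean_sd_by_group, self.bmi_mean_sd_by_group, self.caps_mean_sd):
            for g, (_, sd) in d.items():
                if sd <= 0:
                    raise ConfigurationError(f"SD for {g} must be > 0")
        if self.residual_scale < 0:
            raise ConfigurationError("residual_scale must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigurationError("outlier_fraction must be in [0, 1]")

    @property
    def regions(self):
        return tuple(self.baseline_vt_by_region)


def _draw_clusters(rng, n, total_mean, total_sd, correlation):
    """Correlated non-negative integer 8-cluster scores.

    Truncated multivariate normal with equicorrelation, per-cluster location
    proportional to item count, rounded and capped at 4 points per item; the
    common scale is set so the summed total has approximately the requested
    SD before truncation.
    """
    names = list(CLUSTER_ITEMS)
    w = np.array([CLUSTER_ITEMS[c] for c in names], dtype=float)
    w = w / w.sum()
    rho = correlation
    # Var(total) = s² (Σw² + ρ((Σw)² − Σw²)) for sd_i = s·w_i
    norm = np.sqrt(np.sum(w**2) + rho * (1.0 - np.sum(w**2)))
    sds = total_sd * w / norm
    cov = np.outer(sds, sds) * (rho + (1.0 - rho) * np.eye(len(names)))
    means = total_mean * w
    raw = rng.multivariate_normal(means, cov, size=n, method="cholesky")
    caps = 4.0 * np.array([CLUSTER_ITEMS[c] for c in names])
    scores = np.clip(np.rint(raw), 0.0, caps)
    return pd.DataFrame(scores, columns=[f"cl_{c}" for c in names])


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the subject table with ground-truth regional V_T.

    True V_T per region is baseline + Σ effect·predictor + a shared
    Student-t subject residual (with gross-outlier contamination) + optional
    per-region jitter.  The whole-brain column is the volume-weighted
    composite of the lobes and cerebellum.  Deterministic given
    ``config.seed``.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)

    rows = []
    for group, n in (("HC", config.n_hc), ("TC", config.n_tc), ("PTSD", config.n_ptsd)):
        if n == 0:
            continue
        a_m, a_s = config.age_mean_sd_by_group[group]
        b_m, b_s = config.bmi_mean_sd_by_group[group]
        male = rng.random(n) < config.male_prob_by_group[group]
        age = np.clip(rng.normal(a_m, a_s, n), 18.0, 85.0)
        bmi = np.clip(rng.normal(b_m, b_s, n), 16.0, 55.0)
        g = pd.DataFrame(
            {
                "group": group,
                "sex": np.where(male, "male", "female"),
                "age": age,
                "bmi": bmi,
            }
        )
        if group in config.caps_mean_sd:
            m, s = config.caps_mean_sd[group]
            g = pd.concat(
                [g.reset_index(drop=True),
                 _draw_clusters(rng, n, m, s, config.cluster_correlation)],
                axis=1,
            )
        rows.append(g)
    cohort = pd.concat(rows, ignore_index=True)
    cluster_cols = [f"cl_{c}" for c in CLUSTER_ITEMS]
    for c in cluster_cols:
        if c not in cohort:
            cohort[c] = np.nan
    # a couple of TC subjects without CAPS (symptom-analysis subset n = 44)
    tc_idx = cohort.index[cohort["group"] == "TC"]
    drop = tc_idx[: min(config.n_tc_missing_caps, tc_idx.size)]
    cohort.loc[drop, cluster_cols] = np.nan
    for dsm, parts in DSM5_FROM_8.items():
        cohort[dsm] = sum(cohort[f"cl_{p}"] for p in parts)
    cohort["caps_total"] = cohort[cluster_cols].sum(axis=1, min_count=len(cluster_cols))

    # ground-truth V_T
    female = (cohort["sex"] == "female").astype(float)
    predictors = {
        "ptsd": (cohort["group"] == "PTSD").astype(float),
        "tc": (cohort["group"] == "TC").astype(float),
        "female": female,
        "age": cohort["age"],
        "bmi": cohort["bmi"],
        "caps_total": cohort["caps_total"].fillna(0.0),
    }
    for c in CLUSTER_ITEMS:
        predictors[c] = cohort[f"cl_{c}"].fillna(0.0)
    shift = np.zeros(len(cohort))
    for name, eff in config.effect_sizes.items():
        if name not in predictors:
            raise ConfigurationError(f"unknown effect predictor: {name}")
        shift = shift + eff * predictors[name].to_numpy()
    n_sub = len(cohort)
    if config.residual_scale > 0:
        resid = config.residual_scale * rng.standard_t(config.residual_df, n_sub)
        gross = rng.random(n_sub) < config.outlier_fraction
        resid = resid + gross * rng.choice([-1.0, 1.0], n_sub) * (
            config.outlier_shift * config.residual_scale
        )
    else:
        resid = np.zeros(n_sub)
    for region, base in config.baseline_vt_by_region.items():
        vt = base + shift + resid
        if config.region_noise > 0:
            vt = vt + rng.normal(0.0, config.region_noise, n_sub)
        # V_T is a physical concentration ratio; keep truth positive
        cohort[f"vt_{region}"] = np.maximum(vt, 0.05)
    weights = default_region_weights()
    have = [r for r in COMPOSITE_REGIONS if f"vt_{r}" in cohort]
    if have:
        w = np.array([weights[r] for r in have])
        comp = cohort[[f"vt_{r}" for r in have]].to_numpy() @ w / w.sum()
        cohort["vt_whole_brain"] = comp

    cohort.insert(0, "subject_id", [f"S{i:03d}" for i in range(1, n_sub + 1)])
    return cohort


def cohort_truth_sidecar(config: CohortConfig) -> dict:
    """JSON-serializable record of the generating parameters."""
    d = asdict(config)
    return d
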