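"""Synthetic TSST cohort generator.

Simulates complete laboratory stress-test cohorts with the statistical
structure the downstream pipeline assumes: salivary cortisol sampled at an
arrival occasion plus six post-baseline occasions (T1..T6), blood pressure
and heart rate at five phases (baseline, preparation, speech, mental
arithmetic, recovery), 48 candidate predictors with planted linear effects
on a latent resilience index, stressor exposures, and a psychological
distress outcome inversely related to the index.

The generator is the ground-truth oracle for every downstream stage: the
planted parameters are returned alongside the data so that feature
extraction, PCA integration, the validity regression and the LASSO
selection can all be scored against a known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "PREDICTOR_NAMES",
    "BINARY_PREDICTORS",
    "DEFAULT_TRUE_COEFFICIENTS",
    "simulate_cortisol",
    "simulate_cardio",
    "simulate_predictors_and_outcomes",
    "inject_missingness",
    "generate_cohort",
]

CORTISOL_LABELS = ("arrival", "T1", "T2", "T3", "T4", "T5", "T6")
CARDIO_LABELS = ("baseline", "preparation", "speech", "calculation", "recovery")

# 48 candidate predictors: baseline physiology, mood states around the
# stressor, stressor exposure, affective styles, protective traits, coping
# and cognitive emotion-regulation strategies, cognitive function, and
# demographics.
PREDICTOR_NAMES = (
    "baseline_cortisol",
    "baseline_bp",
    "baseline_hr",
    "positive_mood_baseline",
    "negative_mood_baseline",
    "positive_mood_recovery",
    "negative_mood_recovery",
    "positive_mood_reactivity",
    "negative_mood_reactivity",
    "major_life_events",
    "daily_stressors",
    "perceived_stress",
    "trait_positive_affect",
    "trait_negative_affect",
    "emotion_reactivity",
    "trait_resilience",
    "general_self_efficacy",
    "perceived_loneliness",
    "self_distraction",
    "instrumental_support_seeking",
    "positive_reappraisal",
    "acceptance",
    "behavioral_disengagement",
    "catastrophizing",
    "denial",
    "emotional_support_seeking",
    "humor",
    "other_blame",
    "positive_refocusing",
    "problem_solving",
    "putting_into_perspective",
    "religion",
    "rumination",
    "self_blame",
    "substance_use",
    "venting",
    "immediate_memory",
    "working_memory",
    "interference_inhibition",
    "cognitive_flexibility",
    "inattentiveness",
    "gender",
    "age",
    "education",
    "marital_status",
    "employment_status",
    "income",
    "medical_condition",
)

# Binary predictors are thresholded latent Gaussians at these prevalences
# (male gender, degree-level education, married/cohabiting, full-time
# employment, household income >= HK$45k, minor medical condition).
BINARY_PREDICTORS = {
    "gender": 0.440,
    "education": 0.839,
    "marital_status": 0.290,
    "employment_status": 0.742,
    "income": 0.552,
    "medical_condition": 0.153,
}

# The three baseline-physiology predictors are taken verbatim from the
# simulated trajectories (so they carry a mechanistic, not planted,
# association with the index); planted coefficients may only target the
# remaining questionnaire/cognitive/demographic predictors.
PHYSIO_PREDICTORS = ("baseline_cortisol", "baseline_bp", "baseline_hr")

# Default planted effects: the loading of each predictor's latent Gaussian
# on the standardized resilience index (correlation scale). Ten predictors
# carry signal at |loading| 0.3; jointly they account for
# 10 * 0.3^2 / (1 + 9 * 0.3^2) ~ 0.50 of the index variance.
DEFAULT_TRUE_COEFFICIENTS = {
    "positive_reappraisal": 0.3,
    "instrumental_support_seeking": 0.3,
    "emotional_support_seeking": -0.3,
    "trait_positive_affect": 0.3,
    "self_distraction": 0.3,
    "emotion_reactivity": -0.3,
    "perceived_stress": -0.3,
    "problem_solving": -0.3,
    "interference_inhibition": 0.3,
    "negative_mood_recovery": -0.3,
}


@dataclass
class CohortConfig:
    """Full parameterization of one synthetic cohort.

    ``seed`` fixes every source of randomness end-to-end; two configs that
    compare equal generate bit-identical cohorts.
    """

    n_participants: int = 248
    responder_fraction: float = 0.8
    cortisol_grid_min: tuple = (-30.0, 0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    cardio_grid_min: tuple = (0.0, 5.0, 10.0, 15.0, 50.0)
    true_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    # measurement noise per modality: cortisol is a log-scale SD
    # (multiplicative noise); MAP/HR are additive SDs in native units.
    # Cardio occasions are three-reading phase averages, hence the small SDs.
    noise_sd: dict = field(
        default_factory=lambda: {"cortisol": 0.08, "MAP": 1.5, "HR": 2.0}
    )
    distress_beta: float = -0.25
    seed: int = 0

    # --- shape parameters of the trajectory model ---
    responder_peak_min: float = 35.0  # minutes after T1; snapped to grid
    responder_arrival_ratio: float = 1.25
    nonresponder_arrival_ratio: float = 1.5
    responder_end_ratio: float = 0.85
    nonresponder_end_ratio: float = 0.60
    # cortisol baseline: log-normal, median 1.06 ng/ml
    log_baseline_mu: float = float(np.log(1.06))
    log_baseline_sd: float = 0.72
    # responder relative amplitude: peak = baseline * (1 + rel_amp)
    log_rel_amp_mu: float = float(np.log(1.6))
    log_rel_amp_sd: float = 0.55
    # cardio population means (MAP and HR at the five phases)
    map_baseline_mean: float = 81.0
    map_baseline_sd: float = 9.0
    map_phase_offsets: tuple = (0.0, 11.51, 26.34, 22.30, 1.39)
    hr_baseline_mean: float = 67.75
    hr_baseline_sd: float = 9.5
    hr_phase_offsets: tuple = (0.0, 10.97, 24.87, 18.24, 0.0)
    cardio_react_log_sd: float = 0.20
    cardio_recovery_sd: float = 4.5
    cortisol_recovery_log_sd: float = 0.30
    pulse_pressure_mean: float = 42.0
    pulse_pressure_sd: float = 8.0

    # --- latent structure ---
    # index_coupling: correlation of each of the reactivity / recovery
    # factors with the (negated) latent index; their mutual correlation is
    # index_coupling**2.
    index_coupling: float = 0.72
    modality_loading: float = 0.60
    baseline_recovery_loading: float = 0.25
    # sum of squared index loadings across planted predictors; with the
    # default ten loadings of 0.3 this equals 0.9 and the coefficients are
    # the loadings themselves (sigma_latent = 1)
    planted_variance_share: float = 0.9
    # distress model
    distress_intercept: float = 20.0
    distress_daily_beta: float = 0.08
    distress_major_beta: float = 0.8
    distress_noise_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        for grid in (self.cortisol_grid_min, self.cardio_grid_min):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("sampling grids must be strictly increasing")
        if len(self.cardio_grid_min) != len(self.map_phase_offsets):
            raise ValueError("cardio grid and phase offsets must align")
        unknown = set(self.true_coefficients) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown predictor names in true_coefficients: {sorted(unknown)}")
        planted_physio = set(self.true_coefficients) & set(PHYSIO_PREDICTORS)
        if planted_physio:
            raise ValueError(
                "baseline physiology predictors are generated from trajectories "
                f"and cannot carry planted coefficients: {sorted(planted_physio)}"
            )
        for key in ("cortisol", "MAP", "HR"):
            if self.noise_sd.get(key, 0.0) < 0:
                raise ValueError("noise SDs must be non-negative")


@dataclass
class SyntheticCohort:
    """One generated cohort plus the planted truth.

    ``physio`` is a long table (participant_id, modality, phase_label,
    time_min, value) with modalities cortisol / SBP / DBP / HR; ``predictors``
    is wide with the 48 named predictors plus the distress outcome.
    ``truth`` carries everything needed to score recovery of the planted
    structure. ``complete_physio`` / ``complete_predictors`` retain the
    pre-missingness data after :func:`inject_missingness`.
    """

    config: CohortConfig
    physio: pd.DataFrame
    predictors: pd.DataFrame
    truth: dict
    complete_physio: pd.DataFrame | None = None
    complete_predictors: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> dict:
        """Write physio.csv, predictors.csv and truth.json; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "physio": out / "physio.csv",
            "predictors": out / "predictors.csv",
            "truth": out / "truth.json",
        }
        self.physio.to_csv(paths["physio"], index=False)
        self.predictors.to_csv(paths["predictors"], index=False)
        serializable = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        paths["truth"].write_text(json.dumps(serializable, indent=2))
        return paths


def _check_rng(rng) -> np.random.Generator:
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a numpy.random.Generator")
    return rng


def _cortisol_mean_curve(
    profile: str,
    baseline_level: np.ndarray,
    amplitude: np.ndarray,
    grid: np.ndarray,
    *,
    arrival_ratio: float,
    end_ratio: np.ndarray,
    peak_time_min: float,
) -> np.ndarray:
    """Noise-free log-scale cortisol curve(s) on the sampling grid.

    ``baseline_level``/``amplitude``/``end_ratio`` may be scalars or length-n
    arrays; the result has shape (n, len(grid)).
    """
    b = np.atleast_1d(np.asarray(baseline_level, dtype=float))[:, None]
    a = np.atleast_1d(np.asarray(amplitude, dtype=float))[:, None]
    er = np.atleast_1d(np.asarray(end_ratio, dtype=float))[:, None]
    t = np.asarray(grid, dtype=float)
    t1, t_end = t[1], t[-1]
    log_b = np.log(b)
    curves = np.empty((b.shape[0], t.size))
    if profile == "responder":
        peak_idx = 1 + int(np.argmin(np.abs(t[1:] - (t1 + peak_time_min))))
        t_peak = t[peak_idx]
        log_peak = np.log(b + a)
        log_end = log_b + np.log(er)
        # arrival -> T1: decline from the elevated arrival sample
        curves[:, 0] = (log_b + np.log(arrival_ratio)).ravel()
        rise = t[1 : peak_idx + 1]
        curves[:, 1 : peak_idx + 1] = log_b + (log_peak - log_b) * (
            (rise - t1) / (t_peak - t1)
        )
        fall = t[peak_idx:]
        if t_end > t_peak:
            curves[:, peak_idx:] = log_peak + (log_end - log_peak) * (
                (fall - t_peak) / (t_end - t_peak)
            )
        else:  # peak at the final sample: nothing to decay
            curves[:, -1] = log_peak.ravel()
    elif profile == "non-responder":
        # maximum at arrival, then a monotone log-linear decline
        curves[:, 0] = (log_b + np.log(arrival_ratio)).ravel()
        decline = t[1:]
        log_end = log_b + np.log(er)
        curves[:, 1:] = log_b + (log_end - log_b) * ((decline - t1) / (t_end - t1))
    else:
        raise ValueError(f"unknown cortisol profile {profile!r}")
    return curves


def simulate_cortisol(
    profile: str,
    baseline_level: float,
    amplitude: float,
    grid,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    arrival_ratio: float | None = None,
    end_ratio: float | None = None,
    peak_time_min: float = 35.0,
) -> np.ndarray:
    """Simulate one cortisol series (ng/ml) on ``grid`` (minutes).

    Responders rise from T1 on the log scale, peak at the grid point nearest
    ``T1 + peak_time_min`` and decay back toward baseline by the last
    sample; non-responders peak at arrival and decline monotonically in
    expectation. Noise is multiplicative log-normal, so all values are
    strictly positive.
    """
    baseline_level = float(baseline_level)
    amplitude = float(amplitude)
    if baseline_level <= 0:
        raise ValueError("baseline_level must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    _check_rng(rng)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 3 points")
    if arrival_ratio is None:
        arrival_ratio = 1.25 if profile == "responder" else 1.5
    if end_ratio is None:
        end_ratio = 0.85 if profile == "responder" else 0.60
    log_curve = _cortisol_mean_curve(
        profile,
        baseline_level,
        amplitude,
        grid,
        arrival_ratio=arrival_ratio,
        end_ratio=np.asarray([end_ratio]),
        peak_time_min=peak_time_min,
    )[0]
    return np.exp(log_curve + noise_sd * rng.standard_normal(grid.size))


def simulate_cardio(
    modality: str,
    baseline: float,
    phase_effects,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one cardiovascular series (MAP in mm Hg or HR in BPM).

    ``phase_effects`` holds one additive offset per cardio phase with the
    baseline offset fixed at 0; the population defaults place the peak at
    the speech phase.
    """
    if modality not in {"BP", "MAP", "HR"}:
        raise ValueError("modality must be 'BP'/'MAP' or 'HR'")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    _check_rng(rng)
    effects = np.asarray(phase_effects, dtype=float)
    if effects.ndim != 1 or effects.size < 2:
        raise ValueError("phase_effects must be a 1-D sequence per phase")
    if effects[0] != 0.0:
        raise ValueError("the baseline phase offset must be 0")
    return baseline + effects + noise_sd * rng.standard_normal(effects.size)


def simulate_predictors_and_outcomes(
    config: CohortConfig,
    latent_index: np.ndarray,
    rng: np.random.Generator,
    *,
    baseline_values: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the 48-predictor table and the distress outcome.

    ``latent_index`` is the participant-level noise-free resilience index
    (computed from the noiseless trajectory parameters). Each planted
    predictor's latent Gaussian loads linearly on the standardized index:
    ``U_j = theta_j * z(index) + sqrt(1 - theta_j^2) * eps`` with
    ``theta_j = w_j / sigma_L``, the joint law implied by an index that is a
    linear combination of the predictor latents plus noise. Binary
    predictors are thresholded at their configured prevalences. Distress is
    ``intercept + distress_beta * centered index + stressor terms + noise``.
    """
    _check_rng(rng)
    idx = np.asarray(latent_index, dtype=float)
    n = idx.size
    w = np.array(
        [config.true_coefficients.get(name, 0.0) for name in PREDICTOR_NAMES]
    )
    missing = [
        name
        for name, coef in config.true_coefficients.items()
        if name not in PREDICTOR_NAMES or coef is None
    ]
    if missing:
        raise ValueError(f"undeclared/invalid planted coefficients: {missing}")
    ssq = float(np.sum(w**2))
    if ssq > 0:
        share = config.planted_variance_share
        sigma_l = np.sqrt(ssq / share)
        theta = w / sigma_l
    else:
        theta = np.zeros_like(w)

    sd = idx.std(ddof=1) if n > 1 else 0.0
    z_idx = (idx - idx.mean()) / sd if sd > 0 else np.zeros(n)

    latents = theta[None, :] * z_idx[:, None] + np.sqrt(
        1.0 - theta[None, :] ** 2
    ) * rng.standard_normal((n, w.size))

    cols = {}
    from scipy.stats import norm

    for j, name in enumerate(PREDICTOR_NAMES):
        u = latents[:, j]
        if name in PHYSIO_PREDICTORS:
            continue  # filled from trajectories below
        if name in BINARY_PREDICTORS:
            cut = norm.ppf(1.0 - BINARY_PREDICTORS[name])
            cols[name] = (u > cut).astype(float)
        elif name == "age":
            cols[name] = np.clip(30.63 + 4.61 * u, 18.0, 45.0)
        elif name == "daily_stressors":
            cols[name] = np.clip(50.0 + 15.0 * u, 0.0, None)
        elif name == "major_life_events":
            cols[name] = np.round(np.clip(3.0 + 2.0 * u, 0.0, None))
        else:
            # questionnaire / cognitive scores kept on a z-like scale
            cols[name] = u

    if baseline_values is not None:
        cols["baseline_cortisol"] = np.asarray(baseline_values["cortisol"], float)
        cols["baseline_bp"] = np.asarray(baseline_values["MAP"], float)
        cols["baseline_hr"] = np.asarray(baseline_values["HR"], float)
    else:
        for name in PHYSIO_PREDICTORS:
            cols[name] = latents[:, PREDICTOR_NAMES.index(name)]

    distress = (
        config.distress_intercept
        + config.distress_beta * (idx - idx.mean())
        + config.distress_daily_beta * (cols["daily_stressors"] - 50.0)
        + config.distress_major_beta * cols["major_life_events"]
        + config.distress_noise_sd * rng.standard_normal(n)
    )

    table = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    for name in PREDICTOR_NAMES:
        table[name] = cols[name]
    table["distress"] = distress

    truth = {
        "theta": theta,
        "sigma_latent": float(np.sqrt(ssq / config.planted_variance_share))
        if ssq > 0
        else None,
        "planted": {k: float(v) for k, v in config.true_coefficients.items() if v != 0.0},
        "distress_beta": config.distress_beta,
    }
    return table, truth


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a complete synthetic cohort under ``config``.

    Participant-level latent structure: a single standardized resilience
    factor drives (negatively) a reactivity factor and a recovery factor
    (each with loading ``index_coupling``); modality-specific reactivity,
    recovery and baseline latents load on those with ``modality_loading``
    and ``baseline_recovery_loading``. Trajectory parameters (cortisol
    baseline and amplitude, cardio baselines, phase-offset scalings,
    recovery offsets) are monotone maps of the latents. The noise-free
    trajectories are pushed through the package's own feature and composite
    stages to obtain each participant's noiseless resilience index, on
    which predictors and distress are planted.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    c = config.index_coupling
    lam = config.modality_loading
    bl = config.baseline_recovery_loading

    # latent resilience factor; G is its negation (a "badness" factor so
    # that higher G = higher reactivity / slower recovery)
    resilience_factor = rng.standard_normal(n)
    g = -resilience_factor
    l_react = c * g + np.sqrt(1 - c**2) * rng.standard_normal(n)
    l_recov = c * g + np.sqrt(1 - c**2) * rng.standard_normal(n)

    def modality_latents():
        react = lam * l_react + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        recov = lam * l_recov + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        base = bl * recov + np.sqrt(1 - bl**2) * rng.standard_normal(n)
        return react, recov, base

    cort_react, cort_recov, cort_base = modality_latents()
    map_react, map_recov, map_base = modality_latents()
    hr_react, hr_recov, hr_base = modality_latents()

    responder = rng.random(n) < config.responder_fraction

    # --- cortisol trajectory parameters ---
    baseline_cort = np.exp(config.log_baseline_mu + config.log_baseline_sd * cort_base)
    rel_amp = np.exp(config.log_rel_amp_mu + config.log_rel_amp_sd * cort_react)
    amplitude = np.where(responder, baseline_cort * rel_amp, 0.0)
    end_ratio = np.where(
        responder, config.responder_end_ratio, config.nonresponder_end_ratio
    ) * np.exp(config.cortisol_recovery_log_sd * cort_recov)
    # keep the responder decay real (end below peak) and the non-responder
    # trend declining
    end_ratio = np.where(
        responder,
        np.minimum(end_ratio, (1.0 + rel_amp) * 0.95),
        np.minimum(end_ratio, 0.95),
    )
    grid_c = np.asarray(config.cortisol_grid_min, dtype=float)
    log_curves = np.empty((n, grid_c.size))
    for profile, mask, arr_ratio in (
        ("responder", responder, config.responder_arrival_ratio),
        ("non-responder", ~responder, config.nonresponder_arrival_ratio),
    ):
        if mask.any():
            log_curves[mask] = _cortisol_mean_curve(
                profile,
                baseline_cort[mask],
                amplitude[mask],
                grid_c,
                arrival_ratio=arr_ratio,
                end_ratio=end_ratio[mask],
                peak_time_min=config.responder_peak_min,
            )
    cort_clean = np.exp(log_curves)
    cort_noisy = np.exp(
        log_curves
        + config.noise_sd["cortisol"] * rng.standard_normal((n, grid_c.size))
    )

    # --- cardio trajectories (simulated on the MAP / HR scale) ---
    grid_k = np.asarray(config.cardio_grid_min, dtype=float)

    def cardio_curves(base_mean, base_sd, offsets, base_lat, react_lat, recov_lat, noise):
        baseline = base_mean + base_sd * base_lat
        offsets = np.asarray(offsets, dtype=float)
        scale = np.exp(config.cardio_react_log_sd * react_lat)
        curves = baseline[:, None] + offsets[None, :] * scale[:, None]
        curves[:, -1] = baseline + offsets[-1] + config.cardio_recovery_sd * recov_lat
        noisy = curves + noise * rng.standard_normal(curves.shape)
        return baseline, curves, noisy

    map_baseline, map_clean, map_noisy = cardio_curves(
        config.map_baseline_mean,
        config.map_baseline_sd,
        config.map_phase_offsets,
        map_base,
        map_react,
        map_recov,
        config.noise_sd["MAP"],
    )
    hr_baseline, hr_clean, hr_noisy = cardio_curves(
        config.hr_baseline_mean,
        config.hr_baseline_sd,
        config.hr_phase_offsets,
        hr_base,
        hr_react,
        hr_recov,
        config.noise_sd["HR"],
    )
    hr_clean = np.clip(hr_clean, 30.0, None)
    hr_noisy = np.clip(hr_noisy, 30.0, None)
    map_clean = np.clip(map_clean, 40.0, None)
    map_noisy = np.clip(map_noisy, 40.0, None)

    # SBP/DBP consistent with the simulated MAP and a participant-level
    # pulse pressure: MAP = DBP + PP/3, SBP = DBP + PP.
    pulse = np.clip(
        config.pulse_pressure_mean + config.pulse_pressure_sd * rng.standard_normal(n),
        15.0,
        None,
    )
    dbp_noisy = map_noisy - pulse[:, None] / 3.0
    sbp_noisy = dbp_noisy + pulse[:, None]

    # --- noiseless resilience index from the package's own pipeline ---
    from . import composite, features

    clean_features = features.feature_table_from_arrays(
        cort_clean, map_clean, hr_clean, grid_c, grid_k
    )
    clean_composites, _ = composite.compute_composites(clean_features)
    noiseless_index = clean_composites["resilience_index"].to_numpy()

    predictors, planted_truth = simulate_predictors_and_outcomes(
        config,
        noiseless_index,
        rng,
        baseline_values={
            "cortisol": cort_noisy[:, 1],
            "MAP": map_noisy[:, 0],
            "HR": hr_noisy[:, 0],
        },
    )

    physio = _long_table(
        cort_noisy, sbp_noisy, dbp_noisy, hr_noisy, grid_c, grid_k
    )

    active = sorted(planted_truth["planted"]) + list(PHYSIO_PREDICTORS)
    truth = {
        "seed": config.seed,
        "responder": responder.astype(int),
        "responder_fraction": config.responder_fraction,
        "noiseless_index": noiseless_index,
        "latent_resilience_factor": resilience_factor,
        "baseline_cortisol": baseline_cort,
        "amplitude": amplitude,
        "end_ratio": end_ratio,
        "map_baseline": map_baseline,
        "hr_baseline": hr_baseline,
        "active_predictors": active,
        **planted_truth,
    }
    return SyntheticCohort(
        config=config, physio=physio, predictors=predictors, truth=truth
    )


def _long_table(cort, sbp, dbp, hr, grid_c, grid_k) -> pd.DataFrame:
    n = cort.shape[0]
    pid = np.arange(1, n + 1)
    frames = []
    for modality, vals, grid, labels in (
        ("cortisol", cort, grid_c, CORTISOL_LABELS),
        ("SBP", sbp, grid_k, CARDIO_LABELS),
        ("DBP", dbp, grid_k, CARDIO_LABELS),
        ("HR", hr, grid_k, CARDIO_LABELS),
    ):
        k = len(grid)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pid, k),
                    "modality": modality,
                    "phase_label": np.tile(labels, n),
                    "time_min": np.tile(np.asarray(grid, float), n),
                    "value": np.asarray(vals, float).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def inject_missingness(
    cohort: SyntheticCohort, rate: float, rng: np.random.Generator
) -> SyntheticCohort:
    """Return a copy of ``cohort`` with MCAR missingness at ``rate``.

    Physiological values and (continuous) predictor cells are blanked
    completely at random; the complete tables are retained on the returned
    cohort so imputation can be scored against truth.
    """
    if not 0.0 <= rate < 0.05:
        raise ValueError("missingness rate must lie in [0, 0.05)")
    _check_rng(rng)
    physio = cohort.physio.copy()
    predictors = cohort.predictors.copy()
    if rate > 0:
        mask = rng.random(len(physio)) < rate
        physio.loc[mask, "value"] = np.nan
        pred_cols = [c for c in PREDICTOR_NAMES if c not in BINARY_PREDICTORS]
        block = predictors[pred_cols].to_numpy(dtype=float)
        cell_mask = rng.random(block.shape) < rate
        block[cell_mask] = np.nan
        predictors[pred_cols] = block
    return SyntheticCohort(
        config=cohort.config,
        physio=physio,
        predictors=predictors,
        truth=cohort.truth,
        complete_physio=cohort.physio,
        complete_predictors=cohort.predictors,
    )
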