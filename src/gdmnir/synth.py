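"""Synthetic cohorts with the structure the pipeline assumes.

Real serum NIR spectra and clinical records for this problem are not
publicly deposited, so this module generates stand-ins that reproduce the
*statistical* features the analysis relies on: two-class transflectance
spectra on the 10,500-4000 cm^-1 grid built from a smooth polynomial
baseline plus Gaussian absorption bands (broad water bands near 6900 and
5150 cm^-1, protein/CH combination bands in the 4700-4200 cm^-1 region,
weak overtones at high wavenumber); five instrumental replicates per
sample; additive noise whose SD is piecewise-constant per spectral region
(high in R1, intermediate in R2, low in R3); per-sample multiplicative
scatter; a class effect that multiplicatively scales band amplitudes inside
configurable wavenumber intervals (emulating a concentration difference,
by default on the 4762-4348 cm^-1 carbohydrate-associated region); and a
28-variable clinical covariate table whose per-class Bernoulli frequencies
and Gaussian moments default to the published cohort tables (67/15 cases
in the first-trimester scenario, 39/8 in the second).

Everything is deterministic given the config seed; spectra and covariates
draw from independent child streams so either table can be regenerated
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import RANGE_BOUNDS, RangeName, SpectrumSet, default_wavenumber_grid

__all__ = [
    "CohortConfig",
    "first_trimester_config",
    "second_trimester_config",
    "generate_spectra",
    "generate_medical_table",
    "DEFAULT_BANDS",
    "FIRST_TRIMESTER_COVARIATES",
    "SECOND_TRIMESTER_COVARIATES",
]

#: (center cm^-1, width cm^-1, base amplitude AU) of serum-like NIR bands.
DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (10_100.0, 400.0, 0.010),  # weak third overtones, high-wavenumber tail
    (8_700.0, 450.0, 0.020),  # CH second overtone region
    (6_900.0, 260.0, 0.350),  # water first overtone
    (5_600.0, 220.0, 0.080),  # protein/CH first combination shoulder
    (5_150.0, 150.0, 0.450),  # water combination band
    (4_700.0, 80.0, 0.100),  # carbohydrate O-H/C-H combination
    (4_600.0, 110.0, 0.120),  # protein N-H/C-H combinations
    (4_350.0, 60.0, 0.180),  # CH combination
    (4_260.0, 50.0, 0.150),  # CH combination
)

# Per-class (control, case) Bernoulli frequencies of the binary covariates
# and Gaussian (mean, sd) of the quantitative ones; month-of-last-period is
# categorical with per-class monthly frequencies. Values follow the
# published cohort tables.
FIRST_TRIMESTER_COVARIATES = {
    "gaussian": {
        "age": ((30.0, 5.0), (32.0, 7.0)),
        "bmi": ((27.6, 5.9), (29.7, 3.7)),
        "menarche_age": ((13.0, 1.5), (12.0, 1.5)),
    },
    "binary": {
        "supplement": (43 / 67, 8 / 15),
        "hyperemesis": (18 / 67, 4 / 15),
        "vaginal_bleeding": (6 / 67, 2 / 15),
        "cigarettes": (23 / 67, 8 / 15),
        "alcohol": (36 / 67, 9 / 15),
        "other_drugs": (9 / 67, 2 / 15),
        "prior_gdm": (1 / 67, 5 / 15),
        "prior_hypertensive_disorder": (3 / 67, 1 / 15),
        "prior_preterm_birth": (3 / 67, 1 / 15),
        "prior_other_issue": (7 / 67, 1 / 15),
        "prior_nonviable_pregnancy": (14 / 67, 3 / 15),
        "fertility_problems": (10 / 67, 1 / 15),
        "pcos": (17 / 67, 2 / 15),
        "personal_insulin_resistance": (2 / 67, 1 / 15),
        "personal_thyroid_dysfunction": (3 / 67, 1 / 15),
        "personal_asthma": (4 / 67, 0 / 15),
        "personal_other": (7 / 67, 3 / 15),
        "family_insulin_resistance": (2 / 67, 1 / 15),
        "family_dm": (22 / 67, 10 / 15),
        "family_hypertension": (28 / 67, 9 / 15),
        "family_hypothyroidism": (12 / 67, 5 / 15),
        "family_hyperthyroidism": (1 / 67, 2 / 15),
        "family_asthma": (5 / 67, 0 / 15),
        "family_other": (11 / 67, 2 / 15),
    },
    "month": (
        np.array([5, 4, 5, 2, 9, 7, 6, 5, 4, 9, 7, 4]) / 67,
        np.array([1, 3, 0, 1, 3, 2, 2, 0, 0, 1, 2, 0]) / 15,
    ),
}

SECOND_TRIMESTER_COVARIATES = {
    "gaussian": {
        "age": ((29.0, 5.0), (30.0, 7.0)),
        "bmi": ((27.0, 4.7), (31.3, 6.5)),
        "menarche_age": ((13.0, 1.5), (12.0, 1.0)),
    },
    "binary": {
        "supplement": (25 / 39, 5 / 8),
        "hyperemesis": (13 / 39, 2 / 8),
        "vaginal_bleeding": (2 / 39, 2 / 8),
        "cigarettes": (13 / 39, 3 / 8),
        "alcohol": (24 / 39, 4 / 8),
        "other_drugs": (10 / 39, 0 / 8),
        "prior_gdm": (0 / 39, 3 / 8),
        "prior_hypertensive_disorder": (3 / 39, 0 / 8),
        "prior_preterm_birth": (2 / 39, 1 / 8),
        "prior_other_issue": (3 / 39, 0 / 8),
        "prior_nonviable_pregnancy": (7 / 39, 1 / 8),
        "fertility_problems": (7 / 39, 0 / 8),
        "pcos": (10 / 39, 1 / 8),
        "personal_insulin_resistance": (2 / 39, 0 / 8),
        "personal_thyroid_dysfunction": (4 / 39, 0 / 8),
        "personal_asthma": (3 / 39, 0 / 8),
        "personal_other": (4 / 39, 3 / 8),
        "family_insulin_resistance": (3 / 39, 1 / 8),
        "family_dm": (14 / 39, 5 / 8),
        "family_hypertension": (19 / 39, 5 / 8),
        "family_hypothyroidism": (7 / 39, 2 / 8),
        "family_hyperthyroidism": (2 / 39, 1 / 8),
        "family_asthma": (4 / 39, 0 / 8),
        "family_other": (5 / 39, 1 / 8),
    },
    "month": (
        np.array([1, 3, 5, 2, 5, 4, 6, 5, 1, 4, 2, 1]) / 39,
        np.array([0, 2, 0, 1, 0, 1, 2, 0, 1, 1, 0, 0]) / 8,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for one synthetic cohort."""

    n_controls: int = 39
    n_cases: int = 8
    replicates: int = 5
    grid_step: float = 2.0
    bands: tuple[tuple[float, float, float], ...] = DEFAULT_BANDS
    #: (high cm^-1, low cm^-1, delta): case band amplitudes inside the
    #: interval are scaled by (1 + delta).
    class_effects: tuple[tuple[float, float, float], ...] = ((4762.0, 4348.0, 0.20),)
    baseline_coeffs: tuple[float, ...] = (0.30, 0.05, 0.03)
    amplitude_cv: float = 0.12  # between-subject band-amplitude variation
    scatter_sd: float = 0.02  # per-sample multiplicative scatter
    base_noise_sd: float = 0.01  # replicate-level additive noise SD in R3
    #: per-subject center jitter (cm^-1 SD) of the dominant 6900 cm^-1
    #: water band; emulates thermally/solute-driven shifts of the water
    #: first overtone, the main nuisance variance outside R3
    water_shift_sd: float = 6.0
    water_band_centers: tuple[float, ...] = (6_900.0,)
    #: correlation length of the additive noise per region, in grid points
    #: (0 = white). The high-noise region shows slow, wavy "sequential"
    #: noise; the low-wavenumber region is close to white.
    noise_corr_points: tuple[float, float, float] = (30.0, 10.0, 0.0)
    noise_region_factors: tuple[float, float, float] = (10.0, 3.0, 1.0)  # R1, R2, R3
    unit: str = "reflectance"
    covariates: dict = field(default_factory=lambda: SECOND_TRIMESTER_COVARIATES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("both classes need at least one subject")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.base_noise_sd <= 0 or min(self.noise_region_factors) <= 0:
            raise ValueError("noise SDs must be > 0")
        if any(a < 0 for _, _, a in self.bands):
            raise ValueError("band amplitudes must be >= 0")
        if self.unit not in ("reflectance", "absorbance"):
            raise ValueError("unit must be reflectance or absorbance")

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_cases

    def labels(self) -> np.ndarray:
        """Per-subject labels: controls first, then cases (fixed order)."""
        return np.r_[np.zeros(self.n_controls, int), np.ones(self.n_cases, int)]

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_subjects)]


def first_trimester_config(**overrides) -> CohortConfig:
    """67 controls / 15 cases with first-trimester covariate frequencies."""
    base = dict(n_controls=67, n_cases=15, covariates=FIRST_TRIMESTER_COVARIATES)
    base.update(overrides)
    return CohortConfig(**base)


def second_trimester_config(**overrides) -> CohortConfig:
    """39 controls / 8 cases with second-trimester covariate frequencies."""
    base = dict(n_controls=39, n_cases=8, covariates=SECOND_TRIMESTER_COVARIATES)
    base.update(overrides)
    return CohortConfig(**base)


def _noise_sd_profile(cfg: CohortConfig, wn: np.ndarray) -> np.ndarray:
    f1, f2, f3 = cfg.noise_region_factors
    sd = np.full(wn.size, cfg.base_noise_sd * f3)
    _, r1_low = RANGE_BOUNDS[RangeName.R1]
    _, r2_low = RANGE_BOUNDS[RangeName.R2]
    sd[wn > r1_low] = cfg.base_noise_sd * f1
    sd[(wn <= r1_low) & (wn > r2_low)] = cfg.base_noise_sd * f2
    return sd


def _region_masks(wn: np.ndarray) -> list[np.ndarray]:
    _, r1_low = RANGE_BOUNDS[RangeName.R1]
    _, r2_low = RANGE_BOUNDS[RangeName.R2]
    return [wn > r1_low, (wn <= r1_low) & (wn > r2_low), wn <= r2_low]


def _make_noise(
    rng: np.random.Generator,
    wn: np.ndarray,
    sd_profile: np.ndarray,
    corr_points: tuple[float, float, float],
) -> np.ndarray:
    """Additive noise with per-region SD and correlation length (points)."""
    from scipy.ndimage import gaussian_filter1d

    z = rng.standard_normal(wn.size)
    for mask, sigma in zip(_region_masks(wn), corr_points):
        if sigma > 0 and mask.any():
            smooth = gaussian_filter1d(z[mask], sigma, mode="reflect")
            # restore unit per-point SD after low-pass filtering
            size = 2 * int(8 * sigma) + 1
            impulse = np.zeros(size)
            impulse[size // 2] = 1.0
            kernel = gaussian_filter1d(impulse, sigma, mode="constant")
            z[mask] = smooth / np.sqrt((kernel**2).sum())
    return z * sd_profile


def _rng_for(cfg: CohortConfig, stream: str) -> np.random.Generator:
    tag = {"spectra": 1, "medical": 2}[stream]
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, tag)))


def generate_spectra(cfg: CohortConfig) -> SpectrumSet:
    """Replicate-level synthetic spectra for one cohort.

    Each subject's absorbance spectrum is baseline + Gaussian bands with
    subject-specific amplitudes; case subjects' bands inside the configured
    effect intervals are scaled by (1 + delta). A per-sample multiplicative
    scatter factor and per-replicate region-dependent additive noise are
    then applied; reflectance output is R = 10^(-A).
    """
    rng = _rng_for(cfg, "spectra")
    wn = default_wavenumber_grid(cfg.grid_step)
    labels = cfg.labels()
    subjects = cfg.subject_ids()
    noise_sd = _noise_sd_profile(cfg, wn)

    # smooth baseline on a scaled axis, identical for all subjects
    t = (wn - wn.min()) / (wn.max() - wn.min())
    baseline = np.polynomial.polynomial.polyval(t, cfg.baseline_coeffs)

    band_centers = np.array([c for c, _, _ in cfg.bands])
    band_widths = np.array([w for _, w, _ in cfg.bands])
    band_amps = np.array([a for _, _, a in cfg.bands])
    # multiplicative class effect per band
    effect = np.ones(band_amps.size)
    for high, low, delta in cfg.class_effects:
        inside = (band_centers <= high) & (band_centers >= low)
        effect[inside] *= 1.0 + delta
    jittered = np.isin(band_centers, cfg.water_band_centers)
    shapes = np.exp(-0.5 * ((wn[None, :] - band_centers[:, None]) / band_widths[:, None]) ** 2)

    rows, meta = [], []
    for i, subject in enumerate(subjects):
        amps = band_amps * (1.0 + cfg.amplitude_cv * rng.standard_normal(band_amps.size))
        amps = np.clip(amps, 0.0, None)
        if labels[i] == 1:
            amps = amps * effect
        scatter = 1.0 + cfg.scatter_sd * rng.standard_normal()
        centers = band_centers.copy()
        if cfg.water_shift_sd > 0 and jittered.any():
            centers[jittered] += cfg.water_shift_sd * rng.standard_normal(jittered.sum())
            subj_shapes = np.where(
                jittered[:, None],
                np.exp(-0.5 * ((wn[None, :] - centers[:, None]) / band_widths[:, None]) ** 2),
                shapes,
            )
        else:
            subj_shapes = shapes
        clean = scatter * (baseline + amps @ subj_shapes)
        for rep in range(1, cfg.replicates + 1):
            noisy = clean + _make_noise(rng, wn, noise_sd, cfg.noise_corr_points)
            rows.append(noisy)
            meta.append(
                {"subject_id": subject, "replicate_index": rep, "label": int(labels[i])}
            )

    values = np.asarray(rows)
    if cfg.unit == "reflectance":
        values = 10.0 ** (-values)
    return SpectrumSet(wn, values, cfg.unit, pd.DataFrame(meta))


def generate_medical_table(cfg: CohortConfig) -> pd.DataFrame:
    """28-variable clinical covariate table with a ``label`` column.

    Binary covariates are Bernoulli draws with per-class frequencies;
    age, BMI and menarche age are Gaussian per class;
    ``last_period_month`` is categorical (1..12) with per-class monthly
    frequencies. Row order matches :meth:`CohortConfig.labels`.
    """
    rng = _rng_for(cfg, "medical")
    spec = cfg.covariates
    labels = cfg.labels()
    n = labels.size
    data: dict[str, np.ndarray] = {"subject_id": np.array(cfg.subject_ids(), dtype=object)}

    for name, ((m0, s0), (m1, s1)) in spec["gaussian"].items():
        mu = np.where(labels == 1, m1, m0)
        sd = np.where(labels == 1, s1, s0)
        data[name] = mu + sd * rng.standard_normal(n)

    for name, (p0, p1) in spec["binary"].items():
        p = np.where(labels == 1, p1, p0)
        data[name] = (rng.random(n) < p).astype(int)

    p_month = np.vstack(spec["month"])  # (2, 12)
    p_month = p_month / p_month.sum(axis=1, keepdims=True)
    months = np.empty(n, dtype=int)
    for i in range(n):
        months[i] = rng.choice(12, p=p_month[labels[i]]) + 1
    data["last_period_month"] = months

    df = pd.DataFrame(data)
    df["label"] = labels
    return df


def medical_design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric (X, y, names) for modeling; month one-hot encoded."""
    y = df["label"].to_numpy(dtype=int)
    cols = [c for c in df.columns if c not in ("subject_id", "label", "last_period_month")]
    X = df[cols].to_numpy(dtype=float)
    month = df["last_period_month"].to_numpy(dtype=int)
    onehot = np.zeros((len(df), 12))
    onehot[np.arange(len(df)), month - 1] = 1.0
    names = cols + [f"month_{m}" for m in range(1, 13)]
    return np.hstack([X, onehot]), y, names
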