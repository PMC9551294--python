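"""Synthetic cohort generator with known compositional ground truth.

Emulates a community-dwelling older-adult accelerometer study: each
participant gets (a) a covariate row (sex, age, education, BMI category,
smoking, alcohol, three medication flags, intracranial volume), (b) a latent
3-part wear-time composition (SB, LPA, MVPA) drawn on the pivot ilr scale
(logistic-normal, which guarantees strictly positive parts), (c) seven days
of 60-second epoch MET streams whose bouted activity and inserted non-wear
runs reproduce the intended daily minutes exactly under the screening rules
in :mod:`timecoda.accelerometry`, and (d) hippocampal-volume outcomes from a
linear model on the pivot coordinates plus covariates.

Default calibration targets the cohort this package was designed around:
485 participants, 47% male, age 73.3 (5.5) y, wear 887.5 (109.4) min/day,
arithmetic-mean activity 442.7/391.2/53.6 min/day, compositional center
50.5/44.9/4.6%, log-ratio dispersion matching the published variation
matrix (SB-LPA 0.26, SB-MVPA 1.19, LPA-MVPA 0.76), right hippocampal volume
3,687.7 (420.3) mm^3 with an MVPA-pivot effect of 57.1 mm^3 per ilr unit.
The outcome intercept and residual SD are solved in closed form so the
simulated marginal mean and SD hit the targets in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coda
from .accelerometry import EPOCHS_PER_DAY

# ---------------------------------------------------------------------------
# Calibration constants (cohort descriptives the defaults emulate)
# ---------------------------------------------------------------------------

N_PARTICIPANTS = 485
PROP_MALE = 0.47
AGE_MEAN, AGE_SD = 73.3, 5.5
ICV_MEAN, ICV_SD = 1_432_369.0, 152_092.0
WEAR_MEAN, WEAR_SD = 887.5, 109.4
RIGHT_HV_MEAN, RIGHT_HV_SD = 3_687.7, 420.3
LEFT_HV_MEAN, LEFT_HV_SD = 3_522.1, 391.1

#: compositional center of time use (SB, LPA, MVPA), proportions of wear
CENTER_COMPOSITION = np.array([0.505, 0.449, 0.046])

#: published variation matrix of ln-part ratios, order (SB, LPA, MVPA)
VARIATION_TARGET = np.array(
    [[0.0, 0.26, 1.19], [0.26, 0.0, 0.76], [1.19, 0.76, 0.0]]
)

#: model-5 pivot-first coefficients (mm^3 per ilr unit) for the right /
#: left hippocampal volume, order (SB, LPA, MVPA); the generating model is
#: reconstructed from these via the log-contrast representation
RIGHT_PIVOT_BETAS = np.array([-22.7, -34.3, 57.1])
LEFT_PIVOT_BETAS = np.array([34.9, -52.4, 17.5])

#: covariate -> (effect mm^3, prevalence or None for continuous)
COVARIATE_PREVALENCE = {
    "male": PROP_MALE,
    "education": 0.196,
    "bmi_under": 0.082,
    "bmi_over": 0.177,
    "smoker": 0.085,
    "alcohol": 0.045,
    "med_hypertension": 0.456,
    "med_dyslipidemia": 0.344,
    "med_diabetes": 0.095,
}

#: default outcome effects, mm^3 per unit: ICV slope ~ the hippocampus/ICV
#: volume ratio, age slope ~ annual atrophy at this age; binaries are small
DEFAULT_COVARIATE_EFFECTS = {
    "male": 40.0,
    "age": -30.0,
    "icv": 0.002,
    "education": 20.0,
    "bmi_under": -40.0,
    "bmi_over": 10.0,
    "smoker": -30.0,
    "alcohol": -20.0,
    "med_hypertension": -10.0,
    "med_dyslipidemia": -10.0,
    "med_diabetes": -10.0,
}

COVARIATE_COLUMNS = list(DEFAULT_COVARIATE_EFFECTS)


def _pivot_betas_to_z(pivot_betas: np.ndarray) -> tuple[float, float]:
    """(beta_z1, beta_z2) in the MVPA-first pivot from the three pivot-first
    coefficients (order SB, LPA, MVPA).

    Exact pivot identities: beta_z1(k) = sqrt(3/2) * a_k for the zero-sum
    log-contrast a with a_k = sqrt(2/3) * beta_k, so the MVPA-first z1 slope
    is the MVPA entry itself, and z2 = sqrt(1/2) ln(LPA/SB) picks up the
    SB/LPA difference (invariant to the rounding of the published betas,
    which sum to 0.1 rather than 0).
    """
    b = np.asarray(pivot_betas, dtype=float)
    beta_z1 = float(b[2])
    beta_z2 = float(np.sqrt(1.0 / 2.0) * np.sqrt(2.0 / 3.0) * (b[1] - b[0]))
    return beta_z1, beta_z2


def _default_ilr_mean() -> np.ndarray:
    return coda.ilr_pivot(CENTER_COMPOSITION, coda.MVPA_FIRST)


def _default_ilr_cov() -> np.ndarray:
    return coda.ilr_cov_from_variation(VARIATION_TARGET, coda.MVPA_FIRST)


def _covariate_variances() -> dict[str, float]:
    v = {k: p * (1.0 - p) for k, p in COVARIATE_PREVALENCE.items()}
    v["age"] = AGE_SD**2
    v["icv"] = ICV_SD**2
    return v


def _covariate_means() -> dict[str, float]:
    m = dict(COVARIATE_PREVALENCE)
    m["age"] = AGE_MEAN
    m["icv"] = ICV_MEAN
    return m


def _solve_intercept_noise(
    target_mean: float,
    target_sd: float,
    beta_z: np.ndarray,
    ilr_mean: np.ndarray,
    ilr_cov: np.ndarray,
    effects: dict[str, float],
) -> tuple[float, float]:
    """Intercept and residual SD that hit the outcome's marginal moments.

    Covariates are sampled independently, so the explained variance is the
    sum of effect^2 * var plus the ilr quadratic form; the residual picks up
    the remainder of the target variance.
    """
    means, variances = _covariate_means(), _covariate_variances()
    mean_expl = float(beta_z @ ilr_mean) + sum(e * means[k] for k, e in effects.items())
    var_expl = float(beta_z @ ilr_cov @ beta_z) + sum(
        e * e * variances[k] for k, e in effects.items()
    )
    if var_expl >= target_sd**2:
        raise ValueError(
            "configured effects explain more variance than the target outcome SD"
        )
    return target_mean - mean_expl, float(np.sqrt(target_sd**2 - var_expl))


_R_BZ1, _R_BZ2 = _pivot_betas_to_z(RIGHT_PIVOT_BETAS)
_L_BZ1, _L_BZ2 = _pivot_betas_to_z(LEFT_PIVOT_BETAS)
_R_INTERCEPT, _R_NOISE = _solve_intercept_noise(
    RIGHT_HV_MEAN, RIGHT_HV_SD, np.array([_R_BZ1, _R_BZ2]),
    _default_ilr_mean(), _default_ilr_cov(), DEFAULT_COVARIATE_EFFECTS,
)
_L_INTERCEPT, _L_NOISE = _solve_intercept_noise(
    LEFT_HV_MEAN, LEFT_HV_SD, np.array([_L_BZ1, _L_BZ2]),
    _default_ilr_mean(), _default_ilr_cov(), DEFAULT_COVARIATE_EFFECTS,
)


@dataclass
class CohortConfig:
    """All knobs of the generator; the defaults are the calibrated cohort."""

    n_participants: int = N_PARTICIPANTS
    seed: int = 2017
    prop_male: float = PROP_MALE
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    icv_mean: float = ICV_MEAN
    icv_sd: float = ICV_SD
    ilr_mean: np.ndarray = field(default_factory=_default_ilr_mean)
    ilr_cov: np.ndarray = field(default_factory=_default_ilr_cov)
    outcome_intercept: float = _R_INTERCEPT
    beta_z1: float = _R_BZ1
    beta_z2: float = _R_BZ2
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = _R_NOISE
    left_intercept: float = _L_INTERCEPT
    left_beta_z1: float = _L_BZ1
    left_beta_z2: float = _L_BZ2
    left_noise_sd: float = _L_NOISE
    days_per_participant: int = 7
    target_wear_min: float = WEAR_MEAN
    wear_sd: float = WEAR_SD
    #: confounding knob: shift of z1 per year of age above the mean (0 = none)
    age_ilr_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_sd < 0 or self.left_noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("prop_male",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        self.ilr_mean = np.asarray(self.ilr_mean, dtype=float).reshape(2)
        cov = np.asarray(self.ilr_cov, dtype=float).reshape(2, 2)
        if not np.allclose(cov, cov.T):
            raise ValueError("ilr_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-10):
            raise ValueError("ilr_cov must be positive semi-definite")
        self.ilr_cov = cov
        if not 0 < self.target_wear_min <= EPOCHS_PER_DAY:
            raise ValueError("target_wear_min must lie in (0, 1440]")


@dataclass
class GroundTruth:
    """What the generator actually laid down, for downstream verification.

    ``table`` holds, per participant, the realized pooled composition (from
    the integer daily minutes), its MVPA-first pivot coordinates, and — after
    :func:`generate_outcomes` — the noiseless linear predictors.
    ``daily_minutes`` holds the integer per-day wear/SB/LPA/MVPA minutes that
    :func:`generate_epochs` encodes and the screening chain must recover.
    """

    table: pd.DataFrame
    daily_minutes: pd.DataFrame

    def compositions(self) -> np.ndarray:
        return self.table[["t_sb", "t_lpa", "t_mvpa"]].to_numpy()


def _sample_mvn(rng: np.random.Generator, mean, cov, n: int) -> np.ndarray:
    """MVN draws via eigendecomposition (tolerates a singular covariance)."""
    w, U = np.linalg.eigh(np.asarray(cov, dtype=float))
    if np.any(w < -1e-10):
        raise ValueError("ilr_cov must be positive semi-definite")
    root = U * np.sqrt(np.clip(w, 0.0, None))
    return np.asarray(mean) + rng.standard_normal((n, len(w))) @ root.T


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative targets to integers summing exactly to ``total``,
    keeping every part >= 1 so pooled compositions stay strictly positive
    (extreme logistic-normal draws can fall below the 1-min resolution)."""
    base = np.floor(targets).astype(int)
    short = total - base.sum()
    order = np.argsort(-(targets - base))
    base[order[:short]] += 1
    while np.any(base == 0):
        base[np.argmin(base)] += 1
        base[np.argmax(base)] -= 1
    return base


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw covariates, latent compositions, and integer daily minutes.

    Returns the covariate table (one row per participant) and the ground
    truth.  The per-participant "true" composition is the pooled composition
    of the realized integer daily minutes, so a noiseless outcome generated
    from it is exactly recoverable through the epoch-processing chain.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_participants
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    cov_rows = {
        "participant_id": ids,
        "male": (rng.random(n) < cfg.prop_male).astype(int),
        "age": rng.normal(cfg.age_mean, cfg.age_sd, n),
        "icv": np.clip(rng.normal(cfg.icv_mean, cfg.icv_sd, n), 1e5, None),
    }
    bmi_u = rng.random(n)
    p_under = COVARIATE_PREVALENCE["bmi_under"]
    p_over = COVARIATE_PREVALENCE["bmi_over"]
    cov_rows["bmi_under"] = (bmi_u < p_under).astype(int)
    cov_rows["bmi_over"] = (bmi_u >= 1.0 - p_over).astype(int)
    for name in ("education", "smoker", "alcohol", "med_hypertension",
                 "med_dyslipidemia", "med_diabetes"):
        cov_rows[name] = (rng.random(n) < COVARIATE_PREVALENCE[name]).astype(int)
    covariates = pd.DataFrame(cov_rows)
    covariates["bmi_cat"] = np.select(
        [covariates["bmi_under"] == 1, covariates["bmi_over"] == 1],
        ["under", "over"], default="normal",
    )

    z = _sample_mvn(rng, cfg.ilr_mean, cfg.ilr_cov, n)
    if cfg.age_ilr_slope != 0.0:
        z[:, 0] += cfg.age_ilr_slope * (covariates["age"].to_numpy() - cfg.age_mean)
    comps = coda.ilr_inverse(z, coda.MVPA_FIRST)

    # integer daily minutes: participant-level wear with mild day-to-day jitter
    wear_base = np.clip(
        rng.normal(cfg.target_wear_min, cfg.wear_sd, n), 620, EPOCHS_PER_DAY - 2
    )
    day_rows = []
    pooled = np.zeros((n, 3), dtype=int)
    pooled_wear = np.zeros(n, dtype=int)
    for i, pid in enumerate(ids):
        for d in range(cfg.days_per_participant):
            wear = int(np.clip(round(wear_base[i] + rng.integers(-25, 26)),
                               601, EPOCHS_PER_DAY))
            minutes = _largest_remainder(comps[i] * wear, wear)
            day_rows.append(
                {"participant_id": pid, "day": d, "wear": wear,
                 "sb": minutes[0], "lpa": minutes[1], "mvpa": minutes[2]}
            )
            pooled[i] += minutes
            pooled_wear[i] += wear
    daily = pd.DataFrame(day_rows)

    realized = pooled / pooled_wear[:, None]
    if np.any(realized <= 0):
        raise ValueError(
            "a pooled behavior rounded to zero minutes; increase wear or ilr_mean"
        )
    zr = coda.ilr_pivot(realized, coda.MVPA_FIRST)
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "t_sb": realized[:, 0],
            "t_lpa": realized[:, 1],
            "t_mvpa": realized[:, 2],
            "z1": zr[:, 0],
            "z2": zr[:, 1],
            "z1_sampled": z[:, 0],
            "z2_sampled": z[:, 1],
            "total_wear": pooled_wear,
        }
    )
    return covariates, GroundTruth(table=truth, daily_minutes=daily)


def generate_outcomes(
    covariates: pd.DataFrame, truth: GroundTruth, config: CohortConfig
) -> pd.DataFrame:
    """Hippocampal-volume outcomes from the linear model on (z1, z2) + covariates.

    Returns a table with ``right_hv`` and ``left_hv`` in mm^3 and records the
    noiseless linear predictors in ``truth.table``.
    """
    cfg = config
    if not covariates["participant_id"].equals(truth.table["participant_id"]):
        raise ValueError("covariates and ground truth are not aligned by participant_id")
    rng = np.random.default_rng([cfg.seed, 1])
    n = len(covariates)
    xeff = np.zeros(n)
    for name, effect in cfg.covariate_effects.items():
        if name not in covariates.columns:
            raise KeyError(f"covariate_effects references unknown column {name!r}")
        xeff += effect * covariates[name].to_numpy(dtype=float)
    z1 = truth.table["z1"].to_numpy()
    z2 = truth.table["z2"].to_numpy()
    lp_right = cfg.outcome_intercept + cfg.beta_z1 * z1 + cfg.beta_z2 * z2 + xeff
    lp_left = cfg.left_intercept + cfg.left_beta_z1 * z1 + cfg.left_beta_z2 * z2 + xeff
    truth.table["lp_right"] = lp_right
    truth.table["lp_left"] = lp_left
    return pd.DataFrame(
        {
            "participant_id": covariates["participant_id"],
            "right_hv": lp_right + rng.normal(0.0, cfg.noise_sd, n),
            "left_hv": lp_left + rng.normal(0.0, cfg.left_noise_sd, n),
        }
    )


def _lay_out_day(
    rng: np.random.Generator, wear: int, sb: int, lpa: int, mvpa: int
) -> np.ndarray:
    """One 1440-epoch MET vector realizing the given integer minutes.

    Non-wear (MET 0) is placed as one or two runs framing the worn block —
    each longer than 60 epochs whenever the budget allows, so the non-wear
    rule is exercised.  Worn minutes are laid down in bouts with MET values
    drawn inside each band: SB [0.9, 1.5), LPA [1.6, 2.9), MVPA [3.0, 6.0).
    """
    if sb + lpa + mvpa != wear or wear > EPOCHS_PER_DAY or min(sb, lpa, mvpa) < 0:
        raise ValueError("infeasible day targets")
    nonwear = EPOCHS_PER_DAY - wear
    half = nonwear // 2
    head = nonwear if half < 61 else half

    remaining = {"sb": sb, "lpa": lpa, "mvpa": mvpa}
    lo_hi = {"sb": (0.9, 1.5), "lpa": (1.6, 2.9), "mvpa": (3.0, 6.0)}
    bout_len = {"sb": (10, 45), "lpa": (10, 40), "mvpa": (3, 15)}
    met = np.zeros(EPOCHS_PER_DAY)
    pos = head
    while any(remaining.values()):
        bands = [b for b, m in remaining.items() if m > 0]
        weights = np.array([remaining[b] for b in bands], dtype=float)
        band = bands[rng.choice(len(bands), p=weights / weights.sum())]
        length = min(remaining[band], int(rng.integers(*bout_len[band])) + 1)
        lo, hi = lo_hi[band]
        met[pos : pos + length] = rng.uniform(lo, hi, length)
        pos += length
        remaining[band] -= length
    return met


def generate_epochs(truth: GroundTruth, config: CohortConfig) -> pd.DataFrame:
    """Long-format epochs table (participant_id, date, epoch_index, met_value).

    Construction is its own oracle: running the accelerometry screen on the
    output recovers ``truth.daily_minutes`` exactly.
    """
    rng = np.random.default_rng([config.seed, 2])
    frames = []
    for row in truth.daily_minutes.itertuples(index=False):
        met = _lay_out_day(rng, row.wear, row.sb, row.lpa, row.mvpa)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": row.participant_id,
                    "date": f"2017-09-{row.day + 1:02d}",
                    "epoch_index": np.arange(EPOCHS_PER_DAY),
                    "met_value": np.round(met, 3),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_study(config: CohortConfig | None = None):
    """Convenience: cohort + outcomes + epochs in one call."""
    cfg = config or CohortConfig()
    covariates, truth = generate_cohort(cfg)
    outcomes = generate_outcomes(covariates, truth, cfg)
    epochs = generate_epochs(truth, cfg)
    return covariates, outcomes, epochs, truth
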