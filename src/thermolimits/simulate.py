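"""Synthetic method-of-limits cohorts with realistic distributional structure.

The generator emulates the features the downstream analysis relies on:

* right-skewed (lognormal) subject-level detection thresholds, with the
  default location/scale reproducing a warm-threshold median near 1.9 degC
  and IQR near [1.2, 2.9];
* multiplicative coupling between a subject's latent threshold and their
  trial-to-trial noise SD, which induces a threshold-GMD rank correlation
  around 0.65-0.7 at the default coupling;
* group separations specified as target Cliff's deltas and converted to
  normal mean shifts via shift = sqrt(2) * Phi^-1((delta+1)/2) * sigma
  (exact on the scale where the variable is normal);
* MCAR missingness on questionnaire/IQ covariates at per-variable rates.

A fixed seed yields bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .thresholds import DEVICE_MAX_C, DEVICE_MIN_C, BASELINE_C

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_trials",
    "inject_missingness",
    "simulate_study",
]

#: columns that may never be made missing
PROTECTED_COLUMNS = frozenset(
    {
        "subject_id", "diagnosis", "age", "age_group", "sex",
        "counterbalance", "modality", "block", "trial", "temperature_c",
    }
)

_QUADRANTS = ("low_registration", "seeking", "sensitivity", "avoiding")


def _default_questionnaire_deltas() -> dict:
    # Signed ASD-vs-TD targets; SP (caregiver) scales are reverse-keyed,
    # hence the negative signs for children.
    return {
        "srs_t": 0.97,
        "srs_item42": 0.73,
        "viq": -0.35,
        "piq": -0.12,
        "fsiq": -0.29,
        "aasp_low_registration": 0.87,
        "aasp_seeking": -0.55,
        "aasp_sensitivity": 0.75,
        "aasp_avoiding": 0.73,
        "sp_low_registration": -0.86,
        "sp_seeking": -0.58,
        "sp_sensitivity": -0.73,
        "sp_avoiding": -0.82,
    }


def _default_missing_rates() -> dict:
    rates = {"viq": 0.03, "piq": 0.03, "fsiq": 0.03,
             "srs_t": 0.22, "srs_item42": 0.20, "ados_css": 0.13}
    rates.update({f"sp_{q}": 0.13 for q in _QUADRANTS})
    rates.update({f"aasp_{q}": 0.20 for q in _QUADRANTS})
    return rates


@dataclass
class SyntheticConfig:
    """Full parameterization of a simulated thermal-detection cohort."""

    n_asd: int = 83
    n_td: int = 59
    prop_child: float = 86 / 142
    prop_male_asd: float = 62 / 83
    prop_male_td: float = 40 / 59
    latent_log_mean: float = float(np.log(1.9))   # log degC, warm modality
    latent_log_sd: float = 0.65
    cool_log_offset: float = float(np.log(2.41 / 1.9))
    modality_corr: float = 0.8
    noise_coupling: float = 1.0
    noise_log_sd: float = 0.55
    noise_log_level: float = float(np.log(0.5 / 1.128) - np.log(1.9))
    group_shift_delta: float = 0.17
    gmd_group_delta: float = 0.22
    piq_effect: float = -0.01     # degC per IQ point
    sex_effect: float = 0.3       # degC, male - female
    questionnaire_deltas: dict = field(
        default_factory=_default_questionnaire_deltas
    )
    missing_rates: dict = field(default_factory=_default_missing_rates)
    n_trials_per_block: int = 5
    n_blocks: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_child", "prop_male_asd", "prop_male_td"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_asd", "n_td", "n_trials_per_block", "n_blocks"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.latent_log_sd <= 0:
            raise ValueError("latent_log_sd must be positive")
        if self.noise_log_sd < 0:
            raise ValueError("noise_log_sd must be non-negative")
        for name in ("group_shift_delta", "gmd_group_delta"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be inside (-1, 1), got {v}")
        for key, rate in self.missing_rates.items():
            if key in PROTECTED_COLUMNS:
                raise ValueError(f"cannot inject missingness into {key!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {key!r} outside [0, 1]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _delta_shift(delta: float, sigma: float) -> float:
    """Normal mean shift producing population Cliff's delta ``delta``."""
    return float(np.sqrt(2.0) * norm.ppf((delta + 1.0) / 2.0) * sigma)


def _shifted_normal(rng, n, mean, sd, delta, is_asd, clip=None):
    """Normal draws where the ASD rows are shifted to hit a target delta."""
    vals = mean + sd * rng.standard_normal(n)
    vals = vals + _delta_shift(delta, sd) * is_asd
    if clip is not None:
        vals = np.clip(vals, *clip)
    return vals


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the subject-level covariate table.

    Demographic structure (group sizes, child proportion, sex ratios)
    follows the configuration; IQ and questionnaire scores are normal
    variables whose ASD-TD separations are calibrated to the configured
    Cliff's-delta targets.  ADOS-2 severity exists only for ASD rows, and
    each subject carries exactly one sensory-profile instrument according
    to age group (SP for children, AASP for adults).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_asd + config.n_td
    is_asd = np.concatenate(
        [np.ones(config.n_asd, bool), np.zeros(config.n_td, bool)]
    )
    ids = np.array([f"S{i:04d}" for i in range(1, n + 1)])

    child = rng.random(n) < config.prop_child
    age = np.where(
        child,
        rng.uniform(7.0, 17.99, n),
        18.0 + 36.0 * rng.beta(1.5, 3.0, n),
    )
    p_male = np.where(is_asd, config.prop_male_asd, config.prop_male_td)
    male = rng.random(n) < p_male

    q = config.questionnaire_deltas
    viq = _shifted_normal(rng, n, 108, 13, q.get("viq", 0.0), is_asd)
    piq = _shifted_normal(rng, n, 109, 14, q.get("piq", 0.0), is_asd)
    fsiq = _shifted_normal(rng, n, 110, 12, q.get("fsiq", 0.0), is_asd)
    srs_t = _shifted_normal(rng, n, 44, 6.5, q.get("srs_t", 0.0), is_asd)
    srs_item42 = _shifted_normal(
        rng, n, 0.4, 0.9, q.get("srs_item42", 0.0), is_asd, clip=(0.0, 3.0)
    )

    quad_params = {  # TD mean, sd per instrument/quadrant
        "aasp_low_registration": (25, 6), "aasp_seeking": (45, 6),
        "aasp_sensitivity": (34, 6), "aasp_avoiding": (33, 7),
        "sp_low_registration": (70, 5), "sp_seeking": (111, 11),
        "sp_sensitivity": (88, 9), "sp_avoiding": (122, 11),
    }
    quads = {
        name: _shifted_normal(rng, n, m, s, q.get(name, 0.0), is_asd)
        for name, (m, s) in quad_params.items()
    }
    # age-group appropriate instrument only
    for name in quads:
        mask = child if name.startswith("sp_") else ~child
        quads[name] = np.where(mask, quads[name], np.nan)

    ados = np.clip(7.5 + 1.8 * rng.standard_normal(n), 1.0, 10.0)
    ados = np.where(is_asd, ados, np.nan)

    counterbalance = np.where(
        np.arange(n) % 2 == 0, "warm_first", "cool_first"
    )
    return pd.DataFrame(
        {
            "subject_id": ids,
            "diagnosis": np.where(is_asd, "ASD", "TD"),
            "age": age,
            "age_group": np.where(child, "child", "adult"),
            "sex": np.where(male, "M", "F"),
            "viq": viq, "piq": piq, "fsiq": fsiq,
            "srs_t": srs_t, "srs_item42": srs_item42,
            **quads,
            "ados_css": ados,
            "counterbalance": counterbalance,
        }
    )


def _latent_thresholds(subjects: pd.DataFrame, config: SyntheticConfig, rng):
    """Per-subject latent mean threshold change and trial-noise SD.

    Latent log-threshold is normal with a group shift calibrated to the
    target delta; trial-noise log-SD couples to the log-threshold
    (coefficient ``noise_coupling``) plus independent lognormal variation,
    with the group noise shift calibrated against the total log-SD spread.
    """
    n = len(subjects)
    is_asd = (subjects["diagnosis"] == "ASD").to_numpy()
    male = (subjects["sex"] == "M").to_numpy()
    piq = subjects["piq"].to_numpy(dtype=float)
    piq = np.where(np.isfinite(piq), piq, np.nanmean(piq))

    dx_shift = _delta_shift(config.group_shift_delta, config.latent_log_sd)
    out = {}
    z_w = rng.standard_normal(n)
    z_c = config.modality_corr * z_w + np.sqrt(
        1 - config.modality_corr**2
    ) * rng.standard_normal(n)
    pert = {
        "warm": rng.standard_normal(n),
        "cool": rng.standard_normal(n),
    }
    sd_logsigma = np.sqrt(
        (config.noise_coupling * config.latent_log_sd) ** 2
        + config.noise_log_sd**2
    )
    # Table-2 direction: TD median GMD exceeds ASD, positive printed delta;
    # shift the TD group's noise level up, net of the coupling pass-through.
    noise_shift = (
        _delta_shift(config.gmd_group_delta, sd_logsigma)
        + config.noise_coupling * dx_shift
    )
    for modality, z in (("warm", z_w), ("cool", z_c)):
        log_mu = (
            config.latent_log_mean
            + (config.cool_log_offset if modality == "cool" else 0.0)
            + dx_shift * is_asd
            + config.latent_log_sd * z
        )
        mu = np.exp(log_mu)
        mu = mu + config.piq_effect * (piq - np.mean(piq))
        mu = mu + config.sex_effect * male
        mu = np.maximum(mu, 0.05)
        log_sigma = (
            config.noise_log_level
            + config.noise_coupling * np.log(mu)
            + noise_shift * (~is_asd)
            + config.noise_log_sd * pert[modality]
        )
        out[modality] = (mu, np.exp(log_sigma))
    return out


def generate_trials(
    subjects: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Generate the trial-level temperature table.

    Each subject contributes ``n_blocks x n_trials_per_block`` trials per
    modality; recorded temperature is baseline plus (warm) or minus (cool)
    the subject's latent threshold change plus trial noise, clamped to the
    device bounds [0, 50] degC.
    """
    if subjects.empty:
        raise ValueError("subject table is empty")
    required = {"subject_id", "diagnosis", "sex", "piq"}
    if not required <= set(subjects.columns):
        raise ValueError(
            f"subject table lacks required columns: {sorted(required - set(subjects.columns))}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    latents = _latent_thresholds(subjects, config, rng)
    n = len(subjects)
    n_trials = config.n_blocks * config.n_trials_per_block
    frames = []
    for modality, sign in (("warm", 1.0), ("cool", -1.0)):
        mu, sigma = latents[modality]
        eps = sigma[:, None] * rng.standard_normal((n, n_trials))
        temp = BASELINE_C + sign * (mu[:, None] + eps)
        # the ramp moves away from baseline, so a warm trial can never stop
        # below 32 degC (nor a cool trial above); clamp to the reachable span
        lo = BASELINE_C if modality == "warm" else DEVICE_MIN_C
        hi = DEVICE_MAX_C if modality == "warm" else BASELINE_C
        temp = np.clip(temp, lo, hi)
        blocks = np.repeat(
            np.arange(1, config.n_blocks + 1), config.n_trials_per_block
        )
        trials = np.tile(
            np.arange(1, config.n_trials_per_block + 1), config.n_blocks
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(
                        subjects["subject_id"].to_numpy(), n_trials
                    ),
                    "modality": modality,
                    "block": np.tile(blocks, n),
                    "trial": np.tile(trials, n),
                    "temperature_c": temp.ravel(),
                }
            )
        )
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["subject_id", "modality", "block", "trial"])
        .reset_index(drop=True)
    )


def inject_missingness(
    table: pd.DataFrame, missing_rates: dict, seed: int
) -> pd.DataFrame:
    """Set covariate cells missing completely at random at per-column rates.

    Protected identity/design columns (ids, diagnosis, modality,
    temperatures, ...) may not be targeted.
    """
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    for col, rate in missing_rates.items():
        if col in PROTECTED_COLUMNS:
            raise ValueError(f"cannot inject missingness into {col!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        if col not in out.columns:
            raise KeyError(f"no such column: {col!r}")
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def simulate_study(config: SyntheticConfig):
    """Generate subjects (with missingness applied) and trials in one call."""
    subjects = generate_cohort(config)
    trials = generate_trials(subjects, config)
    subjects = inject_missingness(subjects, config.missing_rates, config.seed)
    return subjects, trials
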