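"""Synthetic cohort generator.

The study data the pipeline targets is a cohort of healthy adults (HC) and a
smaller Parkinson's disease (PD) sample, each with demographics, seven
clinical scores and 199 oculomotor parameters. The raw data is not public,
so this module emulates its statistical structure with a minimal generative
model:

* one latent "neural integrity" factor ``g`` per participant, partially
  age-linked: ``g = alpha * z(age) + sqrt(1 - alpha^2) * eps``;
* informative oculomotor parameters load on ``g`` with signed loadings
  scaled by a group-level coupling strength ``kappa``; the remaining
  parameters are pure noise;
* each clinical score is an affine function of age and ``kappa * g`` plus
  noise, rounded/clipped into its legal range (Trail-Making times get
  right-skewed noise instead, mirroring the skew that motivates rank
  statistics in the analysis).

Disease is modelled purely as stronger oculomotor-cognition coupling
(larger ``kappa``), shifted score means, an older age distribution and more
structural missingness — the qualitative pattern reported for PD cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import DEFAULT_TASK_COUNTS, ParameterCatalog, TASKS, make_catalog
from .cohort import OUTCOMES, CohortTable

__all__ = [
    "ScoreSpec", "SimulationConfig", "GenerativeTruth",
    "generate_cohort", "theoretical_r2", "apply_missingness",
]

#: scores reported as integers by the instruments
_INTEGER_SCORES = {"MoCA", "SDMT", "HVLT", "COWAT", "BAI"}
#: timed scores with right-skewed (shifted log-normal) noise
_SKEWED_SCORES = {"TMTA", "TMTB"}
#: hard clipping bounds applied after noise (None = unbounded)
_CLIP_BOUNDS = {
    "MoCA": (0.0, 30.0), "SDMT": (0.0, 110.0), "BAI": (0.0, 63.0),
    "HVLT": (0.0, 36.0), "COWAT": (0.0, None),
    "TMTA": (5.0, None), "TMTB": (10.0, None),
}
_LOGNORM_SIGMA = 0.5  # shape of the skewed noise for TMT times


@dataclass(frozen=True)
class ScoreSpec:
    """Generative parameters of one clinical score (natural units)."""

    intercept: float          # expected score at age 0 with g = 0
    age_slope: float          # points per year
    latent_weight: float      # points per unit of kappa * g (signed)
    noise_sd: float           # residual SD


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int
    group: str                                  # "HC" or "PD"
    age_range: tuple[float, float]
    age_mean_sd: tuple[float, float]
    sex_counts: tuple[int, int]                 # (n_male, n_female)
    coupling_kappa: float
    scores: dict[str, ScoreSpec]
    n_params_per_task: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TASK_COUNTS))
    n_informative_params: int = 60
    noise_sd_params: float = 1.0
    loading_magnitude_range: tuple[float, float] = (0.7, 1.3)
    age_latent_mixing: float = 0.5              # alpha in g = a*z(age)+...
    missing_block_rate: float = 0.0
    missing_cell_rate: float = 0.0
    score_completion: dict[str, int] = field(default_factory=dict)
    sex_effect_per_score: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    # -- convenience views matching the generative-model notation ---------
    @property
    def age_slope_per_score(self) -> dict[str, float]:
        return {name: spec.age_slope for name, spec in self.scores.items()}

    @property
    def noise_sd_scores(self) -> dict[str, float]:
        return {name: spec.noise_sd for name, spec in self.scores.items()}

    @property
    def n_params_total(self) -> int:
        return sum(self.n_params_per_task.values())

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("invalid config: n_participants must be positive")
        if sum(self.sex_counts) != self.n_participants:
            raise ValueError("invalid config: sex_counts must sum to n_participants")
        if not (0 <= self.missing_block_rate <= 1
                and 0 <= self.missing_cell_rate <= 1):
            raise ValueError("invalid config: missing rates must lie in [0, 1]")
        if self.coupling_kappa < 0:
            raise ValueError("invalid config: coupling_kappa must be >= 0")
        if self.n_informative_params > self.n_params_total:
            raise ValueError("invalid config: more informative parameters "
                             "than parameters")
        if not 0 <= self.age_latent_mixing <= 1:
            raise ValueError("invalid config: age_latent_mixing must lie in [0, 1]")
        unknown = set(self.scores) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"invalid config: unknown scores {sorted(unknown)}")
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ValueError("invalid config: bad age_range")


@dataclass(frozen=True)
class GenerativeTruth:
    """Ground truth emitted alongside a generated cohort for recovery tests."""

    latent_factor: np.ndarray
    informative_param_ids: tuple[str, ...]
    loadings: dict[str, float]
    theoretical_r2_per_score: dict[str, float]


def _truncnorm_moments(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mu, var = sps.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(mu), float(np.sqrt(var))


def _sample_truncated_ages(rng, config) -> np.ndarray:
    """Truncated-normal ages by resampling (no boundary atoms)."""
    mean, sd = config.age_mean_sd
    lo, hi = config.age_range
    ages = np.empty(config.n_participants)
    filled = 0
    while filled < ages.size:
        draw = rng.normal(mean, sd, size=2 * (ages.size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: ages.size - filled]
        ages[filled:filled + keep.size] = keep
        filled += keep.size
    return ages


def theoretical_r2(config: SimulationConfig, outcome: str) -> float:
    """Population R^2 of an ideal model given (g, age) for one score.

    The signal variance includes the age/latent covariance term that arises
    because ``g`` carries an age component; noise is the score's residual
    variance (rounding and clipping are ignored, a good approximation when
    scores rarely touch their bounds).
    """
    if outcome not in config.scores:
        raise KeyError(f"unknown outcome {outcome!r}")
    spec = config.scores[outcome]
    mean, sd = config.age_mean_sd
    lo, hi = config.age_range
    _, sigma_a = _truncnorm_moments(mean, sd, lo, hi)
    alpha = config.age_latent_mixing
    u = spec.age_slope * sigma_a           # age contribution SD
    w = spec.latent_weight * config.coupling_kappa  # latent contribution SD
    signal = u * u + w * w + 2.0 * alpha * u * w
    return float(signal / (signal + spec.noise_sd**2))


def apply_missingness(cohort: CohortTable, block_rate: float,
                      cell_rate: float, seed: int) -> CohortTable:
    """Structural (per participant x task block) then cell-wise MCAR masking.

    Demographics and clinical scores are never masked.
    """
    if not (0 <= block_rate <= 1 and 0 <= cell_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frame = cohort.frame.copy()
    n = len(frame)
    for task in TASKS:
        cols = cohort.catalog.parameters_for(task)
        if not cols:
            continue
        drop_block = rng.random(n) < block_rate
        block = frame.loc[:, cols].to_numpy(dtype=float)
        block[drop_block, :] = np.nan
        drop_cell = rng.random(block.shape) < cell_rate
        block[drop_cell] = np.nan
        frame.loc[:, cols] = block
    return CohortTable(frame, cohort.catalog)


def generate_cohort(config: SimulationConfig,
                    catalog: ParameterCatalog | None = None,
                    ) -> tuple[CohortTable, GenerativeTruth]:
    """Draw one cohort from the generative model. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if catalog is None:
        catalog = make_catalog(config.n_params_per_task)

    ages = _sample_truncated_ages(rng, config)
    mu_a, sigma_a = _truncnorm_moments(*config.age_mean_sd, *config.age_range)
    z_age = (ages - mu_a) / sigma_a
    alpha = config.age_latent_mixing
    g = alpha * z_age + np.sqrt(1.0 - alpha**2) * rng.standard_normal(n)

    n_male, n_female = config.sex_counts
    sexes = np.array(["male"] * n_male + ["female"] * n_female, dtype=object)
    rng.shuffle(sexes)

    # informative parameters: evenly spread through the catalog so every
    # task carries some signal
    total = len(catalog)
    k = config.n_informative_params
    info_idx = np.unique(np.linspace(0, total - 1, k).round().astype(int))
    lo_m, hi_m = config.loading_magnitude_range
    lam = rng.uniform(lo_m, hi_m, size=info_idx.size)
    lam *= rng.choice([-1.0, 1.0], size=info_idx.size)

    X = rng.normal(0.0, config.noise_sd_params, size=(n, total))
    X[:, info_idx] += np.outer(g, lam * config.coupling_kappa)

    frame = pd.DataFrame({
        "id": [f"{config.group}{i + 1:04d}" for i in range(n)],
        "group": config.group,
        "sex": sexes,
        "age": ages,
    })
    sex_is_female = (sexes == "female").astype(float)
    for outcome in OUTCOMES:
        if outcome not in config.scores:
            frame[outcome] = np.nan
            continue
        spec = config.scores[outcome]
        base = (spec.intercept + spec.age_slope * ages
                + spec.latent_weight * config.coupling_kappa * g
                + config.sex_effect_per_score.get(outcome, 0.0) * sex_is_female)
        if outcome in _SKEWED_SCORES:
            # additive shifted log-normal noise: mean 0, SD noise_sd, skewed
            raw = np.exp(_LOGNORM_SIGMA * rng.standard_normal(n))
            m = np.exp(_LOGNORM_SIGMA**2 / 2.0)
            s = m * np.sqrt(np.expm1(_LOGNORM_SIGMA**2))
            noise = spec.noise_sd * (raw - m) / s
        else:
            noise = spec.noise_sd * rng.standard_normal(n)
        values = base + noise
        if outcome in _INTEGER_SCORES:
            values = np.round(values)
        lo, hi = _CLIP_BOUNDS[outcome]
        values = np.clip(values, lo, hi if hi is not None else np.inf)
        # per-score completion: mask participants so available-n matches
        target_n = config.score_completion.get(outcome)
        if target_n is not None and target_n < n:
            drop = rng.choice(n, size=n - target_n, replace=False)
            values = values.astype(float)
            values[drop] = np.nan
        frame[outcome] = values

    frame = pd.concat(
        [frame, pd.DataFrame(X, columns=list(catalog.names))], axis=1)

    cohort = CohortTable(frame, catalog)
    if config.missing_block_rate > 0 or config.missing_cell_rate > 0:
        sub_seed = int(np.random.default_rng(config.seed + 1).integers(2**31))
        cohort = apply_missingness(cohort, config.missing_block_rate,
                                   config.missing_cell_rate, sub_seed)

    truth = GenerativeTruth(
        latent_factor=g,
        informative_param_ids=tuple(catalog.names[i] for i in info_idx),
        loadings={catalog.names[i]: float(l) for i, l in zip(info_idx, lam)},
        theoretical_r2_per_score={
            o: theoretical_r2(config, o) for o in config.scores
        },
    )
    return cohort, truth
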