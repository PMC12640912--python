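"""Frozen default simulation presets for the HC and PD regimes.

The healthy-control (HC) preset emulates a cohort of 204 adults aged 18-79
(120 male / 84 female) with weak oculomotor-cognition coupling; the
Parkinson's disease (PD) preset emulates 65 patients aged 45-89 (43/22)
with markedly stronger coupling, shifted score means, and heavier
structural missingness. Per-score completion counts reproduce the
per-test available-n pattern of such studies (SDMT and BAI collected for
the healthy group only).

Score slopes and noise SDs were set analytically from target age-score
rank correlations and score scales, then adjusted once against large-n
simulations; the coupling strengths ``kappa`` were calibrated once so the
full pipeline's median adjusted R^2 lands inside the regimes the package
is designed to emulate (roughly 0.10-0.33 for HC, 0.47-0.63 for PD), and
frozen here.
"""

from __future__ import annotations

from .simulate import ScoreSpec, SimulationConfig

# Coupling strengths: the single knob separating the regimes.
KAPPA_HC = 1.0
KAPPA_PD = 3.0

# Per-score generative parameters (natural units). latent_weight is the
# score change per unit of kappa*g, with g oriented as a "neural aging"
# factor: timed tests worsen (increase), performance scores decline.
_HC_SCORES = {
    "TMTA":  ScoreSpec(intercept=18.0, age_slope=0.300, latent_weight=2.90,
                       noise_sd=13.5),
    "TMTB":  ScoreSpec(intercept=45.0, age_slope=0.700, latent_weight=8.00,
                       noise_sd=34.0),
    "COWAT": ScoreSpec(intercept=41.4, age_slope=0.016, latent_weight=-3.96,
                       noise_sd=10.3),
    "SDMT":  ScoreSpec(intercept=74.1, age_slope=-0.478, latent_weight=-2.40,
                       noise_sd=8.9),
    "MoCA":  ScoreSpec(intercept=27.3, age_slope=-0.0054, latent_weight=-0.55,
                       noise_sd=2.43),
    "HVLT":  ScoreSpec(intercept=31.2, age_slope=-0.115, latent_weight=-0.85,
                       noise_sd=3.97),
    "BAI":   ScoreSpec(intercept=12.6, age_slope=-0.085, latent_weight=-1.90,
                       noise_sd=6.6),
}

# PD: same score model, shifted means for the outcomes that differ between
# groups (timed tests slower, MoCA/HVLT lower, COWAT comparable); SDMT and
# BAI were not collected for the PD group.
_PD_SHIFTS = {"TMTA": 15.0, "TMTB": 35.0, "MoCA": -2.5, "HVLT": -4.0,
              "COWAT": 0.0}
# disease amplifies the latent coupling score-dependently (on top of the
# group-level kappa), reflecting that neurodegeneration tightens the
# oculomotor-cognition link more for some instruments than others
_PD_LATENT_BOOST = {"TMTA": 1.30, "TMTB": 1.45, "COWAT": 0.90, "MoCA": 1.35,
                    "HVLT": 1.60}
_PD_SCORES = {
    name: ScoreSpec(
        intercept=_HC_SCORES[name].intercept + shift,
        age_slope=_HC_SCORES[name].age_slope,
        latent_weight=_HC_SCORES[name].latent_weight * _PD_LATENT_BOOST[name],
        noise_sd=_HC_SCORES[name].noise_sd,
    )
    for name, shift in _PD_SHIFTS.items()
}

# Per-test completion counts (available n) emulated by the generator.
_HC_COMPLETION = {"MoCA": 203, "TMTA": 203, "TMTB": 203, "COWAT": 203,
                  "HVLT": 200, "SDMT": 198, "BAI": 203}
_PD_COMPLETION = {"MoCA": 36, "TMTA": 50, "TMTB": 49, "COWAT": 48,
                  "HVLT": 50}


def hc_default(seed: int = 0) -> SimulationConfig:
    """Healthy-control preset: n=204, ages 18-79, weak coupling."""
    return SimulationConfig(
        n_participants=204,
        group="HC",
        age_range=(18.0, 79.0),
        age_mean_sd=(40.2, 15.0),
        sex_counts=(120, 84),
        coupling_kappa=KAPPA_HC,
        scores=dict(_HC_SCORES),
        score_completion=dict(_HC_COMPLETION),
        missing_block_rate=0.04,
        missing_cell_rate=0.01,
        seed=seed,
    )


def pd_default(seed: int = 0) -> SimulationConfig:
    """Parkinson's preset: n=65, ages 45-89, strong coupling."""
    return SimulationConfig(
        n_participants=65,
        group="PD",
        age_range=(45.0, 89.0),
        age_mean_sd=(64.1, 8.4),
        sex_counts=(43, 22),
        coupling_kappa=KAPPA_PD,
        scores=dict(_PD_SCORES),
        score_completion=dict(_PD_COMPLETION),
        missing_block_rate=0.08,
        missing_cell_rate=0.02,
        seed=seed,
    )


def null_default(seed: int = 0, n: int = 204) -> SimulationConfig:
    """Zero-coupling, zero-age-slope control preset for calibration checks."""
    flat = {name: ScoreSpec(spec.intercept, 0.0, 0.0, spec.noise_sd)
            for name, spec in _HC_SCORES.items()}
    n_male = n // 2
    return SimulationConfig(
        n_participants=n,
        group="HC",
        age_range=(18.0, 79.0),
        age_mean_sd=(40.2, 15.0),
        sex_counts=(n_male, n - n_male),
        coupling_kappa=0.0,
        scores=flat,
        seed=seed,
    )
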