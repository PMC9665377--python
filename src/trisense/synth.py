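"""Synthetic participants and datasets for the full-body-illusion study.

Emulates the two-part design: 80 participants rate seven questionnaire
statements (S1-S6 on a -3..+3 Likert scale, S7 on a 0-10 visual analog
scale) after each of the four conditions of the 2x2 synchrony design,
and 50 of them additionally complete 16 threat trials with skin
conductance responses (SCR) recorded, conditions pseudorandomized over
four printed orders and responses attenuating over repetitions.

Every participant is a draw from population distributions over the
causal-inference model parameters plus response-linking parameters, so
the generated data carry the model's signature: ownership drives S1,
the post-feedback pairwise posteriors drive S2/S3, self-motion drives
S7, and ownership multiplies the threat-evoked SCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .bci import (
    CausalPriors,
    ConditionSpec,
    ModalityNoise,
    SelfMotionCoeffs,
    CONDITION_KEYS,
    infer_trial,
    predict_conditions,
    predict_self_motion,
)

__all__ = [
    "ParticipantProfile",
    "StudyDesign",
    "PopulationHyperparams",
    "DEFAULT_SCR_ORDERS",
    "substream",
    "draw_profiles",
    "latent_to_likert",
    "simulate_questionnaire",
    "simulate_scr",
]

#: The four pseudorandomization sequences of the SCR experiment; each
#: condition occupies each within-block position exactly once across orders.
DEFAULT_SCR_ORDERS = (
    ("SVV_SVT", "AVV_AVT", "AVV_SVT", "SVV_AVT"),
    ("AVV_SVT", "SVV_SVT", "SVV_AVT", "AVV_AVT"),
    ("SVV_AVT", "AVV_SVT", "AVV_AVT", "SVV_SVT"),
    ("AVV_AVT", "SVV_AVT", "SVV_SVT", "AVV_SVT"),
)

STATEMENTS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")

#: Exponent of the concave ownership -> threat-arousal link.  The defensive
#: SCR saturates: even a weak but affirmative illusion triggers the automatic
#: threat response, so arousal rises steeply at low ownership and flattens
#: near 1.  (The response-linking law is a modeling choice of this package.)
SCR_OWNERSHIP_EXPONENT = 0.15


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named child RNG so every stage draws from its own stream."""
    import zlib

    keys = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31), spawn_key=keys))


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant model and response parameters."""

    id: str
    noise: ModalityNoise
    priors: CausalPriors
    likert_thresholds: tuple  # 6 strictly increasing cutpoints on the latent scale
    latent_slope: float
    latent_intercept: float
    vas_gain: float
    vas_offset: float
    random_intercept: float
    scr_baseline: float        # mmho
    scr_attenuation: float     # per-repetition decay rate
    scr_ownership_gain: float
    scr_noise_sd: float        # mmho

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.likert_thresholds)
        if len(th) != 6 or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("likert_thresholds must be 6 strictly increasing values")
        object.__setattr__(self, "likert_thresholds", th)
        if self.scr_baseline <= 0:
            raise ValueError("scr_baseline must be positive")
        if self.scr_attenuation < 0 or self.scr_ownership_gain < 0:
            raise ValueError("scr_attenuation and scr_ownership_gain must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Sample sizes and timing constants of the two experiments."""

    n_questionnaire: int = 80
    n_scr: int = 50
    n_scr_trials: int = 16
    scr_orders: tuple = DEFAULT_SCR_ORDERS
    questionnaire_duration: float = 180.0
    scr_trial_duration_range: tuple = (59.0, 67.0)
    threat_window: tuple = (39.0, 64.0)

    def __post_init__(self) -> None:
        if len(self.scr_orders) != 4 or any(
            sorted(o) != sorted(CONDITION_KEYS) for o in self.scr_orders
        ):
            raise ValueError("scr_orders must be four permutations of the condition keys")
        if self.n_questionnaire < 1 or self.n_scr < 1:
            raise ValueError("participant counts must be >= 1")


@dataclass(frozen=True)
class PopulationHyperparams:
    """Population distributions the participant profiles are drawn from.

    Sensory noises are log-normal (median, sd of log); the wide
    ``sigma_vest`` spread (sdlog 0.6, CV ~ 0.66) is what creates the
    between-participant variation in vestibular reliability that drives
    the negative difference-score correlation at the population level.
    Common-cause priors are Beta with mean 0.5 and concentration 16
    (infinite concentration pins them exactly); Likert cutpoints are a fixed
    grid plus sorted Gaussian jitter.
    """

    sigma_v_median: float = 0.05
    sigma_v_sdlog: float = 0.2
    sigma_t_median: float = 0.08
    sigma_t_sdlog: float = 0.3
    sigma_vest_median: float = 0.45
    sigma_vest_sdlog: float = 0.6
    sigma_indep_median: float = 1.0
    sigma_indep_sdlog: float = 0.1
    prior_mean: float = 0.5
    prior_concentration: float = 16.0  # Beta(mean*c, (1-mean)*c); inf = degenerate
    w_prior: float = 0.5
    gamma: float = 1.0
    threshold_grid: tuple = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    threshold_jitter_sd: float = 0.2
    latent_intercept_mean: float = 0.7
    latent_intercept_sd: float = 0.3
    latent_slope_mean: float = 0.5
    latent_slope_sd: float = 0.1
    random_intercept_sd: float = 1.5
    vas_gain_mean: float = 2.5
    vas_gain_sd: float = 0.4
    vas_offset_mean: float = 0.5
    vas_offset_sd: float = 0.5
    vas_noise_sd: float = 1.2
    scr_baseline_median: float = 0.30
    scr_baseline_sdlog: float = 0.3
    scr_attenuation_mean: float = 0.04
    scr_attenuation_sd: float = 0.01
    scr_ownership_gain_mean: float = 0.35
    scr_ownership_gain_sd: float = 0.08
    scr_noise_sd_median: float = 0.10
    scr_noise_sd_sdlog: float = 0.2
    likert_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_v_sdlog", "sigma_t_sdlog", "sigma_vest_sdlog", "sigma_indep_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.prior_mean < 1.0) or self.prior_concentration <= 0:
            raise ValueError("prior_mean must be in (0,1) and prior_concentration positive")
        th = self.threshold_grid
        if len(th) != 6 or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("threshold_grid must be 6 strictly increasing values")


def _lognormal(rng: np.random.Generator, median: float, sdlog: float) -> float:
    if sdlog == 0:
        return median
    return float(median * math.exp(rng.normal(0.0, sdlog)))


def draw_profiles(
    n: int, hyperparams: PopulationHyperparams = PopulationHyperparams(), seed: int = 0
) -> List[ParticipantProfile]:
    """Draw ``n`` participants from the population distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    h = hyperparams
    rng = substream(seed, "profiles")
    profiles = []
    for i in range(n):
        noise = ModalityNoise(
            sigma_v=_lognormal(rng, h.sigma_v_median, h.sigma_v_sdlog),
            sigma_t=_lognormal(rng, h.sigma_t_median, h.sigma_t_sdlog),
            sigma_vest=_lognormal(rng, h.sigma_vest_median, h.sigma_vest_sdlog),
            sigma_indep=_lognormal(rng, h.sigma_indep_median, h.sigma_indep_sdlog),
        )
        if math.isinf(h.prior_concentration):
            p_vt0 = p_vv0 = h.prior_mean
        else:
            a = h.prior_mean * h.prior_concentration
            b = (1.0 - h.prior_mean) * h.prior_concentration
            p_vt0 = float(np.clip(rng.beta(a, b), 0.02, 0.98))
            p_vv0 = float(np.clip(rng.beta(a, b), 0.02, 0.98))
        priors = CausalPriors(
            p_vt0=p_vt0, p_vv0=p_vv0,
            w_prior_vt=h.w_prior, w_prior_vv=h.w_prior, gamma=h.gamma,
        )
        jitter = np.sort(rng.normal(0.0, h.threshold_jitter_sd, size=6))
        thresholds = np.asarray(h.threshold_grid) + jitter
        # jitter is sorted, so the grid stays strictly increasing as long as
        # grid spacing dominates; enforce monotonicity defensively
        thresholds = np.maximum.accumulate(thresholds + 1e-9 * np.arange(6))
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:03d}",
                noise=noise,
                priors=priors,
                likert_thresholds=tuple(thresholds),
                latent_slope=max(0.05, float(rng.normal(h.latent_slope_mean, h.latent_slope_sd))),
                latent_intercept=float(rng.normal(h.latent_intercept_mean, h.latent_intercept_sd)),
                vas_gain=max(0.1, float(rng.normal(h.vas_gain_mean, h.vas_gain_sd))),
                vas_offset=float(rng.normal(h.vas_offset_mean, h.vas_offset_sd)),
                random_intercept=float(rng.normal(0.0, h.random_intercept_sd)),
                scr_baseline=_lognormal(rng, h.scr_baseline_median, h.scr_baseline_sdlog),
                scr_attenuation=max(0.0, float(rng.normal(h.scr_attenuation_mean, h.scr_attenuation_sd))),
                scr_ownership_gain=max(0.0, float(rng.normal(h.scr_ownership_gain_mean, h.scr_ownership_gain_sd))),
                scr_noise_sd=_lognormal(rng, h.scr_noise_sd_median, h.scr_noise_sd_sdlog),
            )
        )
    return profiles


def latent_to_likert(
    latent: float,
    thresholds: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
) -> int:
    """Map a latent value to a -3..+3 rating through a cumulative-logit link.

    Adds logistic noise with scale ``noise_sd`` and bins by the six
    cutpoints, so the implied category probabilities are exactly
    ``P(Y <= k) = logistic((theta_k - latent) / noise_sd)`` — the
    generative counterpart of the cumulative link mixed model fitted
    downstream.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    y = latent if noise_sd == 0 else latent + rng.logistic(0.0, noise_sd)
    return int(np.searchsorted(thresholds, y, side="left")) - 3


def _clip_logit(p: float, cap: float = 8.0) -> float:
    p = min(max(p, expit(-cap)), expit(cap))
    return float(np.log(p / (1.0 - p)))


def _participant_estimates(profile: ParticipantProfile) -> Dict[str, "OwnershipEstimate"]:
    return predict_conditions(profile.noise, profile.priors)


def simulate_questionnaire(
    profiles: Sequence[ParticipantProfile],
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the long-format questionnaire table (participant x condition x statement).

    Latent scores: S1 follows the combined ownership estimate (logit
    scale), S2 the post-feedback visuo-vestibular posterior, S3 the
    visuo-tactile posterior; the control statements S4-S5 sit below the
    lowest cutpoint (participants reject made-up experiences), S6
    (dizziness) is condition-independent; S7 maps the latent
    self-motion signal onto the 0-10 VAS.  Condition presentation order
    is counterbalanced with a balanced Latin square and rows appear in
    presentation order.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    rng = substream(seed, "questionnaire")
    latin = [list(np.roll(CONDITION_KEYS, -k)) for k in range(4)]
    rows = []
    for pi, prof in enumerate(profiles):
        order = list(latin[pi % 4])
        ests = _participant_estimates(prof)
        for cond_key in order:
            est = ests[cond_key]
            cond = ConditionSpec(
                vt_sync=cond_key.endswith("SVT"), vv_sync=cond_key.startswith("SVV")
            )
            base = prof.latent_intercept + prof.random_intercept
            latents = {
                "S1": base + prof.latent_slope * _clip_logit(est.d_own),
                "S2": base + prof.latent_slope * _clip_logit(est.d_vv),
                "S3": base + prof.latent_slope * _clip_logit(est.d_vt),
                "S4": prof.likert_thresholds[0] - 1.5,
                "S5": prof.likert_thresholds[0] - 1.5,
                "S6": prof.likert_thresholds[1] - 0.5,
            }
            for st in ("S1", "S2", "S3", "S4", "S5", "S6"):
                value = latent_to_likert(
                    latents[st], prof.likert_thresholds, PopulationHyperparams().likert_noise_sd, rng
                )
                rows.append((prof.id, cond_key, st, float(value)))
            m = predict_self_motion(est, cond, SelfMotionCoeffs())
            vas = prof.vas_gain * m + prof.vas_offset + rng.normal(0.0, PopulationHyperparams().vas_noise_sd)
            rows.append((prof.id, cond_key, "S7", float(np.clip(vas, 0.0, 10.0))))
    return pd.DataFrame(rows, columns=["participant", "condition", "statement", "value"])


def simulate_scr(
    profiles: Sequence[ParticipantProfile],
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the long-format SCR trial table (participant x 16 trials).

    Each participant is assigned one of the four printed condition
    orders (counterbalanced) and runs it four times; the raw threat
    response decays exponentially over repetitions, scales with the
    ownership estimate of the trial's condition, and carries additive
    Gaussian noise floored at zero.  Threat identities 1..16 are a
    random permutation per participant.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    rng = substream(seed, "scr")
    rows = []
    for pi, prof in enumerate(profiles):
        order = design.scr_orders[pi % 4]
        ests = _participant_estimates(prof)
        threat_ids = rng.permutation(design.n_scr_trials) + 1
        for r in range(1, design.n_scr_trials + 1):
            cond_key = order[(r - 1) % 4]
            arousal = ests[cond_key].d_own ** SCR_OWNERSHIP_EXPONENT
            mean = (
                prof.scr_baseline
                * math.exp(-prof.scr_attenuation * (r - 1))
                * (1.0 + prof.scr_ownership_gain * arousal)
            )
            raw = max(0.0, mean + rng.normal(0.0, prof.scr_noise_sd))
            rows.append((prof.id, r, cond_key, int(threat_ids[r - 1]), float(raw), np.nan))
    return pd.DataFrame(
        rows, columns=["participant", "trial", "condition", "threat_id", "raw", "normalized"]
    )
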