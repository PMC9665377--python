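"""Shared fixtures: small synthetic datasets generated at collection time."""

import numpy as np
import pandas as pd
import pytest

from trisense.bci import CONDITION_KEYS
from trisense.synth import (
    PopulationHyperparams,
    StudyDesign,
    draw_profiles,
    latent_to_likert,
    simulate_questionnaire,
    simulate_scr,
)


@pytest.fixture(scope="session")
def default_profiles():
    return draw_profiles(20, seed=11)


@pytest.fixture(scope="session")
def questionnaire_small():
    """A 20-participant questionnaire table (fast, schema-complete)."""
    profiles = draw_profiles(20, seed=11)
    return simulate_questionnaire(profiles, StudyDesign(n_questionnaire=20), seed=11)


@pytest.fixture(scope="session")
def scr_small():
    """A 12-participant SCR table (fast, schema-complete)."""
    profiles = draw_profiles(12, seed=7)
    return simulate_scr(profiles, StudyDesign(n_scr=12), seed=7)


def make_ordinal_dataset(
    n_participants: int,
    beta_vt: float,
    beta_vv: float,
    random_sd: float,
    seed: int,
    thresholds=(-2.5, -1.5, -0.5, 0.5, 1.5, 2.5),
) -> pd.DataFrame:
    """Cumulative-logit generator with known truth, for recovery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_participants):
        u = rng.normal(0.0, random_sd) if random_sd > 0 else 0.0
        for c in CONDITION_KEYS:
            eta = beta_vt * c.endswith("SVT") + beta_vv * c.startswith("SVV") + u
            rows.append((f"P{s:03d}", c, "S1", float(latent_to_likert(eta, thresholds, 1.0, rng))))
    return pd.DataFrame(rows, columns=["participant", "condition", "statement", "value"])


def make_scr_dataset(
    n_participants: int,
    beta_vt: float,
    beta_vv: float,
    rep_slope: float,
    seed: int,
    noise_sd: float = 0.12,
    random_sd: float = 0.08,
    outlier_frac: float = 0.0,
) -> pd.DataFrame:
    """Gaussian LMM generator with known truth on the raw column."""
    from trisense.synth import DEFAULT_SCR_ORDERS

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_participants):
        u = rng.normal(0.0, random_sd)
        order = DEFAULT_SCR_ORDERS[s % 4]
        for r in range(1, 17):
            c = order[(r - 1) % 4]
            mu = 0.6 + u + rep_slope * r + beta_vt * c.endswith("SVT") + beta_vv * c.startswith("SVV")
            val = mu + rng.normal(0.0, noise_sd)
            if outlier_frac > 0 and rng.random() < outlier_frac:
                val *= 10.0
            rows.append((f"P{s:03d}", r, c, r, max(val, 0.0), np.nan))
    return pd.DataFrame(
        rows, columns=["participant", "trial", "condition", "threat_id", "raw", "normalized"]
    )
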