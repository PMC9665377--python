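"""Skin conductance response (SCR) preprocessing and modeling.

The threat-evoked SCR pipeline: classify null responses (< 0.01 mmho),
range-normalize within participant (divide by that participant's
strongest response), summarize per-condition magnitude (all trials) or
amplitude (elicited trials only), fit a linear mixed model of trial
magnitude on repetition and the two congruence factors (optionally
robust via Huber-weighted IRLS), and run the six planned pairwise
comparisons (five one-sided, one two-sided) with effect sizes and JZS
Bayes factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .stats import TestResult, paired_t

__all__ = [
    "NULL_THRESHOLD",
    "HUBER_C",
    "LmmFit",
    "classify_response",
    "range_normalize",
    "summarize",
    "fit_lmm",
    "planned_scr_comparisons",
    "analysis_variants",
]

NULL_THRESHOLD = 0.01  # mmho; below this a threat elicited no response
HUBER_C = 1.345        # Huber tuning constant on scaled residuals

#: Table of planned comparisons: (larger-hypothesized, smaller, tails),
#: in report row order.
PLANNED_COMPARISONS = (
    ("SVV_SVT", "AVV_SVT", 1),
    ("SVV_SVT", "SVV_AVT", 1),
    ("SVV_SVT", "AVV_AVT", 1),
    ("AVV_SVT", "AVV_AVT", 1),
    ("SVV_AVT", "AVV_AVT", 1),
    ("SVV_AVT", "AVV_SVT", 2),
)


@dataclass(frozen=True)
class LmmFit:
    """Linear mixed model estimates for the SCR magnitude analysis."""

    coefficients: Dict[str, float]
    tvalues: Dict[str, float]
    random_intercept_var: float
    residual_var: float
    robust: bool
    weight_summary: Dict[str, float]
    converged: bool
    n_obs: int
    n_groups: int
    loglik: float


def classify_response(raw: float) -> str:
    """Classify one raw SCR value as ``"null"`` (< 0.01 mmho) or ``"valid"``."""
    if raw < 0:
        raise ValueError(f"raw SCR must be >= 0, got {raw}")
    return "null" if raw < NULL_THRESHOLD else "valid"


def range_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``normalized`` by dividing raw by each participant's maximum.

    Participants whose every response is zero get 0 with a warning.
    Idempotent on the raw column: re-running produces the same values.
    """
    out = records.copy()
    maxima = out.groupby("participant")["raw"].transform("max")
    zero = maxima == 0
    if zero.any():
        warnings.warn(
            f"{out.loc[zero, 'participant'].nunique()} participant(s) with all-zero "
            "responses; normalized set to 0",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["normalized"] = np.where(zero, 0.0, out["raw"] / maxima.replace(0, np.nan))
    return out


def summarize(records: pd.DataFrame, mode: str = "magnitude", value_col: str = "normalized") -> pd.DataFrame:
    """Per participant x condition means.

    ``magnitude`` averages every trial (nulls included); ``amplitude``
    averages only trials where a response was elicited (> 0.01 mmho raw).
    Cells with no elicited trial come back as NaN in amplitude mode.
    """
    if mode not in ("magnitude", "amplitude"):
        raise ValueError("mode must be 'magnitude' or 'amplitude'")
    df = records
    if mode == "amplitude":
        df = df[df["raw"] > NULL_THRESHOLD]
    cells = (
        df.groupby(["participant", "condition"])[value_col]
        .mean()
        .unstack("condition")
    )
    # reindex so empty amplitude cells surface as NaN rather than vanishing
    cells = cells.reindex(index=records["participant"].unique())
    return cells


def _design(records: pd.DataFrame, value_col: str):
    vt = records["condition"].str.endswith("SVT").to_numpy(dtype=float)
    vv = records["condition"].str.startswith("SVV").to_numpy(dtype=float)
    rep = records["trial"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(records)), rep, vt, vv, vt * vv])
    names = ["intercept", "repetition", "vt_sync", "vv_sync", "vt_sync:vv_sync"]
    y = records[value_col].to_numpy(dtype=float)
    groups = records["participant"].to_numpy()
    return y, X, names, groups


def fit_lmm(records: pd.DataFrame, robust: bool = True, value_col: str = "normalized") -> LmmFit:
    """Mixed model of trial SCR on repetition + congruence with random intercepts.

    ML fit via profiled variance components.  With ``robust=True`` the
    fit is wrapped in iteratively reweighted estimation: Huber weights
    (c = 1.345) on residuals scaled by the MAD, entering the refit by
    scaling the response, design and random-intercept columns by
    sqrt(w), iterated until the weights stabilize (max change < 1e-6).
    """
    if records["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    y, X, names, groups = _design(records, value_col)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    n = len(y)
    w = np.ones(n)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(50 if robust else 1):
            sw = np.sqrt(w)
            model = MixedLM(y * sw, X * sw[:, None], groups=groups, exog_re=sw[:, None])
            try:
                res = model.fit(reml=False)
                if not res.converged:
                    alt = model.fit(reml=False, method="powell")
                    if alt.converged and alt.llf >= res.llf:
                        res = alt
            except np.linalg.LinAlgError:
                # singular observed information (variance component on the
                # boundary); Powell avoids the failing curvature-based step
                res = model.fit(reml=False, method="powell")
            if not robust:
                break
            # observation-level residuals including the BLUP of the random intercept
            re = res.random_effects
            u = np.array([float(np.asarray(re[g]).ravel()[0]) for g in groups])
            resid = y - X @ res.fe_params - u
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            scale = max(scale, 1e-12)
            r = np.abs(resid / scale)
            w_new = np.minimum(1.0, HUBER_C / np.maximum(r, 1e-12))
            if np.max(np.abs(w_new - w)) < 1e-6:
                w = w_new
                break
            w = w_new
    coefs = dict(zip(names, (float(b) for b in res.fe_params)))
    tvals = dict(zip(names, (float(t) for t in res.tvalues[: len(names)])))
    wsum = {
        "min": float(w.min()),
        "mean": float(w.mean()),
        "frac_downweighted": float((w < 1.0).mean()),
    }
    if not robust:
        wsum = {"min": 1.0, "mean": 1.0, "frac_downweighted": 0.0}
    return LmmFit(
        coefficients=coefs,
        tvalues=tvals,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        robust=robust,
        weight_summary=wsum,
        converged=bool(res.converged),
        n_obs=n,
        n_groups=int(records["participant"].nunique()),
        loglik=float(res.llf),
    )


def planned_scr_comparisons(cell_means: pd.DataFrame) -> pd.DataFrame:
    """The six planned pairwise tests on participant x condition means.

    Five one-sided contrasts test that each partly or fully synchronous
    condition exceeds its comparison condition; the sixth contrast
    (SVV_AVT vs AVV_SVT) is two-sided.  Each row reports the paired t,
    p, Cohen's d_z and the JZS Bayes factor.
    """
    missing = cell_means.isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"missing condition cells for participants {list(cell_means.index[missing])[:5]}"
        )
    rows = []
    for first, second, tails in PLANNED_COMPARISONS:
        res = paired_t(cell_means[first], cell_means[second], tails=tails)
        label = f"{first} {'>' if tails == 1 else '!='} {second}"
        rows.append(
            {
                "comparison": label,
                "t": res.statistic,
                "p": res.p,
                "tails": tails,
                "bf10": res.bf10,
                "d_z": res.effect_size,
            }
        )
    return pd.DataFrame(rows)


def analysis_variants(
    records: pd.DataFrame,
    normalize: bool = True,
    exclude_null_responders: bool = False,
    null_responder_median: float = 0.02,
    robust: bool = True,
) -> Tuple[LmmFit, pd.DataFrame]:
    """Run the SCR pipeline under the requested preprocessing variant.

    ``exclude_null_responders`` drops participants whose median raw
    response falls below ``null_responder_median`` (mmho) — the
    configurable stand-in for "very weak SCR amplitudes".
    """
    df = records.copy()
    if exclude_null_responders:
        med = df.groupby("participant")["raw"].median()
        keep = med[med >= null_responder_median].index
        if len(keep) == 0:
            raise ValueError("null-responder exclusion removed every participant")
        df = df[df["participant"].isin(keep)]
    df = range_normalize(df)
    value_col = "normalized" if normalize else "raw"
    fit = fit_lmm(df, robust=robust, value_col=value_col)
    cells = summarize(df, mode="magnitude", value_col=value_col)
    report = planned_scr_comparisons(cells)
    return fit, report
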