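"""Population summaries, marginal effects, and weather-sensitivity classification.

Population level: posterior mean and equal-tailed credible interval per
weather coefficient, plus the marginal effect at the mean (MEM) — the
change in P(pain >= moderate) for a one-scaled-unit increase of a weather
variable with every other variable at its mean and random effects at zero
(the population-typical participant).

Participant level: each participant's total weather slope gamma_k + b_ik
is summarized by an equal-tailed credible interval whose sign pattern
defines the sensitivity label — entirely positive -> high-value sensitive,
entirely negative -> low-value sensitive, straddling zero -> undetermined.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import ConfigurationError, DataError
from .probit import WEATHER_LABELS
from .sampler import PosteriorDraws

logger = logging.getLogger(__name__)

LOW = "low-value-sensitive"
HIGH = "high-value-sensitive"
UNDET = "undetermined"

#: single-diagnosis grouping used in the breakdown
DIAGNOSIS_GROUPS = {
    "osteoarthritis": "osteoarthritis",
    "fibromyalgia/CWP": "fibromyalgia/CWP",
    "rheumatoid-arthritis": "inflammatory arthritic pain",
    "ankylosing-spondylitis/spondyloarthropathy": "inflammatory arthritic pain",
    "arthritis-unspecified": "other chronic pain",
    "neuropathic": "other chronic pain",
    "chronic-headache": "other chronic pain",
    "gout": "other chronic pain",
    "other/none": "other chronic pain",
}


def _eqt_interval(draws: np.ndarray, level: float, axis=0):
    lo = (1 - level) / 2
    return (np.quantile(draws, lo, axis=axis),
            np.quantile(draws, 1 - lo, axis=axis))


def population_summary(draws: PosteriorDraws, cri_level: float = 0.95,
                       analysis_table: pd.DataFrame | None = None,
                       mem_threshold: int = 3) -> pd.DataFrame:
    """Coefficient-table summary: posterior mean, equal-tailed CrI, MEM
    per weather parameter (draws pooled across chains)."""
    rows = []
    for k, col in enumerate(draws.weather_cols):
        g = draws.pooled("gamma")[:, k]
        lo, hi = _eqt_interval(g, cri_level)
        mem = marginal_effect_at_mean(draws, col, threshold=mem_threshold)
        rows.append({
            "parameter": WEATHER_LABELS.get(col, col),
            "column": col,
            "estimate": float(g.mean()),
            "cri_lower": float(lo),
            "cri_upper": float(hi),
            "mem": mem["value"],
        })
    return pd.DataFrame(rows)


def marginal_effect_at_mean(draws: PosteriorDraws, parameter: str,
                            threshold: int = 3, delta: float = 1.0,
                            average: str = "draws") -> dict:
    """MEM: change in P(Y >= threshold) per ``delta`` scaled units.

    Covariates are centered in the design and the spline basis carries no
    intercept, so the latent mean of the population-typical participant is
    zero; the MEM per posterior draw is
    ``Phi(eta0 + gamma_k * delta - tau_{thr-1}) - Phi(eta0 - tau_{thr-1})``
    with eta0 = 0, averaged over draws (or evaluated at posterior means
    when ``average='posterior-mean'``).
    """
    if threshold not in (2, 3, 4, 5):
        raise ConfigurationError(f"threshold must be in 2..5, got {threshold}")
    if parameter not in draws.weather_cols:
        raise ConfigurationError(f"unknown weather parameter {parameter!r}")
    k = draws.weather_cols.index(parameter)
    g = draws.pooled("gamma")[:, k]
    tau_thr = draws.pooled("tau")[:, threshold - 2]
    if average == "posterior-mean":
        g = np.array([g.mean()])
        tau_thr = np.array([tau_thr.mean()])
    elif average != "draws":
        raise ConfigurationError(f"unknown average mode {average!r}")
    per_draw = ndtr(g * delta - tau_thr) - ndtr(-tau_thr)
    return {"parameter": parameter, "threshold": threshold, "delta": delta,
            "value": float(per_draw.mean())}


def classify_participants(draws: PosteriorDraws, cri_level: float = 0.95) -> pd.DataFrame:
    """Sensitivity label per participant x weather parameter.

    The equal-tailed ``cri_level`` interval of the participant's total slope
    gamma_k + b_ik determines the label: entirely above zero ->
    high-value-sensitive, entirely below -> low-value-sensitive, otherwise
    undetermined.
    """
    frames = []
    for k, col in enumerate(draws.weather_cols):
        total = draws.total_slopes(k)          # (draws, N)
        lo, hi = _eqt_interval(total, cri_level, axis=0)
        med = np.median(total, axis=0)
        label = np.where(lo > 0, HIGH, np.where(hi < 0, LOW, UNDET))
        frames.append(pd.DataFrame({
            "participant_id": draws.participant_ids,
            "parameter": col, "lower": lo, "median": med, "upper": hi,
            "label": label,
        }))
    return pd.concat(frames, ignore_index=True)


def label_interval(lower: float, upper: float) -> str:
    """Label from an interval's sign pattern (the classification rule itself)."""
    if lower > 0:
        return HIGH
    if upper < 0:
        return LOW
    return UNDET


def sensitivity_profile(labels: pd.DataFrame) -> dict:
    """Per-parameter cluster proportions and the multi-parameter count
    histogram among weather-sensitive participants."""
    dup = labels.duplicated(subset=["participant_id", "parameter"])
    if dup.any():
        raise DataError("duplicate (participant, parameter) labels")

    prop = (labels.groupby("parameter")["label"]
            .value_counts(normalize=True).unstack(fill_value=0.0)
            .reindex(columns=[LOW, HIGH, UNDET], fill_value=0.0))

    sens = labels[labels["label"] != UNDET]
    counts = sens.groupby("participant_id").size()
    hist = counts.value_counts().sort_index()
    n_sens = len(counts)
    single_frac = float(hist.get(1, 0) / n_sens) if n_sens else float("nan")
    return {"proportions": prop, "n_sensitive": n_sens,
            "multi_parameter_histogram": hist,
            "single_parameter_fraction": single_frac}


def diagnosis_breakdown(labels: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Cluster prevalence per diagnosis group, single-diagnosis participants only.

    Diagnoses are mapped to {osteoarthritis, fibromyalgia/CWP, inflammatory
    arthritic pain, other chronic pain}; participants reporting more than
    one condition are excluded.
    """
    base = baselines.copy()
    diag_lists = base["diagnoses"].fillna("").str.split(";")
    single = diag_lists.str.len() == 1
    base = base[single]
    diag = diag_lists[single].str[0]

    def to_group(d: str) -> str:
        if d not in DIAGNOSIS_GROUPS:
            logger.warning("unknown diagnosis label %r mapped to 'other chronic pain'", d)
            return "other chronic pain"
        return DIAGNOSIS_GROUPS[d]

    base = base.assign(group=diag.map(to_group))
    merged = labels.merge(base[["participant_id", "group"]], on="participant_id",
                          how="inner")
    rows = []
    for (group, param), sub in merged.groupby(["group", "parameter"]):
        n = sub["participant_id"].nunique()
        rows.append({
            "group": group, "parameter": param, "n": n,
            "low_sensitive": float((sub["label"] == LOW).mean()),
            "high_sensitive": float((sub["label"] == HIGH).mean()),
        })
    return pd.DataFrame(rows)


def forest_plot_data(labels: pd.DataFrame, summary: pd.DataFrame,
                     parameter: str) -> dict:
    """Per-participant intervals sorted by posterior median, with the
    population posterior mean as the reference line."""
    sub = (labels[labels["parameter"] == parameter]
           .sort_values("median", kind="mergesort").reset_index(drop=True))
    ref_rows = summary[summary["column"] == parameter]
    if ref_rows.empty:
        raise ConfigurationError(f"no population summary for {parameter!r}")
    return {"parameter": parameter, "rows": sub,
            "reference": float(ref_rows["estimate"].iloc[0])}
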