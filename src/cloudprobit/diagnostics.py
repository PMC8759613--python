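"""Convergence diagnostics and posterior predictive checks."""

from __future__ import annotations

import logging

import arviz as az
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .probit import Design
from .sampler import PosteriorDraws

logger = logging.getLogger(__name__)

RHAT_GATE = 1.05


def rhat(draws_per_chain: np.ndarray) -> float:
    """Rank-normalized split R-hat for one scalar parameter.

    ``draws_per_chain`` has shape (chains, draws) with >= 2 chains and
    >= 10 draws each.  Constant chains yield NaN (a "not computable" flag)
    rather than an error.
    """
    arr = np.asarray(draws_per_chain, dtype=float)
    if arr.ndim != 2:
        raise ConfigurationError("expected a (chains, draws) array")
    if arr.shape[0] < 2:
        raise ConfigurationError("R-hat needs at least 2 chains")
    if arr.shape[1] < 10:
        raise ConfigurationError("R-hat needs at least 10 draws per chain")
    if np.allclose(arr, arr.flat[0]):
        return float("nan")
    return float(az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr))["x"].values)


def ess(draws_per_chain: np.ndarray) -> float:
    """Bulk effective sample size for one scalar parameter."""
    arr = np.asarray(draws_per_chain, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ConfigurationError("expected a (chains, draws) array")
    return float(az.ess(az.convert_to_dataset(arr))["x"].values)


def convergence_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """R-hat and ESS for every population-level scalar (coefficients,
    cutpoints, random-effect variances)."""
    rows = []
    for name, arr in draws.population_dict().items():
        rows.append({"parameter": name, "rhat": rhat(arr), "ess_bulk": ess(arr),
                     "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))})
    df = pd.DataFrame(rows)
    worst = df["rhat"].max()
    if worst >= RHAT_GATE:
        logger.warning("convergence gate: max population R-hat %.3f >= %.2f", worst, RHAT_GATE)
    return df


def posterior_predictive_check(draws: PosteriorDraws, design: Design, rng,
                               n_rep: int = 200) -> dict:
    """Observed vs replicated pain-category frequencies.

    For a thinned subset of kept draws, a full replicate dataset is simulated
    from the model at that draw (same design, same participants, drawn
    random effects) and its 5-category frequency distribution recorded.

    Returns a dict with ``observed`` (5,), ``replicates`` (n_rep, 5) and
    ``interval`` (2, 5) — the central 95% predictive band per category.
    """
    total = draws.n_chains * draws.n_draws
    idx = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    beta = draws.pooled("beta")[idx]
    gamma = draws.pooled("gamma")[idx]
    spl = draws.pooled("spline")[idx]
    tau = draws.pooled("tau")[idx]
    b = draws.pooled("b")[idx] if draws.b is not None else None

    M = design.n_obs
    freqs = np.empty((len(idx), 5))
    for r in range(len(idx)):
        theta = np.concatenate([beta[r], gamma[r], spl[r]])
        eta = design.F @ theta
        if b is not None:
            eta = eta + np.einsum("mq,mq->m", design.R, b[r][design.group_idx])
        z = eta + rng.standard_normal(M)
        y_rep = np.searchsorted(tau[r], z) + 1
        freqs[r] = np.bincount(y_rep, minlength=6)[1:6] / M

    observed = np.bincount(design.y, minlength=6)[1:6] / M
    interval = np.percentile(freqs, [2.5, 97.5], axis=0)
    return {"observed": observed, "replicates": freqs, "interval": interval}
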