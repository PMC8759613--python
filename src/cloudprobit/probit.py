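"""Cumulative-probit model core: design assembly, likelihood, priors.

The model
---------
Each participant-day carries an ordinal pain report ``y in {1..5}``.  A
standard-normal latent utility

    z_ij = x_ij' beta + w_ij' (gamma + u_i) + u_i0 + B(t_ij)' s + eps_ij

crossed with strictly ordered cutpoints tau_1 < ... < tau_4 generates the
observed category: ``y = c  iff  tau_{c-1} < z <= tau_c`` (tau_0 = -inf,
tau_5 = +inf).  ``w_ij`` holds the four scaled daily weather exposures
(temperature per 1 degC, pressure per 10 mbar, relative humidity per 10
percentage points, wind per 1 m/s); ``gamma`` is the population weather
effect and ``u_i`` a participant's 5-vector of correlated random effects
(intercept + 4 weather slopes) with covariance Sigma.  ``B(t)`` is a
natural cubic spline in days since study entry.

Identification: no global intercept, 4 free ordered cutpoints, latent
residual variance fixed at 1.  "Noninformative" priors are concretized as
normal(0, prior_sd^2) on every regression and spline coefficient, a flat
prior on the ordered cutpoints, and inverse-Wishart(iw_df, iw_scale * I_5)
on Sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, log_ndtr, roots_hermite
from scipy.stats import norm

from .exceptions import ConfigurationError, DataError
from .splines import SplineBasis, spline_basis

WEATHER_COLS = ["x_temp", "x_press", "x_hum", "x_wind"]
WEATHER_LABELS = {
    "x_temp": "Temperature (per 1°C)",
    "x_press": "Pressure (per 10 mbar)",
    "x_hum": "Relative humidity (per 10%)",
    "x_wind": "Wind speed (per 1 m·s⁻¹)",
}
DEFAULT_COVARIATE_COLS = ["age", "sex_indicator", "belief", "mood", "exercise"]


@dataclass
class ModelSpec:
    """Model structure and prior configuration.

    Parameters
    ----------
    covariate_cols : fixed-effect adjustment columns (linear by default).
    weather_cols : the four scaled weather exposures carrying random slopes.
    spline_df : columns of the natural cubic spline in time-since-entry.
    prior_sd : normal prior standard deviation for every fixed/spline
        coefficient (latent scale; 10 is vague relative to unit residual sd).
    iw_df, iw_scale : inverse-Wishart prior on the 5x5 random-effect
        covariance — degrees of freedom and scalar multiplier of I_5.
    cri_level : credible-interval mass used in summaries.
    random_effects : disable to fit a plain fixed-effects cumulative probit.
    ordinal_covariates_as_indicators : expand mood/exercise into category
        indicator columns instead of entering them as linear scores.
    """

    covariate_cols: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATE_COLS))
    weather_cols: list[str] = field(default_factory=lambda: list(WEATHER_COLS))
    spline_df: int = 5
    prior_sd: float = 10.0
    iw_df: float = 7.0
    iw_scale: float = 1.0
    cri_level: float = 0.95
    random_effects: bool = True
    ordinal_covariates_as_indicators: bool = False

    def __post_init__(self):
        if self.spline_df < 3:
            raise ConfigurationError("spline_df must be >= 3")
        if self.prior_sd <= 0:
            raise ConfigurationError("prior_sd must be positive")
        n_re = 1 + len(self.weather_cols)
        if self.iw_df <= n_re + 1:
            raise ConfigurationError(
                f"iw_df must exceed {n_re + 1} for a proper inverse-Wishart prior")
        if not 0 < self.cri_level < 1:
            raise ConfigurationError("cri_level must lie in (0, 1)")


@dataclass
class Design:
    """Assembled numeric design for the sampler.

    Rows are sorted by (participant, t).  ``F`` stacks centered covariates,
    weather exposures and the centered spline columns; ``R`` is the
    per-row random-effect design ``[1, w_ij]``.
    """

    F: np.ndarray                # (M, p) full fixed design
    R: np.ndarray                # (M, q) random-effect design, q = 1 + n_weather
    y: np.ndarray                # (M,) int categories 1..5
    group_idx: np.ndarray        # (M,) participant index 0..N-1
    group_starts: np.ndarray     # (N,) start row of each participant block
    participant_ids: list        # length N
    col_names: list[str]         # length p
    beta_slice: slice
    gamma_slice: slice
    spline_slice: slice
    covariate_means: dict[str, float]
    spline: SplineBasis
    t: np.ndarray                # (M,) days since entry
    #: beta-column index -> per-participant value, for covariates constant
    #: within participant (used by the sampler's translation moves)
    between_covariates: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_coef(self) -> int:
        return self.F.shape[1]


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Turn an assembled analysis table into sampler-ready arrays.

    Covariate columns are centered at their table means (a pure
    reparameterization: slopes are unchanged, cutpoints are defined at
    covariate means, and the sampler mixes far better without the
    cutpoint/covariate-location ridge).
    """
    required = {"participant_id", "t", "y", *spec.covariate_cols, *spec.weather_cols}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"analysis table is missing columns: {sorted(missing)}")

    df = table.sort_values(["participant_id", "t"], kind="mergesort").reset_index(drop=True)
    y = df["y"].to_numpy(dtype=int)
    if y.size == 0:
        raise DataError("analysis table is empty")
    if y.min() < 1 or y.max() > 5:
        raise DataError("pain categories must lie in 1..5")

    pids, group_idx = np.unique(df["participant_id"].to_numpy(), return_inverse=True)
    order_ok = np.all(np.diff(group_idx) >= 0)
    if not order_ok:  # np.unique sorts, and df is sorted by participant_id
        raise DataError("internal ordering error in design assembly")
    group_starts = np.searchsorted(group_idx, np.arange(len(pids)))

    cov_blocks, cov_names, cov_means = [], [], {}
    for col in spec.covariate_cols:
        vals = df[col].to_numpy(dtype=float)
        if spec.ordinal_covariates_as_indicators and col in ("mood", "exercise"):
            cats = np.unique(vals)
            for c in cats[1:]:  # first category is the reference
                ind = (vals == c).astype(float)
                m = ind.mean()
                cov_blocks.append(ind - m)
                cov_names.append(f"{col}=={int(c)}")
                cov_means[f"{col}=={int(c)}"] = float(m)
        else:
            m = vals.mean()
            cov_blocks.append(vals - m)
            cov_names.append(col)
            cov_means[col] = float(m)

    W = df[spec.weather_cols].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    B, sb = spline_basis(t, df=spec.spline_df)

    F = np.column_stack(cov_blocks + [W, B])
    n_cov = len(cov_names)
    n_w = len(spec.weather_cols)
    col_names = (cov_names + list(spec.weather_cols)
                 + [f"spline_{k + 1}" for k in range(B.shape[1])])

    _check_rank(F, col_names)

    # covariates constant within every participant (age, sex, belief ...)
    between: dict[int, np.ndarray] = {}
    group_sizes = np.diff(np.append(group_starts, len(df)))
    for j in range(n_cov):
        col = F[:, j]
        per_group_first = col[group_starts]
        if np.array_equal(np.repeat(per_group_first, group_sizes), col):
            between[j] = per_group_first

    R = np.column_stack([np.ones(len(df)), W])
    return Design(
        F=F, R=R, y=y, group_idx=group_idx, group_starts=group_starts,
        participant_ids=list(pids), col_names=col_names,
        beta_slice=slice(0, n_cov),
        gamma_slice=slice(n_cov, n_cov + n_w),
        spline_slice=slice(n_cov + n_w, n_cov + n_w + B.shape[1]),
        covariate_means=cov_means, spline=sb, t=t,
        between_covariates=between,
    )


def _check_rank(F: np.ndarray, col_names: list[str]) -> None:
    scale = np.linalg.norm(F, axis=0)
    scale[scale == 0] = 1.0
    sv = np.linalg.svd(F / scale, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        _, _, vt = np.linalg.svd(F / scale)
        null = np.abs(vt[-1])
        bad = [c for c, w in zip(col_names, null) if w > 0.3]
        raise DataError(f"design matrix is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# likelihood pieces


def _validate_tau(tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 1 or np.any(np.diff(tau) <= 0):
        raise ConfigurationError(f"cutpoints must be strictly increasing, got {tau}")
    return tau


def category_probs(eta, tau) -> np.ndarray:
    """P(Y = c | eta, tau) for c = 1..K+1 under the cumulative probit link.

    ``p_c = Phi(tau_c - eta) - Phi(tau_{c-1} - eta)`` with tau_0 = -inf and
    tau_{K+1} = +inf.  ``eta`` may be scalar or an array; the result gains a
    trailing axis of length K+1 and rows sum to 1.
    """
    tau = _validate_tau(tau)
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    cum = ndtr(tau[None, :] - eta_arr[:, None])
    p = np.diff(np.concatenate(
        [np.zeros((eta_arr.size, 1)), cum, np.ones((eta_arr.size, 1))], axis=1), axis=1)
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(eta) or np.asarray(eta).ndim == 0:
        return p[0]
    return p.reshape(*np.asarray(eta).shape, tau.size + 1)


def ordinal_loglik(y: np.ndarray, eta: np.ndarray, tau: np.ndarray) -> float:
    """Sum of log category probabilities, numerically stable in both tails."""
    tau = _validate_tau(tau)
    tau_ext = np.concatenate([[-np.inf], tau, [np.inf]])
    upper = tau_ext[y] - eta
    lower = tau_ext[y - 1] - eta
    # reflect when the interval sits in the far right tail (relative precision)
    p = np.where(lower > 0,
                 ndtr(-lower) - ndtr(-upper),
                 ndtr(upper) - ndtr(lower))
    return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def linear_predictor(design: Design, theta: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """eta_ij = F theta + R b_i (b may be None for fixed-effects-only)."""
    eta = design.F @ theta
    if b is not None:
        eta = eta + np.einsum("mq,mq->m", design.R, b[design.group_idx])
    return eta


@dataclass
class ModelParameters:
    """A single point in parameter space (used for likelihood evaluation and truth storage)."""

    beta: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    spline: np.ndarray
    b: np.ndarray | None      # (N, 1 + n_weather) or None
    Sigma: np.ndarray | None

    def __post_init__(self):
        _validate_tau(self.tau)
        if self.Sigma is not None:
            S = np.asarray(self.Sigma, float)
            if not np.allclose(S, S.T) or np.any(np.linalg.eigvalsh(S) <= 0):
                raise ConfigurationError("Sigma must be symmetric positive definite")

    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma, self.spline])

    def to_json(self) -> str:
        d = {k: (np.asarray(v).tolist() if v is not None else None)
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        d = json.loads(text)
        return cls(**{k: (np.asarray(v, float) if v is not None else None)
                      for k, v in d.items()})


def log_likelihood(params: ModelParameters, design: Design) -> float:
    """Conditional log-likelihood given the random effects (no integration).

    Sums log P(y_ij | eta_ij, tau) over all rows, with
    eta_ij = F theta + b_i0 + w_ij' b_i,slopes.
    """
    eta = linear_predictor(design, params.theta(), params.b)
    return ordinal_loglik(design.y, eta, params.tau)


def marginal_log_likelihood_1p(eta_fixed: np.ndarray, y: np.ndarray, tau: np.ndarray,
                               intercept_sd: float, quadrature_order: int = 40) -> float:
    """Marginal log-likelihood of one participant's rows, random intercept only.

    Integrates ``b0 ~ N(0, intercept_sd^2)`` out of the conditional ordinal
    likelihood by Gauss–Hermite quadrature.  Serves as an independent check
    on the hierarchical structure; not used by the sampler.
    """
    if quadrature_order < 5:
        raise ConfigurationError("quadrature order must be >= 5")
    tau = _validate_tau(tau)
    if intercept_sd < 0:
        raise ConfigurationError("intercept_sd must be non-negative")
    y = np.asarray(y, int)
    eta_fixed = np.asarray(eta_fixed, float)
    if intercept_sd == 0:
        return ordinal_loglik(y, eta_fixed, tau)
    nodes, weights = roots_hermite(quadrature_order)
    b_vals = np.sqrt(2.0) * intercept_sd * nodes
    tau_ext = np.concatenate([[-np.inf], tau, [np.inf]])
    # (Q, n) matrix of per-row log-probs at each node
    upper = tau_ext[y][None, :] - (eta_fixed[None, :] + b_vals[:, None])
    lower = tau_ext[y - 1][None, :] - (eta_fixed[None, :] + b_vals[:, None])
    p = np.clip(ndtr(upper) - ndtr(lower), 1e-300, None)
    log_joint = np.sum(np.log(p), axis=1) + np.log(weights / np.sqrt(np.pi))
    m = log_joint.max()
    return float(m + np.log(np.sum(np.exp(log_joint - m))))
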