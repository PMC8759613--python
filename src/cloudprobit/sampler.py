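"""Data-augmentation Gibbs sampler for the multilevel cumulative probit model.

One iteration cycles through:

1. ordered-cutpoint update by random-walk Metropolis on (tau_1, log-gaps)
   with the latent utilities marginalized out (partially collapsed; the
   utilities are redrawn immediately afterwards, so the joint chain is
   invariant) — the proposal scale adapts during warmup to a 20–50%
   acceptance rate;
2. latent utilities ``z_ij`` from normals truncated to the category interval
   (Albert–Chib augmentation);
3. all fixed and spline coefficients jointly from their conjugate normal
   full conditional (the Cholesky factor of the posterior precision is
   precomputed once — the fixed design never changes);
4. each participant's random-effect vector from its conjugate normal full
   conditional (batched 5x5 Cholesky solves);
5. the random-effect covariance from its inverse-Wishart full conditional.

Chains use independent ``numpy`` Philox-family streams derived from
``(seed, chain_index)``; runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .exceptions import ConfigurationError, DataError
from .probit import Design, ModelSpec, ordinal_loglik, build_design

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# truncated normal


def truncated_normal_draw(lower, upper, mean, sd, rng) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to (lower, upper), vectorized.

    Inverse-CDF sampling with tail reflection: when the interval lies in a
    Gaussian tail the computation is carried out on the survival-function
    side, which keeps full relative precision for truncations many standard
    deviations from the mean (stable well beyond 6 sd).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ConfigurationError("sd must be positive")
    if np.any(lower >= upper):
        raise ConfigurationError("lower bound must be strictly below upper bound")

    shape = np.broadcast_shapes(lower.shape, upper.shape, mean.shape, sd.shape)
    a = np.broadcast_to((lower - mean) / sd, shape).copy()
    b = np.broadcast_to((upper - mean) / sd, shape).copy()
    u = rng.uniform(size=shape)

    # reflect intervals in the right tail onto the left tail
    flip = a > 0
    a_f = np.where(flip, -b, a)
    b_f = np.where(flip, -a, b)

    Fa = ndtr(a_f)
    Fb = ndtr(b_f)
    p = Fa + u * (Fb - Fa)
    x = ndtri(np.clip(p, 1e-300, 1 - 1e-16))
    x = np.where(flip, -x, x)
    # numerical guard: the clip above can land exactly on a bound
    x = np.clip(x, (lower - mean) / sd, (upper - mean) / sd)
    out = mean + sd * x
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# configuration and draws container


@dataclass
class SamplerConfig:
    """Gibbs sampler run configuration."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_keep: int = 1000
    thin: int = 1
    seed: int = 0
    cutpoint_proposal_sd: float = 0.05
    n_cutpoint_steps: int = 3              # collapsed MH sub-steps per iteration
    init_strategy: str = "data-informed"   # or "prior-draw"
    prior_only: bool = False               # likelihood switched off (prior checks)

    def __post_init__(self):
        if self.n_keep < 1:
            raise ConfigurationError("n_keep must be >= 1")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if self.n_warmup < 0:
            raise ConfigurationError("n_warmup must be >= 0")
        if self.init_strategy not in ("data-informed", "prior-draw"):
            raise ConfigurationError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class PosteriorDraws:
    """Kept MCMC draws, shaped (chains, draws, ...)."""

    beta: np.ndarray            # (C, K, p_beta)
    gamma: np.ndarray           # (C, K, n_weather)
    tau: np.ndarray             # (C, K, 4)
    spline: np.ndarray          # (C, K, df)
    b: np.ndarray | None        # (C, K, N, q) or None
    Sigma: np.ndarray | None    # (C, K, q, q) or None
    participant_ids: list
    col_names: list[str]
    weather_cols: list[str]
    covariate_means: dict[str, float]
    tau_acceptance: np.ndarray  # (C,)

    @property
    def n_chains(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one block pooled across chains, shape (C*K, ...)."""
        arr = getattr(self, name)
        if arr is None:
            raise DataError(f"no draws stored for {name!r}")
        return arr.reshape(-1, *arr.shape[2:])

    def total_slopes(self, k: int) -> np.ndarray:
        """Pooled draws of gamma_k + b_{i,k} for every participant, shape (C*K, N)."""
        if self.b is None:
            raise DataError("random effects were disabled; no participant slopes")
        g = self.pooled("gamma")[:, k]
        return g[:, None] + self.pooled("b")[:, :, k + 1]

    def population_dict(self) -> dict[str, np.ndarray]:
        """Population-level blocks (chains, draws) per scalar, for diagnostics."""
        full = np.concatenate([self.beta, self.gamma, self.spline], axis=2)
        out = {name: full[:, :, i] for i, name in enumerate(self.col_names)}
        for c in range(self.tau.shape[2]):
            out[f"tau_{c + 1}"] = self.tau[:, :, c]
        if self.Sigma is not None:
            for q in range(self.Sigma.shape[2]):
                out[f"Sigma_{q}{q}"] = self.Sigma[:, :, q, q]
        return out

    def save(self, path) -> None:
        import json, pathlib
        path = pathlib.Path(path)
        arrays = {k: getattr(self, k) for k in
                  ("beta", "gamma", "tau", "spline", "b", "Sigma", "tau_acceptance")
                  if getattr(self, k) is not None}
        np.savez_compressed(path, **arrays)
        meta = {
            "participant_ids": [str(p) for p in self.participant_ids],
            "col_names": self.col_names,
            "weather_cols": self.weather_cols,
            "covariate_means": self.covariate_means,
            "has_b": self.b is not None,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import json, pathlib
        path = pathlib.Path(path)
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            beta=arrays["beta"], gamma=arrays["gamma"], tau=arrays["tau"],
            spline=arrays["spline"], b=arrays.get("b"), Sigma=arrays.get("Sigma"),
            participant_ids=meta["participant_ids"], col_names=meta["col_names"],
            weather_cols=meta["weather_cols"], covariate_means=meta["covariate_means"],
            tau_acceptance=arrays["tau_acceptance"],
        )


# ---------------------------------------------------------------------------
# the sampler


def _init_tau(design: Design, strategy: str, rng) -> np.ndarray:
    if strategy == "prior-draw":
        return np.sort(rng.normal(0, 1, size=4))
    freq = np.bincount(design.y, minlength=6)[1:6].astype(float)
    cum = np.cumsum(freq)[:4] / freq.sum()
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    tau = ndtri(cum)
    # enforce strict ordering in degenerate cases (e.g. empty categories)
    for c in range(1, 4):
        if tau[c] <= tau[c - 1]:
            tau[c] = tau[c - 1] + 1e-3
    return tau


def run_sampler(analysis_table, model_spec: ModelSpec, sampler_config: SamplerConfig,
                design: Design | None = None) -> PosteriorDraws:
    """Fit the multilevel cumulative probit model by Gibbs sampling.

    Parameters
    ----------
    analysis_table : assembled analysis table (one row per participant-day);
        ignored when an explicit ``design`` is supplied.
    model_spec : model structure and priors.
    sampler_config : chains, iterations, seed.

    Returns
    -------
    PosteriorDraws with kept draws of every parameter block (including
    per-participant random effects when enabled).
    """
    if design is None:
        design = build_design(analysis_table, model_spec)
    cfg = sampler_config
    spec = model_spec

    q = 1 + len(spec.weather_cols)
    N, M, p = design.n_participants, design.n_obs, design.n_coef
    F, R, y = design.F, design.R, design.y
    gidx, starts = design.group_idx, design.group_starts
    tau_ext_idx_up = y          # tau_ext[y]
    tau_ext_idx_lo = y - 1

    # fixed-coefficient full-conditional pieces (design never changes)
    A = F.T @ F + np.eye(p) / spec.prior_sd ** 2
    chol_A = cho_factor(A, lower=False)
    U = np.linalg.cholesky(A).T    # A = U' U with U upper triangular

    # per-participant R_i' R_i blocks
    RtR = np.add.reduceat(np.einsum("mi,mj->mij", R, R), starts, axis=0)

    iw_scale_mat = spec.iw_scale * np.eye(q)

    chains = {k: [] for k in ("beta", "gamma", "tau", "spline", "b", "Sigma")}
    acc_rates = []

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, chain])
        theta = np.zeros(p)
        if cfg.init_strategy == "prior-draw":
            theta = rng.normal(0, 1, size=p)
        b = np.zeros((N, q))
        Sigma = 0.1 * np.eye(q)
        Sigma_inv = np.linalg.inv(Sigma)
        tau = _init_tau(design, cfg.init_strategy, rng)
        prop_sd = cfg.cutpoint_proposal_sd
        zeta = np.concatenate([[tau[0]], np.log(np.diff(tau))])

        keep = {k: [] for k in chains}
        n_iter = cfg.n_warmup + cfg.n_keep * cfg.thin
        acc_count = 0
        prop_count = 0
        acc_window = 0
        win_size = 50

        for it in range(n_iter):
            in_warmup = it < cfg.n_warmup

            if cfg.prior_only:
                theta = rng.normal(0, spec.prior_sd, size=p)
                if spec.random_effects:
                    Lp = np.linalg.cholesky(Sigma)
                    b = rng.standard_normal((N, q)) @ Lp.T
                    S_post = iw_scale_mat + b.T @ b
                    Sigma = invwishart.rvs(df=spec.iw_df + N, scale=S_post, random_state=rng)
                    Sigma = np.atleast_2d(Sigma)
            else:
                eta = F @ theta
                if spec.random_effects:
                    eta = eta + np.einsum("mq,mq->m", R, b[gidx])

                # --- 1. cutpoints: collapsed random-walk Metropolis on
                # (tau_1, log-gaps); several cheap sub-steps per cycle
                ll_cur = ordinal_loglik(y, eta, tau)
                for _ in range(cfg.n_cutpoint_steps):
                    zeta_prop = zeta + prop_sd * rng.standard_normal(4)
                    tau_prop = np.concatenate(
                        [[zeta_prop[0]],
                         zeta_prop[0] + np.cumsum(np.exp(zeta_prop[1:]))])
                    ll_prop = ordinal_loglik(y, eta, tau_prop)
                    log_alpha = ll_prop - ll_cur + np.sum(zeta_prop[1:] - zeta[1:])
                    prop_count += 1
                    if np.log(rng.uniform()) < log_alpha:
                        tau, zeta, ll_cur = tau_prop, zeta_prop, ll_prop
                        acc_count += 1
                        acc_window += 1
                if in_warmup and (it + 1) % win_size == 0:
                    rate = acc_window / (win_size * cfg.n_cutpoint_steps)
                    prop_sd *= float(np.exp(rate - 0.35))
                    prop_sd = float(np.clip(prop_sd, 1e-4, 2.0))
                    acc_window = 0

                # --- 2. latent utilities
                tau_ext = np.concatenate([[-np.inf], tau, [np.inf]])
                z = truncated_normal_draw(tau_ext[tau_ext_idx_lo], tau_ext[tau_ext_idx_up],
                                          eta, 1.0, rng)
                if not np.all(np.isfinite(z)):
                    raise DataError(f"non-finite latent draw at iteration {it}")

                # --- 3. fixed + spline coefficients
                resid = z - np.einsum("mq,mq->m", R, b[gidx]) if spec.random_effects else z
                mu = cho_solve(chol_A, F.T @ resid)
                theta = mu + solve_triangular(U, rng.standard_normal(p), lower=False)

                # --- 4. random effects
                if spec.random_effects:
                    e = z - F @ theta
                    Rte = np.add.reduceat(R * e[:, None], starts, axis=0)
                    P = RtR + Sigma_inv[None, :, :]
                    Lb = np.linalg.cholesky(P)
                    m = np.linalg.solve(P, Rte[:, :, None])[:, :, 0]
                    eps = rng.standard_normal((N, q))
                    b = m + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), eps[:, :, None])[:, :, 0]

                    # --- 5. covariance
                    S_post = iw_scale_mat + b.T @ b
                    Sigma = np.atleast_2d(
                        invwishart.rvs(df=spec.iw_df + N, scale=S_post, random_state=rng))
                    Sigma_inv = np.linalg.inv(Sigma)

                    # --- 6. translation moves along likelihood-invariant
                    # ridges (generalized Gibbs): each move shifts a
                    # coefficient together with the matching random-effect
                    # components so eta is unchanged, and draws the shift
                    # from its exact Gaussian conditional under the priors.
                    # These decorrelate (a) the cutpoint location vs the
                    # random intercepts, (b) each population weather effect
                    # vs the mean of its random slopes, and (c) each
                    # participant-level covariate effect vs the intercepts.
                    prior_prec = 1.0 / spec.prior_sd ** 2

                    # (a) tau location vs b_i0 (flat cutpoint prior)
                    Ab = b @ Sigma_inv
                    P_d = N * Sigma_inv[0, 0]
                    delta = rng.normal(-np.sum(Ab[:, 0]) / P_d, 1.0 / np.sqrt(P_d))
                    b[:, 0] += delta
                    tau = tau + delta

                    # (b) gamma_k vs mean of b_{., k}
                    gamma_idx = range(design.gamma_slice.start, design.gamma_slice.stop)
                    for k, j in enumerate(gamma_idx, start=1):
                        Ab = b @ Sigma_inv
                        P_d = N * Sigma_inv[k, k] + prior_prec
                        L = np.sum(Ab[:, k]) - theta[j] * prior_prec
                        delta = rng.normal(L / P_d, 1.0 / np.sqrt(P_d))
                        theta[j] += delta
                        b[:, k] -= delta

                    # (c) participant-level covariates vs b_i0
                    for j, xc in design.between_covariates.items():
                        Ab0 = b @ Sigma_inv[:, 0]
                        P_d = Sigma_inv[0, 0] * float(xc @ xc) + prior_prec
                        L = float(xc @ Ab0) - theta[j] * prior_prec
                        delta = rng.normal(L / P_d, 1.0 / np.sqrt(P_d))
                        theta[j] += delta
                        b[:, 0] -= delta * xc

                    zeta = np.concatenate([[tau[0]], np.log(np.diff(tau))])

            if not in_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
                keep["beta"].append(theta[design.beta_slice].copy())
                keep["gamma"].append(theta[design.gamma_slice].copy())
                keep["spline"].append(theta[design.spline_slice].copy())
                keep["tau"].append(tau.copy())
                if spec.random_effects:
                    keep["b"].append(b.copy())
                    keep["Sigma"].append(np.asarray(Sigma).copy())

        for k in chains:
            if keep[k]:
                chains[k].append(np.stack(keep[k]))
        acc_rates.append(acc_count / max(prop_count, 1))
        logger.info("chain %d finished: cutpoint acceptance %.2f, proposal sd %.4f",
                    chain, acc_rates[-1], prop_sd)

    def stack(name):
        return np.stack(chains[name]) if chains[name] else None

    return PosteriorDraws(
        beta=stack("beta"), gamma=stack("gamma"), tau=stack("tau"),
        spline=stack("spline"), b=stack("b"), Sigma=stack("Sigma"),
        participant_ids=design.participant_ids, col_names=design.col_names,
        weather_cols=list(spec.weather_cols), covariate_means=design.covariate_means,
        tau_acceptance=np.asarray(acc_rates),
    )
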