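"""Scikit-learn-style estimator wrapping the Gibbs-fitted multilevel probit.

``HierarchicalOrdinalProbit`` composes with sklearn tooling (``clone``,
``get_params``/``set_params``, pipelines); ``fit`` runs the Gibbs sampler
on an assembled analysis table and exposes the draws and summaries as
fitted attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diagnostics import convergence_summary
from .effects import population_summary
from .exceptions import DataError
from .probit import ModelSpec, build_design, category_probs
from .sampler import PosteriorDraws, SamplerConfig, run_sampler


class HierarchicalOrdinalProbit(BaseEstimator):
    """Bayesian multilevel cumulative probit with correlated random weather slopes.

    Parameters mirror :class:`ModelSpec` and :class:`SamplerConfig`; see
    those classes for semantics.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    summary_ : population coefficient table (estimate, CrI, MEM)
    convergence_ : per-parameter R-hat / ESS table
    design_ : the assembled numeric design
    n_obs_, participant_ids_
    """

    def __init__(self, covariate_cols=None, weather_cols=None, spline_df=5,
                 prior_sd=10.0, iw_df=7.0, iw_scale=1.0, cri_level=0.95,
                 random_effects=True, ordinal_covariates_as_indicators=False,
                 n_chains=4, n_warmup=1000, n_keep=1000, thin=1, seed=0,
                 cutpoint_proposal_sd=0.05, init_strategy="data-informed"):
        self.covariate_cols = covariate_cols
        self.weather_cols = weather_cols
        self.spline_df = spline_df
        self.prior_sd = prior_sd
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.cri_level = cri_level
        self.random_effects = random_effects
        self.ordinal_covariates_as_indicators = ordinal_covariates_as_indicators
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_keep = n_keep
        self.thin = thin
        self.seed = seed
        self.cutpoint_proposal_sd = cutpoint_proposal_sd
        self.init_strategy = init_strategy

    # -- internal builders -------------------------------------------------
    def _model_spec(self) -> ModelSpec:
        kwargs = {}
        if self.covariate_cols is not None:
            kwargs["covariate_cols"] = list(self.covariate_cols)
        if self.weather_cols is not None:
            kwargs["weather_cols"] = list(self.weather_cols)
        return ModelSpec(spline_df=self.spline_df, prior_sd=self.prior_sd,
                         iw_df=self.iw_df, iw_scale=self.iw_scale,
                         cri_level=self.cri_level, random_effects=self.random_effects,
                         ordinal_covariates_as_indicators=self.ordinal_covariates_as_indicators,
                         **kwargs)

    def _sampler_config(self) -> SamplerConfig:
        return SamplerConfig(n_chains=self.n_chains, n_warmup=self.n_warmup,
                             n_keep=self.n_keep, thin=self.thin, seed=self.seed,
                             cutpoint_proposal_sd=self.cutpoint_proposal_sd,
                             init_strategy=self.init_strategy)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalOrdinalProbit":
        """Fit on an assembled analysis table.

        ``X`` must carry participant_id, t, the covariate and scaled weather
        columns, and (unless ``y`` is given separately) the ordinal outcome
        column ``y``.
        """
        table = X.copy()
        if y is not None:
            table["y"] = np.asarray(y)
        if "y" not in table.columns:
            raise DataError("no outcome: pass a 'y' column or the y argument")
        spec = self._model_spec()
        design = build_design(table, spec)
        self.draws_ = run_sampler(table, spec, self._sampler_config(), design=design)
        self.design_ = design
        self.n_obs_ = design.n_obs
        self.participant_ids_ = list(design.participant_ids)
        self.convergence_ = convergence_summary(self.draws_)
        self.summary_ = population_summary(self.draws_, cri_level=self.cri_level)
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise DataError("estimator is not fitted")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean category probabilities for new participant-days.

        Random effects enter for participants seen during fitting; unseen
        participants are scored at the population-typical (zero) random
        effect.
        """
        self._check_fitted()
        d = self.design_
        spec = self._model_spec()
        draws = self.draws_
        theta_mean = np.concatenate([draws.pooled("beta").mean(0),
                                     draws.pooled("gamma").mean(0),
                                     draws.pooled("spline").mean(0)])
        tau_mean = draws.pooled("tau").mean(0)

        cols = []
        for name in d.col_names[d.beta_slice]:
            if name in X.columns:
                cols.append(X[name].to_numpy(float) - d.covariate_means[name])
            else:  # indicator column generated at fit time
                base_col, _, cat = name.partition("==")
                ind = (X[base_col].to_numpy(float) == float(cat)).astype(float)
                cols.append(ind - d.covariate_means[name])
        W = X[spec.weather_cols].to_numpy(float)
        B = d.spline.transform(X["t"].to_numpy(float))
        F = np.column_stack(cols + [W, B])
        eta = F @ theta_mean

        if draws.b is not None and "participant_id" in X.columns:
            b_mean = draws.pooled("b").mean(0)
            index = {p: i for i, p in enumerate(d.participant_ids)}
            R = np.column_stack([np.ones(len(X)), W])
            for r, pid in enumerate(X["participant_id"]):
                i = index.get(pid)
                if i is not None:
                    eta[r] += R[r] @ b_mean[i]
        return category_probs(eta, tau_mean)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Most probable pain category (1..5) per row."""
        return self.predict_proba(X).argmax(axis=1) + 1

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean predictive log-probability of the observed categories."""
        self._check_fitted()
        yy = np.asarray(X["y"] if y is None else y, int)
        p = self.predict_proba(X)
        return float(np.mean(np.log(np.clip(p[np.arange(len(yy)), yy - 1], 1e-300, None))))
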