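"""Shared test helper: degenerate (point-mass) posterior draws."""

import numpy as np

from cloudprobit.sampler import PosteriorDraws


def point_mass_draws(gamma, tau, n_draws=4, b=None, participant_ids=("A", "B")):
    C, K = 1, n_draws
    N = len(participant_ids)
    gamma = np.asarray(gamma, float)
    b_arr = np.zeros((C, K, N, 5)) if b is None else np.tile(b, (C, K, 1, 1))
    return PosteriorDraws(
        beta=np.zeros((C, K, 2)),
        gamma=np.tile(gamma, (C, K, 1)),
        tau=np.tile(np.asarray(tau, float), (C, K, 1)),
        spline=np.zeros((C, K, 5)),
        b=b_arr,
        Sigma=np.tile(np.eye(5), (C, K, 1, 1)),
        participant_ids=list(participant_ids),
        col_names=["mood", "exercise", "x_temp", "x_press", "x_hum", "x_wind",
                   "s1", "s2", "s3", "s4", "s5"],
        weather_cols=["x_temp", "x_press", "x_hum", "x_wind"],
        covariate_means={}, tau_acceptance=np.array([0.3]))
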