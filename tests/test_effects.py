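import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from cloudprobit.effects import (HIGH, LOW, UNDET, classify_participants,
                                 diagnosis_breakdown, forest_plot_data,
                                 label_interval, marginal_effect_at_mean,
                                 population_summary, sensitivity_profile)
from cloudprobit.exceptions import ConfigurationError, DataError
from cloudprobit.sampler import PosteriorDraws


def _point_mass_draws(gamma, tau, n_draws=4, b=None, participant_ids=("A", "B")):
    """A degenerate PosteriorDraws with every draw equal (for closed forms)."""
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


class TestPopulationSummary:
    def test_degenerate_posterior(self):
        d = _point_mass_draws([0.1, 0.2, 0.3, 0.4], [-1, 0, 1, 2])
        s = population_summary(d)
        assert np.allclose(s["estimate"], [0.1, 0.2, 0.3, 0.4])
        assert np.allclose(s["cri_lower"], s["estimate"])
        assert np.allclose(s["cri_upper"], s["estimate"])

    def test_normal_quantiles(self):
        """10^5 draws from N(0.041, 0.0036^2) give a (0.034, 0.048) interval."""
        rng = np.random.default_rng(0)
        g = rng.normal(0.041, 0.0036, (1, 100_000, 1))
        d = _point_mass_draws([0.0] * 4, [-1, 0, 1, 2])
        d = dataclasses.replace(
            d, gamma=np.tile(g, (1, 1, 4)),
            tau=np.tile(np.array([-1.0, 0, 1, 2]), (1, 100_000, 1)),
            beta=np.zeros((1, 100_000, 2)), spline=np.zeros((1, 100_000, 5)),
            b=np.zeros((1, 100_000, 2, 5)),
            Sigma=np.tile(np.eye(5), (1, 100_000, 1, 1)))
        s = population_summary(d)
        assert s["cri_lower"].iloc[0] == pytest.approx(0.034, abs=5e-4)
        assert s["cri_upper"].iloc[0] == pytest.approx(0.048, abs=5e-4)

    def test_chain_order_invariance(self, fitted):
        d = fitted["draws"]
        swapped = dataclasses.replace(
            d, gamma=d.gamma[::-1].copy(), tau=d.tau[::-1].copy(),
            beta=d.beta[::-1].copy(), spline=d.spline[::-1].copy(),
            b=d.b[::-1].copy(), Sigma=d.Sigma[::-1].copy())
        s1 = population_summary(d)
        s2 = population_summary(swapped)
        pd.testing.assert_frame_equal(s1, s2)


class TestMEM:
    def test_zero_effect_gives_zero(self):
        d = _point_mass_draws([0, 0, 0, 0], [-1, 0, 1, 2])
        assert marginal_effect_at_mean(d, "x_hum")["value"] == 0.0

    def test_closed_form(self):
        """tau_2 = 0, gamma = 0.1, delta 1: MEM = Phi(0.1) - Phi(0) = 0.03983."""
        d = _point_mass_draws([0, 0, 0.1, 0], [-1, 0, 1, 2])
        mem = marginal_effect_at_mean(d, "x_hum", threshold=3, delta=1.0)
        assert mem["value"] == pytest.approx(ndtr(0.1) - 0.5, abs=1e-12)
        assert mem["value"] == pytest.approx(0.03983, abs=5e-6)

    def test_sign_matches_gamma_when_draws_share_sign(self, fitted):
        for k, col in enumerate(fitted["draws"].weather_cols):
            g = fitted["draws"].pooled("gamma")[:, k]
            if np.all(g > 0) or np.all(g < 0):
                mem = marginal_effect_at_mean(fitted["draws"], col)
                assert np.sign(mem["value"]) == np.sign(g.mean())

    def test_finite_difference_consistency(self):
        """MEM/delta converges to phi(tau_2) * gamma_k as delta -> 0."""
        d = _point_mass_draws([0, 0, 0.2, 0], [-1.5, 0.3, 1.1, 2.0])
        deriv = norm.pdf(0.3) * 0.2
        for delta, tol in ((1e-3, 1e-4), (1e-5, 1e-6)):
            mem = marginal_effect_at_mean(d, "x_hum", delta=delta)
            assert mem["value"] / delta == pytest.approx(deriv, abs=tol)

    def test_invalid_threshold_rejected(self):
        d = _point_mass_draws([0, 0, 0, 0], [-1, 0, 1, 2])
        with pytest.raises(ConfigurationError):
            marginal_effect_at_mean(d, "x_hum", threshold=1)


class TestClassification:
    def test_interval_sign_rules(self):
        assert label_interval(0.01, 0.05) == HIGH
        assert label_interval(-0.05, -0.01) == LOW
        assert label_interval(-0.01, 0.02) == UNDET

    def test_labels_from_fixed_draws(self):
        b = np.zeros((3, 5))
        b[0, 3] = 0.5    # participant A: humidity slope +0.5 exactly
        b[1, 3] = -0.6   # participant B: -0.6
        d = _point_mass_draws([0, 0, 0.0, 0], [-1, 0, 1, 2], b=b,
                              participant_ids=("A", "B", "C"))
        labels = classify_participants(d)
        hum = labels[labels.parameter == "x_hum"].set_index("participant_id")
        assert hum.loc["A", "label"] == HIGH
        assert hum.loc["B", "label"] == LOW
        assert hum.loc["C", "label"] == UNDET

    def test_cri_level_nesting(self, fitted):
        """Raising the interval mass can only move labels toward
        undetermined, never away from it."""
        l90 = classify_participants(fitted["draws"], cri_level=0.90)
        l99 = classify_participants(fitted["draws"], cri_level=0.99)
        merged = l90.merge(l99, on=["participant_id", "parameter"],
                           suffixes=("_90", "_99"))
        moved_to_sensitive = ((merged["label_90"] == UNDET)
                              & (merged["label_99"] != UNDET))
        assert not moved_to_sensitive.any()

    def test_thinning_stability_away_from_zero(self, fitted):
        """Labels of intervals bounded away from zero survive thinning by 2."""
        full = classify_participants(fitted["draws"])
        d = fitted["draws"]
        thinned = dataclasses.replace(
            d, gamma=d.gamma[:, ::2], beta=d.beta[:, ::2], tau=d.tau[:, ::2],
            spline=d.spline[:, ::2], b=d.b[:, ::2], Sigma=d.Sigma[:, ::2])
        half = classify_participants(thinned)
        merged = full.merge(half, on=["participant_id", "parameter"],
                            suffixes=("_f", "_h"))
        # restrict to intervals clearly bounded away from zero
        width = merged["upper_f"] - merged["lower_f"]
        clear = (np.minimum(np.abs(merged["lower_f"]), np.abs(merged["upper_f"]))
                 > 0.1 * width) & (merged["lower_f"] * merged["upper_f"] > 0)
        sub = merged[clear]
        assert (sub["label_f"] == sub["label_h"]).all()


class TestProfileAndBreakdown:
    def _labels(self):
        rows = []
        spec = {
            "P1": {"x_temp": HIGH, "x_press": UNDET, "x_hum": HIGH, "x_wind": UNDET},
            "P2": {"x_temp": UNDET, "x_press": UNDET, "x_hum": UNDET, "x_wind": UNDET},
            "P3": {"x_temp": LOW, "x_press": UNDET, "x_hum": UNDET, "x_wind": UNDET},
            "P4": {"x_temp": UNDET, "x_press": LOW, "x_hum": HIGH, "x_wind": HIGH},
        }
        for pid, per in spec.items():
            for param, lab in per.items():
                rows.append({"participant_id": pid, "parameter": param,
                             "label": lab, "lower": -1.0, "median": 0.0,
                             "upper": 1.0})
        return pd.DataFrame(rows)

    def test_hand_counted_proportions(self):
        prof = sensitivity_profile(self._labels())
        prop = prof["proportions"]
        assert prop.loc["x_temp", HIGH] == pytest.approx(0.25)
        assert prop.loc["x_temp", LOW] == pytest.approx(0.25)
        assert prop.loc["x_press", LOW] == pytest.approx(0.25)
        assert prof["n_sensitive"] == 3
        hist = prof["multi_parameter_histogram"]
        assert hist.loc[1] == 1   # P3
        assert hist.loc[2] == 1   # P1
        assert hist.loc[3] == 1   # P4
        assert prof["single_parameter_fraction"] == pytest.approx(1 / 3)

    def test_proportions_partition(self):
        prop = sensitivity_profile(self._labels())["proportions"]
        assert np.allclose(prop.sum(axis=1), 1.0)

    def test_all_undetermined_empty_histogram(self):
        labels = self._labels()
        labels["label"] = UNDET
        prof = sensitivity_profile(labels)
        assert prof["n_sensitive"] == 0
        assert len(prof["multi_parameter_histogram"]) == 0
        assert (prof["proportions"][[LOW, HIGH]] == 0).all().all()

    def test_duplicate_labels_rejected(self):
        labels = pd.concat([self._labels(), self._labels().iloc[:1]])
        with pytest.raises(DataError):
            sensitivity_profile(labels)

    def _baselines(self):
        return pd.DataFrame({
            "participant_id": ["P1", "P2", "P3", "P4"],
            "age": 50.0, "sex": "female", "belief": 7,
            "diagnoses": ["rheumatoid-arthritis;gout",
                          "ankylosing-spondylitis/spondyloarthropathy",
                          "osteoarthritis", "chronic-headache"],
            "consented": True, "baseline_complete": True})

    def test_multi_diagnosis_excluded(self):
        bd = diagnosis_breakdown(self._labels(), self._baselines())
        counted = bd.groupby("parameter")["n"].sum()
        assert (counted == 3).all()     # P1 has two diagnoses -> excluded

    def test_spondyloarthropathy_is_inflammatory(self):
        bd = diagnosis_breakdown(self._labels(), self._baselines())
        groups = set(bd["group"])
        assert "inflammatory arthritic pain" in groups
        infl = bd[(bd.group == "inflammatory arthritic pain")
                  & (bd.parameter == "x_temp")]
        assert infl["n"].iloc[0] == 1   # P2 only

    def test_empty_cluster_prevalences_zero(self):
        labels = self._labels()
        labels["label"] = UNDET
        bd = diagnosis_breakdown(labels, self._baselines())
        assert (bd["low_sensitive"] == 0).all()
        assert (bd["high_sensitive"] == 0).all()


class TestForest:
    def test_sorted_medians_and_consistent_flags(self, fitted):
        labels = classify_participants(fitted["draws"])
        summary = population_summary(fitted["draws"])
        forest = forest_plot_data(labels, summary, "x_hum")
        med = forest["rows"]["median"].to_numpy()
        assert np.all(np.diff(med) >= 0)
        ref = summary.loc[summary["column"] == "x_hum", "estimate"].iloc[0]
        assert forest["reference"] == pytest.approx(ref, abs=1e-12)
        relabel = [label_interval(lo, hi) for lo, hi in
                   zip(forest["rows"]["lower"], forest["rows"]["upper"])]
        assert list(forest["rows"]["label"]) == relabel
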