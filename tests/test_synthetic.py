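"""Ground-truth construction and the Gaussian-copula cohort sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import null_config
from psynet.scoring import ScaleScorer, composite_risk
from psynet.synthetic import (
    DEFAULT_BRIDGES,
    GeneratorConfig,
    build_ground_truth,
    sample_cohort,
    simulate_study,
    thresholds_from_probs,
)


class TestGroundTruth:
    def test_template_carries_printed_bridge_weights(self):
        truth = build_ground_truth(GeneratorConfig(seed=0))
        t = truth.theta_template
        assert t.loc["PHQ1", "GAD1"] == pytest.approx(0.23)
        assert t.loc["UCLA1", "SOI_DES"] == pytest.approx(0.25)
        assert t.loc["SIHS_PUBID", "SOI_ATT"] == pytest.approx(-0.11)

    def test_implied_precisions_are_positive_definite(self):
        truth = build_ground_truth(GeneratorConfig(seed=5))
        for g in ("young", "old"):
            K = np.eye(37) - truth.theta[g].to_numpy()
            assert np.linalg.eigvalsh(K).min() > 0

    def test_zero_attenuation_clears_older_cross_edges(self):
        truth = build_ground_truth(GeneratorConfig(seed=0, attenuation=0.0,
                                                   older_boosts=()))
        # every bridge crosses clusters except the emotional PHQ-GAD tie
        for a, b, _ in DEFAULT_BRIDGES:
            if {a[:3], b[:3]} == {"PHQ", "GAD"}:
                continue
            assert truth.theta["old"].loc[a, b] == 0.0

    def test_empty_template_gives_independent_truth(self):
        truth = build_ground_truth(null_config(seed=0))
        assert np.abs(truth.theta_template.to_numpy()).max() == 0.0
        assert np.allclose(truth.sigma["young"], np.eye(37))

    def test_pooled_template_sits_between_group_truths(self):
        truth = build_ground_truth(GeneratorConfig(seed=0))
        f = truth.shrink_factor
        young = truth.theta["young"].loc["UCLA1", "SOI_DES"]
        old = truth.theta["old"].loc["UCLA1", "SOI_DES"]
        assert (young + old) / 2 == pytest.approx(0.25 * f, abs=1e-12)
        assert old == pytest.approx(young * 0.5, abs=1e-12)


class TestSampler:
    def test_deterministic_given_seed(self):
        a = simulate_study(n=50, seed=9).cohort
        b = simulate_study(n=50, seed=9).cohort
        pd.testing.assert_frame_equal(a, b)

    def test_null_truth_yields_uncorrelated_nodes(self):
        cfg = null_config(seed=2, n=2000)
        truth = build_ground_truth(cfg)
        cohort, _ = sample_cohort(truth, cfg)
        nodes = ScaleScorer().fit(cohort).transform(cohort)
        R = np.asarray(stats.spearmanr(nodes).statistic)
        off = np.abs(R - np.eye(37))
        # null sampling distribution of rho at n=2000: sd ~ 0.022
        assert off.max() < 0.09

    def test_copula_spearman_matches_greiner_relation(self):
        # continuous (pre-threshold) latent pairs: rho_S = (6/pi) asin(r/2)
        r = 0.5
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=50_000)
        rho = stats.spearmanr(z[:, 0], z[:, 1]).statistic
        assert rho == pytest.approx(6 / np.pi * np.arcsin(r / 2), abs=0.02)

    def test_item_thresholds_control_marginal_means(self):
        # P(item >= 1) = 0.5 with a two-point marginal puts the expected
        # depression total at 4.5
        cfg = null_config(seed=4, n=4000)
        cfg.marginals = dict(cfg.marginals)
        cfg.marginals["PHQ"] = [0.5, 0.5]
        truth = build_ground_truth(cfg)
        cohort, _ = sample_cohort(truth, cfg)
        totals = ScaleScorer().fit(cohort).scale_totals(cohort)
        assert totals["PHQ_total"].mean() == pytest.approx(4.5, abs=0.5)

    def test_marginals_match_published_means(self, default_sim):
        totals = ScaleScorer().fit(default_sim.cohort).scale_totals(default_sim.cohort)
        assert totals["PHQ_total"].mean() == pytest.approx(4.6, abs=1.0)
        assert totals["UCLA_total"].mean() == pytest.approx(4.3, abs=0.5)
        assert totals["RSES_total"].mean() == pytest.approx(20.3, abs=1.5)

    def test_age_mixture_and_eligibility(self, default_sim):
        age = default_sim.cohort["age"]
        assert age.min() >= 16 and age.max() <= 76
        assert 0.35 < (age >= 33).mean() < 0.60

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_probs([0.5, 0.6], 0)


class TestRiskAttachment:
    def test_zero_weights_give_null_connection_values(self):
        cfg = null_config(seed=7, n=2000)
        truth = build_ground_truth(cfg)
        cohort, _ = sample_cohort(truth, cfg)
        nodes = ScaleScorer().fit(cohort).transform(cohort)
        risk = composite_risk(cohort)["risk_score"]
        rhos = [stats.spearmanr(nodes[c], risk).statistic for c in nodes.columns]
        assert np.max(np.abs(rhos)) < 0.09

    def test_single_weight_dominates(self):
        cfg = GeneratorConfig(n=2000, seed=8, risk_weights={"SOI_DES": 1.0})
        truth = build_ground_truth(cfg)
        cohort, _ = sample_cohort(truth, cfg)
        nodes = ScaleScorer().fit(cohort).transform(cohort)
        risk = composite_risk(cohort)["risk_score"]
        rhos = pd.Series(
            {c: stats.spearmanr(nodes[c], risk).statistic for c in nodes.columns}
        )
        assert rhos.idxmax() == "SOI_DES"
        assert rhos["SOI_DES"] > 0.2

    def test_code_marginals_match_published_rates(self, default_sim):
        risk = composite_risk(default_sim.cohort)
        assert risk["uai"].mean() == pytest.approx(0.193, abs=0.05)
        assert risk["msp"].mean() == pytest.approx(0.689, abs=0.05)

    def test_unknown_weight_name_rejected(self):
        cfg = GeneratorConfig(n=50, seed=0, risk_weights={"NOPE": 1.0})
        truth = build_ground_truth(cfg)
        with pytest.raises(ValueError, match="NOPE"):
            sample_cohort(truth, cfg)


def test_missingness_rate_applied():
    sim = simulate_study(n=400, seed=13, missing_rate=0.05)
    items = sim.cohort[[c for c in sim.cohort.columns if c[:3] in
                        ("PHQ", "GAD", "UCL", "RSE", "MSP", "SOI", "SIH")]]
    frac = items.isna().to_numpy().mean()
    assert 0.03 < frac < 0.07
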