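"""Effect vectors, additive prediction and the additivity classifier."""

import numpy as np
import pytest

from spheroquant.combination import (
    GroupSummary,
    classify_additivity,
    classify_additivity_bootstrap,
    effect_vector,
    predict_additive,
    summarize_group,
)


def g(area, pi, sem_area=0.05, sem_pi=1.0, model="M", day=5, pdt=0.0, rt=0.0, n=10):
    return GroupSummary(model, day, pdt, rt, area, sem_area, pi, sem_pi, n)


class TestEffectVector:
    def test_identical_groups_give_zero_vector(self):
        ev = effect_vector(g(1.0, 10.0), g(1.0, 10.0))
        assert ev.d_area == 0.0 and ev.d_pi == 0.0

    def test_componentwise_arithmetic(self):
        ev = effect_vector(g(0.5, 12.0), g(1.0, 10.0))
        assert ev.d_area == pytest.approx(-0.5)
        assert ev.d_pi == pytest.approx(2.0)

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            effect_vector(g(1.0, 10.0, day=5), g(1.0, 10.0, day=12))

    def test_designed_cohort_displacement_recovered(self, rng):
        control = summarize_group("M", 5, 0, 0, rng.normal(1.0, 0.05, 30),
                                  rng.normal(10.0, 1.0, 30))
        treated = summarize_group("M", 5, 2.5, 0, rng.normal(0.7, 0.05, 30),
                                  rng.normal(35.0, 1.0, 30))
        ev = effect_vector(treated, control)
        assert ev.d_area == pytest.approx(-0.3, abs=3 * 0.05 / np.sqrt(15))
        assert ev.d_pi == pytest.approx(25.0, abs=3 * 1.0 / np.sqrt(15))


class TestAdditivePrediction:
    def test_componentwise_sum(self):
        pred = predict_additive(g(1.0, 10.0), g(0.95, 40.0, pdt=2.5), g(0.5, 12.0, rt=20))
        assert pred.area == pytest.approx(0.45)
        assert pred.pi == pytest.approx(42.0)

    def test_zero_single_agent_effect_is_identity(self):
        control = g(1.0, 10.0)
        pred = predict_additive(control, g(1.0, 10.0, pdt=2.5), g(0.6, 11.0, rt=20))
        assert (pred.area, pred.pi) == (pytest.approx(0.6), pytest.approx(11.0))

    def test_symmetric_in_single_agents(self):
        a = predict_additive(g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20))
        b = predict_additive(g(1.0, 10.0), g(0.5, 12.0, rt=20), g(0.9, 30.0, pdt=2.5))
        assert (a.area, a.pi, a.sigma_area, a.sigma_pi) == (b.area, b.pi, b.sigma_area, b.sigma_pi)

    def test_rss_uncertainty(self):
        pred = predict_additive(g(1.0, 10.0, sem_pi=3.0), g(0.9, 30.0, pdt=2.5, sem_pi=4.0),
                                g(0.5, 12.0, rt=20, sem_pi=12.0))
        assert pred.sigma_pi == pytest.approx(13.0)  # 3-4-12 right triangle


class TestClassifier:
    def test_exact_prediction_is_additive_on_both_axes(self):
        control, pdt, rt = g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20)
        pred = predict_additive(control, pdt, rt)
        calls = classify_additivity(g(pred.area, pred.pi, pdt=2.5, rt=20), pred)
        assert {c.verdict for c in calls.values()} == {"additive"}

    def test_large_necrosis_excess_is_super_additive(self):
        pred = predict_additive(g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20))
        ci = 1.96 * np.hypot(pred.sigma_pi, 1.0)
        calls = classify_additivity(g(pred.area, pred.pi + 10 * ci, pdt=2.5, rt=20), pred)
        assert calls["necrosis"].verdict == "super_additive"
        assert calls["area"].verdict == "additive"

    def test_weaker_shrinkage_is_sub_additive_on_area(self):
        pred = predict_additive(g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20))
        ci = 1.96 * np.hypot(pred.sigma_area, 0.05)
        calls = classify_additivity(g(pred.area + 5 * ci, pred.pi, pdt=2.5, rt=20), pred)
        assert calls["area"].verdict == "sub_additive"

    def test_translation_invariance_of_verdicts(self):
        base = (g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20))
        shifted = (g(1.0, 110.0), g(0.9, 130.0, pdt=2.5), g(0.5, 112.0, rt=20))
        for groups, obs_pi in ((base, 60.0), (shifted, 160.0)):
            pred = predict_additive(*groups)
            calls = classify_additivity(g(0.42, obs_pi, pdt=2.5, rt=20), pred)
        ref = classify_additivity(g(0.42, 60.0, pdt=2.5, rt=20), predict_additive(*base))
        assert {a: c.verdict for a, c in calls.items()} == \
               {a: c.verdict for a, c in ref.items()}

    def test_paper_style_pattern_on_designed_cohorts(self, rng):
        """Combination built to exceed the additive necrosis prediction and to
        shrink less than additively: super-additive necrosis, sub-additive area."""
        n = 40
        mk = lambda pdt, rt, area, pi: summarize_group(
            "M", 5, pdt, rt, rng.normal(area, 0.02, n), rng.normal(pi, 0.5, n))
        control, pdt, rt = mk(0, 0, 1.0, 10.0), mk(2.5, 0, 0.95, 40.0), mk(0, 20, 0.5, 12.0)
        combo = mk(2.5, 20, 0.60, 55.0)  # additive would be (0.45, 42)
        calls = classify_additivity(combo, predict_additive(control, pdt, rt))
        assert calls["necrosis"].verdict == "super_additive"
        assert calls["area"].verdict == "sub_additive"

    def test_invalid_alpha_rejected(self):
        pred = predict_additive(g(1.0, 10.0), g(0.9, 30.0, pdt=2.5), g(0.5, 12.0, rt=20))
        with pytest.raises(ValueError):
            classify_additivity(g(0.5, 40.0, pdt=2.5, rt=20), pred, alpha=1.5)

    def test_zero_n_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary("M", 5, 0, 0, 1.0, 0.0, 10.0, 0.0, 0)


class TestBootstrapClassifier:
    def test_agrees_with_normal_rule_on_clear_synergy(self, rng):
        n = 30
        cohorts = {
            "control": (rng.normal(1.0, 0.05, n), rng.normal(10, 1, n)),
            "pdt": (rng.normal(0.95, 0.05, n), rng.normal(40, 1, n)),
            "rt": (rng.normal(0.5, 0.05, n), rng.normal(12, 1, n)),
            "combo": (rng.normal(0.45, 0.05, n), rng.normal(60, 1, n)),
        }
        calls = classify_additivity_bootstrap(cohorts["control"], cohorts["pdt"],
                                              cohorts["rt"], cohorts["combo"],
                                              n_boot=500, seed=0)
        assert calls["necrosis"].verdict == "super_additive"
        assert calls["area"].verdict == "additive"
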