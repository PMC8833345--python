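"""Boosted stump model and permutation significance: design encoding,
logistic-limit oracle, centering/monotonicity invariants, and an
exhaustively enumerated permutation null on a tiny design."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snakeonc import outcome_model as om


def toy_design(y, **columns):
    return om.design_from_frame(pd.DataFrame(columns), y)


def effects_by_level(model):
    table = om.extract_effects(model)
    return {(r.predictor, r.level): r.outcome_effect for r in table.itertuples()}


class TestBuildDesign:
    def test_fixture_row_count_and_exclusions(self, fixture_bundle, fixture_design):
        d = fixture_design
        # 121 snakes have a known cause of death; one of them carries only
        # an unspecified-behavior tumor and cannot enter the tally
        assert d.n == 120
        excluded = {c.case_id for c in fixture_bundle.cases
                    if not c.eligible_for_outcome_model}
        assert len(excluded) == 12
        assert not excluded & set(d.case_ids)

    def test_fixture_predictor_tallies(self, fixture_design):
        table = om.extract_effects(om.fit_boost(fixture_design))
        sizes = table.set_index(["predictor", "level"])["sample_size"]
        met = sizes.loc["metastasis"]
        assert (met["yes"], met["unknown"], met["no"]) == (56, 2, 62)
        beh = sizes.loc["type_of_neoplasm"]
        # published tallies are 112 malignant / 9 benign; the rebuilt
        # registry lands nearby, moving only with the multi-tumor sampling
        assert beh["malignant"] + beh["benign"] == 120
        assert 104 <= beh["malignant"] <= 114
        assert 6 <= beh["benign"] <= 16

    def test_sample_sizes_sum_to_design_rows_per_predictor(self, fixture_design):
        table = om.extract_effects(om.fit_boost(fixture_design))
        assert (table.groupby("predictor")["sample_size"].sum() == fixture_design.n).all()

    def test_sampling_deterministic_under_seed(self, fixture_bundle):
        d1 = om.build_design(fixture_bundle.cases, seed=5)
        d2 = om.build_design(fixture_bundle.cases, seed=5)
        assert np.array_equal(d1.codes, d2.codes)

    def test_no_eligible_cases_rejected(self, fixture_bundle):
        ineligible = [c for c in fixture_bundle.cases
                      if not c.eligible_for_outcome_model]
        with pytest.raises(ValueError, match="no eligible"):
            om.build_design(ineligible)


class TestFitBoost:
    def test_informative_binary_predictor_converges_to_logistic_fit(self):
        # 8/10 deaths at level a, 2/10 at level b: the boosted log-odds
        # gap must approach logit(0.8) - logit(0.2) as mstop grows
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        d = toy_design(y, x=["a"] * 10 + ["b"] * 10)
        model = om.fit_boost(d, om.BoostConfig(nu=0.1, mstop=3000))
        eff = effects_by_level(model)
        gap = eff[("x", "a")] - eff[("x", "b")]
        target = np.log(0.8 / 0.2) - np.log(0.2 / 0.8)
        assert gap == pytest.approx(target, rel=0.02)

    def test_contribution_grows_monotonically_with_mstop(self):
        y = np.array([1] * 9 + [0] + [1] + [0] * 9)
        d = toy_design(y, x=["a"] * 10 + ["b"] * 10)
        gaps = []
        for mstop in (5, 20, 80):
            eff = effects_by_level(om.fit_boost(d, om.BoostConfig(mstop=mstop)))
            assert eff[("x", "a")] > 0 > eff[("x", "b")]
            gaps.append(eff[("x", "a")] - eff[("x", "b")])
        assert gaps[0] < gaps[1] < gaps[2]

    def test_uninformative_predictor_has_near_zero_effects(self):
        # z has identical outcome rates at each level; x carries signal
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0] * 4)
        x = (["a"] * 4 + ["b"] * 4) * 4
        z = ["u", "u", "v", "v", "v", "v", "u", "u"] * 4  # 2/4 deaths each
        d = toy_design(y, x=x, z=z)
        eff = effects_by_level(om.fit_boost(d))
        assert abs(eff[("z", "u")]) < 0.05 and abs(eff[("z", "v")]) < 0.05
        assert eff[("x", "a")] > 0.2

    def test_single_level_predictor_never_selected_effect_exactly_zero(self):
        y = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        d = toy_design(y, x=list("aabbaabb"), const=["k"] * 8)
        eff = effects_by_level(om.fit_boost(d, om.BoostConfig(minbucket=1)))
        assert eff[("const", "k")] == 0.0

    def test_balanced_binary_effects_are_symmetric(self):
        y = np.array([1] * 7 + [0] * 3 + [1] * 3 + [0] * 7)
        d = toy_design(y, x=["a"] * 10 + ["b"] * 10)
        eff = effects_by_level(om.fit_boost(d))
        assert eff[("x", "a")] == pytest.approx(-eff[("x", "b")], abs=1e-12)

    def test_training_loss_non_increasing(self, fixture_design):
        model = om.fit_boost(fixture_design)
        assert (np.diff(model.training_loss_path) <= 1e-9).all()

    def test_weighted_centering_within_each_predictor(self, fixture_design):
        model = om.fit_boost(fixture_design)
        table = om.extract_effects(model)
        for _, grp in table.groupby("predictor"):
            weighted = (grp["sample_size"] * grp["outcome_effect"]).sum()
            assert abs(weighted) < 1e-8 * fixture_design.n

    def test_predictions_stable_as_nu_shrinks_at_fixed_budget(self):
        y = np.array([1, 1, 1, 0, 1, 0, 1, 0, 0, 0] * 3)
        d = toy_design(y, x=list("aaabbbccdd") * 3)
        eff_a = effects_by_level(om.fit_boost(d, om.BoostConfig(nu=0.2, mstop=150)))
        eff_b = effects_by_level(om.fit_boost(d, om.BoostConfig(nu=0.05, mstop=600)))
        for key in eff_a:
            assert eff_a[key] == pytest.approx(eff_b[key], abs=0.05)

    def test_two_subset_stump_variant(self):
        y = np.array([1, 1, 1, 1, 0, 0, 1, 0, 0, 0] * 2)
        d = toy_design(y, x=list("aabbccddee") * 2)
        model = om.fit_boost(d, om.BoostConfig(stump="two_subset"))
        assert (np.diff(model.training_loss_path) <= 1e-9).all()
        eff = effects_by_level(model)
        assert eff[("x", "a")] > 0 > eff[("x", "e")]

    def test_single_class_outcome_rejected(self):
        d = toy_design(np.ones(6, dtype=int), x=list("aabbcc"))
        with pytest.raises(ValueError, match="one outcome class"):
            om.fit_boost(d)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            om.BoostConfig(nu=0.0)
        with pytest.raises(ValueError):
            om.BoostConfig(mstop=0)
        with pytest.raises(ValueError):
            om.BoostConfig(stump="forest")


class TestPermutation:
    def test_pvalues_within_add_one_bounds_small_B(self, fixture_design):
        res = om.permutation_test(fixture_design, B=10, seed=3)
        p = res.table["p_two_sided"]
        assert (p >= 1 / 11 - 1e-12).all() and (p <= 1.0).all()

    def test_sampled_p_matches_exhaustive_enumeration(self):
        """On 6 rows the permutation null is fully enumerable; the
        Monte-Carlo p must agree within sampling error."""
        y = np.array([1, 1, 1, 0, 0, 0])
        x = list("aabbcc")
        d = toy_design(y, x=x)
        cfg = om.BoostConfig(mstop=30, minbucket=1)
        obs = effects_by_level(om.fit_boost(d, cfg))[("x", "a")]

        null = []
        for ones in itertools.combinations(range(6), 3):
            y_perm = np.zeros(6, dtype=int)
            y_perm[list(ones)] = 1
            eff = effects_by_level(om.fit_boost(toy_design(y_perm, x=x), cfg))
            null.append(eff[("x", "a")])
        exact_tail = np.mean(np.abs(null) >= abs(obs) - 1e-12)

        B = 600
        res = om.permutation_test(d, cfg, B=B, seed=11)
        p_hat = res.table.set_index(["predictor", "level"]).loc[
            ("x", "a"), "p_two_sided"
        ]
        mc_err = 3 * np.sqrt(exact_tail * (1 - exact_tail) / B) + 2 / (B + 1)
        assert abs(p_hat - exact_tail) <= mc_err

    def test_effect_at_null_median_gets_large_p(self):
        # outcome independent of the predictor: p should be far from 0.05
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        d = toy_design(y, x=list(rng.choice(["a", "b"], 60)))
        res = om.permutation_test(d, B=199, seed=5)
        assert (res.table["p_two_sided"] > 0.2).all()

    def test_B_must_be_positive(self, fixture_design):
        with pytest.raises(ValueError, match="B"):
            om.permutation_test(fixture_design, B=0)

    def test_pipeline_smoke_with_resampled_tumor_assignment(self, fixture_bundle):
        effects, perm = om.run_outcome_pipeline(
            fixture_bundle, B=10, seed=2, resample_per_permutation=True
        )
        assert perm.B == 10
        assert (perm.table["p_two_sided"] >= 1 / 11 - 1e-12).all()
        assert set(effects.columns) == {
            "predictor", "level", "sample_size", "outcome_effect"
        }
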