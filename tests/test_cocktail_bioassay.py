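import numpy as np
import pandas as pd
import pytest

import symbioscreen as ss
from symbioscreen.cocktail_bioassay import DEFAULT_MULTIPLIERS
from symbioscreen.errors import InputError

SEVEN_COMPONENTS = {
    "Ketoisocaproic acid": 66.1,
    "Glutaric acid": 63.7,
    "Adipic acid": 587.5,
    "Phenyllactic acid": 6.3,
    "Indoleacetic acid": 191.2,
    "Kynurenic acid": 0.1,
    "Picolinic acid": 0.18,
}


class TestRecipe:
    def test_nonaxenic_means_give_seven_components(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        assert recipe.components == pytest.approx(SEVEN_COMPONENTS)

    def test_impossible_threshold_rejected(self, measured_surface_means):
        with pytest.raises(InputError, match="threshold"):
            ss.build_recipe(measured_surface_means, "nonaxenic", 1000.0)

    def test_zero_threshold_adds_trace_components(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.0)
        # 9 detected metabolites (the undetected one stays out)
        assert len(recipe.components) == 9
        assert "Thymine" not in recipe.components
        assert recipe.components["Hypoxanthine"] == pytest.approx(0.001)

    def test_empty_components_rejected(self):
        with pytest.raises(InputError):
            ss.CocktailRecipe({}, "nonaxenic")


class TestDoseSeries:
    def test_halving_adipic_acid(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        doses = ss.dose_series(recipe)
        half = doses[doses["multiplier"] == 0.5]["Adipic acid"].iloc[0]
        assert half == pytest.approx(293.75)

    def test_unit_multiplier_preserves_recipe(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        doses = ss.dose_series(recipe)
        row = doses[doses["multiplier"] == 1.0].iloc[0]
        for name, conc in recipe.components.items():
            assert row[name] == pytest.approx(conc)

    def test_default_series_shape(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        doses = ss.dose_series(recipe)
        assert len(doses) == 9  # 2^1 .. 2^-6 plus control
        assert doses["multiplier"].iloc[0] == 2.0
        assert doses["multiplier"].iloc[-1] == 0.0
        assert (np.diff(doses["multiplier"]) < 0).all()
        assert (doses.iloc[-1, 1:] == 0).all()

    def test_linearity_in_recipe(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        scaled = ss.CocktailRecipe(
            {k: 3 * v for k, v in recipe.components.items()}, "nonaxenic", 0.1
        )
        a = ss.dose_series(recipe).set_index("multiplier")
        b = ss.dose_series(scaled).set_index("multiplier")
        pd.testing.assert_frame_equal(b, a * 3)

    def test_negative_multiplier_rejected(self, measured_surface_means):
        recipe = ss.build_recipe(measured_surface_means, "nonaxenic", 0.1)
        with pytest.raises(InputError):
            ss.dose_series(recipe, (-1.0, 1.0))


def _assay_frame(assay, dose_values):
    rows = []
    for dose, values in dose_values.items():
        for rep, v in enumerate(values):
            rows.append({"assay": assay, "dose_level": dose,
                         "replicate": rep + 1, "value": v})
    return pd.DataFrame(rows)


class TestRelativeRate:
    def test_control_is_exactly_100(self):
        data = _assay_frame("germination", {0.0: [0.8, 0.8], 1.0: [0.8, 0.8]})
        rates = ss.relative_rate(data).set_index("dose_level")
        assert rates.loc[0.0, "relative_rate_pct"] == 100.0
        assert rates.loc[1.0, "relative_rate_pct"] == 100.0

    def test_germination_fraction_arithmetic(self):
        data = _assay_frame("germination", {0.0: [0.8, 0.8], 1.0: [0.12, 0.12]})
        rates = ss.relative_rate(data).set_index("dose_level")
        assert rates.loc[1.0, "relative_rate_pct"] == pytest.approx(15.0)

    def test_growth_subtracts_plug(self):
        data = _assay_frame("growth", {0.0: [43.0, 43.0], 1.0: [9.52, 9.52]})
        rates = ss.relative_rate(data).set_index("dose_level")
        # 100 * (9.52 - 3) / (43 - 3)
        assert rates.loc[1.0, "relative_rate_pct"] == pytest.approx(16.3)

    def test_missing_control_rejected(self):
        data = _assay_frame("germination", {1.0: [0.5, 0.5]})
        with pytest.raises(InputError, match="control"):
            ss.relative_rate(data)


class TestWelchAnova:
    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        groups = [rng.normal(10, sd, 8) for sd in (0.5, 1.0, 3.0)]
        f, df1, df2, p = ss.welch_anova(groups)
        long = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], 8),
        })
        ref = pingouin.welch_anova(long, dv="y", between="g").iloc[0]
        assert f == pytest.approx(ref["F"], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"], rel=1e-9)

    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 3, 6)
        f, _, df2, p = ss.welch_anova([a, b])
        from scipy import stats
        t = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, rel=1e-9)


class TestDoseResponseSummary:
    def test_separated_means_get_distinct_letters(self):
        data = _assay_frame(
            "germination",
            {d: list(10 * (4 - d) + np.array([-0.01, 0.0, 0.01, 0.02]))
             for d in range(4)},
        )
        summary = ss.dose_response_summary(data)
        letters = list(summary.letters.values())
        assert len(set(letters)) == 4
        # letters follow the mean ordering
        ordered = sorted(summary.letters, key=lambda d: -summary.group_means[d])
        assert [summary.letters[d] for d in ordered] == ["a", "b", "c", "d"]

    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(2)
        data = _assay_frame("germination",
                            {float(d): rng.normal(10, 1, 6) for d in range(4)})
        summary = ss.dose_response_summary(data)
        if summary.p_value > 0.05:
            assert len(set(summary.letters.values())) == 1

    def test_heteroscedastic_groups_select_welch_branch(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            data = _assay_frame(
                "germination",
                {float(d): rng.normal(10, sd, 6) + 10
                 for d, sd in enumerate([0.2, 1.0, 5.0, 0.5, 2.5])},
            )
            hits += ss.dose_response_summary(data).omnibus_test == "welch_anova"
        assert hits / 200 >= 0.90

    def test_single_dose_rejected(self):
        data = _assay_frame("germination", {0.0: [1, 2, 3]})
        with pytest.raises(InputError):
            ss.dose_response_summary(data)

    def test_simulated_dose_response_is_detected(self):
        data = ss.simulate_bioassay(
            list(DEFAULT_MULTIPLIERS), lambda d: 1 / (1 + 5 * d), n_reps=6, seed=0
        )
        summary = ss.dose_response_summary(data)
        assert summary.p_value < 0.001
        # control and the strongest dose never share a letter
        assert not set(summary.letters[0.0]) & set(summary.letters[2.0])


class TestCompactLetters:
    def test_no_significance_single_letter(self):
        letters = ss.compact_letter_display(
            ["a", "b", "c"], [3, 2, 1],
            {("a", "b"): False, ("a", "c"): False, ("b", "c"): False},
        )
        assert set(letters.values()) == {"a"}

    def test_chain_overlap(self):
        # a != c, but b bridges both
        letters = ss.compact_letter_display(
            ["x", "y", "z"], [3, 2, 1],
            {("x", "y"): False, ("y", "z"): False, ("x", "z"): True},
        )
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])
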