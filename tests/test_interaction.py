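"""The expected-additivity index: theoretical values, differences, classes."""

import numpy as np
import pandas as pd
import pytest

from synermix import (
    InteractionAnalyzer,
    InteractionConfig,
    analyze_panel,
    classify_interaction,
    concentration_trend,
    difference_percent,
    difference_uncertainty,
    enumerate_equimolar_mixtures,
    round_difference,
    theoretical_mixture_value,
)
from synermix.interaction import format_difference, round_half_away


class TestTheoreticalValue:
    @pytest.mark.parametrize(
        "means, expected",
        [
            ([282, 294], 288.0),  # protocatechuic + gentisic, FRAP 100 µM
            ([33, 45], 39.0),  # p-coumaric + ferulic, ORAC 5 µM
            ([282, 294, 494, 193, 245], 301.6),  # quinary hydroxybenzoic, FRAP 100 µM
        ],
    )
    def test_published_examples(self, means, expected):
        assert theoretical_mixture_value(means) == pytest.approx(expected)

    def test_identical_components_give_their_common_value(self):
        assert theoretical_mixture_value([7.5, 7.5, 7.5]) == pytest.approx(7.5)

    def test_fewer_than_two_components_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mixture_value([100.0])

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mixture_value([100.0, float("nan")])

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mixture_value([1.0, 2.0], k=3)


class TestDifferencePercent:
    @pytest.mark.parametrize(
        "exp, theo, value, reported",
        [
            (520, 288, 80.6, 81),  # P+Ge FRAP 100 µM
            (74, 68, 8.8, 9),  # Si+R ORAC 5 µM
            (229, 343.5, -33.3, -33),  # G+V FRAP 100 µM
        ],
    )
    def test_published_examples(self, exp, theo, value, reported):
        d = difference_percent(exp, theo)
        assert d == pytest.approx(value, abs=0.05)
        # printed cells are integers for these rows
        assert round_half_away(d, 0) == reported

    def test_zero_when_experimental_equals_expectation(self):
        for e in (0.3, 57, 5033):
            assert difference_percent(e, e) == pytest.approx(0.0)

    def test_nonpositive_theoretical_rejected(self):
        for t in (0.0, -3.0):
            with pytest.raises(ValueError):
                difference_percent(100.0, t)

    def test_negative_experimental_rejected(self):
        with pytest.raises(ValueError):
            difference_percent(-1.0, 100.0)


class TestClassification:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (81, "synergistic"),
            (4.0, "additive"),
            (-58, "antagonistic"),
            (5.0, "additive"),  # band is inclusive
            (-5.0, "additive"),
            (5.0000001, "synergistic"),
            (0.0, "additive"),
        ],
    )
    def test_band_rule(self, d, expected):
        assert classify_interaction(d, InteractionConfig(5.0)) == expected

    def test_band_width_is_configurable(self):
        assert classify_interaction(7.0, InteractionConfig(10.0)) == "additive"
        assert classify_interaction(1.0, InteractionConfig(0.0)) == "synergistic"

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            InteractionConfig(-1.0)


class TestDifferenceUncertainty:
    def test_zero_when_noiseless(self):
        assert difference_uncertainty(520, 0, 3, [282, 294], [0, 0], 3) == 0.0

    def test_scale_invariance(self):
        a = difference_uncertainty(520, 12, 3, [282, 294], [5, 4], 3)
        c = 37.2
        b = difference_uncertainty(520 * c, 12 * c, 3, [282 * c, 294 * c], [5 * c, 4 * c], 3)
        assert b == pytest.approx(a, rel=1e-12)

    def test_matches_monte_carlo_oracle(self):
        # Gaussian resampling of the mixture mean and the individual means
        rng = np.random.default_rng(20260920)
        e_mean, e_sd, n_e = 520.0, 12.0, 3
        means, sds, n_i = [282.0, 294.0, 245.0], [5.0, 4.0, 6.0], 3
        n_mc = 100_000
        E = rng.normal(e_mean, e_sd / np.sqrt(n_e), n_mc)
        M = np.column_stack(
            [rng.normal(m, s / np.sqrt(n_i), n_mc) for m, s in zip(means, sds)]
        )
        D = 100 * E / M.mean(axis=1) - 100
        mc_sd = D.std(ddof=1)
        delta = difference_uncertainty(e_mean, e_sd, n_e, means, sds, n_i)
        assert delta == pytest.approx(mc_sd, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            difference_uncertainty(520, -1, 3, [282, 294], [5, 4], 3)
        with pytest.raises(ValueError):
            difference_uncertainty(520, 1, 3, [282, 294], [5], 3)
        with pytest.raises(ValueError):
            difference_uncertainty(520, 1, 0, [282, 294], [5, 4], 3)


class TestEnumerateMixtures:
    def test_counts_for_the_study_design(self):
        ids = ["P", "Ge", "G", "V", "Sy"]
        assert len(enumerate_equimolar_mixtures(ids, (2, 2))) == 10
        assert len(enumerate_equimolar_mixtures(ids, (5, 5))) == 1
        mixtures = enumerate_equimolar_mixtures(ids, (2, 5))
        assert len(mixtures) == 26  # 10 + 10 + 5 + 1

    def test_deterministic_order(self):
        ids = ["V", "P", "G"]
        labels = [m.label for m in enumerate_equimolar_mixtures(ids, (2, 3))]
        assert labels == ["G+P", "G+V", "P+V", "G+P+V"]

    def test_k_larger_than_panel_rejected(self):
        with pytest.raises(ValueError):
            enumerate_equimolar_mixtures(["P", "Ge"], (2, 3))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            enumerate_equimolar_mixtures(["P", "P", "G"], (2, 2))


class TestAnalyzerOnStudyData:
    def test_frap_100_panel(self, study_results):
        res = study_results.query("table == 3 and concentration_um == 100")
        assert len(res) == 26
        gentisic_binaries = res[(res["k"] == 2) & res["mixture"].str.contains("Ge")]
        assert len(gentisic_binaries) == 4
        assert set(gentisic_binaries["classification"]) == {"synergistic"}
        diffs = gentisic_binaries["difference_pct"].map(round_difference)
        assert diffs.between(28, 89).all()
        p_sy = res[res["mixture"] == "P+Sy"].iloc[0]
        assert p_sy["classification"] == "additive"
        assert round_difference(p_sy["difference_pct"]) == 4.0

    def test_orac_hydroxybenzoic_counts_on_printed_differences(self, fixtures):
        # classifying the printed difference cells of the hydroxybenzoic ORAC table
        printed = fixtures.mixtures.query("table == 5")["printed_difference"].astype(float)
        counts = printed.map(classify_interaction).value_counts().to_dict()
        assert counts == {"synergistic": 22, "additive": 2, "antagonistic": 2}

    def test_missing_individual_measurement_is_named(self, fixtures):
        analyzer = InteractionAnalyzer().fit(
            fixtures.individual_summary().query("analyte != 'Ge'")
        )
        with pytest.raises(KeyError, match=r"Ge.*FRAP.*100"):
            analyzer.transform(
                pd.DataFrame(
                    [{"analyte": "P+Ge", "assay": "FRAP", "concentration_um": 100.0, "mean": 520.0}]
                )
            )

    def test_empty_mixture_set_gives_empty_results(self, fixtures):
        out = analyze_panel(fixtures.individual_summary(), fixtures.mixture_summary().iloc[:0])
        assert out == []

    def test_duplicate_individuals_averaged_with_warning(self):
        ind = pd.DataFrame(
            [
                {"analyte": "A", "assay": "FRAP", "concentration_um": 100.0, "mean": 100.0},
                {"analyte": "A", "assay": "FRAP", "concentration_um": 100.0, "mean": 300.0},
                {"analyte": "B", "assay": "FRAP", "concentration_um": 100.0, "mean": 200.0},
            ]
        )
        mix = pd.DataFrame(
            [{"analyte": "A+B", "assay": "FRAP", "concentration_um": 100.0, "mean": 200.0}]
        )
        with pytest.warns(UserWarning, match="duplicate"):
            res = InteractionAnalyzer().fit(ind).transform(mix)
        assert res["theoretical"].iloc[0] == pytest.approx(200.0)  # (avg 200 + 200)/2
        assert res["difference_pct"].iloc[0] == pytest.approx(0.0)

    def test_predict_returns_labels(self, fixtures, fitted_analyzer):
        labels = fitted_analyzer.predict(fixtures.mixture_summary().head(5))
        assert set(labels) <= {"synergistic", "additive", "antagonistic"}

    def test_sklearn_params_roundtrip(self):
        a = InteractionAnalyzer(additive_band_pct=7.5)
        assert a.get_params()["additive_band_pct"] == 7.5
        a.set_params(additive_band_pct=3.0)
        assert a.additive_band_pct == 3.0

    def test_unfitted_transform_raises(self, fixtures):
        with pytest.raises(RuntimeError, match="not fitted"):
            InteractionAnalyzer().transform(fixtures.mixture_summary())


class TestConcentrationTrend:
    def test_ternary_trend_decreases_with_concentration(self, fixtures):
        # pC+C+R under FRAP: published differences 127 > 48 > 11
        results = analyze_panel(
            fixtures.individual_summary(),
            fixtures.mixture_summary().query("analyte == 'pC+C+R' and assay == 'FRAP'"),
        )
        trend = concentration_trend(results)
        assert trend.monotone_decrease
        concs = [p[0] for p in trend.points]
        assert concs == sorted(concs) == [100, 500, 1000]
        rounded = [round_difference(p[1]) for p in trend.points]
        assert rounded == [127, 48, 11]

    def test_constant_differences_are_not_a_decrease(self, fixtures):
        results = analyze_panel(
            fixtures.individual_summary(),
            fixtures.mixture_summary().query("analyte == 'pC+C+R' and assay == 'FRAP'"),
        )
        flat = [results[0], results[0], results[0]]
        flat = [
            type(r)(
                mixture=r.mixture, assay=r.assay, experimental=r.experimental,
                theoretical=r.theoretical, difference_pct=10.0,
                classification=r.classification,
            )
            for r in flat
        ]
        assert not concentration_trend(flat).monotone_decrease

    def test_single_concentration_rejected(self, fixtures):
        results = analyze_panel(
            fixtures.individual_summary(),
            fixtures.mixture_summary().query("analyte == 'pC+C+R' and concentration_um == 100"),
        )
        with pytest.raises(ValueError):
            concentration_trend(results)


class TestReportingConvention:
    @pytest.mark.parametrize(
        "d, text",
        [(80.56, "81"), (3.98, "4.0"), (-33.33, "-33"), (8.82, "8.8"), (-3.08, "-3.1"), (-0.5, "-0.5")],
    )
    def test_half_away_from_zero_with_mixed_precision(self, d, text):
        assert format_difference(d) == text
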