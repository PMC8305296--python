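"""Retention indices, PLS-DA, VID coefficients and discriminant selection."""

import numpy as np
import pandas as pd
import pytest

from instabean.chemometrics import (
    AlkaneLadder,
    PeakTable,
    biplot_coordinates,
    loo_class_accuracy,
    normalize_peaks,
    plsda_fit,
    retention_index,
    select_discriminants,
    total_peak_area,
    vid_coefficients,
)
from instabean.models import InvalidInputError
from instabean.simulate import PeakTableSimSpec, gen_peak_table


@pytest.fixture
def ladder():
    return AlkaneLadder(tuple(range(8, 23)), tuple(np.linspace(5.0, 41.0, 15)))


@pytest.fixture
def planted_table():
    return gen_peak_table(PeakTableSimSpec(seed=11))


class TestRetentionIndex:
    def test_exact_alkane_hits(self, ladder):
        for n, rt in zip(ladder.carbon_numbers, ladder.retention_times):
            assert retention_index(rt, ladder) == pytest.approx(100.0 * n)

    def test_midpoint_linearity(self):
        lad = AlkaneLadder((10, 11), (12.0, 14.0))
        assert retention_index(13.0, lad) == pytest.approx(1050.0)

    def test_worked_example(self):
        lad = AlkaneLadder((14, 15), (20.0, 22.0))
        assert retention_index(21.5, lad) == pytest.approx(1475.0)

    def test_out_of_span_requires_optin(self, ladder):
        with pytest.raises(InvalidInputError):
            retention_index(2.0, ladder)
        assert retention_index(2.0, ladder, extrapolate=True) < 800.0

    def test_invalid_ladder(self):
        with pytest.raises(InvalidInputError):
            AlkaneLadder((8, 9), (5.0, 5.0))


class TestNormalization:
    def test_quotients_hand_computed(self):
        areas = pd.DataFrame(
            {"V1": [2.0, 4.0], "V2": [6.0, 8.0], "IS": [2.0, 4.0]},
            index=["s1", "s2"],
        )
        table = PeakTable(areas, pd.Series(["a", "b"], index=["s1", "s2"]),
                          internal_standard="IS")
        out = normalize_peaks(table)
        assert list(out.areas.columns) == ["V1", "V2"]
        assert out.areas.loc["s1"].tolist() == [1.0, 3.0]
        assert out.areas.loc["s2"].tolist() == [1.0, 2.0]

    def test_joint_scaling_of_sample_is_removed(self):
        areas = pd.DataFrame(
            {"V1": [2.0, 4.0], "IS": [1.0, 2.0]}, index=["s1", "s2"]
        )
        table = PeakTable(areas, pd.Series(["a", "b"], index=["s1", "s2"]),
                          internal_standard="IS")
        out = normalize_peaks(table)
        assert out.areas["V1"].tolist() == [2.0, 2.0]

    def test_zero_is_area_rejected(self):
        areas = pd.DataFrame({"V1": [1.0], "IS": [0.0]}, index=["s1"])
        table = PeakTable(areas, pd.Series(["a"], index=["s1"]), internal_standard="IS")
        with pytest.raises(InvalidInputError):
            normalize_peaks(table)


class TestTotals:
    def test_row_sums_and_permutation_invariance(self, planted_table):
        totals, _ = total_peak_area(planted_table)
        shuffled = PeakTable(
            planted_table.areas[list(reversed(planted_table.areas.columns))],
            planted_table.classes,
        )
        totals2, _ = total_peak_area(shuffled)
        assert np.allclose(totals.values, totals2.values)

    def test_attenuated_class_flagged_lower(self):
        table = gen_peak_table(PeakTableSimSpec(seed=5, effect_size=0.0))
        areas = table.areas.copy()
        mask = (table.classes == "FD").to_numpy()
        areas.loc[mask] *= 0.2  # global attenuation of one class
        _, cmp_res = total_peak_area(PeakTable(areas, table.classes))
        others = [g for g in cmp_res.letters if g != "FD"]
        assert all(cmp_res.letters["FD"] != cmp_res.letters[g] for g in others)
        assert cmp_res.means["FD"] < min(cmp_res.means[g] for g in others)


class TestPlsda:
    def test_deterministic_refit(self, planted_table):
        m1 = plsda_fit(planted_table, n_lv=3)
        m2 = plsda_fit(planted_table, n_lv=3)
        assert np.allclose(m1.x_scores, m2.x_scores)
        assert np.allclose(m1.coef, m2.coef)

    def test_single_variable_separation(self):
        rng = np.random.default_rng(0)
        n = 12
        indicator = np.repeat([0.0, 1.0], n // 2)
        areas = pd.DataFrame(
            {
                "marker": 1e5 * (1.0 + 5.0 * indicator) * np.exp(rng.normal(0, 0.01, n)),
                **{f"noise{i}": 1e5 * np.exp(rng.normal(0, 0.3, n)) for i in range(8)},
            },
            index=[f"s{i}" for i in range(n)],
        )
        classes = pd.Series(np.where(indicator > 0, "treat", "ctrl"),
                            index=areas.index)
        model = plsda_fit(PeakTable(areas, classes), n_lv=1)
        scores = model.x_scores[:, 0]
        assert max(scores[:6]) < min(scores[6:]) or min(scores[:6]) > max(scores[6:])

    def test_explained_y_variance_accumulates(self, planted_table):
        model = plsda_fit(planted_table, n_lv=3)
        assert np.all(model.explained_y > 0)
        assert model.explained_y.sum() <= 1.0 + 1e-9

    def test_permuted_labels_accuracy_near_chance(self):
        table = gen_peak_table(PeakTableSimSpec(seed=21, effect_size=0.0,
                                                n_classes=2, n_samples_per_class=8))
        rng = np.random.default_rng(0)
        permuted = pd.Series(
            rng.permutation(table.classes.to_numpy()), index=table.classes.index
        )
        acc = loo_class_accuracy(PeakTable(table.areas, permuted), n_lv=2)
        # chance is 0.5; binomial 95% envelope for 16 draws is about [0.2, 0.8]
        assert 0.1 <= acc <= 0.85

    def test_constant_variable_dropped_with_warning(self, planted_table):
        areas = planted_table.areas.copy()
        areas["flat"] = 123.0
        with pytest.warns(UserWarning, match="constant"):
            model = plsda_fit(PeakTable(areas, planted_table.classes), n_lv=2)
        assert "flat" not in model.feature_names


class TestVid:
    def test_indicator_variable_has_unit_vid(self):
        rng = np.random.default_rng(1)
        n = 12
        indicator = np.repeat([0.0, 1.0], n // 2)
        areas = pd.DataFrame(
            {
                "marker": np.exp(indicator * 3.0),
                **{f"noise{i}": np.exp(rng.normal(0, 0.1, n)) for i in range(6)},
            },
            index=[f"s{i}" for i in range(n)],
        )
        classes = pd.Series(np.where(indicator > 0, "treat", "ctrl"), index=areas.index)
        table = PeakTable(areas, classes)
        # enough LVs that the membership reconstruction is exact: the marker
        # IS the (centred) class dummy, so its correlation with it is 1
        model = plsda_fit(table, n_lv=7)
        vid = vid_coefficients(model, table)
        assert vid.loc["marker", "treat"] == pytest.approx(1.0, abs=1e-3)
        assert vid.loc["marker", "ctrl"] == pytest.approx(-1.0, abs=1e-3)

    def test_bounded_in_unit_interval(self, planted_table):
        model = plsda_fit(planted_table, n_lv=3)
        vid = vid_coefficients(model, planted_table)
        assert (vid.values <= 1.0).all() and (vid.values >= -1.0).all()

    def test_invariant_to_multiplicative_rescaling(self, planted_table):
        model = plsda_fit(planted_table, n_lv=3)
        vid = vid_coefficients(model, planted_table)
        areas = planted_table.areas.copy()
        areas[areas.columns[0]] *= 37.5
        scaled = PeakTable(areas, planted_table.classes)
        model2 = plsda_fit(scaled, n_lv=3)
        vid2 = vid_coefficients(model2, scaled)
        assert np.allclose(vid.values, vid2.values, atol=1e-9)

    def test_invariant_to_affine_rescaling_without_log(self, planted_table):
        model = plsda_fit(planted_table, n_lv=3, log_transform=False)
        vid = vid_coefficients(model, planted_table)
        areas = planted_table.areas.copy()
        areas[areas.columns[0]] = areas[areas.columns[0]] * 2.5 + 1e4
        scaled = PeakTable(areas, planted_table.classes)
        model2 = plsda_fit(scaled, n_lv=3, log_transform=False)
        vid2 = vid_coefficients(model2, scaled)
        assert np.allclose(vid.values, vid2.values, atol=1e-9)

    def test_planted_discriminants_recovered(self, planted_table):
        spec = PeakTableSimSpec(seed=11)
        model = plsda_fit(planted_table, n_lv=3)
        vid = vid_coefficients(model, planted_table)
        for cls, idx in spec.default_discriminants().items():
            for i in idx:
                assert vid.loc[f"V{i + 1:03d}", cls] > 0.8


class TestSelection:
    def test_threshold_and_ordering(self):
        vid = pd.DataFrame({"treat": [0.95, 0.81, 0.79, -0.9]},
                           index=["v1", "v2", "v3", "v4"])
        report = select_discriminants(vid, threshold=0.8)
        assert report["variable"].tolist() == ["v1", "v2", "v4"]
        assert report["vid"].tolist() == [0.95, 0.81, -0.9]

    def test_empty_when_all_below(self):
        vid = pd.DataFrame({"treat": [0.5, -0.3]}, index=["v1", "v2"])
        assert select_discriminants(vid).empty

    def test_threshold_one_keeps_only_perfect(self):
        vid = pd.DataFrame({"treat": [1.0, 0.999]}, index=["v1", "v2"])
        report = select_discriminants(vid, threshold=1.0)
        assert report.empty  # strict inequality: |VID| > 1 never holds

    def test_retention_indices_attached(self, planted_table, ladder):
        model = plsda_fit(planted_table, n_lv=3)
        vid = vid_coefficients(model, planted_table)
        report = select_discriminants(
            vid, retention_times=planted_table.retention_times, ladder=ladder
        )
        assert "retention_index" in report.columns
        assert report["retention_index"].between(700, 2300).all()


class TestBiplot:
    def test_duplicated_samples_coincide(self, planted_table):
        areas = pd.concat([planted_table.areas, planted_table.areas.iloc[[0]]])
        areas.index = list(planted_table.areas.index) + ["dup"]
        classes = pd.concat(
            [planted_table.classes,
             pd.Series([planted_table.classes.iloc[0]], index=["dup"])]
        )
        table = PeakTable(areas, classes)
        model = plsda_fit(table, n_lv=2)
        coords = biplot_coordinates(model, table)
        first = coords["scores"].iloc[0].to_numpy()
        dup = coords["scores"].loc["dup"].to_numpy()
        assert np.allclose(first, dup)

    def test_correlation_loadings_inside_unit_circle(self, planted_table):
        model = plsda_fit(planted_table, n_lv=3)
        coords = biplot_coordinates(model, planted_table, lv_pair=(1, 2))
        radii = np.linalg.norm(coords["variable_correlations"].values, axis=1)
        assert np.all(radii <= 1.0 + 1e-9)
        assert coords["circle_radii"] == (0.7, 1.0)

    def test_lv_beyond_model_rejected(self, planted_table):
        model = plsda_fit(planted_table, n_lv=2)
        with pytest.raises(InvalidInputError):
            biplot_coordinates(model, planted_table, lv_pair=(1, 3))

    def test_null_variable_near_origin_discriminant_near_circle(self):
        spec = PeakTableSimSpec(seed=13, n_classes=2, n_samples_per_class=10)
        table = gen_peak_table(spec)
        model = plsda_fit(table, n_lv=2)
        coords = biplot_coordinates(model, table)
        rad = np.linalg.norm(coords["variable_correlations"].values, axis=1)
        rad = pd.Series(rad, index=coords["variable_correlations"].index)
        planted = [f"V{i + 1:03d}" for idx in spec.default_discriminants().values()
                   for i in idx]
        null = [v for v in rad.index if v not in planted]
        assert rad[planted].min() > 0.8
        assert np.median(rad[null]) < 0.5
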