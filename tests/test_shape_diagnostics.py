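import numpy as np
import pytest

import rocshape as rs
from conftest import curve_from_points

H = rs.Direction.HIGHER_PREDICTS_EVENT
L = rs.Direction.LOWER_PREDICTS_EVENT


class TestDiagonalCrossings:
    def test_proper_curve_has_no_crossings(self):
        curve = curve_from_points([(0, 0), (0, 1), (1, 1)])
        assert rs.diagonal_crossings(curve) == []

    def test_single_crossing_located_by_interpolation(self):
        # segment (0.5,0.25)-(0.75,0.9) meets y = x at fpr = 21/32
        curve = curve_from_points([(0, 0), (0.5, 0.25), (0.75, 0.9), (1, 1)])
        crossings = rs.diagonal_crossings(curve, tolerance=0.02)
        assert len(crossings) == 1
        assert crossings[0][0] == pytest.approx(0.65625, abs=1e-12)
        assert crossings[0][0] == crossings[0][1]

    def test_crossings_are_interior(self):
        curve = curve_from_points(
            [(0, 0), (0.2, 0.5), (0.55, 0.5), (0.6, 0.52), (1, 1)]
        )
        for f, t in rs.diagonal_crossings(curve):
            assert 0 < f < 1 and f == t

    def test_wobble_below_tolerance_not_reported(self):
        curve = curve_from_points(
            [(0, 0), (0.3, 0.31), (0.5, 0.495), (0.7, 0.71), (1, 1)]
        )
        assert rs.diagonal_crossings(curve, tolerance=0.02) == []

    def test_symmetric_u_simulation_has_exactly_one_crossing(self, symmetric_u_sample):
        curve = rs.empirical_roc(symmetric_u_sample, H)
        assert len(rs.diagonal_crossings(curve)) == 1

    def test_bad_tolerance(self):
        curve = curve_from_points([(0, 0), (1, 1)])
        with pytest.raises(rs.InputError):
            rs.diagonal_crossings(curve, tolerance=0.0)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "points, label",
        [
            ([(0, 0), (0.2, 0.6), (1, 1)], "proper_concave"),
            # touching the diagonal from above is still proper
            ([(0, 0), (0.1, 0.4), (0.5, 0.5), (0.9, 0.92), (1, 1)],
             "proper_concave"),
            # above first then below: logit-shaped, U-shaped-risk signature
            ([(0, 0), (0.1, 0.4), (0.6, 0.5), (0.9, 0.8), (1, 1)],
             "inverse_sigmoidal"),
            # below first then above: sigmoidal, inverted-U signature
            ([(0, 0), (0.4, 0.1), (0.5, 0.4), (0.6, 0.9), (1, 1)], "sigmoidal"),
            ([(0, 0), (0.5, 0.505), (1, 1)], "near_diagonal"),
            # two genuine crossings
            ([(0, 0), (0.1, 0.3), (0.5, 0.3), (0.6, 0.85), (0.97, 0.9), (1, 1)],
             "irregular"),
            # entirely below the diagonal
            ([(0, 0), (0.6, 0.2), (1, 1)], "irregular"),
        ],
    )
    def test_synthetic_curves(self, points, label):
        assert rs.classify_shape(curve_from_points(points)).label == label

    def test_u_shaped_simulation_is_inverse_sigmoidal(self, symmetric_u_sample):
        report = rs.classify_shape(rs.empirical_roc(symmetric_u_sample, H))
        assert report.label == "inverse_sigmoidal"
        assert len(report.crossings) == 1

    def test_inverted_u_simulation_is_sigmoidal(self):
        s = rs.simulate_dataset(rs.preset_model("inverted_u_500"), 5000, 6)
        assert rs.classify_shape(rs.empirical_roc(s, H)).label == "sigmoidal"

    def test_centering_restores_proper_concavity(self, symmetric_u_sample):
        centered = symmetric_u_sample.with_values(symmetric_u_sample.values ** 2)
        assert rs.classify_shape(rs.empirical_roc(centered, H)).label == "proper_concave"

    def test_mirror_swaps_sigmoidal_classes(self):
        points = [(0, 0), (0.1, 0.4), (0.6, 0.5), (0.9, 0.8), (1, 1)]
        curve = curve_from_points(points)
        mirrored = curve_from_points([(t, f) for f, t in points])
        assert rs.classify_shape(curve).label == "inverse_sigmoidal"
        assert rs.classify_shape(mirrored).label == "sigmoidal"

    def test_direction_flip_rotates_curve_and_preserves_class(self):
        """Reversing orientation rotates the ROC 180 degrees about (1/2, 1/2),
        which preserves the above-then-below excursion sequence: a U-shaped
        predictor is inverse-sigmoidal whichever way it is oriented."""
        s = rs.simulate_dataset(rs.symmetric_u_model(), 4000, 9)
        c_hi = rs.empirical_roc(s, H)
        c_lo = rs.empirical_roc(s, L)
        # rotation identity on the vertex sets (continuous values, no ties)
        rot = set(zip(np.round(1 - c_hi.fpr, 12), np.round(1 - c_hi.tpr, 12)))
        pts = set(zip(np.round(c_lo.fpr, 12), np.round(c_lo.tpr, 12)))
        assert pts == rot
        assert rs.classify_shape(c_hi).label == rs.classify_shape(c_lo).label == "inverse_sigmoidal"
        s2 = rs.simulate_dataset(rs.preset_model("inverted_u_500"), 4000, 9)
        assert (
            rs.classify_shape(rs.empirical_roc(s2, H)).label
            == rs.classify_shape(rs.empirical_roc(s2, L)).label
            == "sigmoidal"
        )

    def test_report_invariants(self, symmetric_u_sample):
        report = rs.classify_shape(rs.empirical_roc(symmetric_u_sample, H))
        assert report.max_excursion_above >= 0
        assert report.max_excursion_below >= 0
        for f, t in report.crossings:
            assert f == t and 0 < f < 1


class TestLikelihoodRatios:
    def test_cumulative_ratios_at_known_point(self):
        curve = curve_from_points([(0, 0), (0.2, 0.6), (1, 1)])
        table = rs.likelihood_ratios(curve)
        row = table.iloc[1]
        assert row.cum_lr_pos == pytest.approx(3.0)
        assert row.cum_lr_neg == pytest.approx(0.5)

    def test_interval_lr_is_segment_slope(self):
        curve = curve_from_points([(0, 0), (0.1, 0.4), (0.3, 0.5), (1, 1)])
        table = rs.likelihood_ratios(curve)
        assert table.interval_lr.iloc[2] == pytest.approx(0.5)  # 0.1 / 0.2

    def test_vertex_on_diagonal_has_unit_ratios(self):
        curve = curve_from_points([(0, 0), (0.1, 0.4), (0.6, 0.6), (0.9, 0.8), (1, 1)])
        table = rs.likelihood_ratios(curve)
        row = table.iloc[2]
        assert row.cum_lr_pos == pytest.approx(1.0)
        assert row.cum_lr_neg == pytest.approx(1.0)

    def test_undefined_and_infinite_markers(self):
        curve = curve_from_points([(0, 0), (0, 0.5), (0.5, 0.5), (1, 1)])
        table = rs.likelihood_ratios(curve)
        assert np.isnan(table.cum_lr_pos.iloc[0])  # 0/0 at the origin
        assert np.isinf(table.cum_lr_pos.iloc[1])  # TPR > 0 at FPR = 0
        assert np.isnan(table.interval_lr.iloc[0])  # no segment before first point
        assert np.isinf(table.interval_lr.iloc[1])  # vertical rise
        assert table.interval_lr.iloc[2] == 0.0  # horizontal run

    def test_proper_curve_has_useful_ratios_everywhere(self, separable_sample):
        curve = rs.empirical_roc(separable_sample, H)
        table = rs.likelihood_ratios(curve)
        pos = table.cum_lr_pos.dropna()
        neg = table.cum_lr_neg.dropna()
        assert (pos[np.isfinite(pos)] >= 1.0 - 1e-12).all()
        assert (neg[np.isfinite(neg)] <= 1.0 + 1e-12).all()

    def test_interval_lr_mass_sums_to_unit_tpr_span(self, symmetric_u_sample):
        curve = rs.empirical_roc(symmetric_u_sample, H)
        table = rs.likelihood_ratios(curve)
        dfpr = np.diff(curve.fpr)
        dtpr = np.diff(curve.tpr)
        seg = table.interval_lr.to_numpy()[1:]
        finite = np.isfinite(seg)
        # vertical segments contribute their TPR rise directly
        total = np.sum(seg[finite] * dfpr[finite]) + np.sum(dtpr[~finite])
        assert total == pytest.approx(1.0, abs=1e-9)
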