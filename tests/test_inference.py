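import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rocshape as rs

H = rs.Direction.HIGHER_PREDICTS_EVENT
L = rs.Direction.LOWER_PREDICTS_EVENT


class TestHanleyMcneilSe:
    @pytest.mark.parametrize(
        "auroc, m, n, expected",
        [
            (1.0, 5, 9, 0.0),
            (0.0, 5, 9, 0.0),
            # A=0.5: Q1=Q2=1/3; m=n=1: SE^2 = 0.25
            (0.5, 1, 1, 0.5),
            # m=n=10: SE^2 = (0.25 + 18/12)/100 = 0.0175
            (0.5, 10, 10, pytest.approx(np.sqrt(0.0175))),
        ],
    )
    def test_known_values(self, auroc, m, n, expected):
        assert rs.hanley_mcneil_se(auroc, m, n) == expected

    def test_domain_errors(self):
        with pytest.raises(rs.InputError):
            rs.hanley_mcneil_se(1.2, 5, 5)
        with pytest.raises(rs.InputError):
            rs.hanley_mcneil_se(0.5, 0, 5)

    @given(
        # milli-unit grid: the identity is exact in real arithmetic but
        # cancels catastrophically in floats as A approaches 0 or 1
        a_milli=st.integers(1, 999),
        m=st.integers(1, 500),
        n=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_class_relabelling_symmetry(self, a_milli, m, n):
        """Swapping event and non-event classes flips A and swaps the counts;
        the SE must be invariant under that relabelling (it is NOT symmetric
        in A alone)."""
        a = a_milli / 1000.0
        assert rs.hanley_mcneil_se(a, m, n) == pytest.approx(
            rs.hanley_mcneil_se(1.0 - a, n, m), rel=1e-9
        )
        assert rs.hanley_mcneil_se(0.0, m, n) == rs.hanley_mcneil_se(1.0, n, m) == 0.0

    def test_bootstrap_cross_check_on_null_sample(self):
        """HM SE at A~0.5 tracks a stratified bootstrap SE."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=200)
        labels = np.r_[np.ones(80, int), np.zeros(120, int)]
        s = rs.BinaryOutcomeSample(values, labels)
        a = rs.auroc_mann_whitney(s, H)
        hm = rs.hanley_mcneil_se(a, 80, 120)
        pos, neg = values[labels == 1], values[labels == 0]
        boots = []
        for _ in range(2000):
            bs = rs.BinaryOutcomeSample(
                np.r_[rng.choice(pos, 80), rng.choice(neg, 120)], labels
            )
            boots.append(rs.auroc_mann_whitney(bs, H))
        assert hm == pytest.approx(np.std(boots, ddof=1), rel=0.15)


class TestAurocEstimate:
    def test_perfect_separation_degenerates_with_warning(self, separable_sample):
        with pytest.warns(rs.DegenerateCIWarning):
            est = rs.auroc_estimate(separable_sample, H)
        assert (est.auroc, est.se, est.ci_low, est.ci_high) == (1.0, 0.0, 1.0, 1.0)

    def test_formula_plug_in(self, alternating_sample):
        est = rs.auroc_estimate(alternating_sample, H, alpha=0.05)
        assert est.auroc == 0.75
        assert est.se == pytest.approx(rs.hanley_mcneil_se(0.75, 2, 2))
        assert 0.0 <= est.ci_low <= est.auroc <= est.ci_high <= 1.0
        assert (est.n_pos, est.n_neg) == (2, 2)

    def test_interval_clipped_to_unit_range(self):
        # A = 0.8 with tiny counts: the unclipped Wald upper limit exceeds 1
        s = rs.BinaryOutcomeSample(
            np.array([2.0, 1, 3, 4, 5, 6]), np.array([0, 1, 1, 1, 1, 1])
        )
        est = rs.auroc_estimate(s, H)
        assert est.auroc == 0.8
        assert est.auroc + 1.96 * est.se > 1.0
        assert est.ci_high == 1.0

    def test_wald_interval_coverage_under_null(self):
        """~95% of null-sample intervals should cover 0.5."""
        rng = np.random.default_rng(99)
        covered = 0
        reps = 300
        for _ in range(reps):
            values = rng.normal(size=400)
            labels = (rng.random(400) < 0.3).astype(int)
            if labels.min() == labels.max():
                continue
            est = rs.auroc_estimate(rs.BinaryOutcomeSample(values, labels), H)
            covered += est.ci_low <= 0.5 <= est.ci_high
        assert 0.90 <= covered / reps <= 0.99

    def test_bad_alpha(self, alternating_sample):
        with pytest.raises(rs.InputError):
            rs.auroc_estimate(alternating_sample, H, alpha=1.5)


class TestComparePairedAurocs:
    def test_self_comparison_is_null(self, alternating_sample):
        v = alternating_sample.values
        r = rs.compare_paired_aurocs(v, v.copy(), alternating_sample.labels)
        assert (r.diff, r.z, r.p) == (0.0, 0.0, 1.0)

    def test_monotone_rescoring_gives_zero_diff(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=300)
        y = (rng.random(300) < 0.4).astype(int)
        r = rs.compare_paired_aurocs(v, np.exp(v), y)
        assert r.diff == 0.0 and r.p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(rs.InputError, match="mismatch"):
            rs.compare_paired_aurocs([1.0, 2], [1.0, 2, 3], [0, 1])

    def test_degenerate_labels(self):
        with pytest.raises(rs.DegenerateSampleError):
            rs.compare_paired_aurocs([1.0, 2], [2.0, 1], [1, 1])

    def test_unknown_method(self):
        with pytest.raises(rs.InputError, match="method"):
            rs.compare_paired_aurocs([1.0, 2], [2.0, 1], [0, 1], method="exact")

    @pytest.mark.parametrize("method", ["hanley_mcneil", "delong", "bootstrap"])
    def test_result_invariants(self, method):
        rng = np.random.default_rng(8)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-x))).astype(int)
        noisy = x + rng.normal(scale=1.5, size=400)
        r = rs.compare_paired_aurocs(
            x, noisy, y, method=method, seed=5, n_boot=400
        )
        assert r.diff == pytest.approx(r.auroc_b - r.auroc_a)
        assert r.ci_low <= r.diff <= r.ci_high
        assert 0.0 <= r.p <= 1.0
        assert -1.0 <= r.r <= 1.0
        if method == "hanley_mcneil":
            se_a = rs.hanley_mcneil_se(r.auroc_a, int(y.sum()), int((1 - y).sum()))
            se_b = rs.hanley_mcneil_se(r.auroc_b, int(y.sum()), int((1 - y).sum()))
            assert r.se_diff <= se_a + se_b + 1e-12

    def test_hanley_and_delong_agree_on_large_samples(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=4000)
        y = (rng.random(4000) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        b = 0.7 * x + rng.normal(scale=0.8, size=4000)
        r_hm = rs.compare_paired_aurocs(x, b, y, method="hanley_mcneil")
        r_dl = rs.compare_paired_aurocs(x, b, y, method="delong")
        assert r_hm.z == pytest.approx(r_dl.z, rel=0.10)

    def test_p_value_matches_paired_bootstrap_on_ph_like_data(self):
        """Raw vs median-centered pH-like comparison: the analytic p-value
        and a 2000-replicate paired-bootstrap p-value agree closely."""
        s = rs.simulate_dataset(rs.preset_model("ph_like"), 5000, 11)
        centered = rs.apply_transform(
            s.values,
            rs.TransformSpec("center_square", float(np.median(s.values))),
        )
        r_hm = rs.compare_paired_aurocs(
            s.values, centered, s.labels, direction_a=L, direction_b=H
        )
        r_bs = rs.compare_paired_aurocs(
            s.values, centered, s.labels, direction_a=L, direction_b=H,
            method="bootstrap", n_boot=2000, seed=17,
        )
        assert abs(r_hm.p - r_bs.p) < 0.02


class TestPlacementValues:
    def test_both_sides_average_to_auroc(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=300)
        y = (rng.random(300) < 0.4).astype(int)
        s = rs.BinaryOutcomeSample(v, y)
        a = rs.auroc_mann_whitney(s, H)
        v10, v01 = rs.placement_values(v, y)
        assert np.mean(v10) == pytest.approx(a, abs=1e-12)
        assert np.mean(v01) == pytest.approx(a, abs=1e-12)
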