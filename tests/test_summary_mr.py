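import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomr import (
    InsufficientInstrumentsError,
    ScenarioConfig,
    VariantSummary,
    ivw,
    minus_half_correction,
    mr_egger,
    per_variant_summaries,
    simulate_trio_cohort,
    tsls,
    weighted_median,
)
from triomr.summary_mr import (
    DegenerateRegressionError,
    read_summaries,
    summaries_from_frame,
    summaries_to_frame,
    write_summaries,
)


def make_summaries(beta_x, beta_y, se_x=0.01, se_y=0.01):
    return [
        VariantSummary(j, bx, se_x, by, se_y)
        for j, (bx, by) in enumerate(zip(beta_x, beta_y))
    ]


def wls_oracle(bx, by, w):
    """Independent weighted-least-squares fit (intercept + slope)."""
    X = np.column_stack([np.ones_like(bx), bx])
    W = np.diag(w)
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
    return coef  # (intercept, slope)


class TestVariantSummary:
    def test_orientation_flips_jointly(self):
        s = VariantSummary(0, -0.2, 0.01, 0.04, 0.02)
        o = s.orient()
        assert o.beta_x == 0.2 and o.beta_y == -0.04 and o.oriented

    def test_positive_se_required(self):
        with pytest.raises(ValueError):
            VariantSummary(0, 0.1, 0.0, 0.1, 0.01)

    def test_round_trip_text(self, tmp_path):
        s = make_summaries([0.1, 0.2], [0.01, 0.05])
        path = tmp_path / "summaries.tsv"
        write_summaries(s, path)
        back = read_summaries(path)
        assert [v.beta_x for v in back] == [0.1, 0.2]


class TestIVW:
    def test_shared_ratio_recovered_exactly(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        assert ivw(s).beta == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_two_variant_slope(self):
        # equal se_y: slope = sum(bx*by) / sum(bx^2) = (0.001+0.004)/(0.01+0.04)
        s = make_summaries([0.1, 0.2], [0.01, 0.02])
        assert ivw(s).beta == pytest.approx(0.1, abs=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_summaries([0.1], [0.01]))

    def test_orientation_invariance(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.01, 0.06, 0.03])
        flipped = [
            VariantSummary(v.variant_index, -v.beta_x, v.se_x, -v.beta_y, v.se_y)
            if v.variant_index == 1 else v
            for v in s
        ]
        assert ivw(flipped).beta == pytest.approx(ivw(s).beta, abs=1e-12)


class TestMREgger:
    def test_exact_proportionality_gives_zero_intercept(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.03, 0.06, 0.09])
        intercept, slope = mr_egger(s)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)

    def test_constant_pleiotropy_recovered(self):
        # beta_y = a + c * beta_x exactly; WLS oracle gives the same fit
        bx = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        a, c = 0.02, 0.25
        by = a + c * bx
        s = make_summaries(bx, by)
        intercept, slope = mr_egger(s)
        oracle = wls_oracle(bx, by, np.full(5, 1e4))
        assert intercept.beta == pytest.approx(oracle[0], abs=1e-10)
        assert slope.beta == pytest.approx(oracle[1], abs=1e-10)
        assert intercept.beta == pytest.approx(a, abs=1e-10)
        assert slope.beta == pytest.approx(c, abs=1e-10)

    def test_weighted_fit_matches_wls_oracle(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.4, 10)
        by = 0.01 + 0.2 * bx + rng.normal(0, 0.005, 10)
        se_y = rng.uniform(0.005, 0.02, 10)
        s = [VariantSummary(j, bx[j], 0.01, by[j], se_y[j]) for j in range(10)]
        intercept, slope = mr_egger(s)
        oracle = wls_oracle(bx, by, 1 / se_y**2)
        assert intercept.beta == pytest.approx(oracle[0], abs=1e-10)
        assert slope.beta == pytest.approx(oracle[1], abs=1e-10)

    def test_overdispersion_floor(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.03, 0.06, 0.09])
        _, slope = mr_egger(s)
        assert slope.metadata["overdispersion"] >= 1.0

    def test_too_few_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_summaries([0.1, 0.2], [0.01, 0.02]))

    def test_zero_spread_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            mr_egger(make_summaries([0.2, 0.2, 0.2], [0.01, 0.02, 0.03]))

    def test_directional_pleiotropy_null_ivw_biased_egger_not(self):
        # synthetic null: every variant has the same direct outcome effect a,
        # no causal path; InSIDE holds by construction
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.4, 30)
        a = 0.03
        by = a + rng.normal(0, 1e-4, 30)
        s = make_summaries(bx, by, se_y=0.01)
        assert abs(ivw(s).beta) > 0.05          # biased away from 0
        intercept, slope = mr_egger(s)
        assert slope.beta == pytest.approx(0.0, abs=0.01)
        assert intercept.beta == pytest.approx(a, abs=0.005)


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.02, 0.04, 0.06])
        assert weighted_median(s, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_equal_weight_interpolation_oracle(self):
        # ratios (1, 2, 3), equal weights -> midpoint CDF (1/6, 1/2, 5/6);
        # interpolating at 0.5 gives exactly 2
        s = [
            VariantSummary(0, 0.1, 0.01, 0.1, 0.01),
            VariantSummary(1, 0.1, 0.01, 0.2, 0.01),
            VariantSummary(2, 0.1, 0.01, 0.3, 0.01),
        ]
        assert weighted_median(s, n_boot=50, seed=0).beta == pytest.approx(2.0)

    def test_unequal_weight_interpolation_oracle(self):
        # brute-force interpolation of the weighted ECDF:
        # weights (bx/se_y)^2 proportional to (1, 1, 4) for se_y (1,1,0.5)*bx
        # ratios (1, 2, 3): normalized w = (1/6, 1/6, 4/6),
        # midpoint cdf = (1/12, 3/12, 8/12); interp at 0.5 -> 2 + (0.5-0.25)/(5/12)
        s = [
            VariantSummary(0, 0.1, 0.01, 0.1, 0.01),
            VariantSummary(1, 0.1, 0.01, 0.2, 0.01),
            VariantSummary(2, 0.1, 0.01, 0.3, 0.005),
        ]
        expected = 2 + (0.5 - 0.25) / (5 / 12)
        assert weighted_median(s, n_boot=50, seed=0).beta == pytest.approx(expected)

    def test_majority_valid_weight_recovers_effect(self):
        # 60% of weight valid (ratio 0.1), 40% strongly pleiotropic
        rng = np.random.default_rng(11)
        valid_bx = rng.uniform(0.1, 0.3, 12)
        s = make_summaries(
            np.concatenate([valid_bx, rng.uniform(0.1, 0.3, 8)]),
            np.concatenate([0.1 * valid_bx, rng.uniform(0.2, 0.4, 8)]),
        )
        est = weighted_median(s, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.1, abs=0.02)

    def test_duplication_invariance(self):
        # splitting the median-carrying variant into two copies at half
        # weight (variance doubled) leaves the weighted ECDF -- and hence
        # the estimate -- unchanged
        s = [
            VariantSummary(0, 0.1, 0.01, 0.1, 0.01),
            VariantSummary(1, 0.1, 0.01, 0.2, 0.01),
            VariantSummary(2, 0.1, 0.01, 0.3, 0.01),
        ]
        half = 0.01 * np.sqrt(2)
        split = [
            s[0],
            VariantSummary(1, 0.1, 0.01, 0.2, half),
            VariantSummary(3, 0.1, 0.01, 0.2, half),
            s[2],
        ]
        a = weighted_median(s, n_boot=50, seed=3).beta
        b = weighted_median(split, n_boot=50, seed=3).beta
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(2.0, abs=1e-12)

    def test_bootstrap_se_reproducible(self):
        s = make_summaries([0.1, 0.2, 0.3], [0.01, 0.06, 0.03])
        a = weighted_median(s, n_boot=200, seed=9)
        b = weighted_median(s, n_boot=200, seed=9)
        assert a.se == b.se > 0


class TestDegenerateAgreement:
    def test_all_estimators_agree_on_equal_ratios(self):
        s = make_summaries([0.08, 0.15, 0.22, 0.3], [0.04, 0.075, 0.11, 0.15])
        c = 0.5
        assert ivw(s).beta == pytest.approx(c, abs=1e-10)
        _, slope = mr_egger(s)
        assert slope.beta == pytest.approx(c, abs=1e-10)
        assert weighted_median(s, n_boot=50, seed=0).beta == pytest.approx(c, abs=1e-10)


class TestMinusHalfCorrection:
    def test_printed_table_shift(self):
        base = tsls_like(beta=0.60, ci=(0.37, 0.82))
        corrected = minus_half_correction(base)
        assert corrected.beta == pytest.approx(0.10, abs=1e-12)
        assert corrected.ci_low == pytest.approx(-0.13, abs=1e-12)
        assert corrected.ci_high == pytest.approx(0.32, abs=1e-12)
        assert corrected.se == base.se
        assert "minus_0.5" in corrected.metadata["correction"]

    def test_half_shifts_to_zero(self):
        corrected = minus_half_correction(tsls_like(beta=0.5, ci=(0.3, 0.7)))
        assert corrected.beta == pytest.approx(0.0)

    def test_applicability_recorded_not_enforced(self):
        corrected = minus_half_correction(tsls_like(beta=1.0, ci=(0.5, 1.5)))
        assert "applicability" in corrected.metadata


def tsls_like(beta, ci):
    from triomr.estimators import IVEstimate

    return IVEstimate(
        method_label="unadjusted",
        beta=beta,
        se=(ci[1] - ci[0]) / (2 * 1.96),
        ci_low=ci[0],
        ci_high=ci[1],
        n_used=1000,
        first_stage_F=50.0,
    )


@pytest.fixture(scope="module")
def valid_cohort():
    cfg = ScenarioConfig(
        n_trios=30000, n_variants=12, q_x=0.05, gamma=0.15, v_o=0.0, seed=23
    )
    return simulate_trio_cohort(cfg, 0)


class TestPerVariantSummaries:
    def test_mean_ratio_recovers_gamma_when_valid(self, valid_cohort):
        with pytest.warns(UserWarning, match="internal"):
            s = per_variant_summaries(valid_cohort, adjust_offspring=False)
        ratios = [v.ratio for v in s]
        assert np.mean(ratios) == pytest.approx(0.15, abs=0.08)
        assert ivw(s).beta == pytest.approx(0.15, abs=0.04)

    def test_orientation_applied(self, valid_cohort):
        with pytest.warns(UserWarning, match="internal"):
            s = per_variant_summaries(valid_cohort)
        assert all(v.beta_x >= 0 and v.oriented for v in s)

    def test_external_weights_no_warning(self, valid_cohort):
        import warnings

        with pytest.warns(UserWarning, match="internal"):
            frame = summaries_to_frame(per_variant_summaries(valid_cohort))
        ext = frame[["variant", "beta_x", "se_x"]]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            per_variant_summaries(valid_cohort, external_beta_x=ext)

    def test_same_trait_unadjusted_ratio_biased_by_half(self):
        # same-trait design: matched panels/weights, v_o = q_x; without
        # offspring adjustment the mean ratio converges to gamma + 0.5
        cfg = ScenarioConfig(
            n_trios=60000, n_variants=12, q_x=0.02, v_o=0.02, gamma=0.1, seed=29
        )
        cohort = simulate_trio_cohort(cfg, 0)
        with pytest.warns(UserWarning, match="internal"):
            unadj = per_variant_summaries(cohort, adjust_offspring=False)
            adj = per_variant_summaries(cohort, adjust_offspring=True)
        assert ivw(unadj).beta == pytest.approx(0.6, abs=0.08)
        # InSIDE restored by conditioning on the offspring variant
        assert ivw(adj).beta == pytest.approx(0.1, abs=0.08)

    def test_monomorphic_variant_excluded(self, valid_cohort):
        cohort = valid_cohort
        mono = cohort.maternal_transmitted.copy()
        mono[:, 0] = 0
        patched = type(cohort)(
            maternal_transmitted=mono,
            maternal_nontransmitted=np.zeros_like(mono),
            paternal_transmitted=cohort.paternal_transmitted,
            paternal_nontransmitted=cohort.paternal_nontransmitted,
            G_m=cohort.G_m, G_o=cohort.G_o, G_p=cohort.G_p,
            G_t=cohort.G_t, G_nt=cohort.G_nt, C=cohort.C,
            X_m=cohort.X_m, Y_o=cohort.Y_o, config=cohort.config,
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            s = per_variant_summaries(patched, adjust_offspring=False)
        assert len(s) == cohort.n_variants - 1


@given(
    data=st.lists(
        st.tuples(
            st.floats(0.02, 0.5), st.floats(-0.2, 0.2),
            st.floats(0.005, 0.05), st.floats(0.005, 0.05),
        ),
        min_size=3,
        max_size=12,
    ),
    flips=st.lists(st.booleans(), min_size=12, max_size=12),
)
@settings(max_examples=25, deadline=None)
def test_estimators_invariant_to_allele_coding(data, flips):
    s = [
        VariantSummary(j, bx, sx, by, sy)
        for j, (bx, by, sx, sy) in enumerate(data)
    ]
    flipped = [
        VariantSummary(v.variant_index, -v.beta_x, v.se_x, -v.beta_y, v.se_y)
        if flips[v.variant_index] else v
        for v in s
    ]
    assert ivw(flipped).beta == pytest.approx(ivw(s).beta, abs=1e-9)
    if len({round(v.beta_x, 12) for v in s}) > 1:
        _, slope_a = mr_egger(s)
        _, slope_b = mr_egger(flipped)
        assert slope_b.beta == pytest.approx(slope_a.beta, abs=1e-9)
    wm_a = weighted_median(s, n_boot=10, seed=0).beta
    wm_b = weighted_median(flipped, n_boot=10, seed=0).beta
    assert wm_b == pytest.approx(wm_a, abs=1e-9)
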