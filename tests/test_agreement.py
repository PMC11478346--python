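import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sprintavp as sp
from sprintavp.agreement import MDC95_FACTOR
from sprintavp.errors import (
    InputError,
    InsufficientDataError,
    NumericalDomainError,
)

finite_pcts = st.lists(
    st.floats(min_value=-50, max_value=50), min_size=2, max_size=20
)


class TestPercentDiff:
    @pytest.mark.parametrize(
        "device,criterion,expected",
        [(10.5, 10.0, 5.0), (10.0, 10.0, 0.0), (9.5, 10.0, -5.0)],
    )
    def test_values(self, device, criterion, expected):
        assert sp.percent_diff(device, criterion) == pytest.approx(expected)

    def test_nonpositive_criterion_rejected(self):
        with pytest.raises(InputError):
            sp.percent_diff(1.0, 0.0)


class TestBiasAndMad:
    def test_bias_examples(self):
        assert sp.percent_bias([5.0, -5.0]) == 0.0
        assert sp.percent_bias([2.0, 4.0]) == 3.0
        assert sp.percent_bias([7.0]) == 7.0

    def test_mad_centered_examples(self):
        assert sp.percent_mad([5.0, 5.0, 5.0]) == 0.0
        assert sp.percent_mad([2.0, 4.0]) == 1.0
        assert sp.percent_mad([-5.0, 5.0]) == 5.0

    def test_mad_raw_mode(self):
        assert sp.percent_mad([-5.0, 5.0], mode="raw") == 5.0
        assert sp.percent_mad([2.0, 4.0], mode="raw") == 3.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            sp.percent_bias([])
        with pytest.raises(InputError):
            sp.percent_mad([])

    @given(diffs=finite_pcts, shift=st.floats(min_value=-20, max_value=20))
    def test_mad_invariant_to_constant_shift(self, diffs, shift):
        shifted = [d + shift for d in diffs]
        assert sp.percent_mad(shifted) == pytest.approx(
            sp.percent_mad(diffs), abs=1e-9
        )

    @given(
        device=st.lists(
            st.floats(min_value=1.0, max_value=20.0), min_size=2, max_size=15
        ),
        c=st.floats(min_value=-0.5, max_value=0.5),
    )
    def test_bias_under_multiplicative_device_scaling(self, device, c):
        """Scaling all device values by (1+c) maps %Bias b to (1+c)b + 100c;
        in particular perfect agreement moves to exactly 100c."""
        criterion = np.full(len(device), 10.0)
        b = sp.percent_bias(sp.percent_diff(np.array(device), criterion))
        b_scaled = sp.percent_bias(
            sp.percent_diff(np.array(device) * (1 + c), criterion)
        )
        assert b_scaled == pytest.approx((1 + c) * b + 100 * c, abs=1e-8)


class TestPercentRSE:
    def test_hand_computed_fixture(self):
        # frozen from an explicit closed-form OLS + percentised-residual oracle
        crit = [10.0, 11.0, 12.0, 13.0]
        dev = [9.8, 11.3, 11.9, 13.2]
        assert sp.percent_rse(crit, dev) == pytest.approx(2.3636149965, abs=1e-8)

    def test_exact_line_gives_zero(self):
        crit = np.array([8.0, 9.0, 10.0, 11.0])
        assert sp.percent_rse(crit, 1.02 * crit + 0.3) == pytest.approx(0.0, abs=1e-10)

    def test_two_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            sp.percent_rse([10.0, 11.0], [10.0, 11.0])

    def test_nonpositive_fitted_values_rejected(self):
        with pytest.raises(NumericalDomainError):
            sp.percent_rse([1.0, 2.0, 3.0], [5.0, 0.01, -5.0])


class TestMDC95:
    def test_values(self):
        assert sp.mdc95(0.0) == 0.0
        assert sp.mdc95(1.0) == pytest.approx(2.7718585822, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            sp.mdc95(-0.1)

    @given(
        a=st.floats(min_value=0, max_value=100),
        b=st.floats(min_value=0, max_value=100),
    )
    def test_monotone_and_exact_ratio(self, a, b):
        if a < b:
            assert sp.mdc95(a) < sp.mdc95(b)
        if a > 0:
            assert sp.mdc95(a) / a == pytest.approx(MDC95_FACTOR, rel=1e-12)


class TestBootstrapBCa:
    def test_constant_data_zero_width(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = sp.bootstrap_bca(np.mean, np.full(10, 3.0), seed=0)
        assert lo == hi == 3.0

    def test_seed_reproducibility(self, rng):
        x = rng.normal(0, 1, 25)
        a = sp.bootstrap_bca(np.mean, x, n_resamples=1000, seed=42)
        b = sp.bootstrap_bca(np.mean, x, n_resamples=1000, seed=42)
        assert a == b

    def test_endpoint_stability_across_seeds(self, rng):
        """Monte-Carlo wobble of the endpoints over independent resampling
        streams stays well under the interval width."""
        x = rng.normal(10, 2, 30)
        stat = lambda d, axis=-1: np.mean(d, axis=axis)
        los, his = [], []
        for seed in range(20):
            lo, hi = sp.bootstrap_bca(
                stat, x, n_resamples=5000, seed=seed, vectorized=True
            )
            los.append(lo)
            his.append(hi)
        width = np.mean(his) - np.mean(los)
        assert np.std(los) < 0.1 * width
        assert np.std(his) < 0.1 * width

    def test_interval_brackets_point_estimate(self, rng):
        x = rng.normal(5, 1, 40)
        lo, hi = sp.bootstrap_bca(np.mean, x, n_resamples=2000, seed=1)
        assert lo <= np.mean(x) <= hi

    def test_resamples_rows_of_2d_units(self, rng):
        pairs = np.column_stack([rng.uniform(8, 10, 20), rng.uniform(8, 10, 20)])
        lo, hi = sp.bootstrap_bca(
            lambda u: np.mean(u[:, 1] - u[:, 0]), pairs, n_resamples=500, seed=3
        )
        assert lo < hi


class TestClassifyPractical:
    @pytest.mark.parametrize(
        "ci,expected",
        [((-1, 2), "within"), ((3, 7), "overlapping"), ((6, 9), "outside")],
    )
    def test_symmetric_band(self, ci, expected):
        assert sp.classify_practical(ci) == expected

    def test_nonnegative_band(self):
        assert sp.classify_practical((0.5, 4.0), nonnegative=True) == "within"
        assert sp.classify_practical((4.0, 6.0), nonnegative=True) == "overlapping"
        assert sp.classify_practical((5.5, 9.0), nonnegative=True) == "outside"


class TestAgreementReport:
    def test_perfect_agreement_all_zero_and_within(self):
        values = np.array([8.5, 9.0, 9.5, 10.0, 8.8])
        pair = sp.PairedEstimates(
            parameter="MSS",
            method="time_velocity",
            criterion=values,
            device=values.copy(),
            unit_ids=np.arange(5),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            report = sp.agreement_report([pair], n_resamples=200, seed=0)
        assert np.allclose(report["estimate"], 0.0)
        assert (report["practical_flag"] == "within").all()

    def test_mdc_interval_is_scaled_rse_interval(self, rng):
        crit = rng.uniform(8, 10, 15)
        pair = sp.PairedEstimates(
            parameter="MSS",
            method="time_velocity",
            criterion=crit,
            device=crit * (1 + rng.normal(0, 0.02, 15)),
            unit_ids=np.arange(15),
        )
        report = sp.agreement_report([pair], n_resamples=500, seed=7)
        rse = report[report.metric == "rse_pct"].iloc[0]
        mdc = report[report.metric == "mdc95_pct"].iloc[0]
        assert mdc.ci_lo == pytest.approx(rse.ci_lo * MDC95_FACTOR)
        assert mdc.ci_hi == pytest.approx(rse.ci_hi * MDC95_FACTOR)
        assert mdc.estimate == pytest.approx(rse.estimate * MDC95_FACTOR)
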