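"""ICC, alpha, SEM, agreement and session-variability statistics."""

import numpy as np
import pandas as pd
import pytest

from posturemetrics import (
    classify_icc,
    generate_rater_study,
    icc_two_way,
    method_agreement,
    sem_from,
    session_variability,
)
from posturemetrics.landmarks import MeasurementRecord


def icc21_oracle(m):
    """Independently coded ICC(2,1): explicit-loop two-way mean squares."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    msr = sum((row.mean() - grand) ** 2 for row in m) * k / (n - 1)
    msc = sum((m[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        m = np.tile(np.arange(10, dtype=float)[:, None], (1, 3))
        res = icc_two_way(m)
        assert res.icc == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0)
        assert res.category == "very good"
        assert res.alpha == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_two_way(np.full((5, 3), 7.0))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            icc_two_way(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            icc_two_way(np.zeros((5, 1)))

    def test_matches_independent_oracle(self, rng):
        """Mean-squares algebra vs. explicit-loop oracle on 200 small matrices."""
        for _ in range(200):
            n = rng.integers(2, 6)
            k = rng.integers(2, 4)
            m = rng.normal(20, 5, (n, 1)) + rng.normal(0, 2, (n, k))
            assert icc_two_way(m).icc == pytest.approx(icc21_oracle(m), abs=1e-9)

    def test_matches_pingouin(self, rng):
        """Cross-check ICC(2,1)/(2,k) against pingouin's implementation."""
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            m = rng.normal(25, 7, (12, 1)) + rng.normal(0, 2, (12, 3))
            df = (
                pd.DataFrame(m)
                .reset_index()
                .melt("index", var_name="rater", value_name="v")
            )
            ref = pg.intraclass_corr(df, targets="index", raters="rater", ratings="v")
            ours = icc_two_way(m)
            assert ours.icc == pytest.approx(
                float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0]), abs=1e-9
            )
            ours_k = icc_two_way(m, form="average")
            assert ours_k.icc == pytest.approx(
                float(ref.loc[ref.Type == "ICC(A,k)", "ICC"].iloc[0]), abs=1e-9
            )

    def test_variance_component_calibration(self, rng):
        """Mean estimated ICC near sigma_s^2/(sigma_s^2+sigma_e^2) at n=30, k=3."""
        sigma_s, sigma_e = 7.0, 1.0
        target = sigma_s**2 / (sigma_s**2 + sigma_e**2)  # ~0.98
        estimates = [
            icc_two_way(rng.normal(0, sigma_s, (30, 1)) + rng.normal(0, sigma_e, (30, 3))).icc
            for _ in range(500)
        ]
        assert np.mean(estimates) == pytest.approx(target, abs=0.02)

    def test_shift_and_scale_invariance(self, rng):
        m = rng.normal(25, 7, (15, 1)) + rng.normal(0, 2, (15, 3))
        base = icc_two_way(m).icc
        assert icc_two_way(m + 100.0).icc == pytest.approx(base, abs=1e-9)
        assert icc_two_way(m * 3.5).icc == pytest.approx(base, abs=1e-9)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            m = rng.normal(25, 7, (10, 1)) + rng.normal(0, 3, (10, 3))
            res = icc_two_way(m)
            assert res.ci_low <= res.icc <= res.ci_high


class TestSEM:
    def test_formula_endpoints(self, rng):
        m = rng.normal(25, 7, (20, 3))
        assert sem_from(m, 1.0) == 0.0
        assert sem_from(m, 0.0) == pytest.approx(float(np.std(m, ddof=1)))

    def test_direct_evaluation(self):
        """SD 3.8 at ICC 0.93 gives SEM just above one degree."""
        rng = np.random.default_rng(7)
        m = rng.normal(25, 3.8, (500, 3))
        m = (m - m.mean()) / m.std(ddof=1) * 3.8 + 25  # pin the pooled SD
        assert sem_from(m, 0.93) == pytest.approx(3.8 * np.sqrt(0.07), abs=1e-9)
        assert sem_from(m, 0.93) == pytest.approx(1.005, abs=1e-3)

    def test_invalid_icc_rejected(self, rng):
        m = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError):
            sem_from(m, 1.2)


class TestScale:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.20, "poor"),
            (0.05, "poor"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.55, "moderate"),
            (0.605, "good"),
            (0.80, "good"),
            (0.81, "very good"),
            (0.85, "very good"),
            (1.0, "very good"),
            (-0.3, "poor"),
        ],
    )
    def test_bins(self, value, expected):
        assert classify_icc(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.01)


class TestMethodAgreement:
    def test_identical_methods(self, rng):
        x = rng.normal(25, 7, 20)
        res = method_agreement(x, x)
        assert res.reliability.icc == pytest.approx(1.0)
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_constant_offset_appears_as_bias(self, rng):
        x = rng.normal(25, 7, 20)
        res = method_agreement(x, x + 1.0)
        assert res.bias == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(1.0)  # zero-SD differences

    def test_variance_component_magnitude(self, rng):
        """Shared signal SD 7 with method noise SD 1 per arm: ICC near 0.95."""
        target = 7.0**2 / (7.0**2 + 2 * 1.0**2 / 2)  # per-arm noise var 1
        estimates = []
        for _ in range(500):
            signal = rng.normal(25, 7.0, 30)
            x = signal + rng.normal(0, 1.0, 30)
            y = signal + rng.normal(0, 1.0, 30)
            estimates.append(method_agreement(x, y).reliability.icc)
        assert np.mean(estimates) == pytest.approx(target, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            method_agreement([1.0, 2.0, 3.0], [1.0, 2.0])


def study_records(rng, n=12, sessions=3, shift=None, residual_sd=1.0):
    records = generate_rater_study(
        n_subjects=n,
        k_raters=1,
        s_sessions=sessions,
        residual_sd=residual_sd,
        rng=rng,
    )
    if shift:
        records = [
            MeasurementRecord(
                r.subject_id,
                r.rater_id,
                r.session_id,
                r.parameter,
                r.value + shift.get(r.session_id, 0.0),
            )
            for r in records
        ]
    return records


class TestSessionVariability:
    def test_identical_sessions_show_no_effect(self, rng):
        base = generate_rater_study(n_subjects=10, k_raters=1, s_sessions=1, rng=rng)
        records = [
            MeasurementRecord(r.subject_id, r.rater_id, f"t{t}", r.parameter, r.value)
            for r in base
            for t in range(3)
        ]
        res = session_variability(records)["SS"]
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_large_shift_detected(self, rng):
        records = study_records(rng, shift={"t2": 10.0})
        res = session_variability(records)["SS"]
        assert res.p_value < 0.001
        assert res.posthoc is not None and len(res.posthoc) == 3  # three pairs

    def test_incomplete_grid_lists_missing_cells(self, rng):
        records = study_records(rng)
        dropped = [r for r in records if not (r.subject_id == "s001" and r.session_id == "t2")]
        with pytest.raises(ValueError, match=r"\(s001, t2\)"):
            session_variability(dropped)

    def test_replicates_averaged_per_cell(self, rng):
        records = generate_rater_study(
            n_subjects=10, k_raters=3, s_sessions=3, residual_sd=1.0, rng=rng
        )
        res = session_variability(records)["SS"]
        assert np.isfinite(res.p_value)
        assert set(res.session_means) == {"t0", "t1", "t2"}

    def test_null_p_values_roughly_uniform(self, rng):
        """Under the null the RM-ANOVA p-value should not concentrate low.

        (The full 1000-rep type-I calibration runs in the acceptance suite.)
        """
        ps = []
        for _ in range(100):
            records = generate_rater_study(
                n_subjects=30, k_raters=1, s_sessions=3, residual_sd=1.0, rng=rng
            )
            ps.append(session_variability(records)["SS"].p_value)
        assert 0.3 <= float(np.mean(ps)) <= 0.7
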