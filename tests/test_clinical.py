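"""Clinical validation layer on the packaged cohort and synthetic inputs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegsnn.clinical import (
    ConfusionCounts,
    RecordingSummary,
    classify_showing_hfo,
    concordant_pre_post_pairs,
    confusion,
    fit_loglog,
    is_active_epilepsy,
    load_cohort,
    metrics,
    predict_seizure_freq,
    rank_tests,
    spearman_rate_vs_seizures,
)


def summary(pid="p", surg=1, phase="pre", sf=1.0, ilae=None, aff=1.0, non=None):
    return RecordingSummary(
        patient_id=pid, surgery_index=surg, phase=phase, seizure_freq=sf,
        ilae=ilae, hfo_rate_affected=aff, hfo_rate_nonaffected=non,
    )


@pytest.fixture(scope="module")
def cohort():
    return load_cohort()


class TestCohortFixture:
    def test_shape(self, cohort):
        assert len(cohort) == 20
        assert sum(1 for s in cohort if s.phase == "pre") == 9
        assert sum(1 for s in cohort if s.phase == "post") == 11
        assert all(s.hfo_rate_affected is not None for s in cohort)

    def test_active_epilepsy_split(self, cohort):
        active = [s for s in cohort if is_active_epilepsy(s)]
        assert len(active) == 14


class TestClassification:
    @pytest.mark.parametrize(
        "rate,expected", [(6.38, True), (0.24, False), (0.0, False), (0.25, True)]
    )
    def test_rate_threshold(self, rate, expected):
        assert classify_showing_hfo(rate) is expected

    def test_active_epilepsy_definition(self):
        assert is_active_epilepsy(summary(phase="pre")) is True
        assert is_active_epilepsy(summary(phase="post", ilae=1)) is False
        assert is_active_epilepsy(summary(phase="post", ilae=5)) is True

    def test_post_without_ilae_is_data_error(self):
        with pytest.raises(ValueError, match="ILAE"):
            is_active_epilepsy(summary(phase="post", ilae=None))


class TestConfusionAndMetrics:
    def test_packaged_cohort_counts(self, cohort):
        c = confusion(cohort)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 0, 6, 4)

    def test_empty_cohort_all_zero(self):
        c = confusion([])
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 0)

    def test_single_active_recording(self):
        c = confusion([summary(aff=1.0)])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 0, 0)

    def test_metrics_on_published_counts(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=6, fn=4))
        assert round(100 * m["accuracy"]) == 80
        assert round(100 * m["sensitivity"]) == 71
        assert round(100 * m["specificity"]) == 100
        assert round(100 * m["ppv"]) == 100
        assert round(100 * m["npv"]) == 60

    def test_degenerate_metrics(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=1, fn=1))
        assert m["sensitivity"] == 0.0
        assert m["npv"] == 0.5
        assert m["ppv"] is None
        m2 = metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert all(v == 1.0 for v in m2.values())
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_accuracy_identity(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.n == 0:
            return
        m = metrics(c)
        p, n_neg = tp + fn, tn + fp
        if p and n_neg:
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n_neg) / (p + n_neg)
            )


class TestAssociations:
    def test_cohort_spearman_frozen(self, cohort):
        # recomputed from the printed-precision cohort rates
        assert spearman_rate_vs_seizures(cohort) == pytest.approx(0.8917, abs=2e-4)

    def test_spearman_zero_code_invariance(self, cohort):
        a = spearman_rate_vs_seizures(cohort, zero_code=1e-3)
        b = spearman_rate_vs_seizures(cohort, zero_code=1e-6)
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_pairs(self):
        rows = [summary(pid=str(i), sf=2.0**i, aff=float(i + 1)) for i in range(6)]
        assert spearman_rate_vs_seizures(rows) == pytest.approx(1.0)
        anti = [summary(pid=str(i), sf=2.0**-i, aff=float(i + 1)) for i in range(6)]
        assert spearman_rate_vs_seizures(anti) == pytest.approx(-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_spearman_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            summary(pid=str(i), sf=float(f), aff=float(r))
            for i, (f, r) in enumerate(
                zip(rng.uniform(0.1, 100, 8), rng.uniform(0.01, 9, 8))
            )
        ]
        transformed = [
            RecordingSummary(
                patient_id=s.patient_id, surgery_index=1, phase="pre",
                seizure_freq=s.seizure_freq**3,
                hfo_rate_affected=math.exp(s.hfo_rate_affected),
            )
            for s in rows
        ]
        assert spearman_rate_vs_seizures(rows) == pytest.approx(
            spearman_rate_vs_seizures(transformed), abs=1e-12
        )

    def test_cohort_regression_frozen(self, cohort):
        slope, intercept, r2 = fit_loglog(cohort)
        # recomputed from the printed-precision cohort rates
        assert slope == pytest.approx(2.287, abs=5e-3)
        assert intercept == pytest.approx(0.675, abs=5e-3)
        assert r2 == pytest.approx(0.762, abs=5e-3)

    def test_exact_line_recovered(self):
        rows = [
            summary(pid=str(i), sf=10 ** (2 * math.log10(r) + 1), aff=r)
            for i, r in enumerate([0.1, 0.5, 1.0, 2.0, 5.0])
        ]
        slope, intercept, r2 = fit_loglog(rows)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_flat_response(self):
        rows = [summary(pid=str(i), sf=5.0, aff=r) for i, r in enumerate([0.1, 1, 3, 8])]
        slope, _, r2 = fit_loglog(rows)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_rate_is_data_error(self):
        rows = [summary(pid="a", aff=0.0), summary(pid="b", aff=1.0), summary(pid="c", aff=2.0)]
        with pytest.raises(ValueError, match="> 0"):
            fit_loglog(rows)

    def test_ols_residuals_orthogonal_to_regressor(self, cohort):
        slope, intercept, _ = fit_loglog(cohort)
        x = np.log10([s.hfo_rate_affected for s in cohort])
        y = np.log10([max(s.seizure_freq, 1e-3) for s in cohort])
        resid = y - (slope * x + intercept)
        assert float(resid @ x) == pytest.approx(0.0, abs=1e-9)
        assert float(resid.sum()) == pytest.approx(0.0, abs=1e-9)

    def test_prediction(self):
        assert predict_seizure_freq((2.27, 0.7), 1.0) == pytest.approx(10**0.7)
        assert predict_seizure_freq((1.0, 0.0), 10.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            predict_seizure_freq((2.27, 0.7), 0.0)


class TestConcordance:
    def test_cohort_eight_pairs_all_concordant(self, cohort):
        conc, total, chi2 = concordant_pre_post_pairs(cohort)
        assert total == 8
        assert conc == 8
        assert chi2 == pytest.approx(8.0)

    def test_null_split_gives_zero_chi2(self):
        rows = []
        for i in range(8):
            rows.append(summary(pid=str(i), phase="pre", sf=10.0, aff=1.0))
            # half the pairs move with seizure frequency, half against
            post_sf, post_rate = (0.0, 0.1) if i < 4 else (0.0, 2.0)
            rows.append(
                summary(pid=str(i), phase="post", sf=post_sf, ilae=1, aff=post_rate)
            )
        conc, total, chi2 = concordant_pre_post_pairs(rows)
        assert (conc, total) == (4, 8)
        assert chi2 == pytest.approx(0.0)

    def test_tie_rule_classification_vs_sign(self):
        rows = [
            summary(pid="x", phase="pre", sf=180.0, aff=5.6),
            summary(pid="x", phase="post", sf=180.0, ilae=5, aff=2.05),
        ]
        conc_cls, _, _ = concordant_pre_post_pairs(rows, tie_rule="classification")
        conc_sign, _, _ = concordant_pre_post_pairs(rows, tie_rule="sign")
        assert conc_cls == 1  # both rates above threshold: state unchanged
        assert conc_sign == 0  # raw rate did change while frequency did not

    def test_no_pairs_raises(self):
        with pytest.raises(ValueError, match="pairs"):
            concordant_pre_post_pairs([summary(pid="a", phase="pre")])


class TestRankTests:
    def test_identical_groups_not_significant(self):
        rows = [summary(pid=f"a{i}", phase="pre", aff=r) for i, r in enumerate([1, 2, 3])]
        rows += [
            summary(pid=f"b{i}", phase="post", ilae=1, sf=0.0, aff=r)
            for i, r in enumerate([1, 2, 3])
        ]
        out = rank_tests(rows)
        assert out["ranksum_active_vs_free"]["p"] == pytest.approx(1.0, abs=0.05)

    def test_separated_groups_highly_significant(self):
        rows = [
            summary(pid=f"a{i}", phase="pre", aff=10.0 + i) for i in range(10)
        ] + [
            summary(pid=f"b{i}", phase="post", ilae=1, sf=0.0, aff=0.01 * (i + 1))
            for i in range(10)
        ]
        out = rank_tests(rows)
        assert out["ranksum_active_vs_free"]["p"] < 0.001

    def test_cohort_hemisphere_comparison_not_significant(self, cohort):
        out = rank_tests(cohort)
        sr = out["signedrank_affected_vs_nonaffected"]
        assert sr["n_pairs"] == 14
        assert sr["p"] > 0.05

    def test_degenerate_pairs_reported_not_computable(self):
        rows = [summary(pid="a", aff=1.0, non=1.0)]
        out = rank_tests(rows)
        assert out["signedrank_affected_vs_nonaffected"]["p"] is None
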