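import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import doublesub as ds
from doublesub import stats as st
from doublesub.null_models import NullCountsRecord, NullWindowKey
from doublesub.parsimony import CountsRecord, GeneCounts


def _counts(a1, a2, b, anc=1000, anc_codon="AAA", fin="GGA"):
    return CountsRecord(ancestral=anc_codon, final=fin, a1=a1, a2=a2, b=b, anc_count=anc)


def _null(a1, a2, b, anc=1000):
    key = NullWindowKey("NM2", ("A", "G"), ("A", "G"), "A")
    return NullCountsRecord(key=key, a1=a1, a2=a2, b=b, anc_count=anc)


class TestDoubleFraction:
    @pytest.mark.parametrize(
        "a1,a2,b,expected", [(1, 2, 1, 0.25), (5, 5, 0, 0.0), (0, 0, 3, 1.0)]
    )
    def test_values(self, a1, a2, b, expected):
        assert ds.double_fraction(a1, a2, b) == expected

    def test_undefined_when_no_instances(self):
        assert math.isnan(ds.double_fraction(0, 0, 0))
        assert not ds.df(_counts(0, 0, 0)).defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ds.double_fraction(-1, 0, 0)

    def test_frequencies_are_per_anc(self):
        rec = ds.df(_counts(10, 20, 5, anc=100))
        assert rec.f_b == 0.05 and rec.f_a1 == 0.1 and rec.f_a2 == 0.2

    @given(
        a1=hst.integers(0, 50), a2=hst.integers(0, 50), b=hst.integers(0, 50),
        k=hst.integers(2, 9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, a1, a2, b, k):
        if a1 + a2 + b == 0:
            return
        assert ds.double_fraction(a1, a2, b) == pytest.approx(
            ds.double_fraction(k * a1, k * a2, k * b)
        )


class TestFisherRegimes:
    def test_identical_counts_are_neutral(self):
        p, direction = ds.fisher_test(_counts(25, 25, 50), _null(25, 25, 50))
        assert p == 1.0 and direction == "equal"

    def test_family_of_one_positive(self):
        calls = ds.call_regimes(
            [(("AAA", "GGA"), "NN", _counts(25, 25, 50), _null(50, 45, 5))]
        )
        assert calls[0].regime == st.POSITIVE and calls[0].p_adjusted < 0.05

    def test_family_of_one_negative_by_symmetry(self):
        calls = ds.call_regimes(
            [(("AAA", "GGA"), "NN", _counts(50, 45, 5), _null(25, 25, 50))]
        )
        assert calls[0].regime == st.NEGATIVE

    def test_degenerate_table_is_neutral(self):
        calls = ds.call_regimes(
            [(("AAA", "GGA"), "NN", _counts(0, 0, 0), _null(10, 10, 2))]
        )
        assert calls[0].regime == st.NEUTRAL and not calls[0].sufficient

    def test_insufficient_counts_flagged(self):
        calls = ds.call_regimes(
            [(("AAA", "GGA"), "NN", _counts(1, 0, 2), _null(100, 100, 5))],
            min_total=5,
        )
        assert not calls[0].sufficient and calls[0].regime == st.NEUTRAL

    def test_bh_family_correction(self):
        # one strong signal among nulls: survives BH; borderline ones do not
        pairs = [(("AAA", "GGA"), "NN", _counts(25, 25, 50), _null(50, 45, 5))]
        for i in range(9):
            pairs.append(((f"C{i}", "x"), "NN", _counts(20, 20, 4), _null(20, 20, 4)))
        calls = ds.call_regimes(pairs)
        assert calls[0].regime == st.POSITIVE
        assert all(c.regime == st.NEUTRAL for c in calls[1:])
        assert all(c.p_adjusted >= c.p_value for c in calls)


class TestGroupCompare:
    def test_identical_lists(self):
        res = ds.group_compare([0.1, 0.2, 0.3] * 5, [0.1, 0.2, 0.3] * 5)
        assert res.p_u >= 0.9 and res.p_t > 0.9

    def test_separated_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.1, 0.01, 20)
        y = rng.normal(0.5, 0.01, 20)
        res = ds.group_compare(x, y)
        assert res.p_t < 0.01 and res.p_u < 0.01

    def test_single_observation_disables_t(self):
        res = ds.group_compare([0.1], [0.2, 0.3, 0.4])
        assert math.isnan(res.p_t) and 0 <= res.p_u <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ds.group_compare([], [0.1])


class TestFastSlowCompare:
    def test_equal_sides(self):
        vals = {("A", str(i)): 0.1 * i for i in range(8)}
        res = ds.fast_slow_compare(vals, dict(vals))
        assert res.p_t == 1.0 and res.p_w == 1.0 and res.mean_diff == 0.0

    def test_constant_shift_detected(self):
        slow = {("A", str(i)): 0.1 + 0.01 * i for i in range(16)}
        fast = {k: v + 0.1 for k, v in slow.items()}
        res = ds.fast_slow_compare(fast, slow)
        assert res.p_t < 0.01 and res.p_w < 0.01 and res.mean_diff == pytest.approx(0.1)

    def test_single_shared_key_rejected(self):
        with pytest.raises(ValueError):
            ds.fast_slow_compare({("A", "B"): 0.1}, {("A", "B"): 0.2})


class TestDMEstimate:
    def test_positive_estimate(self):
        est = ds.dm_estimate(_null(100, 100, 20, anc=1000))
        assert est.dm == pytest.approx(0.02 - 0.01) and not est.negative

    def test_negative_flagged_and_excluded_from_mean(self):
        pos = ds.dm_estimate(_null(100, 100, 20, anc=1000))
        neg = ds.dm_estimate(_null(100, 100, 5, anc=1000))
        assert neg.negative
        assert ds.mean_dm([pos, neg]) == pytest.approx(pos.dm)

    def test_zero_anc_rejected(self):
        with pytest.raises(ValueError):
            ds.dm_estimate(_null(1, 1, 1, anc=0))

    def test_pooled_dm_cancels_noise(self):
        # one key with a spurious double, one with a deficit: pooled DM
        # nets them; rectified per-key means would not
        a = _null(100, 100, 11, anc=1000)
        b = _null(100, 100, 9, anc=1000)
        pooled = st.pooled_dm([a, b])
        assert pooled.dm == pytest.approx(20 / 2000 - 20 / 2000)


class TestAdjustedDF:
    def test_subtraction(self):
        est = st.DMEstimate(f_b=0.004, product=0.0)  # DM*ANC = 4
        rec = ds.adjusted_df(_counts(10, 10, 10), est, label="NS")
        assert rec.b == 6 and rec.df == pytest.approx(6 / 26)

    def test_clamped_at_zero(self):
        est = st.DMEstimate(f_b=0.5, product=0.0)
        rec = ds.adjusted_df(_counts(10, 10, 3), est, label="SS")
        assert rec.b == 0 and rec.df == 0.0

    @pytest.mark.parametrize("label", ["SN", "NN"])
    def test_nonsynonymous_classes_refused(self, label):
        est = st.DMEstimate(f_b=0.001, product=0.0)
        with pytest.raises(ValueError):
            ds.adjusted_df(_counts(10, 10, 10), est, label=label)


class TestExpectedNSNeutral:
    def test_extreme_case_matches_printed_limit(self):
        # lethal intermediate: a2n = 0, a1n = a1s, symmetric null a1s = a2s
        b_exp, df_exp = ds.expected_ns_neutral(
            _counts(10, 0, 0), _null(10, 10, 4)
        )
        assert b_exp == pytest.approx(2.0)  # = b_s / 2
        assert df_exp == pytest.approx((4 / 2) / (10 + 4 / 2))

    def test_symmetric_codon_reduces_to_null_df(self):
        b_exp, df_exp = ds.expected_ns_neutral(_counts(10, 10, 0), _null(10, 10, 4))
        assert df_exp == pytest.approx(ds.double_fraction(10, 10, 4), rel=0.2)

    def test_no_null_doubles(self):
        b_exp, df_exp = ds.expected_ns_neutral(_counts(10, 5, 0), _null(10, 10, 0))
        assert b_exp == 0.0 and df_exp == 0.0

    def test_undefined_without_null_singles(self):
        b_exp, df_exp = ds.expected_ns_neutral(_counts(10, 5, 0), _null(0, 0, 3))
        assert math.isnan(b_exp) and math.isnan(df_exp)


class TestGeneRates:
    def test_zero_n_events_is_slow(self):
        records = ds.gene_rates(
            [
                GeneCounts("a", 0, 10, 200.0, 100.0),
                GeneCounts("b", 30, 10, 200.0, 100.0),
            ]
        )
        by_id = {r.gene_id: r for r in records}
        assert by_id["a"].ratio == 0.0 and by_id["a"].speed == st.SLOW
        assert by_id["b"].speed == st.FAST

    def test_ties_go_to_slow(self):
        records = ds.gene_rates(
            [GeneCounts(str(i), 10, 10, 200.0, 100.0) for i in range(4)]
        )
        assert all(r.speed == st.SLOW for r in records)

    def test_undefined_ratio_excluded(self):
        records = ds.gene_rates(
            [GeneCounts("a", 5, 0, 200.0, 100.0), GeneCounts("b", 5, 5, 200.0, 100.0)]
        )
        by_id = {r.gene_id: r for r in records}
        assert by_id["a"].speed is None
        fast, slow = st.split_gene_ids(records)
        assert "a" not in fast | slow
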