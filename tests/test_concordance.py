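"""Rand index, drug-pair concordance, interval correlation, paired OLS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iphdnet import (
    Partition,
    drug_pair_concordance,
    interval_response_correlation,
    paired_response_regression,
    rand_index,
    within_drug_interval_correlation,
)
from iphdnet.preprocess import FoldChangeMatrix

from conftest import make_matrix, sample_row


def brute_force_rand(a, b):
    """Pair-enumeration oracle: fraction of agreeing pairs."""
    n = len(a)
    agree = total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total


def as_partition(labels):
    return Partition({f"i{k}": str(v) for k, v in enumerate(labels)})


class TestRandIndex:
    def test_identical_partitions_give_one(self):
        p = as_partition(["a", "a", "b", "c"])
        assert rand_index(p, p) == 1.0

    def test_textbook_third(self):
        assert rand_index(
            as_partition(["a", "a", "b", "b"]), as_partition(["x", "y", "x", "y"])
        ) == pytest.approx(1 / 3)

    def test_mismatched_items_listed(self):
        with pytest.raises(ValueError, match="i2"):
            rand_index(as_partition(["a", "a"]), as_partition(["a", "a", "b"]))

    def test_symmetric_and_label_invariant(self, rng):
        a = rng.integers(0, 3, size=12)
        b = rng.integers(0, 3, size=12)
        p1, p2 = as_partition(a), as_partition(b)
        assert rand_index(p1, p2) == rand_index(p2, p1)
        relabeled = as_partition([chr(65 + x) for x in b])
        assert rand_index(p1, relabeled) == rand_index(p1, p2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(2, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_pair_enumeration_oracle(self, pair):
        a, b = pair
        assert rand_index(as_partition(a), as_partition(b)) == pytest.approx(
            brute_force_rand(a, b)
        )

    def test_adjusted_variant_zero_mean_under_permutation(self, rng):
        a = ["a"] * 6 + ["b"] * 6
        vals = []
        for _ in range(200):
            b = list(rng.permutation(a))
            vals.append(rand_index(as_partition(a), as_partition(b), adjusted=True))
        assert abs(np.mean(vals)) < 0.05  # chance-corrected: ~0 under the null


class TestDrugPairConcordance:
    def _partitions(self, same_in):
        out = {}
        for i in range(6):
            label_b = "c1" if i < same_in else "c2"
            out[f"line{i}"] = Partition({"flavopiridol": "c1", "dinaciclib": label_b,
                                         "other": "c3"})
        return out

    def test_full_agreement(self):
        flags, overall = drug_pair_concordance(
            self._partitions(6), "flavopiridol", "dinaciclib"
        )
        assert overall == 1.0 and all(flags.values())

    def test_half_agreement(self):
        _, overall = drug_pair_concordance(
            self._partitions(3), "flavopiridol", "dinaciclib"
        )
        assert overall == 0.5

    def test_missing_drug_names_both(self):
        parts = self._partitions(6)
        parts["line3"] = Partition({"flavopiridol": "c1"})
        with pytest.raises(KeyError, match="dinaciclib.*line3"):
            drug_pair_concordance(parts, "flavopiridol", "dinaciclib")


def timecourse_matrix(profiles):
    """profiles: {(drug, t): per-analyte vector}."""
    rows, cols = [], []
    for j, ((drug, t), vec) in enumerate(profiles.items()):
        rows.append(sample_row(f"s{j}", drug, timepoint_h=t))
        cols.append(vec)
    return make_matrix(np.column_stack(cols), sample_meta_rows=rows)


class TestIntervalCorrelation:
    def test_identical_change_vectors(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        delta = np.array([0.5, -1.0, 2.0, 0.1])
        m = timecourse_matrix({
            ("A", 3.0): base, ("A", 6.0): base + delta,
            ("B", 3.0): base * 2, ("B", 6.0): base * 2 + delta,
        })
        assert interval_response_correlation(m, "A", "B", 3.0, 6.0) == pytest.approx(1.0)

    def test_negated_change_vectors(self):
        base = np.zeros(4)
        delta = np.array([0.5, -1.0, 2.0, 0.1])
        m = timecourse_matrix({
            ("A", 3.0): base, ("A", 6.0): delta,
            ("B", 3.0): base, ("B", 6.0): -delta,
        })
        assert interval_response_correlation(m, "A", "B", 3.0, 6.0) == pytest.approx(-1.0)

    def test_scale_invariance(self):
        m = timecourse_matrix({
            ("A", 3.0): np.zeros(3), ("A", 6.0): np.array([1.0, 2.0, 3.0]),
            ("B", 3.0): np.zeros(3), ("B", 6.0): np.array([2.0, 4.0, 6.0]),
        })
        assert interval_response_correlation(m, "A", "B", 3.0, 6.0) == pytest.approx(1.0)

    def test_shift_invariance_in_one_drug(self, rng):
        base = rng.normal(size=8)
        da, db = rng.normal(size=8), rng.normal(size=8)
        m1 = timecourse_matrix({
            ("A", 3.0): base, ("A", 6.0): base + da,
            ("B", 3.0): base, ("B", 6.0): base + db,
        })
        m2 = timecourse_matrix({
            ("A", 3.0): base + 5.0, ("A", 6.0): base + da + 5.0,
            ("B", 3.0): base, ("B", 6.0): base + db,
        })
        r1 = interval_response_correlation(m1, "A", "B", 3.0, 6.0)
        r2 = interval_response_correlation(m2, "A", "B", 3.0, 6.0)
        assert r1 == pytest.approx(r2)

    def test_missing_timepoint_rejected(self):
        m = timecourse_matrix({("A", 3.0): np.zeros(3), ("B", 3.0): np.zeros(3)})
        with pytest.raises(KeyError):
            interval_response_correlation(m, "A", "B", 3.0, 6.0)

    def test_zero_variance_rejected(self):
        m = timecourse_matrix({
            ("A", 3.0): np.zeros(3), ("A", 6.0): np.zeros(3),
            ("B", 3.0): np.zeros(3), ("B", 6.0): np.array([1.0, 2.0, 3.0]),
        })
        with pytest.raises(ValueError, match="zero-variance"):
            interval_response_correlation(m, "A", "B", 3.0, 6.0)

    def test_within_drug_variant(self):
        v3 = np.array([1.0, 2.0, 3.0])
        m = timecourse_matrix({("A", 3.0): v3, ("A", 6.0): 2 * v3 + 1})
        assert within_drug_interval_correlation(m, "A", 3.0, 6.0) == pytest.approx(1.0)


class TestPairedRegression:
    def _fc(self, a, b):
        import pandas as pd

        meta = pd.DataFrame(
            {"perturbagen": ["A", "B"], "cell_line": "MCF7", "timepoint_h": 24.0},
            index=pd.Index(["tA", "tB"], name="treatment_id"),
        )
        return FoldChangeMatrix(
            np.column_stack([a, b]), [f"h{i}" for i in range(len(a))], meta
        )

    def test_identity(self, rng):
        a = rng.normal(size=6)
        slope, intercept, r2 = paired_response_regression(self._fc(a, a), "A", "B")
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine(self, rng):
        a = rng.normal(size=6)
        slope, intercept, r2 = paired_response_regression(self._fc(a, 2 * a + 1), "A", "B")
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_closed_form_oracle(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        slope, intercept, _ = paired_response_regression(self._fc(a, b), "A", "B")
        slope_oracle = np.cov(a, b, ddof=1)[0, 1] / np.var(a, ddof=1)
        assert slope == pytest.approx(slope_oracle, abs=1e-10)
        assert intercept == pytest.approx(b.mean() - slope_oracle * a.mean(), abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_response_regression(self._fc(np.ones(5), np.arange(5.0)), "A", "B")
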