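"""Error rate, log fold difference, pooled z-test, and database scans."""

import math

import numpy as np
import pytest
from scipy.stats import chi2
from statsmodels.stats.proportion import proportions_ztest

from purmine.purification_db import PurificationDatabase, PurificationEntry, BufferRecord, BufferComponent
from purmine.stats import (
    AnnotationTestResult,
    ContingencyInput,
    EvaluationCounts,
    annotation_chemical_scan,
    average_error_rate,
    benjamini_hochberg,
    cap_log_fold,
    co_usage,
    evaluation_counts,
    group_contrast,
    log_fold_difference,
    two_proportion_z_test,
)


class TestAverageErrorRate:
    def test_perfect_extraction_is_zero(self):
        counts = EvaluationCounts(fp=(0, 0), fn=(0, 0), positives=10, negatives=90)
        assert average_error_rate(counts) == 0.0

    def test_hand_worked_two_chemical_case(self):
        counts = EvaluationCounts(fp=(1, 0), fn=(0, 1), positives=10, negatives=90)
        assert average_error_rate(counts) == pytest.approx(0.01)

    def test_degenerate_totals_rejected(self):
        with pytest.raises(ValueError):
            EvaluationCounts(fp=(0,), fn=(0,), positives=0, negatives=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvaluationCounts(fp=(-1,), fn=(0,), positives=1, negatives=1)


class TestLogFold:
    def test_equal_rates_zero(self):
        assert log_fold_difference(ContingencyInput(10, 100, 20, 200)) == 0.0

    def test_doubled_rate_ln2(self):
        lf = log_fold_difference(ContingencyInput(10, 100, 5, 100))
        assert lf == pytest.approx(math.log(2))

    def test_sentinels(self):
        assert log_fold_difference(ContingencyInput(0, 10, 5, 10)) == -math.inf
        assert log_fold_difference(ContingencyInput(5, 10, 0, 10)) == math.inf
        assert math.isnan(log_fold_difference(ContingencyInput(0, 10, 0, 10)))

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(2, 100, 2)
            p1 = rng.integers(1, n1 + 1)
            p2 = rng.integers(1, n2 + 1)
            a = log_fold_difference(ContingencyInput(int(p1), int(n1), int(p2), int(n2)))
            b = log_fold_difference(ContingencyInput(int(p2), int(n2), int(p1), int(n1)))
            assert a == pytest.approx(-b)

    @pytest.mark.parametrize(
        "x,expected,flag",
        [(3.7, 3.0, True), (-0.5, -0.5, False), (math.inf, 3.0, True),
         (-math.inf, -3.0, True), (2.99, 2.99, False)],
    )
    def test_capping(self, x, expected, flag):
        value, capped = cap_log_fold(x)
        assert value == expected and capped is flag

    def test_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            cap_log_fold(1.0, cap=0)


class TestTwoProportionZTest:
    def test_equal_proportions_p_one(self):
        assert two_proportion_z_test(ContingencyInput(10, 100, 20, 200)) == pytest.approx(1.0)

    def test_hand_derived_case(self):
        # z = 0.2 / sqrt(0.2*0.8*(2/100)) = 3.5355..., p ≈ 4.07e-4
        p = two_proportion_z_test(ContingencyInput(30, 100, 10, 100))
        assert p == pytest.approx(4.0695e-4, rel=1e-3)
        # independent oracle: statsmodels pooled two-sided z-test
        p_sm = proportions_ztest([30, 10], [100, 100])[1]
        assert p == pytest.approx(p_sm, rel=1e-10)

    def test_group_swap_symmetry(self):
        a = two_proportion_z_test(ContingencyInput(30, 100, 10, 100))
        b = two_proportion_z_test(ContingencyInput(10, 100, 30, 100))
        assert a == b

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z_test(ContingencyInput(0, 10, 0, 20)) == 1.0
        assert two_proportion_z_test(ContingencyInput(10, 10, 20, 20)) == 1.0

    def test_chi_square_equivalence_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = (int(x) for x in rng.integers(5, 300, 2))
            p1 = int(rng.integers(0, n1 + 1))
            p2 = int(rng.integers(0, n2 + 1))
            p = two_proportion_z_test(ContingencyInput(p1, n1, p2, n2))
            pooled = (p1 + p2) / (n1 + n2)
            if pooled in (0.0, 1.0):
                p_chi = 1.0
            else:
                obs = np.array([[p1, n1 - p1], [p2, n2 - p2]], dtype=float)
                exp = np.outer([n1, n2], [pooled, 1 - pooled])
                p_chi = float(chi2.sf(((obs - exp) ** 2 / exp).sum(), df=1))
            assert abs(p - p_chi) < 1e-10

    def test_p_monotone_in_rate_gap(self):
        # fixed N1=N2=100 and pooled proportion 0.3: widen the gap, p shrinks
        previous = 1.0
        for delta in (0, 5, 10, 15, 20):
            p = two_proportion_z_test(ContingencyInput(30 + delta, 100, 30 - delta, 100))
            assert p <= previous + 1e-15
            previous = p

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyInput(5, 4, 0, 10)
        with pytest.raises(ValueError):
            ContingencyInput(0, 0, 0, 10)


def _usage_db():
    """Six proteins; 'Membrane' proteins prefer DDM, everyone uses NaCl."""
    usage = {
        "U1": {"annotations": {"Membrane"}, "chemicals": {"DDM", "NaCl"}, "tags": {"His"}},
        "U2": {"annotations": {"Membrane"}, "chemicals": {"DDM", "NaCl"}, "tags": {"Fc"}},
        "U3": {"annotations": {"Membrane"}, "chemicals": {"NaCl"}, "tags": set()},
        "U4": {"annotations": set(), "chemicals": {"NaCl"}, "tags": {"His"}},
        "U5": {"annotations": set(), "chemicals": {"NaCl"}, "tags": {"GST"}},
        "U6": {"annotations": set(), "chemicals": {"DDM", "NaCl"}, "tags": set()},
    }
    return usage


class TestScans:
    def test_annotation_floor_excludes_small_annotations(self):
        results = annotation_chemical_scan(_usage_db(), min_annotation_entries=5)
        assert results == []
        results = annotation_chemical_scan(_usage_db(), min_annotation_entries=2)
        assert {r.annotation for r in results} == {"Membrane"}

    def test_scan_counts_unique_proteins(self):
        results = annotation_chemical_scan(_usage_db(), min_annotation_entries=2)
        ddm = next(r for r in results if r.chemical == "DDM")
        assert (ddm.input.P1, ddm.input.N1, ddm.input.P2, ddm.input.N2) == (2, 3, 1, 3)

    def test_direction_needs_significance(self):
        results = annotation_chemical_scan(_usage_db(), min_annotation_entries=2)
        for r in results:  # n = 6 is far too small for significance
            assert r.direction == "none"

    def test_group_contrast_rows(self):
        frame = group_contrast(_usage_db(), "Membrane")
        ddm = frame[(frame["kind"] == "chemical") & (frame["item"] == "DDM")].iloc[0]
        assert ddm["P1"] == 2 and ddm["N1"] == 3 and ddm["P2"] == 1 and ddm["N2"] == 3
        assert ddm["log_fold"] == pytest.approx(math.log(2))
        tags = set(frame[frame["kind"] == "tag"]["item"])
        assert {"His", "Fc", "GST"} <= tags

    def test_group_contrast_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast(_usage_db(), "Nucleus")


class TestCoUsage:
    def _db(self):
        db = PurificationDatabase()
        db.add_or_merge(PurificationEntry(
            uniprot_id="U1", doi="10.1/a", detergents=["CHS", "LMNG"]))
        db.add_or_merge(PurificationEntry(
            uniprot_id="U2", doi="10.1/a", detergents=["CHS"]))
        db.add_or_merge(PurificationEntry(
            uniprot_id="U3", doi="10.1/b", detergents=["CHS", "LMNG", "GDN"]))
        return db

    def test_pair_counts_per_article(self):
        table = co_usage(self._db(), "detergent")
        assert table.loc["CHS", "LMNG"] == 2  # both articles pair them
        assert table.loc["GDN", "LMNG"] == 1
        assert table.loc["CHS", "CHS"] == 2  # two articles use CHS

    def test_symmetry(self):
        table = co_usage(self._db(), "detergent")
        assert (table.values == table.values.T).all()


class TestEvaluationCounts:
    def test_fp_fn_accounting(self):
        predicted = {"u1": {"Tris", "DTT"}, "u2": {"NaCl"}}
        truth = {"u1": {"Tris"}, "u2": {"NaCl", "EDTA"}}
        counts = evaluation_counts(predicted, truth, ["Tris", "NaCl", "DTT", "EDTA"])
        assert counts.positives == 3 and counts.negatives == 5
        assert sum(counts.fp) == 1 and sum(counts.fn) == 1
        assert average_error_rate(counts) == pytest.approx((1 / 8 + 1 / 8) / 4)


def test_benjamini_hochberg_monotone_and_bounded():
    ps = [0.001, 0.01, 0.02, 0.8, 0.04]
    qs = benjamini_hochberg(ps)
    assert all(q >= p for p, q in zip(ps, qs))
    order = np.argsort(ps)
    sorted_qs = [qs[i] for i in order]
    assert sorted_qs == sorted(sorted_qs)
    from statsmodels.stats.multitest import multipletests

    expected = multipletests(ps, method="fdr_bh")[1]
    assert np.allclose(qs, expected)
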