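"""Examiner-agreement battery vs independent brute-force oracles."""

import numpy as np
import pytest

from prepscore import (
    PairedScores,
    bland_altman,
    binary_confusion,
    cohen_kappa,
    diagnostic_metrics,
    full_report,
    icc3k,
    letter_grade,
    ordinal_confusion,
    precision_recall,
    rank_correlations,
    roc_curve_auc,
    simulate_paired_scores,
    summary_stats,
    tail_agreement,
    weighted_kappa,
)
from prepscore.agreement import LETTERS, BinaryConfusion

import oracles


def random_scores(seed, n=None, integer=False):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(5, 26))
    if integer:  # heavy ties
        panel = rng.integers(0, 101, size=n).astype(float)
        software = np.clip(panel + rng.integers(-20, 21, size=n), 0, 100).astype(float)
    else:
        panel = rng.uniform(0, 100, size=n)
        software = np.clip(panel + rng.normal(0, 15, size=n), 0, 100)
    return PairedScores([f"S{i}" for i in range(n)], panel, software)


class TestBinaryConfusion:
    def test_identical_scores_no_disagreement(self):
        s = PairedScores(["a", "b", "c"], [50, 30, 70], [50, 30, 70])
        c = binary_confusion(s, 44)
        assert c.fp == c.fn == 0

    def test_direct_count(self):
        s = PairedScores(["a", "b"], [50, 30], [50, 50])
        c = binary_confusion(s, 44)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 0)

    def test_all_below_cutoff(self):
        s = PairedScores(list("abc"), [10, 20, 30], [5, 15, 25])
        c = binary_confusion(s, 44)
        assert c.tn == 3 and c.total == 3


class TestDiagnosticMetrics:
    def test_perfect_classifier(self):
        m = diagnostic_metrics(BinaryConfusion(tp=50, fp=0, fn=0, tn=20))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_direct_ratios(self):
        m = diagnostic_metrics(BinaryConfusion(tp=9, fp=2, fn=1, tn=8))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.ppv == pytest.approx(9 / 11)
        assert m.npv == pytest.approx(8 / 9)

    def test_empty_positive_class_undefined(self):
        m = diagnostic_metrics(BinaryConfusion(tp=0, fp=2, fn=0, tn=8))
        assert np.isnan(m.sensitivity)


class TestRocAuc:
    def test_perfect_ranking(self):
        s = PairedScores(list("abcd"), [80, 60, 30, 20], [80, 60, 30, 20])
        assert roc_curve_auc(s, 44).area == pytest.approx(1.0)

    def test_constant_software_uninformative(self):
        s = PairedScores(list("abcd"), [80, 60, 30, 20], [50, 50, 50, 50])
        assert roc_curve_auc(s, 44).area == pytest.approx(0.5)

    def test_single_class_truth_undefined(self):
        s = PairedScores(list("abc"), [80, 60, 50], [70, 60, 50])
        assert np.isnan(roc_curve_auc(s, 44).area)

    def test_monotone_transform_invariance(self):
        s = random_scores(7, n=20)
        a1 = roc_curve_auc(s, 44).area
        s2 = PairedScores(s.subject_ids, s.panel, 100 * (s.software / 100) ** 3)
        assert roc_curve_auc(s2, 44).area == pytest.approx(a1, abs=1e-12)


class TestPrecisionRecall:
    def test_perfect_ranking_unit_area(self):
        s = PairedScores(list("abcd"), [80, 60, 30, 20], [80, 60, 30, 20])
        res = precision_recall(s, 44)
        assert res.area == pytest.approx(1.0)
        # a precision-1 operating point exists at full recall
        assert np.any((res.x == 1.0) & (res.y == 1.0))

    def test_recall_one_endpoint_present(self):
        s = random_scores(3, n=15)
        res = precision_recall(s, 44)
        assert res.x.max() == pytest.approx(1.0)

    def test_per_threshold_counts_match_brute_force(self):
        s = random_scores(11, n=15, integer=True)
        truth = s.panel >= 44
        if truth.sum() == 0 or truth.all():
            pytest.skip("degenerate draw")
        res = precision_recall(s, 44)
        for thr, prec, rec in zip(res.thresholds, res.y[:-1], res.x[:-1]):
            pred = s.software >= thr
            tp = int(np.sum(pred & truth))
            assert prec == pytest.approx(tp / max(pred.sum(), 1), abs=1e-12)
            assert rec == pytest.approx(tp / truth.sum(), abs=1e-12)


class TestKappas:
    def test_identical_vectors(self):
        labels = list("ABCABCDDEE")
        assert cohen_kappa(labels, labels) == 1.0
        assert weighted_kappa(labels, labels, "linear") == 1.0
        assert weighted_kappa(labels, labels, "quadratic") == 1.0

    def test_hand_computed_2x2(self):
        # agreement matrix [[20, 5], [10, 15]]: po=0.7, pe=0.5, kappa=0.4
        a = ["A"] * 25 + ["B"] * 25
        b = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        assert cohen_kappa(a, b, categories=("A", "B")) == pytest.approx(0.4)

    def test_constant_rater_gives_zero(self):
        a = list("AB" * 10)
        b = ["A"] * 20
        assert cohen_kappa(a, b, categories=("A", "B")) == pytest.approx(0.0)

    def test_two_category_weighted_equals_unweighted(self):
        rng = np.random.default_rng(5)
        a = [("A", "B")[i] for i in rng.integers(0, 2, 40)]
        b = [("A", "B")[i] for i in rng.integers(0, 2, 40)]
        k = cohen_kappa(a, b, categories=("A", "B"))
        assert weighted_kappa(a, b, "linear", ("A", "B")) == pytest.approx(k, abs=1e-12)
        assert weighted_kappa(a, b, "quadratic", ("A", "B")) == pytest.approx(k, abs=1e-12)

    def test_f_alias_maps_to_lowest_band(self):
        assert cohen_kappa(["F", "A"], ["E", "A"]) == 1.0

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(9)
        a = [LETTERS[i] for i in rng.integers(0, 5, 60)]
        b = [LETTERS[i] for i in rng.integers(0, 5, 60)]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestICC:
    def test_identical_raters(self):
        s = PairedScores(list("abcde"), [10, 30, 50, 70, 90], [10, 30, 50, 70, 90])
        assert icc3k(s).value == pytest.approx(1.0)

    def test_constant_offset_still_one(self):
        """Consistency ICC ignores a fixed shift between raters: the offset
        lands in the rater term of the ANOVA, not the error term."""
        panel = np.array([10.0, 30, 50, 70, 90])
        s = PairedScores(list("abcde"), panel, panel + 5)
        assert icc3k(s).value == pytest.approx(1.0, abs=1e-12)

    def test_variance_component_closed_form(self):
        """Subjects N(60,15²) plus independent rater noise N(0,5²): the
        population ICC(3,k) is σ_s² / (σ_s² + σ_e²/k)."""
        rng = np.random.default_rng(42)
        n = 5000
        subj = rng.normal(60, 15, n)
        s = PairedScores(
            list(range(n)),
            np.clip(subj + rng.normal(0, 5, n), 0, 100),
            np.clip(subj + rng.normal(0, 5, n), 0, 100),
        )
        expected = 225 / (225 + 25 / 2)
        assert icc3k(s).value == pytest.approx(expected, abs=0.01)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        s = random_scores(13, n=24)
        res = icc3k(s)
        val, (lo, hi) = oracles.icc3k_pingouin(s.panel, s.software)
        assert res.value == pytest.approx(val, abs=1e-9)
        assert res.ci_low == pytest.approx(lo, abs=6e-3)  # pingouin rounds its CI
        assert res.ci_high == pytest.approx(hi, abs=6e-3)


class TestRankCorrelations:
    def test_monotone_transform_perfect(self):
        s = PairedScores(list("abcde"), [10, 30, 50, 70, 90], [1, 9, 25, 49, 81])
        r = rank_correlations(s)
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.kendall_tau == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        s = PairedScores(list("abcd"), [1, 2, 3, 4], [1, 3, 2, 4])
        r = rank_correlations(s)
        assert r.spearman_rho == pytest.approx(0.8)
        assert r.kendall_tau == pytest.approx(2 / 3)

    def test_all_tied_undefined(self):
        s = PairedScores(list("abc"), [50, 50, 50], [10, 20, 30])
        r = rank_correlations(s)
        assert np.isnan(r.spearman_rho)

    def test_small_n_permutation_p_values(self):
        s = PairedScores(list("abcdefgh"), [1, 2, 3, 4, 5, 6, 7, 8],
                         [2, 1, 4, 3, 6, 5, 8, 7])
        r1 = rank_correlations(s, seed=1)
        r2 = rank_correlations(s, seed=1)
        assert r1.spearman_p == r2.spearman_p  # seeded determinism
        assert 0 < r1.spearman_p <= 1


class TestBlandAltman:
    def test_identical_vectors(self):
        s = PairedScores(list("abc"), [10, 50, 90], [10, 50, 90])
        ba = bland_altman(s)
        assert ba.bias == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset(self):
        s = PairedScores(list("abc"), [10, 50, 90], [15, 55, 95])
        ba = bland_altman(s)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == pytest.approx(5.0)
        assert ba.loa_high == pytest.approx(5.0)

    def test_sampling_distribution_recovery(self):
        rng = np.random.default_rng(7)
        n = 10_000
        panel = rng.uniform(20, 80, n)
        s = PairedScores(list(range(n)), panel, np.clip(panel + rng.normal(2, 1, n), 0, 100))
        ba = bland_altman(s)
        assert ba.bias == pytest.approx(2.0, abs=0.05)
        assert ba.loa_low == pytest.approx(2 - 1.96, abs=0.1)
        assert ba.loa_high == pytest.approx(2 + 1.96, abs=0.1)


class TestTailAgreement:
    def test_identical_rankings(self):
        s = PairedScores(list("abcdefghij"), np.arange(10.0), np.arange(10.0) * 2 + 50 / 10)
        assert tail_agreement(s, 0.2, "worst") == 100.0

    def test_reversed_rankings_disjoint_tails(self):
        s = PairedScores(list("abcdefghij"), np.arange(1.0, 11), np.arange(10.0, 0, -1))
        assert tail_agreement(s, 0.2, "worst") == 0.0

    def test_invalid_fraction(self):
        s = PairedScores(list("ab"), [1, 2], [1, 2])
        with pytest.raises(ValueError):
            tail_agreement(s, 0.0)


class TestOrdinalConfusion:
    def test_identical_scores_diagonal(self):
        s = PairedScores(list("abcd"), [85, 65, 45, 25], [85, 65, 45, 25])
        mat = ordinal_confusion(s).matrix
        assert mat.sum() == 4
        assert np.trace(mat) == 4

    def test_band_lookup(self):
        s = PairedScores(list("ab"), [85, 65], [65, 65])
        mat = ordinal_confusion(s).matrix
        assert mat[0, 1] == 1  # panel A, software B
        assert mat[1, 1] == 1

    def test_row_sums_match_panel_histogram(self):
        s = random_scores(21, n=25)
        mat = ordinal_confusion(s).matrix
        hist = {letter: 0 for letter in LETTERS}
        for score in s.panel:
            hist[letter_grade(score)] += 1
        assert list(mat.sum(axis=1)) == [hist[letter] for letter in LETTERS]


class TestSummaryStats:
    def test_constant_vector(self):
        st = summary_stats([7.0, 7.0, 7.0])
        assert st.mean == st.median == st.mode == 7.0
        assert st.sd == st.iqr == 0.0

    def test_linear_interpolation_quartiles(self):
        st = summary_stats([1, 2, 3, 4])
        assert st.median == 2.5
        assert st.q1 == 1.75
        assert st.q3 == 3.25
        assert st.iqr == pytest.approx(1.5)

    def test_variance_is_sd_squared(self):
        st = summary_stats([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        assert st.variance == pytest.approx(st.sd**2, abs=1e-12)

    def test_mode_smallest_on_ties(self):
        st = summary_stats([5, 5, 2, 2, 9])
        assert st.mode == 2.0


class TestRaterSymmetry:
    def test_symmetric_metrics_and_antisymmetric_bias(self):
        s = random_scores(31, n=20, integer=True)
        swapped = PairedScores(s.subject_ids, s.software, s.panel)
        la = [letter_grade(v) for v in s.panel]
        lb = [letter_grade(v) for v in s.software]
        assert cohen_kappa(la, lb) == pytest.approx(cohen_kappa(lb, la), abs=1e-12)
        for scheme in ("linear", "quadratic"):
            assert weighted_kappa(la, lb, scheme) == pytest.approx(
                weighted_kappa(lb, la, scheme), abs=1e-12
            )
        assert icc3k(s).value == pytest.approx(icc3k(swapped).value, abs=1e-12)
        r1, r2 = rank_correlations(s), rank_correlations(swapped)
        assert r1.spearman_rho == pytest.approx(r2.spearman_rho, abs=1e-12)
        assert r1.kendall_tau == pytest.approx(r2.kendall_tau, abs=1e-12)
        assert bland_altman(s).bias == pytest.approx(-bland_altman(swapped).bias, abs=1e-12)


@pytest.mark.parametrize("seed", range(100))
def test_oracle_equivalence_battery(seed):
    """Every metric agrees with an independent brute-force implementation on
    small random instances (1e-9 for estimated metrics, 1e-12 for counts)."""
    s = random_scores(seed, integer=(seed % 3 == 0))
    truth = s.panel >= 44

    # ROC AUC == Mann-Whitney concordance probability
    if 0 < truth.sum() < s.n:
        auc = roc_curve_auc(s, 44).area
        assert auc == pytest.approx(
            oracles.auc_concordance(truth, s.software), abs=1e-12
        )

    la = [letter_grade(v) for v in s.panel]
    lb = [letter_grade(v) for v in s.software]
    assert cohen_kappa(la, lb) == pytest.approx(
        oracles.cohen_kappa_loops(la, lb, LETTERS), abs=1e-9
    )
    for scheme in ("linear", "quadratic"):
        assert weighted_kappa(la, lb, scheme) == pytest.approx(
            oracles.weighted_kappa_loops(la, lb, LETTERS, scheme), abs=1e-9
        )

    r = rank_correlations(s)
    assert r.spearman_rho == pytest.approx(
        oracles.spearman_on_ranks(s.panel, s.software), abs=1e-9
    )
    assert r.kendall_tau == pytest.approx(
        oracles.kendall_tau_b_loops(s.panel, s.software), abs=1e-9
    )

    for frac, tail in ((0.05, "worst"), (0.2, "top"), (0.4, "worst")):
        assert tail_agreement(s, frac, tail) == pytest.approx(
            oracles.tail_overlap_sets(s.subject_ids, s.panel, s.software, frac, tail),
            abs=1e-12,
        )

    st = summary_stats(s.panel)
    assert st.mean == pytest.approx(np.mean(s.panel), abs=1e-12)
    assert st.iqr == pytest.approx(st.q3 - st.q1, abs=1e-12)
    assert st.range == pytest.approx(st.maximum - st.minimum, abs=1e-12)


def test_full_report_on_simulated_scores():
    """End-to-end battery on copula-simulated scores: all ranges respected
    and the headline metrics are internally consistent."""
    s = simulate_paired_scores(n=70, target_spearman=0.73, seed=12)
    rep = full_report(s, cutoff=44, seed=12)
    for value in (rep.diagnostics.sensitivity, rep.diagnostics.specificity,
                  rep.diagnostics.ppv, rep.diagnostics.npv):
        assert np.isnan(value) or 0 <= value <= 1
    assert 0 <= rep.roc.area <= 1
    for kappa in (rep.cohen_kappa, rep.linear_weighted_kappa, rep.quadratic_weighted_kappa):
        assert -1 <= kappa <= 1
    assert rep.icc.value <= 1
    assert rep.icc.ci_low <= rep.icc.value <= rep.icc.ci_high
    assert rep.bland_altman.loa_low <= rep.bland_altman.bias <= rep.bland_altman.loa_high
    assert rep.grade_confusion.matrix.sum() == 70
    flat = rep.to_flat_dict()
    assert flat["panel_iqr"] == pytest.approx(flat["panel_q3"] - flat["panel_q1"])
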