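import itertools

import numpy as np
import pandas as pd
import pytest

from synthecv import (agreement_report, bland_altman, concordance,
                      concordance_from_counts, contour_agreement, dice,
                      hausdorff, icc, mcnemar, paired_agreement)
from synthecv.errors import UsageError

from conftest import random_mask


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        report = bland_altman(x, x)
        assert report.bias == 0 and report.sd_diff == 0
        assert report.loa_low == 0 and report.loa_high == 0

    def test_hand_arithmetic(self):
        x = np.array([-2.0, 2.0, -3.0])
        report = bland_altman(x, np.zeros(3))
        assert report.bias == pytest.approx(-1.0)
        assert report.sd_diff == pytest.approx(2.6457513110645907)
        assert report.loa_low == pytest.approx(-6.185672569686598)
        assert report.loa_high == pytest.approx(4.185672569686598)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        report = bland_altman(x, x + 3.5)
        assert report.bias == pytest.approx(-3.5)
        assert report.loa_high - report.loa_low == pytest.approx(0.0)

    def test_small_n_raises(self):
        with pytest.raises(UsageError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_ci_contains_point_estimates(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        report = bland_altman(x, y)
        assert report.ci_bias[0] <= report.bias <= report.ci_bias[1]
        assert (report.ci_loa_low[0] <= report.loa_low
                <= report.ci_loa_low[1])
        assert (report.ci_loa_high[0] <= report.loa_high
                <= report.ci_loa_high[1])

    def test_subset_predicate_on_pair_means(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = x + np.array([1.0, -1.0, 2.0, -2.0, 0.0])
        full = bland_altman(x, y)
        low = bland_altman(x, y, subset=lambda m: m <= 31)
        assert low.n == 3 and full.n == 5

    def test_loa_coverage_on_gaussian(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.3, 1.7, 100_000)
        report = bland_altman(diffs, np.zeros_like(diffs))
        coverage = np.mean((diffs >= report.loa_low)
                           & (diffs <= report.loa_high))
        assert abs(coverage - 0.95) < 0.01


class TestPairedAgreement:
    def test_identical(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        result = paired_agreement(x, x)
        assert result.pearson_r == pytest.approx(1.0)
        assert result.t_statistic == 0.0 and result.t_p == 1.0

    def test_sign_flip(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert paired_agreement(x, -x).pearson_r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([1.0, 3.0, 7.0, 8.0, 8.0])
        result = paired_agreement(x, y)
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert result.pearson_r == pytest.approx(r_oracle, abs=1e-12)
        assert result.t_statistic == pytest.approx(t_oracle, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UsageError):
            paired_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMcNemar:
    def test_printed_first_scheme(self):
        # discordant counts 18 / 22 from the 30%/30% threshold comparison
        statistic, p = mcnemar(18, 22)
        assert statistic == pytest.approx(0.225, abs=1e-12)
        assert round(p, 3) == 0.635

    def test_printed_second_scheme(self):
        # discordant counts 14 / 30 from the 29.5%/30% threshold comparison
        statistic, p = mcnemar(14, 30)
        assert statistic == pytest.approx(225.0 / 44.0, abs=1e-12)
        assert round(p, 3) == 0.024

    def test_exact_symmetric_null(self):
        _, p = mcnemar(7, 7, method="exact")
        assert p == 1.0

    def test_no_discordant_pairs(self):
        _, p = mcnemar(0, 0)
        assert p == 1.0

    def test_exact_vs_binomial_oracle(self):
        from scipy import stats

        b, c = 5, 12
        _, p = mcnemar(b, c, method="exact")
        oracle = min(1.0, 2 * sum(stats.binom.pmf(k, b + c, 0.5)
                                  for k in range(min(b, c) + 1)))
        assert p == pytest.approx(oracle, abs=1e-12)


class TestConcordance:
    def test_printed_counts_same_threshold(self):
        table = concordance_from_counts(241, 44, 18, 22)
        assert table.n == 325
        assert round(100 * table.concordance, 1) == 87.7
        props = table.proportions
        assert round(100 * props["both_negative"], 1) == 74.2
        assert round(100 * props["both_positive"], 1) == 13.5
        assert round(100 * props["false_negative"], 1) == 5.5
        assert round(100 * props["false_positive"], 1) == 6.8

    def test_printed_counts_adapted_threshold(self):
        table = concordance_from_counts(233, 48, 14, 30)
        assert round(100 * table.concordance, 1) == 86.5

    def test_identical_vectors(self):
        ref = np.array([True, False, True, False])
        table = concordance(ref, ref)
        assert table.concordance == 1.0

    def test_from_vectors_counts(self):
        ref = np.array([1, 1, 0, 0, 1], bool)
        test = np.array([1, 0, 0, 1, 1], bool)
        table = concordance(ref, test)
        assert (table.both_positive, table.both_negative,
                table.false_negative, table.false_positive) == (2, 1, 1, 1)

    def test_proportions_sum_to_one(self):
        table = concordance_from_counts(10, 5, 3, 2)
        assert sum(table.proportions.values()) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(UsageError):
            concordance([], [])


def brute_force_icc(x, form):
    """Two-way ANOVA mean squares computed cell-by-cell."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((x[i, j] - grand) ** 2
                   for i, j in itertools.product(range(n), range(k)))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_identical_raters(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc(x, "single") == pytest.approx(1.0)
        assert icc(x, "average") == pytest.approx(1.0)

    @pytest.mark.parametrize("form", ["single", "average"])
    def test_toy_table_vs_anova_oracle(self, form):
        x = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0]])
        assert icc(x, form) == pytest.approx(brute_force_icc(x, form),
                                             abs=1e-10)

    @pytest.mark.parametrize("form", ["single", "average"])
    def test_random_tables_vs_oracle(self, form):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=(rng.integers(3, 10), rng.integers(2, 5)))
            assert icc(x, form) == pytest.approx(brute_force_icc(x, form),
                                                 abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(loc=rng.normal(size=(8, 1)), size=(8, 3))
        frame = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": x.ravel()})
        result = pingouin.intraclass_corr(frame, targets="subject",
                                          raters="rater", ratings="score")
        # McGraw-Wong labels: ICC(A,1)/(A,k) = two-way random, absolute
        # agreement, single/average raters
        icc2_1 = result.loc[result["Type"] == "ICC(A,1)", "ICC"].item()
        icc2_k = result.loc[result["Type"] == "ICC(A,k)", "ICC"].item()
        assert icc(x, "single") == pytest.approx(icc2_1, abs=1e-8)
        assert icc(x, "average") == pytest.approx(icc2_k, abs=1e-8)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1000, 2))
        assert abs(icc(x, "single")) <= 0.1

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.raises(UsageError):
            icc(x, "single")


def brute_force_hausdorff(a, b, spacing):
    """All-pairs distances between boundary voxels (definition oracle)."""
    def boundary(mask):
        pts = []
        rows, cols = mask.shape
        for i, j in np.argwhere(mask):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < rows and 0 <= nj < cols
                            and mask[ni, nj]):
                        pts.append((i, j))
                        break
                else:
                    continue
                break
        return pts

    pa, pb = boundary(a), boundary(b)
    d_ab = max(min(np.hypot(x1 - x2, y1 - y2) for x2, y2 in pb)
               for x1, y1 in pa)
    d_ba = max(min(np.hypot(x1 - x2, y1 - y2) for x2, y2 in pa)
               for x1, y1 in pb)
    return max(d_ab, d_ba) * spacing


class TestContourAgreement:
    def test_identical_masks(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 3:8] = True
        d, h = contour_agreement(mask, mask, spacing_mm=1.17)
        assert d == 1.0 and h == 0.0

    def test_disjoint_dice_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[1:3, 1:3] = True
        b[7:9, 7:9] = True
        assert dice(a, b) == 0.0

    def test_offset_squares_hausdorff(self):
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[3:8, 3:8] = True
        b[4:9, 3:8] = True  # shifted one voxel down
        _, h = contour_agreement(a, b, spacing_mm=1.17)
        assert h == pytest.approx(1.17)

    def test_vs_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = random_mask(rng, shape=(9, 9), p=0.4)
            b = random_mask(rng, shape=(9, 9), p=0.4)
            if not a.any() or not b.any():
                continue
            assert hausdorff(a, b, 1.3) == pytest.approx(
                brute_force_hausdorff(a, b, 1.3), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_mask(rng, shape=(10, 10), p=0.5)
        b = random_mask(rng, shape=(10, 10), p=0.5)
        assert dice(a, b) == dice(b, a)
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_empty_mask_errors(self):
        empty = np.zeros((5, 5), bool)
        full = np.ones((5, 5), bool)
        with pytest.raises(UsageError):
            contour_agreement(empty, empty)
        with pytest.raises(UsageError):
            contour_agreement(empty, full)
        with pytest.raises(UsageError):
            dice(empty, empty)


def fake_results(n=40, seed=0, identical=False):
    rng = np.random.default_rng(seed)
    ref = rng.normal(0.28, 0.05, n).clip(0.12, 0.5)
    if identical:
        auto = ref.copy()
    else:
        auto = (ref + rng.normal(0.002, 0.01, n)).clip(0.10, 0.55)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "field_t": np.where(rng.random(n) < 0.5, 1.5, 3.0),
        "ecv_oracle_laboratory_fraction": ref,
        "ecv_oracle_synthetic_fraction": ref + rng.normal(0, 0.004, n),
        "ecv_auto_laboratory_fraction": auto,
        "ecv_auto_synthetic_fraction": auto if identical
        else auto + rng.normal(0, 0.004, n),
        "ecv_true_fraction": ref,
    })


class TestAgreementReport:
    def test_identical_methods(self):
        results = fake_results(identical=True, seed=1)
        results["ecv_auto_synthetic_fraction"] = \
            results["ecv_oracle_laboratory_fraction"]
        report = agreement_report(results,
                                  comparison_variant=("auto", "synthetic"))
        ba = report["bland_altman_percent"]["overall"]
        assert ba["bias"] == 0.0 and ba["sd_diff"] == 0.0
        assert report["concordance"]["same_threshold"]["concordance"] == 1.0

    def test_variant_rows_per_group(self):
        report = agreement_report(fake_results())
        for group in ("all", "1.5T", "3T"):
            assert set(report["variants"][group]) == {
                "oracle_laboratory", "oracle_synthetic",
                "auto_laboratory", "auto_synthetic"}

    def test_stratified_rows_present(self):
        results = fake_results(n=60, seed=3)
        # force some values above the 35% stratification split
        results.loc[:6, "ecv_oracle_laboratory_fraction"] = 0.42
        results.loc[:6, "ecv_auto_synthetic_fraction"] = 0.43
        report = agreement_report(results)
        assert "ecv_le_35pct" in report["bland_altman_percent"]
        assert "ecv_gt_35pct" in report["bland_altman_percent"]

    def test_recovery_metrics(self):
        report = agreement_report(fake_results(),
                                  truth_column="ecv_true_fraction")
        assert "recovery" in report
        assert report["recovery"]["mae_percent"] >= 0

    def test_missing_reference_raises(self):
        results = fake_results().drop(
            columns=["ecv_oracle_laboratory_fraction"])
        with pytest.raises(UsageError):
            agreement_report(results)
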