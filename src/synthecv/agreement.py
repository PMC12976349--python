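"""Method-agreement statistics: Bland-Altman, Pearson/paired-t, McNemar,
concordance tables, two-way random-effects ICC, Dice and Hausdorff.

Every statistic is implemented from its textbook definition so it can be
checked against brute-force oracles on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError

LOA_Z = 1.96  # conventional normal quantile for limits of agreement


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanReport:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    stratum: str = ""

    def to_dict(self) -> dict:
        return {"n": self.n, "bias": self.bias, "sd_diff": self.sd_diff,
                "loa_low": self.loa_low, "loa_high": self.loa_high,
                "ci_bias": list(self.ci_bias),
                "ci_loa_low": list(self.ci_loa_low),
                "ci_loa_high": list(self.ci_loa_high),
                "stratum": self.stratum}


def bland_altman(x, y, subset=None, stratum: str = "") -> BlandAltmanReport:
    """Bland-Altman agreement of paired measurements (differences x - y).

    Limits of agreement use the 1.96 normal quantile; the bias CI uses the
    t distribution with SE = SD/sqrt(n); each LoA CI uses the large-sample
    SE = SD*sqrt(3/n). ``subset`` optionally restricts the pairs via a
    predicate evaluated on the pair means (or a boolean mask).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be equal-length 1D vectors")
    if subset is not None:
        keep = (subset((x + y) / 2.0) if callable(subset)
                else np.asarray(subset, bool))
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UsageError(f"Bland-Altman needs n >= 3 pairs (got {n})")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - LOA_Z * sd, bias + LOA_Z * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanReport(
        n=n, bias=bias, sd_diff=sd, loa_low=loa_low, loa_high=loa_high,
        ci_bias=(bias - tq * se_bias, bias + tq * se_bias),
        ci_loa_low=(loa_low - tq * se_loa, loa_low + tq * se_loa),
        ci_loa_high=(loa_high - tq * se_loa, loa_high + tq * se_loa),
        stratum=stratum)


# ---------------------------------------------------------------------------
# Pearson + paired t


@dataclass(frozen=True)
class PairedAgreement:
    n: int
    pearson_r: float
    pearson_p: float
    t_statistic: float
    t_p: float
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float

    def to_dict(self) -> dict:
        return {"n": self.n, "pearson_r": self.pearson_r,
                "pearson_p": self.pearson_p,
                "t_statistic": self.t_statistic, "t_p": self.t_p,
                "mean_x": self.mean_x, "sd_x": self.sd_x,
                "mean_y": self.mean_y, "sd_y": self.sd_y}


def paired_agreement(x, y) -> PairedAgreement:
    """Pearson correlation and two-sided paired t-test for paired vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise UsageError("need equal-length 1D vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UsageError("Pearson correlation undefined for zero-variance "
                         "input")
    r, r_p = stats.pearsonr(x, y)
    diffs = x - y
    if np.allclose(diffs, diffs[0]) and diffs.std(ddof=1) == 0:
        if diffs[0] == 0:
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = float("inf"), 0.0
    else:
        t_stat, t_p = stats.ttest_rel(x, y)
    return PairedAgreement(n=x.size, pearson_r=float(r), pearson_p=float(r_p),
                           t_statistic=float(t_stat), t_p=float(t_p),
                           mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
                           mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)))


# ---------------------------------------------------------------------------
# McNemar + concordance


def mcnemar(false_negative: int, false_positive: int,
            method: str = "cc_chi2") -> tuple[float, float]:
    """McNemar's test on the discordant counts.

    ``cc_chi2`` (default): continuity-corrected chi-square
    ``(|b-c|-1)^2/(b+c)`` against the chi-square(1) upper tail. ``exact``:
    two-sided binomial(b+c, 1/2), doubling the smaller tail, capped at 1.
    With no discordant pairs the p-value is 1 by convention.
    """
    b, c = int(false_negative), int(false_positive)
    if b < 0 or c < 0:
        raise UsageError("discordant counts must be non-negative")
    if b + c == 0:
        return 0.0, 1.0
    if method == "cc_chi2":
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
        return float(statistic), float(stats.chi2.sf(statistic, 1))
    if method == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, b + c, 0.5)))
        return float(k), p
    raise UsageError(f"unknown McNemar method {method!r}")


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 classification agreement relative to a reference method."""

    both_negative: int
    both_positive: int
    false_negative: int   # reference positive, test negative
    false_positive: int   # reference negative, test positive
    mcnemar_statistic: float = field(default=float("nan"))
    mcnemar_p: float = field(default=float("nan"))

    @property
    def n(self) -> int:
        return (self.both_negative + self.both_positive
                + self.false_negative + self.false_positive)

    @property
    def concordance(self) -> float:
        return (self.both_negative + self.both_positive) / self.n

    @property
    def proportions(self) -> dict:
        n = self.n
        return {"both_negative": self.both_negative / n,
                "both_positive": self.both_positive / n,
                "false_negative": self.false_negative / n,
                "false_positive": self.false_positive / n}

    def to_dict(self) -> dict:
        return {"counts": {"both_negative": self.both_negative,
                           "both_positive": self.both_positive,
                           "false_negative": self.false_negative,
                           "false_positive": self.false_positive},
                "n": self.n, "concordance": self.concordance,
                "proportions": self.proportions,
                "mcnemar_statistic": self.mcnemar_statistic,
                "mcnemar_p": self.mcnemar_p}


def concordance_from_counts(both_negative: int, both_positive: int,
                            false_negative: int, false_positive: int,
                            mcnemar_method: str = "cc_chi2"
                            ) -> ConcordanceTable:
    if min(both_negative, both_positive, false_negative, false_positive) < 0:
        raise UsageError("counts must be non-negative")
    if both_negative + both_positive + false_negative + false_positive == 0:
        raise UsageError("empty contingency table")
    statistic, p = mcnemar(false_negative, false_positive,
                           method=mcnemar_method)
    return ConcordanceTable(both_negative, both_positive, false_negative,
                            false_positive, statistic, p)


def concordance(classifications_ref, classifications_test,
                mcnemar_method: str = "cc_chi2") -> ConcordanceTable:
    """Agreement table of two binary classification vectors."""
    ref = np.asarray(classifications_ref, bool)
    test = np.asarray(classifications_test, bool)
    if ref.shape != test.shape or ref.ndim != 1 or ref.size == 0:
        raise UsageError("need equal-length non-empty binary vectors")
    return concordance_from_counts(
        both_negative=int(np.sum(~ref & ~test)),
        both_positive=int(np.sum(ref & test)),
        false_negative=int(np.sum(ref & ~test)),
        false_positive=int(np.sum(~ref & test)),
        mcnemar_method=mcnemar_method)


# ---------------------------------------------------------------------------
# ICC


def icc(ratings, form: str = "single") -> float:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    ``ratings`` is an n-subjects x k-raters table with no missing cells.
    ``form='single'`` gives the single-rater ICC(2,1); ``form='average'``
    the k-rater average ICC(2,k). Computed from the two-way ANOVA mean
    squares.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2:
        raise UsageError("ratings must be a 2D subjects x raters table")
    if np.any(~np.isfinite(x)):
        raise UsageError("ratings contain missing cells (no imputation)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise UsageError("need >= 3 subjects and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (np.sum((x - grand) ** 2) - k * np.sum((row_means - grand) ** 2)
           - n * np.sum((col_means - grand) ** 2))
    mse = sse / ((n - 1) * (k - 1))
    if form == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "average":
        denom = msr + (msc - mse) / n
    else:
        raise UsageError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise UsageError("ICC undefined: zero denominator (no variance)")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# contour agreement


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise UsageError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise UsageError("Dice undefined for two empty masks")
    return float(2.0 * np.sum(a & b) / denom)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with an 8-neighbour outside (raster edge counts as
    outside); equals mask minus its 3x3 erosion."""
    from .refinement import erode_mask

    mask = np.asarray(mask, bool)
    return mask & ~erode_mask(mask, 3)


def hausdorff(a, b, spacing_mm: float = 1.0) -> float:
    """Classic (maximum) Hausdorff distance between mask boundaries, in mm.

    Euclidean distances between boundary-voxel centers, scaled by the
    isotropic voxel spacing.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise UsageError("masks must share a shape")
    if not a.any() or not b.any():
        raise UsageError("Hausdorff undefined for an empty mask")
    pa = np.argwhere(boundary_voxels(a)).astype(float)
    pb = np.argwhere(boundary_voxels(b)).astype(float)
    from scipy.spatial.distance import cdist

    d = cdist(pa, pb)
    directed_ab = d.min(axis=1).max()
    directed_ba = d.min(axis=0).max()
    return float(max(directed_ab, directed_ba) * spacing_mm)


def contour_agreement(a, b, spacing_mm: float = 1.0) -> tuple[float, float]:
    """(Dice, Hausdorff in mm) for two binary masks.

    One empty mask gives Dice 0 but an undefined Hausdorff (raised).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if not a.any() and not b.any():
        raise UsageError("contour agreement undefined for two empty masks")
    if not a.any() or not b.any():
        raise UsageError("Hausdorff undefined: one mask is empty (Dice "
                         "would be 0)")
    return dice(a, b), hausdorff(a, b, spacing_mm)


# ---------------------------------------------------------------------------
# cohort-level report


def _pct(x: float) -> float:
    return 100.0 * x


def agreement_report(results: pd.DataFrame,
                     reference_variant: tuple[str, str] = ("oracle",
                                                           "laboratory"),
                     comparison_variant: tuple[str, str] | None = None,
                     strata_threshold: float = 0.35,
                     thresholds=(0.30, 0.295),
                     truth_column: str | None = None) -> dict:
    """Cohort-level agreement report over the contour x HCT variant grid.

    ``results`` is one row per subject with ECV variant columns named
    ``ecv_<contour>_<hctmethod>_fraction``. The reference variant plays the
    role of the conventional measurement; the comparison variant (default:
    the fully automated synthetic one, i.e. the non-reference contour with
    synthetic HCT) is tested against it with Bland-Altman (overall and
    stratified at ``strata_threshold`` of the reference ECV), Pearson,
    paired t and threshold concordance at both threshold schemes. When a
    ground-truth column is given, recovery metrics are added. All ECV
    summaries are reported in percent.
    """
    variant_cols = {}
    for col in results.columns:
        if col.startswith("ecv_") and col.endswith("_fraction"):
            parts = col[len("ecv_"):-len("_fraction")].rsplit("_", 1)
            if len(parts) == 2:
                variant_cols[(parts[0], parts[1])] = col
    ref_key = tuple(reference_variant)
    if ref_key not in variant_cols:
        raise UsageError(f"reference variant {ref_key} not present in the "
                         "results table")
    if comparison_variant is None:
        candidates = [k for k in variant_cols
                      if k[1] == "synthetic" and k[0] != ref_key[0]]
        comparison_variant = (candidates[0] if candidates else
                              next(k for k in variant_cols if k != ref_key))
    cmp_key = tuple(comparison_variant)
    if cmp_key not in variant_cols:
        raise UsageError(f"comparison variant {cmp_key} not present")

    ref = results[variant_cols[ref_key]].to_numpy(float)
    test = results[variant_cols[cmp_key]].to_numpy(float)

    groups = {"all": np.ones(len(results), bool)}
    if "field_t" in results.columns:
        for f in sorted(results["field_t"].unique()):
            groups[f"{f:g}T"] = (results["field_t"] == f).to_numpy()

    variants = {}
    for group_name, keep in groups.items():
        rows = {}
        ref_g = ref[keep]
        for key, col in sorted(variant_cols.items()):
            vals = results.loc[keep, col].to_numpy(float)
            entry = {"contours": key[0], "hct_method": key[1],
                     "n": int(keep.sum()),
                     "mean_percent": _pct(vals.mean()),
                     "sd_percent": _pct(vals.std(ddof=1))}
            if key != ref_key and keep.sum() >= 3 and vals.std() > 0:
                pa = paired_agreement(vals, ref_g)
                entry["paired_t_p_vs_reference"] = pa.t_p
            rows["_".join(key)] = entry
        variants[group_name] = rows

    ba_overall = bland_altman(_pct(test), _pct(ref), stratum="all")
    ba = {"overall": ba_overall.to_dict()}
    low = ref <= strata_threshold
    for name, keep in (
            (f"ecv_le_{_pct(strata_threshold):g}pct", low),
            (f"ecv_gt_{_pct(strata_threshold):g}pct", ~low)):
        if keep.sum() >= 3:
            ba[name] = bland_altman(_pct(test[keep]), _pct(ref[keep]),
                                    stratum=name).to_dict()
    pa = paired_agreement(_pct(test), _pct(ref))

    conc = {}
    schemes = {"same_threshold": (thresholds[0], thresholds[0])}
    if len(thresholds) > 1:
        schemes["adapted_threshold"] = (thresholds[0], thresholds[1])
    for name, (thr_ref, thr_test) in schemes.items():
        table = concordance(ref >= thr_ref, test >= thr_test)
        conc[name] = {"reference_threshold_percent": _pct(thr_ref),
                      "test_threshold_percent": _pct(thr_test),
                      **table.to_dict()}

    report = {
        "n_subjects": int(len(results)),
        "reference_variant": "_".join(ref_key),
        "comparison_variant": "_".join(cmp_key),
        "variants": variants,
        "bland_altman_percent": ba,
        "paired_agreement_percent": pa.to_dict(),
        "concordance": conc,
    }
    if truth_column is not None and truth_column in results.columns:
        truth = results[truth_column].to_numpy(float)
        diffs = _pct(test - truth)
        in_loa = ((_pct(test - ref) >= ba_overall.loa_low)
                  & (_pct(test - ref) <= ba_overall.loa_high))
        report["recovery"] = {
            "mae_percent": float(np.mean(np.abs(diffs))),
            "bias_percent": float(np.mean(diffs)),
            "reference_mae_percent": float(np.mean(np.abs(_pct(ref - truth)))),
            "loa_coverage": float(np.mean(in_loa)),
        }
    return report


def plot_bland_altman(x, y, path, title: str = "Bland-Altman") -> None:
    """Write a Bland-Altman scatter (means vs differences) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(x, y)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((x + y) / 2, x - y, s=12, alpha=0.7)
    ax.axhline(report.bias, color="darkblue", label=f"bias {report.bias:.2f}")
    for loa in (report.loa_low, report.loa_high):
        ax.axhline(loa, color="red", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
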