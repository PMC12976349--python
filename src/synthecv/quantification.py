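"""Median T1 extraction, synthetic hematocrit, ECV and classification.

ECV is computed as

    ECV = (1 - HCT) * (1/T1_myo_post - 1/T1_myo_native)
                      / (1/T1_blood_post - 1/T1_blood_native)

with either a laboratory hematocrit or a "synthetic" one predicted from the
native blood-pool relaxation rate via stratified (sex x field strength)
ordinary-least-squares models. ECV values are fractions internally;
reporting layers render percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EcvComputationError, FittingError, MeasurementError,
                     UsageError)
from .io import T1Map
from .refinement import refine_all
from .segmentation import SegMasks

HCT_HARD_CLAMP = (0.05, 0.70)
HCT_WARN_RANGE = (0.15, 0.60)
DEFAULT_THRESHOLDS = (0.30, 0.295)


def median_t1(t1map: T1Map, mask: np.ndarray) -> float:
    """Median of the map values inside the mask (even count: midpoint mean)."""
    mask = np.asarray(mask, bool)
    if mask.shape != t1map.values.shape:
        raise MeasurementError("mask and map shapes differ")
    if not mask.any():
        raise MeasurementError("empty measurement mask")
    return float(np.median(t1map.values[mask]))


def t1_to_r1(t1_ms: float) -> float:
    """Relaxation rate in 1/s from a T1 in ms."""
    if t1_ms <= 0:
        raise UsageError("T1 must be positive")
    return 1000.0 / t1_ms


@dataclass(frozen=True)
class HctModel:
    """Linear model HCT = intercept + slope * R1_blood_native (R1 in 1/s)."""

    intercept: float
    slope: float
    sex: str | None = None       # None = pooled over the covariate
    field: float | None = None
    chamber: str = "LV"
    n: int = 0
    residual_sd: float = float("nan")

    def predict(self, t1_blood_native_ms: float) -> tuple[float, bool]:
        """Predicted HCT fraction and a flag set when the raw prediction was
        clamped or fell outside the plausible range."""
        raw = self.intercept + self.slope * t1_to_r1(t1_blood_native_ms)
        clamped = float(np.clip(raw, *HCT_HARD_CLAMP))
        flagged = (raw != clamped
                   or not HCT_WARN_RANGE[0] <= raw <= HCT_WARN_RANGE[1])
        return clamped, flagged


@dataclass(frozen=True)
class HctModelSet:
    """Models keyed by stratum; falls back to a pooled model if present."""

    models: dict = field(default_factory=dict)

    def lookup(self, sex: str | None = None,
               field_t: float | None = None) -> HctModel:
        for key in ((sex, field_t), (None, field_t), (sex, None), (None, None)):
            if key in self.models:
                return self.models[key]
        raise UsageError(f"no HCT model for stratum sex={sex}, "
                         f"field={field_t} and no pooled fallback")

    def predict(self, t1_blood_native_ms: float, sex: str | None = None,
                field_t: float | None = None) -> tuple[float, bool]:
        return self.lookup(sex, field_t).predict(t1_blood_native_ms)

    def to_dict(self) -> dict:
        out = {}
        for (sex, field_t), m in self.models.items():
            key = f"sex={sex or 'any'},field={field_t or 'any'}"
            out[key] = {"intercept": m.intercept, "slope": m.slope,
                        "n": m.n, "residual_sd": m.residual_sd}
        return out


HCT_FIT_COLUMNS = ["sex", "field_t", "t1_blood_native_ms", "hct_fraction"]


def fit_hct_models(samples: pd.DataFrame, stratify_sex: bool = True,
                   stratify_field: bool = True, chamber: str = "LV",
                   min_per_stratum: int = 10) -> HctModelSet:
    """OLS fit of HCT on native blood R1, one model per requested stratum.

    ``samples`` needs columns sex, field_t, t1_blood_native_ms,
    hct_fraction. Raises :class:`FittingError` naming any under-sized
    stratum.
    """
    for col in HCT_FIT_COLUMNS:
        if col not in samples.columns:
            raise FittingError(f"calibration table missing column '{col}'")
    group_cols = []
    if stratify_sex:
        group_cols.append("sex")
    if stratify_field:
        group_cols.append("field_t")
    groups = (samples.groupby(group_cols, sort=True) if group_cols
              else [((), samples)])
    models = {}
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        if len(grp) < min_per_stratum:
            raise FittingError(
                f"stratum {dict(zip(group_cols, key))} has only "
                f"{len(grp)} samples (need >= {min_per_stratum})")
        r1 = 1000.0 / grp["t1_blood_native_ms"].to_numpy(float)
        hct = grp["hct_fraction"].to_numpy(float)
        design = np.column_stack([np.ones_like(r1), r1])
        coef, *_ = np.linalg.lstsq(design, hct, rcond=None)
        resid = hct - design @ coef
        dof = max(len(grp) - 2, 1)
        named = dict(zip(group_cols, key))
        models[(named.get("sex"), named.get("field_t"))] = HctModel(
            intercept=float(coef[0]), slope=float(coef[1]),
            sex=named.get("sex"), field=named.get("field_t"),
            chamber=chamber, n=len(grp),
            residual_sd=float(np.sqrt(resid @ resid / dof)))
    return HctModelSet(models=models)


def compute_ecv(t1_myo_native: float, t1_myo_post: float,
                t1_blood_native: float, t1_blood_post: float,
                hct: float) -> float:
    """Extracellular volume fraction from the four T1 medians and HCT."""
    for name, t1 in (("t1_myo_native", t1_myo_native),
                     ("t1_myo_post", t1_myo_post),
                     ("t1_blood_native", t1_blood_native),
                     ("t1_blood_post", t1_blood_post)):
        if t1 <= 0:
            raise EcvComputationError(f"{name} must be positive")
    if not 0 < hct < 1:
        raise EcvComputationError("HCT must lie in (0,1)")
    d_r1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_native
    if d_r1_blood <= 0:
        raise EcvComputationError(
            "non-physiological contrast dynamics: post-contrast blood T1 "
            "not below native blood T1")
    d_r1_myo = 1.0 / t1_myo_post - 1.0 / t1_myo_native
    if d_r1_myo < 0:
        warnings.warn("myocardial T1 increased after contrast; ECV will be "
                      "negative", stacklevel=2)
    return (1.0 - hct) * d_r1_myo / d_r1_blood


def classify_ecv(ecv: float, threshold: float) -> bool:
    """Positive iff ECV >= threshold (boundary counts as positive)."""
    return bool(ecv >= threshold)


@dataclass(frozen=True)
class EcvResult:
    subject_id: str
    medians: dict            # variant -> {t1_myo_native_ms, ...}
    hct_lab: float | None
    hct_synthetic: dict      # variant -> fraction
    ecv: dict                # (variant, hct_method) -> fraction
    classifications: dict    # (variant, hct_method, threshold) -> bool
    otsu_thresholds: dict    # (variant, phase) -> ms
    flags: tuple = ()

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id}
        if self.hct_lab is not None:
            row["hct_lab_fraction"] = self.hct_lab
        for variant, meds in self.medians.items():
            for k, v in meds.items():
                row[f"{k}_{variant}"] = v
        for variant, h in self.hct_synthetic.items():
            row[f"hct_synthetic_fraction_{variant}"] = h
        for (variant, method), e in self.ecv.items():
            row[f"ecv_{variant}_{method}_fraction"] = e
        for (variant, method, thr), c in self.classifications.items():
            row[f"cls_{variant}_{method}_at_{thr:g}"] = int(c)
        row["flags"] = ";".join(self.flags)
        return row


def quantify_subject(native: T1Map, post: T1Map,
                     mask_variants: dict[str, SegMasks],
                     hct_lab: float | None = None,
                     hct_models: HctModelSet | None = None,
                     sex: str | None = None,
                     thresholds=DEFAULT_THRESHOLDS,
                     kernel_size: int = 3) -> EcvResult:
    """Full per-subject quantification over a grid of contour variants.

    For every contour variant the masks are refined, medians extracted, and
    ECV computed once per available HCT method (laboratory and/or
    synthetic), mirroring the contour-method x HCT-method comparison grid.
    """
    if not mask_variants:
        raise UsageError("at least one mask variant is required")
    if hct_lab is None and hct_models is None:
        raise UsageError("need a laboratory HCT and/or fitted HCT models")
    subject_id = native.subject_id or post.subject_id
    medians, hct_syn, ecv, cls, thrs = {}, {}, {}, {}, {}
    flags: list[str] = []
    for variant, masks in mask_variants.items():
        try:
            ref_native, ref_post = refine_all(masks, native, post,
                                              kernel_size=kernel_size)
        except Exception as exc:
            raise type(exc)(f"subject {subject_id}, variant {variant}: "
                            f"{exc}") from exc
        meds = {
            "t1_myo_native_ms": median_t1(native,
                                          ref_native.myocardium_refined),
            "t1_myo_post_ms": median_t1(post, ref_post.myocardium_refined),
            "t1_blood_native_ms": median_t1(native, ref_native.blood_refined),
            "t1_blood_post_ms": median_t1(post, ref_post.blood_refined),
        }
        medians[variant] = meds
        thrs[(variant, "native")] = ref_native.otsu_threshold_ms
        thrs[(variant, "post")] = ref_post.otsu_threshold_ms
        hct_methods = {}
        if hct_lab is not None:
            hct_methods["laboratory"] = hct_lab
        if hct_models is not None:
            pred, flagged = hct_models.predict(
                meds["t1_blood_native_ms"], sex=sex, field_t=native.field)
            hct_syn[variant] = pred
            hct_methods["synthetic"] = pred
            if flagged:
                flags.append(f"hct_clamped:{variant}")
        for method, hct in hct_methods.items():
            value = compute_ecv(meds["t1_myo_native_ms"],
                                meds["t1_myo_post_ms"],
                                meds["t1_blood_native_ms"],
                                meds["t1_blood_post_ms"], hct)
            ecv[(variant, method)] = value
            for thr in thresholds:
                cls[(variant, method, thr)] = classify_ecv(value, thr)
    return EcvResult(subject_id=subject_id, medians=medians, hct_lab=hct_lab,
                     hct_synthetic=hct_syn, ecv=ecv, classifications=cls,
                     otsu_thresholds=thrs, flags=tuple(flags))
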