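"""End-to-end cohort processing used by the CLI and the validation suite."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .agreement import agreement_report
from .errors import RefinementError, SegmentationError, SynthEcvError
from .io import (read_cohort_table, read_json, read_label_raster, read_t1map,
                 write_json)
from .quantification import (DEFAULT_THRESHOLDS, HctModelSet, fit_hct_models,
                             quantify_subject)
from .segmentation import segment_classical, segment_oracle

log = logging.getLogger("synthecv")

BACKENDS = ("oracle", "classical", "learned")

RESULT_REQUIRED_COLUMNS = ["subject_id"]


def segment_backend(backend: str, native, labels=None, learned_model=None):
    if backend == "oracle":
        if labels is None:
            raise SynthEcvError("oracle backend needs a ground-truth label "
                                "raster")
        return segment_oracle(labels)
    if backend == "classical":
        return segment_classical(native)
    if backend == "learned":
        from .learned import segment_learned

        if learned_model is None:
            raise SynthEcvError("learned backend needs a trained model")
        return segment_learned(native, learned_model)
    raise SynthEcvError(f"unknown segmentation backend {backend!r}; "
                        f"choose one of {BACKENDS}")


def calibrate_hct_from_cohort(cohort: pd.DataFrame,
                              stratify_sex: bool = True,
                              stratify_field: bool = True,
                              fallback: bool = True) -> HctModelSet:
    """Fit synthetic-HCT models from a cohort table carrying ground-truth
    (or laboratory) HCT and native blood-pool T1.

    With ``fallback`` the stratification degrades (sex x field -> field ->
    pooled) when a stratum is too small, so tiny cohorts still calibrate.
    """
    from .errors import FittingError

    samples = pd.DataFrame({
        "sex": cohort["sex"],
        "field_t": cohort["field_t"],
        "t1_blood_native_ms": cohort["t1_blood_native_ms"],
        "hct_fraction": cohort["hct_true_fraction"],
    })
    plans = [(stratify_sex, stratify_field)]
    if fallback:
        plans += [(False, stratify_field), (False, False)]
    last_error = None
    for plan_sex, plan_field in plans:
        try:
            return fit_hct_models(samples, stratify_sex=plan_sex,
                                  stratify_field=plan_field,
                                  min_per_stratum=min(10, max(3,
                                                              len(samples))))
        except FittingError as exc:
            last_error = exc
            log.debug("HCT calibration plan (sex=%s, field=%s) failed: %s",
                      plan_sex, plan_field, exc)
    raise last_error


def hct_models_from_coefficients(coeffs: dict) -> HctModelSet:
    """Build an HctModelSet from user-supplied published coefficients.

    ``coeffs`` maps stratum keys (``"sex=male,field=1.5"``, ``"any"``
    allowed for a pooled entry) to ``{"intercept": ..., "slope": ...}``
    with slope per 1/s of native blood R1.
    """
    from .quantification import HctModel

    models = {}
    for key, entry in coeffs.items():
        sex = field_t = None
        for part in key.split(","):
            name, _, value = part.partition("=")
            if name.strip() == "sex" and value.strip() != "any":
                sex = value.strip()
            if name.strip() == "field" and value.strip() != "any":
                field_t = float(value)
        models[(sex, field_t)] = HctModel(
            intercept=float(entry["intercept"]), slope=float(entry["slope"]),
            sex=sex, field=field_t)
    return HctModelSet(models=models)


def run_cohort(cohort_dir: str | Path, backend: str = "oracle",
               hct_models: HctModelSet | None = None,
               thresholds=DEFAULT_THRESHOLDS,
               learned_model=None,
               include_reference_backend: bool = True) -> pd.DataFrame:
    """Quantify every subject of a phantom cohort directory.

    The oracle (ground-truth contour) variant plays the role of the manual
    reference; ``backend`` supplies the automated variant. Laboratory HCT is
    taken from the cohort's ground truth. Returns one row per subject;
    subjects whose segmentation or refinement fails are recorded with an
    ``error`` column and skipped in the numeric columns.
    """
    cohort_dir = Path(cohort_dir)
    manifest = read_json(cohort_dir / "manifest.json")
    cohort = read_cohort_table(cohort_dir / manifest["cohort_table"])
    if hct_models is None:
        hct_models = calibrate_hct_from_cohort(cohort)
    rows = []
    t0 = time.time()
    for _, meta in cohort.iterrows():
        sid = meta["subject_id"]
        entry = manifest["subjects"][sid]
        native = read_t1map(cohort_dir / entry["native"])
        post = read_t1map(cohort_dir / entry["post"])
        labels = read_label_raster(cohort_dir / entry["labels"])
        row = {"subject_id": sid, "sex": meta["sex"],
               "field_t": meta["field_t"],
               "ecv_true_fraction": meta["ecv_true_fraction"],
               "hct_true_fraction": meta["hct_true_fraction"]}
        try:
            variants = {}
            if include_reference_backend or backend == "oracle":
                variants["oracle"] = segment_oracle(labels)
            if backend != "oracle":
                variants[backend] = segment_backend(
                    backend, native, labels=labels,
                    learned_model=learned_model)
            result = quantify_subject(
                native, post, variants,
                hct_lab=float(meta["hct_true_fraction"]),
                hct_models=hct_models, sex=meta["sex"],
                thresholds=thresholds)
            row.update(result.to_row())
        except (SegmentationError, RefinementError) as exc:
            log.warning("subject %s failed: %s", sid, exc)
            row["error"] = str(exc)
        rows.append(row)
    log.info("quantified %d subjects in %.1f s", len(rows), time.time() - t0)
    return pd.DataFrame(rows)


def run_all(cohort_dir: str | Path, out_dir: str | Path,
            backend: str = "classical", thresholds=DEFAULT_THRESHOLDS,
            learned_model=None) -> dict:
    """Quantify a cohort and emit the results CSV plus agreement report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = run_cohort(cohort_dir, backend=backend, thresholds=thresholds,
                         learned_model=learned_model)
    ok = results[results.get("error").isna()] if "error" in results else results
    results_path = out_dir / "results.csv"
    results.to_csv(results_path, index=False)
    automated = backend if backend != "oracle" else "oracle"
    report = agreement_report(
        ok, reference_variant=("oracle", "laboratory"),
        comparison_variant=(automated, "synthetic"),
        thresholds=thresholds, truth_column="ecv_true_fraction")
    report["n_failed"] = int(len(results) - len(ok))
    report_path = out_dir / "agreement_report.json"
    write_json(report, report_path)
    return {"results": str(results_path), "report": str(report_path),
            "n_subjects": int(len(results)), "n_failed": report["n_failed"]}
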