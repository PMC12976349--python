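"""Optional trainable segmentation backend (desk-scale stand-in).

The production system this emulates used a full 2D encoder-decoder trained
per contrast phase on z-score-normalized maps. At desk scale we train a
small multilayer perceptron per phase that classifies every voxel from its
z-scored local patch plus normalized raster coordinates, then assembles
masks with the same conventions and largest-component cleanup as the other
backends. One model per contrast phase; artifacts persist as a directory
holding the weights and a JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier

from .errors import SegmentationError, UsageError
from .io import T1Map, read_label_raster, read_t1map
from .phantom import (LBL_LV_BLOOD, LBL_MYOCARDIUM, LBL_PAPILLARY,
                      LBL_RV_BLOOD)
from .segmentation import SegMasks, clean_structure

MIN_TRAINING_SUBJECTS = 10


@dataclass(frozen=True)
class TrainConfig:
    phase: str = "native"
    patch_radius: int = 2          # (2r+1)^2 intensity features
    hidden_units: int = 32
    max_iter: int = 60
    samples_per_image: int = 2000
    seed: int = 0


def _patch_features(values: np.ndarray, patch_radius: int) -> np.ndarray:
    """Per-voxel features: z-scored patch intensities + normalized coords."""
    z = (values - values.mean()) / (values.std() + 1e-9)
    r = patch_radius
    padded = np.pad(z, r, mode="edge")
    rows, cols = values.shape
    feats = [padded[r + di:r + di + rows, r + dj:r + dj + cols].ravel()
             for di in range(-r, r + 1) for dj in range(-r, r + 1)]
    rr, cc = np.mgrid[0:rows, 0:cols]
    feats.append((rr / rows).ravel())
    feats.append((cc / cols).ravel())
    return np.column_stack(feats)


@dataclass(frozen=True)
class LearnedModel:
    classifier: MLPClassifier
    config: TrainConfig

    @property
    def phase(self) -> str:
        return self.config.phase

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, out_dir / "weights.joblib")
        with open(out_dir / "config.json", "w") as fh:
            json.dump(self.config.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, model_dir: str | Path) -> "LearnedModel":
        model_dir = Path(model_dir)
        with open(model_dir / "config.json") as fh:
            config = TrainConfig(**json.load(fh))
        return cls(classifier=joblib.load(model_dir / "weights.joblib"),
                   config=config)


def train_learned_backend(manifest: dict, cohort_dir: str | Path,
                          config: TrainConfig = TrainConfig()
                          ) -> LearnedModel:
    """Train a per-phase voxel classifier on a phantom cohort.

    ``manifest`` is the cohort manifest from
    :func:`synthecv.phantom.generate_cohort`; ground-truth label rasters
    supply the voxel classes. Deterministic for a fixed config seed.
    """
    subjects = manifest["subjects"]
    if len(subjects) < MIN_TRAINING_SUBJECTS:
        raise SegmentationError(
            f"cohort too small for training ({len(subjects)} < "
            f"{MIN_TRAINING_SUBJECTS} subjects)")
    cohort_dir = Path(cohort_dir)
    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for sid in sorted(subjects):
        entry = subjects[sid]
        t1map = read_t1map(cohort_dir / entry[config.phase])
        labels = read_label_raster(cohort_dir / entry["labels"]).labels
        feats = _patch_features(t1map.values, config.patch_radius)
        idx = rng.choice(feats.shape[0],
                         size=min(config.samples_per_image, feats.shape[0]),
                         replace=False)
        xs.append(feats[idx])
        ys.append(labels.ravel()[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    clf = MLPClassifier(hidden_layer_sizes=(config.hidden_units,),
                        max_iter=config.max_iter, random_state=config.seed,
                        early_stopping=False)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are fine here
        clf.fit(x, y)
    return LearnedModel(classifier=clf, config=config)


def segment_learned(t1map: T1Map, model: LearnedModel) -> SegMasks:
    """Predict per-voxel classes and assemble masks (same conventions as the
    oracle backend, with largest-component cleanup per structure)."""
    if t1map.phase != model.phase:
        raise UsageError(f"phase mismatch: model trained on {model.phase!r} "
                         f"maps applied to a {t1map.phase!r} map")
    feats = _patch_features(t1map.values, model.config.patch_radius)
    pred = model.classifier.predict(feats).reshape(t1map.values.shape)
    endo = clean_structure(np.isin(pred, (LBL_LV_BLOOD, LBL_PAPILLARY)))
    epi = clean_structure(
        np.isin(pred, (LBL_LV_BLOOD, LBL_MYOCARDIUM, LBL_PAPILLARY)))
    rv = clean_structure((pred == LBL_RV_BLOOD) & ~epi)
    for name, mask in (("epicardial", epi), ("endocardial", endo),
                       ("rv", rv)):
        if not mask.any():
            raise SegmentationError(f"learned backend predicted an empty "
                                    f"{name} structure")
    endo = endo & epi  # enforce the subset invariant after cleanup
    return SegMasks(epicardial=epi, endocardial=endo, rv=rv,
                    spacing_mm=t1map.spacing_mm, provenance="learned")
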