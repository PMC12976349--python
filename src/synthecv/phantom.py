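"""Digital short-axis T1-map phantom cohorts with known ground truth.

Each phantom subject is a 2D short-axis scene: LV cavity blood, a myocardial
ring, papillary muscles inside the cavity, and an RV-cavity crescent, all
rendered as paired native / post-contrast T1 maps. Ground-truth hematocrit
(HCT) and extracellular volume fraction (ECV) are drawn from configurable
priors; the post-contrast myocardial T1 is derived by inverting the ECV
formula, so the formula evaluated on noiseless tissue values returns the
true ECV exactly.

Label codes
-----------
0 background, 1 LV cavity blood, 2 myocardium, 3 RV cavity blood,
4 papillary muscle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, GeometryError, RenderingError

LBL_BACKGROUND = 0
LBL_LV_BLOOD = 1
LBL_MYOCARDIUM = 2
LBL_RV_BLOOD = 3
LBL_PAPILLARY = 4

_VALID_LABELS = frozenset({0, 1, 2, 3, 4})


@dataclass(frozen=True)
class Prior:
    """Truncated-normal prior: N(mean, sd) restricted to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: negative SD {self.sd}")
        if not self.low < self.high:
            raise ConfigurationError(f"{name}: empty truncation interval")

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)


@dataclass(frozen=True)
class PapillarySpec:
    center_voxel: tuple[float, float]   # (row, col), may be fractional
    radius_mm: float


@dataclass(frozen=True)
class RvCrescentSpec:
    """Annular sector around the LV centre, beyond the epicardium."""

    gap_mm: float            # radial gap between epicardium and RV cavity
    thickness_mm: float      # radial thickness of the crescent
    center_angle_deg: float  # direction of the crescent midline
    extent_deg: float        # full angular extent


@dataclass(frozen=True)
class GeometrySpec:
    raster_shape: tuple[int, int] = (128, 128)
    spacing_mm: float = 1.17
    lv_center: tuple[float, float] = (64.0, 64.0)
    epicardial_radius_mm: float = 30.0
    wall_thickness_mm: float = 9.0
    papillary: tuple[PapillarySpec, ...] = ()
    # gap wide enough that partial-volume halos around the epicardium and
    # the RV cavity never touch (>= ~4 voxels at 1.17 mm spacing)
    rv_crescent: RvCrescentSpec = field(
        default_factory=lambda: RvCrescentSpec(5.0, 9.0, 180.0, 150.0))

    @property
    def endocardial_radius_mm(self) -> float:
        return self.epicardial_radius_mm - self.wall_thickness_mm

    def validate(self) -> None:
        if self.spacing_mm <= 0:
            raise GeometryError("spacing must be positive")
        if not self.wall_thickness_mm < self.epicardial_radius_mm:
            raise GeometryError("wall thickness must be smaller than the "
                                "epicardial radius")
        cy, cx = self.lv_center
        r_out = (self.epicardial_radius_mm + self.rv_crescent.gap_mm
                 + self.rv_crescent.thickness_mm) / self.spacing_mm
        rows, cols = self.raster_shape
        if (cy - r_out < 0 or cx - r_out < 0
                or cy + r_out > rows - 1 or cx + r_out > cols - 1):
            raise GeometryError("scene extends beyond the raster")
        r_endo = self.endocardial_radius_mm
        for pap in self.papillary:
            d_mm = self.spacing_mm * float(np.hypot(
                pap.center_voxel[0] - cy, pap.center_voxel[1] - cx))
            if d_mm + pap.radius_mm >= r_endo:
                raise GeometryError("papillary disc not strictly inside the "
                                    "endocardial circle")
        if self.rv_crescent.gap_mm <= 0:
            raise GeometryError("RV crescent must not touch the epicardium")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one phantom subject."""

    subject_id: str
    sex: str                 # "female" | "male"
    field: float             # tesla, 1.5 or 3.0
    hct_true: float          # fraction
    ecv_true: float          # fraction
    t1_blood_native: float   # ms
    t1_blood_post: float     # ms
    t1_myo_native: float     # ms
    t1_myo_post: float       # ms, derived (see derive_t1_myo_post)
    geometry: GeometrySpec
    seed: int

    def validate(self) -> None:
        if not (0 < self.hct_true < 1 and 0 < self.ecv_true < 1):
            raise ConfigurationError("hct_true/ecv_true must lie in (0,1)")
        for name in ("t1_blood_native", "t1_blood_post",
                     "t1_myo_native", "t1_myo_post"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.t1_blood_post >= self.t1_blood_native:
            raise ConfigurationError("post-contrast blood T1 must be below "
                                     "native blood T1")
        if self.t1_myo_post >= self.t1_myo_native:
            raise ConfigurationError("post-contrast myocardial T1 must be "
                                     "below native myocardial T1")


@dataclass(frozen=True)
class LabelRaster:
    labels: np.ndarray       # uint8, codes 0..4
    spacing_mm: float

    def validate(self) -> None:
        if not set(np.unique(self.labels)).issubset(_VALID_LABELS):
            raise GeometryError("label raster contains unknown codes")
        if self.spacing_mm <= 0:
            raise GeometryError("spacing must be positive")


@dataclass(frozen=True)
class FieldPriors:
    """Per-field-strength tissue priors and blood R1/HCT coupling."""

    t1_myo_native: Prior
    t1_blood_post: Prior
    # Native blood R1 (s^-1) = c0 + c1 * HCT (+ Gaussian noise), so higher
    # hematocrit shortens native blood T1. Defaults are tuned so the marginal
    # native blood T1 lands near 1550 ms at 1.5 T and 1824 ms at 3 T.
    blood_r1_c0: float
    blood_r1_c1: float

    def validate(self, name: str) -> None:
        self.t1_myo_native.validate(f"{name}.t1_myo_native")
        self.t1_blood_post.validate(f"{name}.t1_blood_post")
        if self.blood_r1_c0 + self.blood_r1_c1 <= 0:
            raise ConfigurationError(f"{name}: blood R1 coupling must stay "
                                     "positive over HCT in (0,1)")


def _default_field_priors() -> dict[float, FieldPriors]:
    # coupling slopes chosen so the marginal native blood T1 spread matches
    # the observed cohort SDs (~115 ms at 1.5 T, ~91 ms at 3 T) given the
    # HCT prior SD of 0.054 and the residual R1 noise
    return {
        1.5: FieldPriors(
            t1_myo_native=Prior(1036.0, 60.0, 800.0, 1300.0),
            t1_blood_post=Prior(311.0, 40.0, 200.0, 480.0),
            blood_r1_c0=1000.0 / 1550.0 - 0.87 * 0.426,
            blood_r1_c1=0.87,
        ),
        3.0: FieldPriors(
            t1_myo_native=Prior(1270.0, 60.0, 1000.0, 1550.0),
            t1_blood_post=Prior(330.0, 40.0, 210.0, 500.0),
            blood_r1_c0=1000.0 / 1824.0 - 0.47 * 0.426,
            blood_r1_c1=0.47,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 50
    seed: int = 0
    field_mix: float = 0.59          # proportion scanned at 3.0 T
    male_fraction: float = 0.61
    hct: Prior = field(default_factory=lambda: Prior(0.426, 0.054, 0.20, 0.60))
    ecv: Prior = field(default_factory=lambda: Prior(0.272, 0.060, 0.10, 0.55))
    field_priors: dict[float, FieldPriors] = field(
        default_factory=_default_field_priors)
    # male blood R1 intercept offset, makes sex-stratified HCT models
    # genuinely different strata
    blood_r1_male_offset: float = 0.01
    blood_r1_noise_sd: float = 0.01  # s^-1
    noise_sd_fraction: float = 0.02  # per-voxel Gaussian T1 noise, x value
    partial_volume: bool = True
    t1_background_native: float = 150.0
    t1_background_post: float = 120.0
    # geometry variability priors (mm)
    epicardial_radius: Prior = field(
        default_factory=lambda: Prior(30.0, 2.0, 25.0, 34.0))
    wall_thickness: Prior = field(
        default_factory=lambda: Prior(9.0, 1.2, 6.0, 13.0))
    raster_shape: tuple[int, int] = (128, 128)
    spacing_mm: float = 1.17
    n_papillary: int = 2
    papillary_radius_mm: float = 2.6

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.field_mix <= 1.0:
            raise ConfigurationError("field_mix must lie in [0,1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0,1]")
        for name, prior, lo, hi in (("hct", self.hct, 0.0, 1.0),
                                    ("ecv", self.ecv, 0.0, 1.0)):
            prior.validate(name)
            if prior.low <= lo or prior.high >= hi:
                raise ConfigurationError(
                    f"{name} truncation bounds must keep samples strictly "
                    "inside (0,1)")
        for f, fp in self.field_priors.items():
            fp.validate(f"field_priors[{f}]")
        if self.blood_r1_noise_sd < 0 or self.noise_sd_fraction < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing must be positive")


def subject_rng(cohort_seed: int, index: int) -> np.random.Generator:
    """Per-subject RNG stream; cohorts are order-independent."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,)))


def derive_t1_myo_post(t1_myo_native: float, t1_blood_native: float,
                       t1_blood_post: float, ecv: float, hct: float) -> float:
    """Post-contrast myocardial T1 consistent with the given ECV and HCT.

    Inverts ECV = (1-HCT) * dR1_myo / dR1_blood for the myocardial
    post-contrast relaxation rate (rates per ms throughout).
    """
    d_r1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_native
    r1_post = 1.0 / t1_myo_native + ecv / (1.0 - hct) * d_r1_blood
    if r1_post <= 0:
        raise RenderingError(
            "ECV/HCT combination yields non-positive post-contrast "
            "myocardial relaxation rate")
    return 1.0 / r1_post


def _sample_geometry(config: CohortConfig,
                     rng: np.random.Generator) -> GeometrySpec:
    epi = float(config.epicardial_radius.sample(rng))
    wall = float(config.wall_thickness.sample(rng))
    r_endo = epi - wall
    center = ((config.raster_shape[0] - 1) / 2.0,
              (config.raster_shape[1] - 1) / 2.0)
    paps = []
    for k in range(config.n_papillary):
        ang = np.deg2rad(250.0 + 130.0 * k + rng.uniform(-15.0, 15.0))
        radius = min(config.papillary_radius_mm, 0.25 * r_endo)
        dist_mm = 0.55 * r_endo
        paps.append(PapillarySpec(
            center_voxel=(center[0] + dist_mm * np.sin(ang) / config.spacing_mm,
                          center[1] + dist_mm * np.cos(ang) / config.spacing_mm),
            radius_mm=radius))
    return GeometrySpec(
        raster_shape=config.raster_shape,
        spacing_mm=config.spacing_mm,
        lv_center=center,
        epicardial_radius_mm=epi,
        wall_thickness_mm=wall,
        papillary=tuple(paps),
    )


def sample_subject(config: CohortConfig, index: int) -> SubjectTruth:
    """Draw one subject's ground truth, reproducible from (seed, index)."""
    config.validate()
    if index >= config.n_subjects:
        raise ConfigurationError(
            f"index {index} out of range for n_subjects={config.n_subjects}")
    rng = subject_rng(config.seed, index)
    tesla = 3.0 if rng.random() < config.field_mix else 1.5
    sex = "male" if rng.random() < config.male_fraction else "female"
    hct = float(config.hct.sample(rng))
    ecv = float(config.ecv.sample(rng))
    fp = config.field_priors[tesla]
    t1_myo_native = float(fp.t1_myo_native.sample(rng))
    c0 = fp.blood_r1_c0 + (config.blood_r1_male_offset if sex == "male"
                           else 0.0)
    r1_blood = c0 + fp.blood_r1_c1 * hct
    if config.blood_r1_noise_sd > 0:
        r1_blood += rng.normal(0.0, config.blood_r1_noise_sd)
    if r1_blood <= 0:
        raise ConfigurationError("sampled native blood R1 non-positive; "
                                 "check coupling coefficients")
    t1_blood_native = 1000.0 / r1_blood
    t1_blood_post = float(fp.t1_blood_post.sample(rng))
    t1_myo_post = derive_t1_myo_post(t1_myo_native, t1_blood_native,
                                     t1_blood_post, ecv, hct)
    geometry = _sample_geometry(config, rng)
    subject = SubjectTruth(
        subject_id=f"phantom_{index:04d}",
        sex=sex, field=tesla, hct_true=hct, ecv_true=ecv,
        t1_blood_native=t1_blood_native, t1_blood_post=t1_blood_post,
        t1_myo_native=t1_myo_native, t1_myo_post=t1_myo_post,
        geometry=geometry, seed=config.seed)
    subject.validate()
    return subject


def build_geometry(subject: SubjectTruth) -> LabelRaster:
    """Rasterize the subject's scene; a voxel belongs to a shape iff its
    center lies inside it. Papillary voxels override cavity voxels."""
    geom = subject.geometry
    geom.validate()
    rows, cols = geom.raster_shape
    sp = geom.spacing_mm
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dy = (rr - geom.lv_center[0]) * sp
    dx = (cc - geom.lv_center[1]) * sp
    d = np.hypot(dy, dx)

    labels = np.zeros((rows, cols), dtype=np.uint8)
    labels[d <= geom.epicardial_radius_mm] = LBL_MYOCARDIUM
    labels[d <= geom.endocardial_radius_mm] = LBL_LV_BLOOD
    for pap in geom.papillary:
        pd = np.hypot((rr - pap.center_voxel[0]) * sp,
                      (cc - pap.center_voxel[1]) * sp)
        labels[pd <= pap.radius_mm] = LBL_PAPILLARY

    rv = geom.rv_crescent
    r_in = geom.epicardial_radius_mm + rv.gap_mm
    r_out = r_in + rv.thickness_mm
    ang = np.rad2deg(np.arctan2(dy, dx))
    dang = np.abs((ang - rv.center_angle_deg + 180.0) % 360.0 - 180.0)
    rv_mask = ((d >= r_in) & (d <= r_out) & (dang <= rv.extent_deg / 2.0)
               & (labels == LBL_BACKGROUND))
    labels[rv_mask] = LBL_RV_BLOOD

    raster = LabelRaster(labels=labels, spacing_mm=sp)
    raster.validate()
    return raster


def _tissue_values(subject: SubjectTruth, config: CohortConfig,
                   phase: str) -> dict[int, float]:
    if phase == "native":
        blood, myo, bg = (subject.t1_blood_native, subject.t1_myo_native,
                          config.t1_background_native)
    else:
        blood, myo, bg = (subject.t1_blood_post, subject.t1_myo_post,
                          config.t1_background_post)
    return {LBL_BACKGROUND: bg, LBL_LV_BLOOD: blood, LBL_MYOCARDIUM: myo,
            LBL_RV_BLOOD: blood, LBL_PAPILLARY: myo}


def _mix_boundary(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-voxel partial-volume band: every voxel with an 8-neighbour of a
    different label becomes a 50/50 mix of its own value and the mean value
    of the differing neighbours."""
    rows, cols = labels.shape
    padded_v = np.pad(values, 1, mode="edge")
    padded_l = np.pad(labels, 1, mode="edge")
    neigh_sum = np.zeros_like(values)
    neigh_n = np.zeros_like(values)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nv = padded_v[1 + di:1 + di + rows, 1 + dj:1 + dj + cols]
            nl = padded_l[1 + di:1 + di + rows, 1 + dj:1 + dj + cols]
            differs = nl != labels
            neigh_sum += np.where(differs, nv, 0.0)
            neigh_n += differs
    mixed = values.copy()
    on_boundary = neigh_n > 0
    mixed[on_boundary] = 0.5 * values[on_boundary] + 0.5 * (
        neigh_sum[on_boundary] / neigh_n[on_boundary])
    return mixed


def render_t1_pair(labels: LabelRaster, subject: SubjectTruth,
                   config: CohortConfig):
    """Render the native and post-contrast T1 maps for one subject.

    Returns a ``(native, post)`` pair of :class:`~synthecv.io.T1Map`.
    """
    from .io import T1Map  # deferred: io depends on nothing here

    labels.validate()
    rng = subject_rng(subject.seed, _render_stream_index(subject))
    maps = []
    for phase in ("native", "post"):
        lut = _tissue_values(subject, config, phase)
        values = np.vectorize(lut.__getitem__, otypes=[float])(labels.labels)
        if config.partial_volume:
            values = _mix_boundary(values, labels.labels)
        if config.noise_sd_fraction > 0:
            values = values + rng.normal(0.0, 1.0, values.shape) * (
                config.noise_sd_fraction * values)
        values = np.maximum(values, 1.0)
        maps.append(T1Map(values=values.astype(np.float64),
                          spacing_mm=labels.spacing_mm,
                          field=subject.field, phase=phase,
                          subject_id=subject.subject_id))
    return maps[0], maps[1]


def _render_stream_index(subject: SubjectTruth) -> int:
    # distinct stream from the sampling stream for the same subject
    return int(subject.subject_id.split("_")[-1]) + 1_000_000


COHORT_COLUMNS = [
    "subject_id", "sex", "field_t", "hct_true_fraction", "ecv_true_fraction",
    "t1_myo_native_ms", "t1_myo_post_ms",
    "t1_blood_native_ms", "t1_blood_post_ms",
]


def subject_row(subject: SubjectTruth) -> dict:
    return {
        "subject_id": subject.subject_id,
        "sex": subject.sex,
        "field_t": subject.field,
        "hct_true_fraction": subject.hct_true,
        "ecv_true_fraction": subject.ecv_true,
        "t1_myo_native_ms": subject.t1_myo_native,
        "t1_myo_post_ms": subject.t1_myo_post,
        "t1_blood_native_ms": subject.t1_blood_native,
        "t1_blood_post_ms": subject.t1_blood_post,
    }


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Generate a full cohort on disk and return its manifest.

    Writes per-subject native/post maps and the ground-truth label raster as
    NIfTI, a cohort CSV with covariates and truths, and ``manifest.json``.
    """
    import pandas as pd

    from .io import write_cohort_table, write_label_raster, write_t1map

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, files = [], {}
    for i in range(config.n_subjects):
        subject = sample_subject(config, i)
        labels = build_geometry(subject)
        native, post = render_t1_pair(labels, subject, config)
        sid = subject.subject_id
        paths = {
            "native": out_dir / f"{sid}_native.nii.gz",
            "post": out_dir / f"{sid}_post.nii.gz",
            "labels": out_dir / f"{sid}_labels.nii.gz",
        }
        write_t1map(native, paths["native"])
        write_t1map(post, paths["post"])
        write_label_raster(labels, paths["labels"])
        files[sid] = {k: str(p.name) for k, p in paths.items()}
        rows.append(subject_row(subject))
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    table_path = out_dir / "cohort.csv"
    write_cohort_table(table, table_path)
    manifest = {
        "format_version": 1,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "cohort_table": table_path.name,
        "subjects": files,
        "config": _config_summary(config),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_summary(config: CohortConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)
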