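"""Synthetic phantoms and studies with known ground truth.

Everything the rest of the package consumes can be generated here with a
seed and no downloads: a brain-like template phantom (nested ellipsoids
with three tissue intensity levels, asymmetric blobs and smooth texture),
per-subject images perturbed by known rigid+scale transforms, smooth
multiplicative bias fields and noise, and whole study directories in two
deliberately heterogeneous metadata dialects:

* longitudinal — ``subjects.csv`` + ``visits.csv`` + one JSON sidecar per
  image, education as qualification codes, image acquisition days offset
  from clinical-visit days;
* cross-sectional — a single ``participants.csv`` with one row per
  subject, education already in years, no visit structure.

Also ships the published study-manifest fixture (12 studies) used for
catalog-summary bookkeeping.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocess import (
    RigidScaleTransform,
    Volume,
    _poly_design,
    apply_transform,
    warp_volume,
)

__all__ = [
    "SyntheticStudySpec",
    "StudyManifest",
    "GroundTruthImage",
    "GroundTruthStudy",
    "make_template",
    "make_subject_image",
    "generate_study",
    "default_longitudinal_spec",
    "default_cross_sectional_spec",
    "reference_manifest",
    "summarize_manifest",
]

FOV_MM = 160.0  # field of view of the phantom space, every axis


# ---------------------------------------------------------------------------
# Template phantom


def make_template(
    shape: Sequence[int] = (64, 64, 64), seed: int = 0
) -> tuple[Volume, Volume]:
    """Deterministic brain-like phantom and its brain mask.

    Nested ellipsoids give three tissue-like intensity levels
    (CSF ~0.12, grey ~0.35, white ~0.7 on a 0 background); a handful of
    asymmetric blobs plus smooth random texture break the ellipsoids'
    rotational symmetry so rigid registration is well posed.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(f"template shape must be >= 32 per axis, got {shape}")
    rng = np.random.default_rng(seed)
    vox = np.array([FOV_MM / s for s in shape])
    A = np.eye(4)
    A[:3, :3] = np.diag(vox)
    A[:3, 3] = -vox * (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    x = idx[0] * vox[0] + A[0, 3]
    y = idx[1] * vox[1] + A[1, 3]
    z = idx[2] * vox[2] + A[2, 3]

    # cerebral ellipsoid plus a posterior-inferior cerebellum-like lobe:
    # the lobe is a large-scale shape asymmetry, so orientation stays
    # identifiable even at the coarsest pyramid level
    brain = (x / 48.0) ** 2 + (y / 55.0) ** 2 + (z / 42.0) ** 2 <= 1.0
    lobe = ((x - 6) / 22.0) ** 2 + ((y + 42) / 20.0) ** 2 + ((z + 28) / 16.0) ** 2 <= 1.0
    lobe_core = ((x - 8) / 12.0) ** 2 + ((y + 44) / 10.0) ** 2 + ((z + 28) / 8.0) ** 2 <= 1.0
    ct, st = np.cos(np.deg2rad(20.0)), np.sin(np.deg2rad(20.0))
    xr = ct * (x - 4) + st * (y + 3)
    yr = -st * (x - 4) + ct * (y + 3)
    white = (xr / 28.0) ** 2 + (yr / 33.0) ** 2 + ((z - 3) / 24.0) ** 2 <= 1.0
    vent_l = ((x + 8) / 7.0) ** 2 + ((y - 10) / 15.0) ** 2 + ((z - 5) / 7.0) ** 2 <= 1.0
    vent_r = ((x - 10) / 7.0) ** 2 + ((y - 8) / 15.0) ** 2 + ((z + 6) / 7.0) ** 2 <= 1.0
    head = brain | lobe

    data = np.zeros(shape)
    data[head] = 0.35
    data[white & brain] = 0.70
    data[lobe_core] = 0.70
    data[(vent_l | vent_r) & brain] = 0.12

    # asymmetric blobs: fixed count, positions drawn inside the brain
    centers = []
    while len(centers) < 4:
        c = rng.uniform(-0.6, 0.6, size=3) * np.array([48, 55, 42])
        if (c[0] / 48) ** 2 + (c[1] / 55) ** 2 + (c[2] / 42) ** 2 <= 0.5:
            centers.append(c)
    for n, c in enumerate(centers):
        amp = 0.08 if n % 2 == 0 else -0.08
        blob = amp * np.exp(-((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / (2 * 6.0 ** 2))
        data += np.where(head, blob, 0.0)

    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    texture *= 0.03 / (texture.std() + 1e-12)
    data += np.where(head, texture, 0.0)
    data = ndimage.gaussian_filter(data, sigma=0.6)
    data = np.clip(data, 0.0, None)

    return Volume(data, A), Volume(head.astype(np.uint8), A.copy())


# ---------------------------------------------------------------------------
# Per-image ground truth


@dataclass
class GroundTruthImage:
    transform: RigidScaleTransform
    bias_field: np.ndarray
    brain_mask: np.ndarray
    bump_field: np.ndarray | None
    noise_sd: float


def _random_transform(
    rng: np.random.Generator,
    rot_max_deg: float,
    trans_max_mm: float,
    scale_range: tuple[float, float],
) -> RigidScaleTransform:
    rot = np.deg2rad(rng.uniform(-rot_max_deg, rot_max_deg, size=3))
    trans = rng.uniform(-trans_max_mm, trans_max_mm, size=3)
    scale = float(rng.uniform(*scale_range))
    return RigidScaleTransform(rot, trans, scale)


def _random_bias_field(
    rng: np.random.Generator,
    template: Volume,
    mask: np.ndarray,
    order: int,
    amplitude: float,
) -> np.ndarray:
    """exp(random polynomial), sd of the log-field = amplitude inside mask."""
    world = template.world_coords().T
    lo, hi = world.min(axis=0), world.max(axis=0)
    coords = 2.0 * (world - lo) / (hi - lo) - 1.0
    X = _poly_design(coords, order)
    coef = rng.standard_normal(X.shape[1])
    coef[0] = 0.0  # no constant term; the field is normalized anyway
    logf = (X @ coef).reshape(template.shape)
    sd = logf[mask > 0].std()
    if sd > 0 and amplitude > 0:
        logf *= amplitude / sd
    else:
        logf[:] = 0.0
    field_ = np.exp(logf - logf[mask > 0].mean())
    field_ /= field_[mask > 0].mean()
    return field_


def _random_bump_field(
    rng: np.random.Generator, template: Volume, amplitude_mm: float
) -> np.ndarray:
    """Smooth random displacement field, peak magnitude = amplitude (mm)."""
    vox = template.voxel_sizes
    sigma_vox = [8.0 / v for v in vox]
    comps = [
        ndimage.gaussian_filter(rng.standard_normal(template.shape), sigma_vox)
        for _ in range(3)
    ]
    u = np.stack(comps, axis=-1)
    mag = np.sqrt((u ** 2).sum(axis=-1)).max()
    if mag > 0:
        u *= amplitude_mm / mag
    return u


def make_subject_image(
    template: Volume,
    template_mask: Volume,
    rng: np.random.Generator,
    rot_max_deg: float = 10.0,
    trans_max_mm: float = 10.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    bias_order: int = 2,
    bias_amplitude: float = 0.15,
    noise_sd: float = 0.02,
    bump_amplitude_mm: float = 0.0,
) -> tuple[Volume, GroundTruthImage]:
    """Perturbed copy of the template with fully known ground truth.

    Samples a 7-DOF transform ``t`` and resamples the template through its
    *inverse*, so registering the output back to the template must recover
    ``t`` itself; then multiplies a smooth positive bias field and adds
    Gaussian noise.  A smooth displacement "bump" can be baked in before
    the affine perturbation to exercise nonlinear registration.
    """
    t = _random_transform(rng, rot_max_deg, trans_max_mm, scale_range)
    src = template
    bump = None
    if bump_amplitude_mm > 0:
        bump = _random_bump_field(rng, template, bump_amplitude_mm)
        src = warp_volume(template, bump)
    moving = apply_transform(src, t.inverse(), target=template)
    mask_moving = apply_transform(
        Volume(np.asarray(template_mask.data, dtype=float), template_mask.affine),
        t.inverse(),
        target=template,
    )
    true_mask = (mask_moving.data > 0.5).astype(np.uint8)
    bias = _random_bias_field(rng, template, true_mask, bias_order, bias_amplitude)
    data = moving.data * bias
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=template.shape)
    out = Volume(data, template.affine.copy())
    return out, GroundTruthImage(t, bias, true_mask, bump, noise_sd)


# ---------------------------------------------------------------------------
# Study generation


@dataclass
class SyntheticStudySpec:
    """Parameters of one synthetic study; the defaults are the standard
    desk-scale study conditions used throughout the test suite."""

    name: str = "synthA"
    kind: str = "longitudinal"  # or "cross_sectional"
    n_subjects: int = 10
    visits_per_subject: int = 3
    visit_spacing_days: int = 180
    visit_jitter_days: int = 15
    image_day_offset: tuple[int, int] = (0, 90)
    images_per_visit: int = 1
    condition_probabilities: dict[str, float] = field(
        default_factory=lambda: {"CTRL": 0.6, "PD": 0.4}
    )
    condition_master: dict[str, str] = field(
        default_factory=lambda: {"CTRL": "healthy", "PD": "parkinson"}
    )
    education_codes: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "secondary": 12.0, "degree_university": 16.0}
    )
    scanners: list[dict] = field(
        default_factory=lambda: [
            {"brand": "Siemens", "model": "Prisma", "field_strength": 3.0},
            {"brand": "GE", "model": "Discovery", "field_strength": 1.5},
        ]
    )
    shape: tuple[int, int, int] = (32, 32, 32)
    rot_max_deg: float = 10.0
    trans_max_mm: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    bias_order: int = 2
    bias_amplitude: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("longitudinal", "cross_sectional"):
            raise ValueError(f"unknown study kind: {self.kind}")
        total = sum(self.condition_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("condition probabilities must sum to 1")


def default_longitudinal_spec(seed: int = 0, **overrides) -> SyntheticStudySpec:
    return SyntheticStudySpec(name="synthA", kind="longitudinal", seed=seed, **overrides)


def default_cross_sectional_spec(seed: int = 0, **overrides) -> SyntheticStudySpec:
    kwargs: dict = dict(
        name="synthB",
        kind="cross_sectional",
        n_subjects=5,
        condition_probabilities={"HC": 0.7, "AD": 0.3},
        condition_master={"HC": "healthy", "AD": "alzheimer"},
        scanners=[{"brand": "Philips", "model": "Achieva", "field_strength": 3.0}],
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticStudySpec(**kwargs)


@dataclass
class GroundTruthStudy:
    spec: SyntheticStudySpec
    subjects: list[dict]
    visits: dict[str, list[dict]]       # subject code -> visit dicts
    images: list[dict]                  # filename, subject, acq day, offset…
    image_truth: dict[str, GroundTruthImage]

    @property
    def n_images(self) -> int:
        return len(self.images)

    def expected_unmatched(self, max_gap_days: int = 60) -> int:
        """Images whose acquisition-to-visit offset exceeds the gap rule.

        Valid for the generated designs, where visit spacing always
        exceeds the largest offset, so the only candidate visit in the
        past is the image's own.
        """
        if self.spec.kind == "cross_sectional":
            return 0
        return sum(1 for im in self.images if im["offset"] > max_gap_days)


def generate_study(
    spec: SyntheticStudySpec, out_dir: str | Path
) -> tuple[Path, GroundTruthStudy]:
    """Write a full synthetic study directory in its metadata dialect."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    template, template_mask = make_template(spec.shape, seed=spec.seed)

    labels = sorted(spec.condition_probabilities)
    probs = [spec.condition_probabilities[k] for k in labels]
    edu_codes = sorted(spec.education_codes)

    subjects: list[dict] = []
    visits: dict[str, list[dict]] = {}
    images: list[dict] = []
    truth: dict[str, GroundTruthImage] = {}

    for i in range(spec.n_subjects):
        code = f"{spec.name}-{i + 1:03d}"
        subj = {
            "code": code,
            "sex": str(rng.choice(["M", "F"])),
            "handedness": str(rng.choice(["R", "L"], p=[0.9, 0.1])),
            "age": round(float(rng.uniform(55, 80)), 1),
            "education_code": str(rng.choice(edu_codes)),
            "condition": str(rng.choice(labels, p=probs)),
            "scanner": int(rng.integers(len(spec.scanners))),
        }
        subj["education_years"] = spec.education_codes[subj["education_code"]]
        subjects.append(subj)

        if spec.kind == "longitudinal":
            days = [0]
            for k in range(1, spec.visits_per_subject):
                jitter = int(rng.integers(-spec.visit_jitter_days, spec.visit_jitter_days + 1))
                days.append(k * spec.visit_spacing_days + jitter)
            visits[code] = [
                {
                    "day": d,
                    "condition": subj["condition"],
                    "bmi": round(float(rng.uniform(19, 32)), 1),
                    "scores": {"cognitive_score": round(float(rng.uniform(20, 30)), 1)},
                }
                for d in days
            ]
            for v in visits[code]:
                for _ in range(spec.images_per_visit):
                    offset = int(rng.integers(spec.image_day_offset[0],
                                              spec.image_day_offset[1] + 1))
                    acq = v["day"] + offset
                    fname = f"{code}_d{acq:04d}_{len(images):04d}.nii.gz"
                    images.append(
                        {"file": fname, "subject": code, "acq_day": acq,
                         "visit_day": v["day"], "offset": offset}
                    )
        else:
            acq = 0
            fname = f"{code}_{len(images):04d}.nii.gz"
            images.append({"file": fname, "subject": code, "acq_day": acq,
                           "visit_day": None, "offset": 0})

    # volumes
    for im in images:
        vol, gt = make_subject_image(
            template,
            template_mask,
            rng,
            rot_max_deg=spec.rot_max_deg,
            trans_max_mm=spec.trans_max_mm,
            scale_range=spec.scale_range,
            bias_order=spec.bias_order,
            bias_amplitude=spec.bias_amplitude,
            noise_sd=spec.noise_sd,
        )
        vol.to_nifti(img_dir / im["file"])
        truth[im["file"]] = gt

    # metadata, study-specific dialect
    if spec.kind == "longitudinal":
        with open(out / "subjects.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant", "gender", "hand_pref", "age_at_entry",
                        "education_level"])
            for s in subjects:
                w.writerow([s["code"], s["sex"], s["handedness"], s["age"],
                            s["education_code"]])
        with open(out / "visits.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant", "days_from_entry", "dx_code", "bmi",
                        "cognitive_score"])
            for code, vlist in visits.items():
                for v in vlist:
                    w.writerow([code, v["day"], v["condition"], v["bmi"],
                                v["scores"]["cognitive_score"]])
        for im in images:
            s = next(x for x in subjects if x["code"] == im["subject"])
            sc = spec.scanners[s["scanner"]]
            sidecar = {
                "participant": im["subject"],
                "acq_day": im["acq_day"],
                "modality": "T1w",
                "image": im["file"],
                "scanner_brand": sc["brand"],
                "scanner_model": sc["model"],
                "field_T": sc["field_strength"],
            }
            (img_dir / (im["file"].removesuffix(".nii.gz") + ".json")).write_text(
                json.dumps(sidecar, indent=1)
            )
        with open(out / "education_map.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "years"])
            for code_, years in sorted(spec.education_codes.items()):
                w.writerow([code_, years])
    else:
        with open(out / "participants.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subj_id", "sex", "handedness", "age", "educ_years",
                        "diagnosis", "scan_file", "scanner", "model", "tesla"])
            for s, im in zip(subjects, images):
                sc = spec.scanners[s["scanner"]]
                w.writerow([s["code"], s["sex"], s["handedness"], s["age"],
                            s["education_years"], s["condition"],
                            f"images/{im['file']}", sc["brand"], sc["model"],
                            sc["field_strength"]])

    with open(out / "condition_map.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_label", "master_condition"])
        for src_label, master in sorted(spec.condition_master.items()):
            w.writerow([src_label, master])

    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "study": spec.name,
                "kind": spec.kind,
                "seed": spec.seed,
                "images": [
                    {
                        "file": im["file"],
                        "subject": im["subject"],
                        "acq_day": im["acq_day"],
                        "visit_day": im["visit_day"],
                        "offset": im["offset"],
                        "rotations_rad": list(truth[im["file"]].transform.rotations),
                        "translations_mm": list(truth[im["file"]].transform.translations),
                        "scale": truth[im["file"]].transform.scale,
                    }
                    for im in images
                ],
            },
            indent=1,
        )
    )
    return out, GroundTruthStudy(spec, subjects, visits, images, truth)


# ---------------------------------------------------------------------------
# Published study manifest fixture


@dataclass(frozen=True)
class StudyManifest:
    study: str
    n_subjects: int
    n_images: int
    population: str


_MANIFEST_ROWS: tuple[tuple[str, int, int, str], ...] = (
    ("ADNI", 2594, 22271, "Alzheimer's Disease"),
    ("AIBL", 703, 1310, "Alzheimer's Disease"),
    ("Cam-CAN", 653, 653, "Large Cohort"),
    ("HCP-Aging", 725, 725, "Large Cohort"),
    ("Human Connectome Project", 1113, 1113, "Large Cohort"),
    ("NKIRS", 1267, 2564, "Large Cohort"),
    ("OASIS", 1088, 3358, "Alzheimer's Disease"),
    ("OpenPain", 117, 434, "Chronic Pain"),
    ("PREDICT-HD", 589, 2177, "Huntington's Disease"),
    ("PPMI", 697, 1613, "Parkinson's Disease"),
    ("SALD", 494, 494, "Large Cohort"),
    ("UK Biobank", 44178, 47381, "Large Cohort"),
)


def reference_manifest() -> list[StudyManifest]:
    """The published 12-study manifest of the reference fused collection
    (name, subjects, images, population)."""
    return [StudyManifest(*row) for row in _MANIFEST_ROWS]


def summarize_manifest(rows: Sequence[StudyManifest]) -> tuple[int, int, int]:
    """Component-wise totals: (total_subjects, total_images, n_studies)."""
    if not rows:
        raise ValueError("manifest is empty")
    return (
        sum(r.n_subjects for r in rows),
        sum(r.n_images for r in rows),
        len(rows),
    )
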