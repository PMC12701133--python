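"""Synthetic stand-ins for the private clinical cohort and face images.

Because the study cohort this package models is not publicly deposited,
every downstream stage is exercised on generated data with *known*
generative structure:

* **Images** — grey "face" images with two ellipse eyes and one ellipse
  lip on a low-frequency textured background.  Ground-truth boxes are the
  exact ellipse bounding boxes.  The eye ellipse aspect ratio
  (height/width) carries a per-patient scalar signal ``s`` in [0,1] — a
  static geometric proxy for the eye-movement variability a clinician
  would observe; frame sequences are supported but default to one frame.
* **Cohort** — 36 physiological indicators drawn from stated normal
  marginals, with the seven-day death label drawn from a logistic model
  ``label ~ Bernoulli(sigmoid(intercept + beta·x_std + gamma·s_std))``
  whose coefficients are fixed, known inputs.

Default coefficient presets follow the indicator panel's reported group
differences in sign (temperature, respiratory rate, AST, BIL, PT, APTT and
FIB push toward death; systolic pressure, MAP, BE and the chronic health
evaluation toward survival), with magnitudes chosen once so that an oracle
linear classifier is strong (AUC ~ 0.98): this is the "strong coefficients"
regime the learnability checks assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (Box, ClinicalRecord, GroundTruthBox, INDICATOR_NAMES,
                    LabeledImage, N_INDICATORS)

__all__ = [
    "SyntheticImageSpec", "SyntheticCohortSpec", "generate_face_images",
    "generate_clinical_cohort", "link_facial_signal", "MultimodalDataset",
    "default_beta", "strong_cohort_spec", "multimodal_cohort_spec",
    "ellipse_box",
]

# sign pattern of the significant indicators (toward death = +)
_SIGNIFICANT_SIGNS = {
    "temperature": +1.0, "systolic_pressure": -1.0, "map": -1.0,
    "respiratory_rate": +1.0, "na": +1.0, "gcs": +1.0,
    "chronic_health_evaluation": -1.0, "be": -1.0, "ast": +1.0,
    "bil": +1.0, "pt": +1.0, "aptt": +1.0, "fib": +1.0,
}


def default_beta(scale: float = 2.0) -> np.ndarray:
    """36-vector of logistic coefficients: +-``scale`` on the 13 significant
    indicators, zero elsewhere."""
    beta = np.zeros(N_INDICATORS)
    for name, sign in _SIGNIFICANT_SIGNS.items():
        beta[INDICATOR_NAMES.index(name)] = sign * scale
    return beta


# plausible clinical marginals (units as measured: °C, mmHg, mmol/L, ...)
_DEFAULT_MEANS = {
    "apache": 14.0, "temperature": 36.9, "systolic_pressure": 115.0,
    "diastolic_pressure": 67.0, "map": 82.0, "heart_rate": 100.0,
    "respiratory_rate": 21.0, "partial_pressure_oxygen": 98.0, "ph": 7.43,
    "na": 137.0, "k": 4.3, "cr": 178.0, "hct": 30.0, "wbc": 12.5,
    "gcs": 8.0, "ae_score": 3.9, "chronic_health_evaluation": 0.7,
    "hemoglobin": 101.0, "anemia": 0.7, "platelet": 199.0, "pco2": 30.5,
    "lac": 2.2, "be": -1.1, "alt": 52.0, "ast": 80.0, "bun": 16.5,
    "bsl": 9.1, "alb": 31.5, "bil": 28.0, "serum_calcium": 2.07,
    "amylase": 90.0, "lipase": 63.0, "pt": 25.0, "aptt": 42.0,
    "fib": 4.3, "d_dimer": 4.9,
}


def _default_mean_vector() -> np.ndarray:
    return np.array([_DEFAULT_MEANS[n] for n in INDICATOR_NAMES])


def _default_sd_vector() -> np.ndarray:
    # 15% coefficient of variation floor'd at a small absolute spread
    means = _default_mean_vector()
    return np.maximum(np.abs(means) * 0.15, 0.5)


@dataclass
class SyntheticImageSpec:
    """Stated world for the image generator."""

    n_images: int
    image_size: int = 96
    eye_scale_range: tuple = (0.10, 0.15)    # eye semi-width / image size
    lip_scale_range: tuple = (0.16, 0.22)    # lip semi-width / image size
    eye_aspect_signal: np.ndarray | None = None   # (n,) in [0,1]
    eye_aspect_range: tuple = (0.35, 0.85)   # ellipse height/width carrier
    noise_sd: float = 0.03                   # additive grey noise
    occlusion_prob: float = 0.0
    contrast: float = 0.35                   # target grey minus background
    background_level: float = 0.35
    frames_per_patient: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 0:
            raise ValueError("n_images must be nonnegative")
        if self.eye_aspect_signal is not None:
            sig = np.asarray(self.eye_aspect_signal, dtype=float)
            if sig.shape != (self.n_images,):
                raise ValueError("eye_aspect_signal must have one entry per image")
            if ((sig < 0) | (sig > 1)).any():
                raise ValueError("eye_aspect_signal values must lie in [0,1]")
            self.eye_aspect_signal = sig
        # geometric feasibility: both eyes plus margins must fit
        if 2 * self.eye_scale_range[1] > 0.45 or self.lip_scale_range[1] > 0.35:
            raise ValueError(
                "target scale range too large for targets to fit the image")


@dataclass
class SyntheticCohortSpec:
    """Stated world for the cohort generator."""

    n_patients: int = 298
    beta: np.ndarray = field(default_factory=default_beta)
    gamma: float = 0.0
    intercept: float = -0.5
    indicator_means: np.ndarray = field(default_factory=_default_mean_vector)
    indicator_sds: np.ndarray = field(default_factory=_default_sd_vector)
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (N_INDICATORS,):
            raise ValueError(
                f"beta must have length {N_INDICATORS}, got {self.beta.shape}")
        self.indicator_means = np.asarray(self.indicator_means, dtype=float)
        self.indicator_sds = np.asarray(self.indicator_sds, dtype=float)
        if self.indicator_means.shape != (N_INDICATORS,) or \
                self.indicator_sds.shape != (N_INDICATORS,):
            raise ValueError("indicator means/sds must be 36-vectors")
        if (self.indicator_sds <= 0).any():
            raise ValueError("indicator sds must be positive")


def strong_cohort_spec(n_patients: int = 1000, seed: int = 0
                       ) -> SyntheticCohortSpec:
    """Strong clinical-only signal: the learnability regime."""
    return SyntheticCohortSpec(n_patients=n_patients, beta=default_beta(2.0),
                               gamma=0.0, intercept=-0.5, seed=seed)


def multimodal_cohort_spec(n_patients: int = 298, gamma: float = 2.0,
                           seed: int = 0) -> SyntheticCohortSpec:
    """Moderate clinical signal plus a facial channel of weight ``gamma``."""
    return SyntheticCohortSpec(n_patients=n_patients, beta=default_beta(0.5),
                               gamma=gamma, intercept=-0.5, seed=seed)


# --------------------------------------------------------------- rendering
@dataclass
class EllipseTarget:
    cx: float
    cy: float
    rx: float
    ry: float
    class_name: str


def ellipse_box(t: EllipseTarget) -> Box:
    """Exact bounding box of an ellipse (the emitted ground truth)."""
    return Box(t.cx - t.rx, t.cy - t.ry, t.cx + t.rx, t.cy + t.ry)


def _render(canvas: np.ndarray, t: EllipseTarget, level: float):
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel centres at integer + 0.5
    mask = (((xx + 0.5 - t.cx) / t.rx) ** 2
            + ((yy + 0.5 - t.cy) / t.ry) ** 2) <= 1.0
    canvas[mask] = level


def _smooth_noise(rng, size: int, amplitude: float) -> np.ndarray:
    """Low-frequency background texture: upsampled coarse noise."""
    coarse = rng.normal(0.0, 1.0, (8, 8))
    reps = int(np.ceil(size / 8))
    grid = np.kron(coarse, np.ones((reps, reps)))[:size, :size]
    # separable box blur to soften block edges
    kernel = np.ones(9) / 9.0
    for axis in (0, 1):
        grid = np.apply_along_axis(
            lambda m: np.convolve(m, kernel, mode="same"), axis, grid)
    return amplitude * grid


def generate_face_images(spec: SyntheticImageSpec
                         ) -> tuple[list[LabeledImage],
                                    dict[str, list[GroundTruthBox]]]:
    """Render annotated face-like images; deterministic given ``spec.seed``.

    Returns the images plus an image_id -> ground-truth-box map in the same
    dialect the annotation reader produces.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    images: list[LabeledImage] = []
    annotations: dict[str, list[GroundTruthBox]] = {}
    lo_a, hi_a = spec.eye_aspect_range
    for p in range(spec.n_images):
        s = (spec.eye_aspect_signal[p] if spec.eye_aspect_signal is not None
             else rng.uniform(0.0, 1.0))
        aspect = lo_a + s * (hi_a - lo_a)
        for f in range(spec.frames_per_patient):
            image_id = (f"img{p:04d}" if spec.frames_per_patient == 1
                        else f"img{p:04d}_f{f}")
            canvas = np.full((size, size), spec.background_level)
            canvas += _smooth_noise(rng, size, 0.05)
            targets: list[EllipseTarget] = []
            rx = rng.uniform(*spec.eye_scale_range) * size
            ry = rx * aspect
            for cx_frac in (0.30, 0.70):
                cx = cx_frac * size + rng.uniform(-0.02, 0.02) * size
                cy = 0.38 * size + rng.uniform(-0.03, 0.03) * size
                targets.append(EllipseTarget(cx, cy, rx, ry, "eye"))
            lrx = rng.uniform(*spec.lip_scale_range) * size
            lry = lrx * rng.uniform(0.30, 0.45)
            lcx = 0.50 * size + rng.uniform(-0.02, 0.02) * size
            lcy = 0.74 * size + rng.uniform(-0.03, 0.03) * size
            targets.append(EllipseTarget(lcx, lcy, lrx, lry, "lip"))
            kept: list[GroundTruthBox] = []
            for t in targets:
                if rng.uniform() < spec.occlusion_prob:
                    continue
                level = spec.background_level + spec.contrast
                _render(canvas, t, level)
                box = ellipse_box(t)
                if box.x_min < 0 or box.y_min < 0 or box.x_max > size \
                        or box.y_max > size:
                    raise ValueError("target does not fit inside the image")
                kept.append(GroundTruthBox(box=box, class_name=t.class_name))
            if spec.noise_sd > 0:
                canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
            canvas = np.clip(canvas, 0.0, 1.0)
            img = LabeledImage(image_id=image_id, pixels=canvas, boxes=kept,
                               occluded=(len(kept) == 0))
            images.append(img)
            annotations[image_id] = kept
    return images, annotations


def generate_clinical_cohort(spec: SyntheticCohortSpec
                             ) -> tuple[list[ClinicalRecord], np.ndarray]:
    """Draw a cohort from the stated logistic model.

    Returns the records and the latent facial signal ``s`` (one per
    patient, uniform on [0,1]); ``s`` only enters the label model scaled to
    zero mean and unit variance and weighted by ``gamma``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    x = rng.normal(spec.indicator_means, spec.indicator_sds,
                   (n, N_INDICATORS))
    s = rng.uniform(0.0, 1.0, n)
    x_std = (x - spec.indicator_means) / spec.indicator_sds
    s_std = (s - 0.5) / np.sqrt(1.0 / 12.0)
    eta = spec.intercept + x_std @ spec.beta + spec.gamma * s_std
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = (rng.uniform(size=n) < prob).astype(int)
    x_out = x.copy()
    if spec.missing_prob > 0:
        mask = rng.uniform(size=x.shape) < spec.missing_prob
        x_out[mask] = np.nan
    records = [
        ClinicalRecord(
            patient_id=f"patient{i:04d}",
            indicators=dict(zip(INDICATOR_NAMES, x_out[i])),
            label=int(labels[i]))
        for i in range(n)
    ]
    return records, s


@dataclass
class MultimodalDataset:
    """Paired images and clinical records, linked by patient."""

    records: list[ClinicalRecord]
    images_by_patient: dict[str, list[LabeledImage]]
    signal: np.ndarray                     # latent s per patient (record order)

    def __len__(self):
        return len(self.records)


def link_facial_signal(images: list[LabeledImage],
                       cohort: list[ClinicalRecord],
                       signal: np.ndarray,
                       frames_per_patient: int = 1) -> MultimodalDataset:
    """Pair image frames with patients in order; one frame set per patient.

    The caller must have generated the images with
    ``eye_aspect_signal=signal`` so each patient's rendered eye aspect
    carries their latent ``s``.
    """
    if len(images) != len(cohort) * frames_per_patient:
        raise ValueError(
            f"pairing error: {len(images)} images cannot cover "
            f"{len(cohort)} patients x {frames_per_patient} frames")
    by_patient: dict[str, list[LabeledImage]] = {}
    for i, rec in enumerate(cohort):
        frames = images[i * frames_per_patient:(i + 1) * frames_per_patient]
        by_patient[rec.patient_id] = frames
    return MultimodalDataset(records=cohort, images_by_patient=by_patient,
                             signal=np.asarray(signal, dtype=float))
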