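"""Fuse detector-derived facial features with clinical indicators and run
the unimodal-vs-multimodal survival experiment.

Facial features are hand-crafted geometric and confidence summaries of a
patient's eye/lip detections (counts, mean eye confidence, eye aspect
ratio, inter-eye distance and eye box area as image fractions).  With
multiple frames per patient the per-frame features are averaged and the
across-frame standard deviation of the eye aspect ratio is appended as the
variability channel.  Fusion is early concatenation after per-feature
standardisation; all statistics (standardisation and imputation of missing
facial features) come from the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import (Standardizer, TrainResult, stratified_split,
                         train_eted)
from .config import RunConfig
from .detector import DetectionModel, detect, train_detector
from .metrics import classification_metrics, summarize_detection
from .synthetic import (MultimodalDataset, SyntheticImageSpec,
                        generate_clinical_cohort, generate_face_images,
                        link_facial_signal, multimodal_cohort_spec)
from .types import ClinicalRecord, Detection, FacialFeatureVector

__all__ = [
    "extract_facial_features", "fuse_modalities", "MultimodalSample",
    "run_pipeline", "PipelineReport",
]


def _frame_features(dets: list[Detection], width: int, height: int) -> dict:
    eyes = sorted([d for d in dets if d.class_name == "eye"],
                  key=lambda d: -d.confidence)[:2]
    lips = [d for d in dets if d.class_name == "lip"]
    out = {"n_eye": float(len(eyes)), "n_lip": float(len(lips)),
           "conf": np.nan, "aspect": np.nan, "dist": np.nan, "area": np.nan}
    if eyes:
        out["conf"] = float(np.mean([d.confidence for d in eyes]))
        out["aspect"] = float(np.mean(
            [d.box.height / d.box.width for d in eyes]))
        out["area"] = float(np.mean(
            [d.box.area for d in eyes]) / (width * height))
    if len(eyes) == 2:
        (x0, y0), (x1, y1) = eyes[0].box.center, eyes[1].box.center
        out["dist"] = float(np.hypot(x1 - x0, y1 - y0) / width)
    return out


def extract_facial_features(detections_per_frame: list[list[Detection]],
                            image_width: int,
                            image_height: int) -> FacialFeatureVector:
    """Summarise one patient's detections into a fixed-length vector.

    ``detections_per_frame`` holds one detection list per frame; empty input
    yields an all-missing vector with every flag set.
    """
    if not detections_per_frame:
        detections_per_frame = [[]]
    frames = [_frame_features(d, image_width, image_height)
              for d in detections_per_frame]

    def agg(key):
        vals = [f[key] for f in frames if np.isfinite(f[key])]
        return (float(np.mean(vals)) if vals else np.nan,
                float(np.std(vals)) if len(vals) > 1 else 0.0)

    aspect_mean, aspect_sd = agg("aspect")
    vec = FacialFeatureVector(
        n_eye_detections=float(np.mean([f["n_eye"] for f in frames])),
        n_lip_detections=float(np.mean([f["n_lip"] for f in frames])),
        mean_eye_confidence=agg("conf")[0],
        eye_aspect_ratio=aspect_mean,
        inter_eye_distance_frac=agg("dist")[0],
        eye_box_area_frac=agg("area")[0],
        eye_aspect_ratio_sd=aspect_sd,
    )
    vec.missing = {name: not np.isfinite(getattr(vec, name))
                   for name in FacialFeatureVector.FEATURE_NAMES}
    return vec


@dataclass
class MultimodalSample:
    patient_id: str
    features: np.ndarray           # 36 standardized indicators + facial
    label: int


class ModalityFuser:
    """Standardise-and-concatenate fusion with train-split statistics."""

    def __init__(self):
        self.clinical_scaler: Standardizer | None = None
        self.facial_scaler: Standardizer | None = None

    def fit(self, records: list[ClinicalRecord],
            facial: list[FacialFeatureVector]):
        self.clinical_scaler = Standardizer.fit(
            np.stack([r.vector() for r in records]))
        self.facial_scaler = Standardizer.fit(
            np.stack([f.vector() for f in facial]))
        return self

    def transform(self, record: ClinicalRecord,
                  facial: FacialFeatureVector) -> MultimodalSample:
        return fuse_modalities(record, facial, self)


def fuse_modalities(record: ClinicalRecord, facial: FacialFeatureVector,
                    fuser: ModalityFuser) -> MultimodalSample:
    """Concatenate standardized indicators and facial features.

    Missing facial features are imputed to training means (zero after
    standardisation); the sample length is 36 + the facial feature count.
    """
    if fuser.clinical_scaler is None:
        raise ValueError("fuser must be fit on the training split first")
    clin = fuser.clinical_scaler.transform(record.vector()[None, :])[0]
    face = fuser.facial_scaler.transform(facial.vector()[None, :])[0]
    return MultimodalSample(patient_id=record.patient_id,
                            features=np.concatenate([clin, face]),
                            label=record.label)


@dataclass
class PipelineReport:
    detection: dict
    unimodal: dict
    multimodal: dict
    detector_losses: list[float]
    n_train: int
    n_val: int

    def as_dict(self) -> dict:
        return {"detection": self.detection, "unimodal": self.unimodal,
                "multimodal": self.multimodal, "n_train": self.n_train,
                "n_val": self.n_val}


def _arm_report(result: TrainResult, x_raw: np.ndarray, y: np.ndarray) -> dict:
    scores = result.predict(x_raw[result.val_idx])
    m = classification_metrics(y[result.val_idx], scores,
                               result.model.cfg.threshold)
    return m.as_dict()


def run_pipeline(cfg: RunConfig,
                 dataset: MultimodalDataset | None = None,
                 detector_model: DetectionModel | None = None
                 ) -> PipelineReport:
    """Train detector, extract facial features, train both classifier arms.

    The unimodal (indicators only) and multimodal (indicators + facial)
    arms share the identical train/validation split and seed, so the
    comparison isolates the facial channel.  A pre-trained
    ``detector_model`` may be supplied to skip detector training (used when
    sweeping classifier seeds).
    """
    seed = cfg.seed
    if dataset is None:
        cohort_spec = multimodal_cohort_spec(seed=seed)
        records, signal = generate_clinical_cohort(cohort_spec)
        img_spec = SyntheticImageSpec(
            n_images=len(records), image_size=cfg.detector.image_size,
            eye_aspect_signal=signal, seed=seed + 1)
        images, _ = generate_face_images(img_spec)
        dataset = link_facial_signal(images, records, signal)

    records = dataset.records
    all_images = [img for rec in records
                  for img in dataset.images_by_patient[rec.patient_id]]
    y = np.array([r.label for r in records])

    # ------------------------------------------------------------ detector
    split_rng = np.random.default_rng(seed + 17)
    train_idx, val_idx = stratified_split(
        y, cfg.split.train_fraction, split_rng, cfg.split.stratified)
    train_images = [img for i in train_idx
                    for img in dataset.images_by_patient[records[i].patient_id]]
    if detector_model is None:
        try:
            detector_model, det_losses = train_detector(
                train_images, cfg.detector, seed=seed)
        except ValueError as exc:
            raise RuntimeError(f"detector stage failed: {exc}") from exc
    else:
        det_losses = []

    # detection metrics on held-out patients' images
    val_images = [img for i in val_idx
                  for img in dataset.images_by_patient[records[i].patient_id]]
    val_dets = []
    for img in val_images:
        val_dets.extend(detect(detector_model, img.pixels, img.image_id))
    gt = {img.image_id: img.boxes for img in val_images}
    try:
        det_metrics = summarize_detection(
            val_dets, gt, cfg.iou_thresholds).as_dict()
    except ValueError as exc:
        raise RuntimeError(f"evaluation stage failed: {exc}") from exc

    # --------------------------------------------------- facial features
    facial = []
    for rec in records:
        frames = dataset.images_by_patient[rec.patient_id]
        dets_per_frame = [detect(detector_model, img.pixels, img.image_id)
                          for img in frames]
        facial.append(extract_facial_features(
            dets_per_frame, frames[0].width, frames[0].height))

    fuser = ModalityFuser().fit([records[i] for i in train_idx],
                                [facial[i] for i in train_idx])
    x_clin = np.stack([r.vector() for r in records])
    x_multi = np.stack([
        fuse_modalities(r, f, fuser).features for r, f in zip(records, facial)])

    # --------------------------------------------- two classifier arms
    uni = train_eted(x_clin, y, cfg.eted, cfg.split, seed=seed,
                     train_idx=train_idx, val_idx=val_idx)
    multi = train_eted(x_multi, y, cfg.eted, cfg.split, seed=seed,
                       train_idx=train_idx, val_idx=val_idx)
    return PipelineReport(
        detection=det_metrics,
        unimodal=_arm_report(uni, x_clin, y),
        multimodal=_arm_report(multi, x_multi, y),
        detector_losses=det_losses,
        n_train=len(train_idx), n_val=len(val_idx))
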