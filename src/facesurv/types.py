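"""Core data containers shared across the pipeline.

Box convention (everywhere in this package): 0-based, half-open pixel
corners ``(x_min, y_min, x_max, y_max)`` so ``area = (x_max-x_min) *
(y_max-y_min)`` with no +1 arithmetic.  COCO ``(x, y, w, h)`` is converted
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("eye", "lip")

#: Canonical ordered names for the 36 physiological indicators carried by a
#: clinical record.  Mirrors the indicator panel of an emergency-department
#: cohort: vitals, blood gas, chemistry, haematology and coagulation values
#: plus composite severity scores.
INDICATOR_NAMES = (
    "apache", "temperature", "systolic_pressure", "diastolic_pressure",
    "map", "heart_rate", "respiratory_rate", "partial_pressure_oxygen",
    "ph", "na", "k", "cr", "hct", "wbc", "gcs", "ae_score",
    "chronic_health_evaluation", "hemoglobin", "anemia", "platelet",
    "pco2", "lac", "be", "alt", "ast", "bun", "bsl", "alb", "bil",
    "serum_calcium", "amylase", "lipase", "pt", "aptt", "fib", "d_dimer",
)

N_INDICATORS = len(INDICATOR_NAMES)
assert N_INDICATORS == 36


@dataclass
class Box:
    """Axis-aligned box with half-open pixel corners."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


@dataclass
class GroundTruthBox:
    box: Box
    class_name: str

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")


@dataclass
class Detection:
    """A predicted box with class and confidence."""

    image_id: str
    class_name: str
    box: Box
    confidence: float

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if not (np.isfinite(self.confidence) and 0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class LabeledImage:
    """An image with its ground-truth annotations — the detector data unit."""

    image_id: str
    pixels: np.ndarray                     # (H, W) float grey image in [0,1]
    boxes: list[GroundTruthBox] = field(default_factory=list)
    occluded: bool = False                 # flagged if occlusion removed all targets

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ClinicalRecord:
    """One patient's 36 physiological indicators and 7-day survival label.

    ``label`` is 1 if the patient died within seven days, 0 if they survived
    beyond seven days.  Missing indicator values are coded as ``nan`` —
    never silently zero; imputation happens downstream with training-split
    statistics only.
    """

    patient_id: str
    indicators: dict[str, float]
    label: int

    def __post_init__(self):
        if set(self.indicators) != set(INDICATOR_NAMES):
            missing = set(INDICATOR_NAMES) - set(self.indicators)
            extra = set(self.indicators) - set(INDICATOR_NAMES)
            raise ValueError(
                f"record must carry exactly the 36 indicators; "
                f"missing={sorted(missing)}, extra={sorted(extra)}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def vector(self) -> np.ndarray:
        """Indicators in canonical order; missing values are nan."""
        return np.array([self.indicators[n] for n in INDICATOR_NAMES])


@dataclass
class FacialFeatureVector:
    """Geometric/confidence summaries of one patient's detections.

    The variability fields hold across-frame standard deviations; with a
    single frame they are zero.  ``missing`` flags name the features whose
    source detections were absent.
    """

    n_eye_detections: float = 0.0
    n_lip_detections: float = 0.0
    mean_eye_confidence: float = np.nan
    eye_aspect_ratio: float = np.nan
    inter_eye_distance_frac: float = np.nan
    eye_box_area_frac: float = np.nan
    eye_aspect_ratio_sd: float = 0.0
    missing: dict[str, bool] = field(default_factory=dict)

    FEATURE_NAMES = (
        "n_eye_detections", "n_lip_detections", "mean_eye_confidence",
        "eye_aspect_ratio", "inter_eye_distance_frac", "eye_box_area_frac",
        "eye_aspect_ratio_sd",
    )

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.FEATURE_NAMES])


@dataclass
class PyramidLevels:
    """Multi-resolution feature maps exchanged between backbone and pyramid.

    ``strides`` are relative to the network input and must halve between
    consecutive (fine -> coarse) levels.
    """

    maps: list                              # list of Tensor, finest first
    strides: list[int]

    def __post_init__(self):
        if len(self.maps) < 2:
            raise ValueError("a pyramid needs at least 2 levels")
        if len(self.maps) != len(self.strides):
            raise ValueError("one stride per level required")
        for a, b in zip(self.strides, self.strides[1:]):
            if b != 2 * a:
                raise ValueError(f"strides must halve resolution: {self.strides}")
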