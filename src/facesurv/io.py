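"""Readers and writers for the pipeline's on-disk formats.

* clinical tables: CSV with a header naming the 36 indicator columns plus a
  ``label`` column (and optionally ``patient_id``);
* annotations and detections: COCO-style JSON (categories ``eye``/``lip``,
  boxes stored as ``[x, y, w, h]``, converted to half-open corners on read);
* images: 8-bit grey PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import (Box, CLASS_NAMES, ClinicalRecord, Detection,
                    GroundTruthBox, INDICATOR_NAMES, LabeledImage)

__all__ = [
    "read_clinical_csv", "write_clinical_csv", "read_annotations",
    "write_annotations", "read_detections", "write_detections",
    "write_images", "read_images", "write_json_report",
]


class SchemaError(ValueError):
    pass


# ------------------------------------------------------------ clinical CSV
def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Read a cohort CSV into records, preserving row order.

    Non-numeric indicator cells become coded-missing (nan).  A wrong column
    set raises :class:`SchemaError` naming the offending columns; a
    non-binary label raises ``ValueError`` with the row index.
    """
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    has_id = "patient_id" in cols
    expected = set(INDICATOR_NAMES) | {"label"} | ({"patient_id"} if has_id else set())
    missing = (set(INDICATOR_NAMES) | {"label"}) - set(cols)
    extra = set(cols) - expected
    if missing or extra:
        raise SchemaError(
            f"clinical CSV schema mismatch; missing columns: {sorted(missing)}, "
            f"unexpected columns: {sorted(extra)}")
    records = []
    for i, row in df.iterrows():
        try:
            label = int(float(row["label"]))
            if label not in (0, 1):
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(
                f"non-binary label {row['label']!r} at row {i}") from None
        indicators = {}
        for name in INDICATOR_NAMES:
            try:
                indicators[name] = float(row[name])
            except (TypeError, ValueError):
                indicators[name] = float("nan")
        pid = str(row["patient_id"]) if has_id else f"patient{i:04d}"
        records.append(ClinicalRecord(patient_id=pid, indicators=indicators,
                                      label=label))
    return records


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path):
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        row.update({n: r.indicators[n] for n in INDICATOR_NAMES})
        row["label"] = r.label
        rows.append(row)
    cols = ["patient_id", *INDICATOR_NAMES, "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# --------------------------------------------------------- COCO-style JSON
def write_annotations(annotations: dict[str, list[GroundTruthBox]],
                      path: str | Path, image_size: int | None = None):
    """Write a COCO-style annotation file (boxes as x, y, w, h)."""
    image_ids = sorted(annotations)
    images = [{"id": i, "file_name": f"{img}.png",
               **({"width": image_size, "height": image_size}
                  if image_size else {})}
              for i, img in enumerate(image_ids)]
    categories = [{"id": ci + 1, "name": c} for ci, c in enumerate(CLASS_NAMES)]
    cat_id = {c: ci + 1 for ci, c in enumerate(CLASS_NAMES)}
    anns = []
    aid = 1
    for i, img in enumerate(image_ids):
        for gt in annotations[img]:
            b = gt.box
            anns.append({
                "id": aid, "image_id": i, "category_id": cat_id[gt.class_name],
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "area": b.area, "iscrowd": 0,
            })
            aid += 1
    payload = {"images": images, "annotations": anns, "categories": categories}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_annotations(path: str | Path
                     ) -> tuple[dict[str, list[GroundTruthBox]], int]:
    """Read COCO-style annotations into the internal corner convention.

    Returns (image_id -> boxes, n_rejected_degenerate).  Every listed image
    gets an entry even with zero annotations.  An annotation referencing an
    unknown image id raises ``KeyError``; degenerate boxes (non-positive
    width/height) are rejected with a count.
    """
    with open(path) as fh:
        data = json.load(fh)
    id_to_name = {}
    for img in data.get("images", []):
        name = Path(img.get("file_name", str(img["id"]))).stem
        id_to_name[img["id"]] = name
    cat_names = {c["id"]: c["name"] for c in data.get("categories", [])}
    out: dict[str, list[GroundTruthBox]] = {n: [] for n in id_to_name.values()}
    rejected = 0
    for ann in data.get("annotations", []):
        if ann["image_id"] not in id_to_name:
            raise KeyError(
                f"annotation {ann.get('id')} references unknown image id "
                f"{ann['image_id']}")
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            import warnings
            warnings.warn(
                f"rejected degenerate box {ann['bbox']} "
                f"(annotation {ann.get('id')})")
            rejected += 1
            continue
        cname = cat_names[ann["category_id"]]
        out[id_to_name[ann["image_id"]]].append(
            GroundTruthBox(box=Box(x, y, x + w, y + h), class_name=cname))
    return out, rejected


def write_detections(detections: list[Detection], path: str | Path):
    """COCO results-style JSON list."""
    cat_id = {c: ci + 1 for ci, c in enumerate(CLASS_NAMES)}
    payload = [{
        "image_id": d.image_id, "category_id": cat_id[d.class_name],
        "bbox": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
        "score": d.confidence,
    } for d in detections]
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_detections(path: str | Path) -> list[Detection]:
    with open(path) as fh:
        data = json.load(fh)
    name_of = {ci + 1: c for ci, c in enumerate(CLASS_NAMES)}
    out = []
    for d in data:
        x, y, w, h = d["bbox"]
        out.append(Detection(
            image_id=str(d["image_id"]), class_name=name_of[d["category_id"]],
            box=Box(x, y, x + w, y + h), confidence=float(d["score"])))
    return out


# ------------------------------------------------------------------ images
def write_images(images: list[LabeledImage], directory: str | Path):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img in images:
        arr = np.clip(img.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / f"{img.image_id}.png")


def read_images(directory: str | Path,
                annotations: dict[str, list[GroundTruthBox]] | None = None
                ) -> list[LabeledImage]:
    directory = Path(directory)
    out = []
    for p in sorted(directory.glob("*.png")):
        arr = np.asarray(Image.open(p).convert("L"), dtype=np.float64) / 255.0
        boxes = (annotations or {}).get(p.stem, [])
        out.append(LabeledImage(image_id=p.stem, pixels=arr, boxes=list(boxes),
                                occluded=(annotations is not None and not boxes)))
    return out


def write_json_report(report: dict, path: str | Path):
    """Deterministic (sorted keys, fixed float formatting) metrics report."""
    def _plain(o):
        if isinstance(o, dict):
            return {k: _plain(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_plain(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o
    with open(path, "w") as fh:
        json.dump(_plain(report), fh, sort_keys=True, indent=2)
        fh.write("\n")
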