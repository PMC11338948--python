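"""File formats: landmark annotations, mask PNGs, spacing, reports.

Serialized pixel coordinates are always 0-based with the origin at the
top-left corner.  Mask channels are single-channel PNGs with 0/255 coding
0/1, named ``<image_id>_<channel>.png`` for the channels ``ngt_line``,
``cvc_line``, ``cvc_tip`` and ``ett_tip``.  Pixel spacing comes from DICOM
metadata when available and from explicit configuration otherwise; its
absence is a hard error because every rule threshold is metric.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .geometry import ImageMeta, LandmarkSet, Point, SpacingError

logger = logging.getLogger(__name__)

MASK_CHANNELS = ("ngt_line", "cvc_line", "cvc_tip", "ett_tip")

# point landmarks carry x and y; level landmarks carry only a row coordinate
_POINT_LANDMARKS = ("carina", "cavoatrial_junction", "ge_junction")
_LEVEL_LANDMARKS = ("t1_level", "aortic_arch_upper")

#: default mapping from annotation-tool label names to landmark fields
DEFAULT_ALIASES = {
    "carina": "carina",
    "cavoatrial junction": "cavoatrial_junction",
    "cavoatrial_junction": "cavoatrial_junction",
    "ge junction": "ge_junction",
    "ge_junction": "ge_junction",
    "gastroesophageal junction": "ge_junction",
    "t1_level": "t1_level",
    "aortic_arch_upper": "aortic_arch_upper",
}


def _records_to_landmarks(
    records: Sequence[Tuple[str, str, float, float]],
) -> Dict[str, LandmarkSet]:
    """(image_id, name, x, y) records -> per-image landmark sets."""
    out: Dict[str, LandmarkSet] = {}
    seen: set = set()
    for image_id, name, x, y in records:
        if name not in _POINT_LANDMARKS + _LEVEL_LANDMARKS:
            raise ValueError(
                f"unknown landmark name {name!r} for image {image_id!r}"
            )
        key = (image_id, name)
        if key in seen:
            raise ValueError(
                f"duplicate landmark {name!r} for image {image_id!r}"
            )
        seen.add(key)
        lm = out.setdefault(image_id, LandmarkSet())
        if name in _POINT_LANDMARKS:
            setattr(lm, name, Point(x=float(x), y=float(y)))
        else:
            setattr(lm, f"{name}_y", float(y))
    return out


def read_landmarks(path) -> Dict[str, LandmarkSet]:
    """Read landmark annotations from JSON or CSV.

    JSON: a list of objects with keys ``image_id``, ``name``, ``x``, ``y``.
    CSV: columns ``image_id,name,x,y``.  An empty file yields an empty
    mapping; unknown names and duplicates are hard errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = []
        with open(path, newline="") as fh:
            text = fh.read().strip()
        if not text:
            return {}
        for i, row in enumerate(csv.DictReader(text.splitlines())):
            try:
                records.append(
                    (row["image_id"], row["name"],
                     float(row["x"]), float(row["y"]))
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed CSV row {i + 2}") from exc
        return _records_to_landmarks(records)
    text = path.read_text().strip()
    if not text:
        return {}
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON: {exc}") from exc
    records = []
    for i, rec in enumerate(data):
        try:
            records.append(
                (rec["image_id"], rec["name"],
                 float(rec["x"]), float(rec["y"]))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed record {i}: {rec}") from exc
    return _records_to_landmarks(records)


def write_landmarks_json(landmarks: Mapping[str, LandmarkSet], path) -> None:
    records = []
    for image_id in sorted(landmarks):
        lm = landmarks[image_id]
        for name in _POINT_LANDMARKS:
            p = getattr(lm, name)
            if p is not None:
                records.append(
                    {"image_id": image_id, "name": name, "x": p.x, "y": p.y}
                )
        for name in _LEVEL_LANDMARKS:
            y = getattr(lm, f"{name}_y")
            if y is not None:
                records.append(
                    {"image_id": image_id, "name": name, "x": 0.0, "y": y}
                )
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


def read_cvat_points(
    path, aliases: Optional[Mapping[str, str]] = None
) -> Dict[str, LandmarkSet]:
    """Import CVAT 1.1 "points" annotations.

    Each ``<image name=...>`` element's ``<points label=... points="x,y">``
    children become landmarks; labels are mapped through the alias table
    (case-insensitive; defaults map e.g. "cavoatrial junction" to
    ``cavoatrial_junction``).  Unmapped labels are hard errors.
    """
    alias = {k.lower(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed CVAT XML: {exc}") from exc
    records = []
    for img in tree.getroot().iter("image"):
        image_id = img.get("name") or img.get("id") or ""
        for pts in img.iter("points"):
            label = (pts.get("label") or "").lower()
            if label not in alias:
                raise ValueError(
                    f"{path}: unmapped CVAT label {pts.get('label')!r} "
                    f"on image {image_id!r}"
                )
            first = (pts.get("points") or "").split(";")[0]
            try:
                x, y = (float(v) for v in first.split(","))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: bad points attribute {pts.get('points')!r} "
                    f"on image {image_id!r}"
                ) from exc
            records.append((image_id, alias[label], x, y))
    return _records_to_landmarks(records)


# ---------------------------------------------------------------------------
# spacing


def read_spacing(
    dicom_path=None, config_spacing=None
) -> Tuple[float, float]:
    """Resolve (row, col) pixel spacing in mm/pixel.

    DICOM PixelSpacing (or ImagerPixelSpacing) wins; an explicit config
    value is the fallback; having neither is a hard error.  When both exist
    and disagree by more than 1 %, a warning is logged and DICOM wins.
    """
    dicom_spacing = None
    if dicom_path is not None:
        import pydicom

        ds = pydicom.dcmread(str(dicom_path), stop_before_pixels=True,
                             force=True)
        attr = getattr(ds, "PixelSpacing", None) or getattr(
            ds, "ImagerPixelSpacing", None
        )
        if attr is not None:
            dicom_spacing = (float(attr[0]), float(attr[1]))
    cfg_spacing = None
    if config_spacing is not None:
        if np.isscalar(config_spacing):
            cfg_spacing = (float(config_spacing), float(config_spacing))
        else:
            row, col = config_spacing
            cfg_spacing = (float(row), float(col))
    if dicom_spacing and cfg_spacing:
        rel = max(
            abs(d - c) / c for d, c in zip(dicom_spacing, cfg_spacing)
        )
        if rel > 0.01:
            logger.warning(
                "DICOM spacing %s disagrees with configured %s by %.1f%%; "
                "using DICOM", dicom_spacing, cfg_spacing, 100 * rel,
            )
        return dicom_spacing
    if dicom_spacing:
        return dicom_spacing
    if cfg_spacing:
        return cfg_spacing
    raise SpacingError(
        "pixel spacing unavailable: no DICOM attribute and no configured "
        "value (metric rules cannot run without a scale)"
    )


# ---------------------------------------------------------------------------
# masks


def write_mask_png(mask: np.ndarray, path) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(str(path))


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr >= 128


def mask_filename(image_id: str, channel: str) -> str:
    if channel not in MASK_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    return f"{image_id}_{channel}.png"


def write_mask_channels(masks, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for channel in MASK_CHANNELS:
        write_mask_png(
            getattr(masks, channel),
            out_dir / mask_filename(masks.meta.image_id, channel),
        )


def read_mask_channels(masks_dir, image_id: str, meta: ImageMeta):
    """Assemble a MaskChannelSet from ``<image_id>_<channel>.png`` files;
    missing channels are all-zero (tube absent)."""
    from .masks import MaskChannelSet

    masks_dir = Path(masks_dir)
    channels = {}
    for channel in MASK_CHANNELS:
        p = masks_dir / mask_filename(image_id, channel)
        if p.exists():
            channels[channel] = read_mask_png(p)
        else:
            channels[channel] = np.zeros((meta.height, meta.width), bool)
    return MaskChannelSet(meta=meta, **channels)


# ---------------------------------------------------------------------------
# reports

_UNDEFINED = "undefined"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dumps_canonical(obj) -> str:
    """Deterministic JSON encoding (sorted keys, fixed separators) so that
    identical configuration and seed reproduce byte-identical reports."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      default=_json_default)


def write_report(report: dict, out_dir, manifest: Optional[dict] = None) -> None:
    """Write the JSON report, CSV AUC tables and the run manifest.

    Undefined AUC cells are serialized as the explicit string
    ``"undefined"``; they are part of the result, not missing data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(dumps_canonical(report))
    if manifest is not None:
        (out_dir / "manifest.json").write_text(dumps_canonical(manifest))

    def rows_from(rep: dict, stratum: str = ""):
        for label, cell in rep.get("per_label", {}).items():
            if cell == _UNDEFINED:
                yield (stratum, label, _UNDEFINED, "", "")
            else:
                yield (stratum, label, f"{cell['auc']:.6f}",
                       f"{cell['lo']:.6f}", f"{cell['hi']:.6f}")
        for tube, cell in rep.get("groups", {}).items():
            name = f"{tube}_Average"
            if cell == _UNDEFINED:
                yield (stratum, name, _UNDEFINED, "", "")
            else:
                yield (stratum, name, f"{cell['auc']:.6f}",
                       f"{cell['lo']:.6f}", f"{cell['hi']:.6f}")

    rows = []
    if "per_label" in report:
        rows += list(rows_from(report))
    for stratum, rep in report.get("strata", {}).items():
        rows += list(rows_from(rep, stratum))
    for system, rep in report.get("systems", {}).items():
        rows += list(rows_from(rep, system))
    if rows:
        with open(out_dir / "auc_table.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stratum", "label", "auc", "ci_lo", "ci_hi"])
            w.writerows(rows)


def read_report(out_dir) -> dict:
    return json.loads((Path(out_dir) / "report.json").read_text())
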