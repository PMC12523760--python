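"""Endocardial/myocardial region-of-interest handling.

Biopsy sections are subdivided into an endocardial compartment (the
collagen-rich inner lining) and a myocardial compartment (the muscle bulk).
This module consumes polygon annotations -- drawn by a human in any
annotation tool, or auto-generated for synthetic studies -- as GeoJSON,
rasterizes them into a compartment label image, and restricts masks and
fiber sets to one compartment.

Conventions: coordinates are 0-based image pixels with (x, y) = (column,
row); polygons must be simple; where endocardium and myocardium overlap the
endocardium wins (it is the thinner, more specific structure); a fiber
belongs to the compartment containing the majority of its skeleton pixels,
so no fiber is split or double-counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .fiberid import FiberRecord
from .stainseg import CollagenMask

__all__ = [
    "ROISet",
    "CompartmentRaster",
    "ALLOWED_LABELS",
    "COMPARTMENT_CODES",
    "load_rois",
    "write_rois",
    "rasterize_compartments",
    "restrict_to_compartment",
    "assign_fibers",
]

ALLOWED_LABELS = ("endocardium", "myocardium")
COMPARTMENT_CODES = {"unassigned": 0, "myocardium": 1, "endocardium": 2}


@dataclass
class ROISet:
    """Labelled simple polygons in image pixel space."""

    polygons: list[tuple[str, np.ndarray]]  # (label, (N, 2) array of (x, y))
    source: str = ""


@dataclass
class CompartmentRaster:
    """Label raster: 0 unassigned, 1 myocardium, 2 endocardium."""

    labels: np.ndarray  # H x W uint8

    def mask(self, label: str) -> np.ndarray:
        return self.labels == COMPARTMENT_CODES[label]


def _validate_feature(idx: int, feature: dict) -> tuple[str, np.ndarray]:
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise ValueError(f"feature {idx}: geometry must be a Polygon, got {geom.get('type')!r}")
    label = (feature.get("properties") or {}).get("label")
    if label not in ALLOWED_LABELS:
        raise ValueError(
            f"feature {idx}: unknown label {label!r}; allowed labels are {ALLOWED_LABELS}"
        )
    rings = geom.get("coordinates") or []
    if not rings:
        raise ValueError(f"feature {idx}: polygon has no coordinate ring")
    coords = np.asarray(rings[0], dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 4:
        raise ValueError(f"feature {idx}: ring must be a closed list of >= 4 (x, y) points")
    poly = Polygon(coords)
    if not (poly.is_valid and poly.is_simple):
        raise ValueError(f"feature {idx}: polygon is self-intersecting or invalid")
    return label, coords


def load_rois(source: str | Path | dict) -> ROISet:
    """Load and validate a GeoJSON FeatureCollection of labelled polygons."""
    if isinstance(source, (str, Path)):
        path = str(source)
        try:
            data = json.loads(Path(source).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed GeoJSON in {path}: {exc}") from exc
    else:
        path = "<dict>"
        data = source
    if not isinstance(data, dict) or data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    polygons = [
        _validate_feature(i, f) for i, f in enumerate(data.get("features") or [])
    ]
    return ROISet(polygons, source=path)


def write_rois(rois: ROISet, path: str | Path) -> None:
    feats = []
    for label, coords in rois.polygons:
        feats.append(
            {
                "type": "Feature",
                "properties": {"label": label},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [np.asarray(coords, dtype=float).tolist()],
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def rasterize_compartments(rois: ROISet, shape: tuple[int, int]) -> CompartmentRaster:
    """Fill polygons into a label raster; endocardium takes precedence."""
    labels = np.zeros(shape, dtype=np.uint8)
    # myocardium first so overlapping endocardium overwrites it
    for wanted in ("myocardium", "endocardium"):
        for label, coords in rois.polygons:
            if label != wanted:
                continue
            rc = np.column_stack([coords[:, 1], coords[:, 0]])  # (y, x) -> (row, col)
            m = polygon2mask(shape, rc)
            labels[m] = COMPARTMENT_CODES[label]
    return CompartmentRaster(labels)


def assign_fibers(
    fibers: list[FiberRecord], raster: CompartmentRaster
) -> dict[int, str]:
    """Compartment per fiber by majority of skeleton pixels (ties: endocardium).

    Assignment is total and exclusive: fibers whose majority lies outside
    both polygons map to ``"unassigned"``.
    """
    code_to_label = {v: k for k, v in COMPARTMENT_CODES.items()}
    out: dict[int, str] = {}
    for f in fibers:
        codes = raster.labels[tuple(f.skeleton_pixels.T)]
        counts = np.bincount(codes, minlength=3)
        best = int(np.flatnonzero(counts == counts.max()).max())  # endo > myo > none
        out[f.fiber_id] = code_to_label[best]
    return out


def restrict_to_compartment(
    target: CollagenMask | list[FiberRecord],
    raster: CompartmentRaster,
    label: str,
) -> CollagenMask | list[FiberRecord]:
    """Restrict a mask (intersection) or fiber list (majority rule) to a compartment."""
    if label not in COMPARTMENT_CODES:
        raise ValueError(f"unknown compartment {label!r}")
    if isinstance(target, CollagenMask):
        return CollagenMask(
            target.mask & raster.mask(label),
            target.mpp,
            provenance={**target.provenance, "compartment": label},
        )
    assignment = assign_fibers(target, raster)
    return [f for f in target if assignment[f.fiber_id] == label]
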