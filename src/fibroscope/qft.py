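"""Quantitative fibrosis trait (qFT) catalog and extraction.

A qFT is one named numeric descriptor of the collagen phenotype of a
sample x compartment.  The catalog spans three families:

* ``content`` -- how much collagen: area fraction, absolute area, object
  count density, nodularity (object compactness), object-size statistics.
* ``morphometry`` -- per-fiber structure: {length, widths, area, junction
  and endpoint counts, continuity, straightness} x {mean, median, sd,
  skewness, kurtosis, p10, p90} x {all, fine, assembled} strata.
* ``architecture`` -- tissue-level organisation: class-resolved fiber
  densities, assembled-fiber area fraction, orientation order and entropy,
  alignment coherence, and GLCM entropy traits.

Trait names follow the grammar
``<compartment>.<family>.<base>.<descriptor>[.<stratum>]`` and parse back
into their parts.  Every trait declares units, a length-dimension exponent
(so scale equivariance under resolution changes is checkable), and a
direction: whether larger values indicate more severe fibrosis, which the
composite-score stage uses to orient normalized traits.  This catalog is an
open construction spanning the three families of commercial fibrosis
phenotyping panels; it does not reproduce any proprietary nomenclature
name-for-name.

Undefined values (e.g. the sd of a single fiber, or any trait of a
zero-area compartment) are NaN -- an explicit missing marker, never a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import structure_tensor
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .entropy import EntropyMap, entropy_traits
from .fiberid import (
    FIBER_MEASURES,
    SUMMARY_DESCRIPTORS,
    FiberRecord,
    fiber_summary,
    records_to_frame,
)
from .roi import CompartmentRaster, assign_fibers
from .stainseg import CollagenMask

__all__ = [
    "TraitDef",
    "TraitCatalog",
    "TraitVector",
    "COMPARTMENTS",
    "trait_catalog",
    "parse_trait_name",
    "extract_traits",
    "traits_to_frame",
]

COMPARTMENTS = ("whole", "myocardium", "endocardium")
STRATA = ("all", "fine", "assembled")

# base -> (units, length exponent)
_MORPH_BASES = {
    "length_um": ("um", 1),
    "width_mean_um": ("um", 1),
    "width_max_um": ("um", 1),
    "area_um2": ("um2", 2),
    "n_junctions": ("count", 0),
    "n_endpoints": ("count", 0),
    "continuity": ("fraction", 0),
    "straightness": ("fraction", 0),
}
assert tuple(_MORPH_BASES) == FIBER_MEASURES

_CONTENT_BASES = {
    "collagen_area_fraction": ("fraction", 0),
    "collagen_area": ("um2", 2),
    "object_count_density": ("per_mm2", -2),
    "nodularity": ("dimensionless", 0),
    "object_area_mean": ("um2", 2),
    "object_area_p90": ("um2", 2),
}

_ENTROPY_BASES = {
    "entropy_mean": ("bits", 0),
    "entropy_sd": ("bits", 0),
    "entropy_p90": ("bits", 0),
    "high_entropy_area_fraction": ("fraction", 0),
}


@dataclass(frozen=True)
class TraitDef:
    name: str
    compartment: str
    family: str  # content | morphometry | architecture
    base: str
    descriptor: str
    stratum: str | None
    units: str
    length_exponent: int
    direction: int  # +1: larger = more fibrotic, -1: larger = less


@dataclass
class TraitCatalog:
    traits: list[TraitDef]
    by_name: dict[str, TraitDef] = field(init=False)

    def __post_init__(self) -> None:
        self.by_name = {t.name: t for t in self.traits}
        if len(self.by_name) != len(self.traits):
            raise ValueError("trait names must be unique")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def __len__(self) -> int:
        return len(self.traits)


def _name(compartment: str, family: str, base: str, descriptor: str, stratum: str | None) -> str:
    parts = [compartment, family, base, descriptor]
    if stratum is not None:
        parts.append(stratum)
    return ".".join(parts)


def parse_trait_name(name: str) -> tuple[str, str, str, str, str | None]:
    """Split a trait name into (compartment, family, base, descriptor, stratum)."""
    parts = name.split(".")
    if len(parts) not in (4, 5):
        raise ValueError(f"not a valid trait name: {name!r}")
    compartment, family, base, descriptor = parts[:4]
    stratum = parts[4] if len(parts) == 5 else None
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment in trait name: {name!r}")
    if family not in ("content", "morphometry", "architecture"):
        raise ValueError(f"unknown family in trait name: {name!r}")
    return compartment, family, base, descriptor, stratum


def trait_catalog(
    compartments: tuple[str, ...] = COMPARTMENTS,
    directions: dict[str, int] | None = None,
) -> TraitCatalog:
    """Enumerate the full qFT catalog.

    ``directions`` overrides the per-name default orientation (larger =
    more fibrotic everywhere except the orientation order parameter, whose
    reading is arguable and which defaults to -1).
    """
    traits: list[TraitDef] = []
    overrides = directions or {}

    def add(comp, family, base, descriptor, stratum, units, exp, direction):
        nm = _name(comp, family, base, descriptor, stratum)
        traits.append(
            TraitDef(
                nm, comp, family, base, descriptor, stratum, units, exp,
                overrides.get(nm, direction),
            )
        )

    for comp in compartments:
        for base, (units, exp) in _CONTENT_BASES.items():
            add(comp, "content", base, "value", None, units, exp, +1)
        for base, (units, exp) in _MORPH_BASES.items():
            for desc in SUMMARY_DESCRIPTORS:
                d_exp = 0 if desc in ("skewness", "kurtosis") else exp
                d_units = "dimensionless" if desc in ("skewness", "kurtosis") else units
                for stratum in STRATA:
                    add(comp, "morphometry", base, desc, stratum, d_units, d_exp, +1)
        for stratum in STRATA:
            add(comp, "architecture", "fiber_count_density", "value", stratum, "per_mm2", -2, +1)
        add(comp, "architecture", "assembled_area_fraction", "value", None, "fraction", 0, +1)
        add(comp, "architecture", "orientation_order", "value", None, "dimensionless", 0, -1)
        add(comp, "architecture", "orientation_entropy", "value", None, "bits", 0, +1)
        add(comp, "architecture", "alignment_coherence", "value", None, "dimensionless", 0, +1)
        for base, (units, exp) in _ENTROPY_BASES.items():
            add(comp, "architecture", base, "value", None, units, exp, +1)
    return TraitCatalog(traits)


@dataclass
class TraitVector:
    """All qFT values for one sample x compartment."""

    sample_id: str
    compartment: str
    values: dict[str, float]


def _content_traits(cm: np.ndarray, mpp: float, comp_area_um2: float) -> dict[str, float]:
    out: dict[str, float] = {}
    n_px = int(cm.sum())
    area_um2 = n_px * mpp**2
    out["collagen_area_fraction"] = area_um2 / comp_area_um2
    out["collagen_area"] = area_um2
    labels, n_obj = sk_label(cm, connectivity=2, return_num=True)
    area_mm2 = comp_area_um2 / 1e6
    out["object_count_density"] = n_obj / area_mm2
    if n_obj:
        props = regionprops(labels)
        areas = np.array([p.area for p in props], dtype=float) * mpp**2
        nod = []
        for p in props:
            per = p.perimeter
            circ = min(4 * np.pi * p.area / per**2, 1.0) if per > 0 else 1.0
            nod.append(p.solidity * circ)
        out["nodularity"] = float(np.mean(nod))
        out["object_area_mean"] = float(areas.mean())
        out["object_area_p90"] = float(np.percentile(areas, 90))
    else:
        out["nodularity"] = float("nan")
        out["object_area_mean"] = float("nan")
        out["object_area_p90"] = float("nan")
    return out


def _orientation_arch(frame: pd.DataFrame) -> dict[str, float]:
    """Length-weighted axial order parameter and orientation entropy (bits)."""
    out: dict[str, float] = {}
    if len(frame) == 0:
        out["orientation_order"] = float("nan")
        out["orientation_entropy"] = float("nan")
        return out
    theta = np.deg2rad(frame["orientation_deg"].to_numpy())
    wgt = frame["length_um"].to_numpy()
    z = np.sum(wgt * np.exp(2j * theta)) / wgt.sum()
    out["orientation_order"] = float(np.abs(z))  # 1 - circular variance
    hist, _ = np.histogram(
        frame["orientation_deg"], bins=12, range=(0.0, 180.0), weights=wgt
    )
    p = hist[hist > 0] / hist.sum()
    out["orientation_entropy"] = float(-(p * np.log2(p)).sum())
    return out


def _coherence_raster(collagen_map: np.ndarray) -> np.ndarray:
    """Structure-tensor coherence, (l1-l2)/(l1+l2), per pixel."""
    axx, axy, ayy = structure_tensor(collagen_map, sigma=2.0, order="xy")
    tmp = np.sqrt((axx - ayy) ** 2 + 4 * axy**2)
    denom = axx + ayy
    return np.divide(tmp, denom, out=np.zeros_like(tmp), where=denom > 1e-12)


def extract_traits(
    mask: CollagenMask,
    fibers: list[FiberRecord],
    emap: EntropyMap | None = None,
    compartments: CompartmentRaster | None = None,
    tissue: np.ndarray | None = None,
    collagen_map: np.ndarray | None = None,
    sample_id: str = "",
    catalog: TraitCatalog | None = None,
) -> list[TraitVector]:
    """Compute every catalog trait per compartment present.

    ``whole`` always covers the entire tissue (pixels outside both ROI
    polygons included); the myocardial and endocardial vectors are emitted
    only when a compartment raster is supplied.  A compartment with zero
    area yields all-NaN traits rather than an error.
    """
    mpp = mask.mpp
    shape = mask.mask.shape
    if tissue is None:
        tissue = np.ones(shape, dtype=bool)
    comp_list = ["whole"] + (["myocardium", "endocardium"] if compartments is not None else [])
    if catalog is None:
        catalog = trait_catalog(tuple(comp_list))

    assignment = assign_fibers(fibers, compartments) if compartments is not None else None
    centers_r = emap.centers(0) if emap is not None else None
    centers_c = emap.centers(1) if emap is not None else None
    coh_raster = _coherence_raster(collagen_map) if collagen_map is not None else None

    vectors: list[TraitVector] = []
    for comp in comp_list:
        if comp == "whole":
            comp_mask = tissue
            comp_fibers = fibers
        else:
            comp_mask = compartments.mask(comp) & tissue
            comp_fibers = [f for f in fibers if assignment[f.fiber_id] == comp]
        comp_area_um2 = float(comp_mask.sum()) * mpp**2
        values: dict[str, float] = {}
        if comp_area_um2 == 0:
            for t in catalog.traits:
                if t.compartment == comp:
                    values[t.name] = float("nan")
            vectors.append(TraitVector(sample_id, comp, values))
            continue
        area_mm2 = comp_area_um2 / 1e6

        content = _content_traits(mask.mask & comp_mask, mpp, comp_area_um2)
        for base, v in content.items():
            values[_name(comp, "content", base, "value", None)] = v

        summary = fiber_summary(comp_fibers, area_mm2=area_mm2, strata=STRATA)
        for stratum in STRATA:
            entry = summary[stratum]
            for base in FIBER_MEASURES:
                for desc in SUMMARY_DESCRIPTORS:
                    values[_name(comp, "morphometry", base, desc, stratum)] = entry[base][desc]
            values[_name(comp, "architecture", "fiber_count_density", "value", stratum)] = (
                entry["count_density_per_mm2"]
            )
        assembled_area = sum(f.area_um2 for f in comp_fibers if f.fiber_class == "assembled")
        values[_name(comp, "architecture", "assembled_area_fraction", "value", None)] = (
            assembled_area / comp_area_um2
        )
        frame = records_to_frame(comp_fibers)
        for base, v in _orientation_arch(frame).items():
            values[_name(comp, "architecture", base, "value", None)] = v
        if coh_raster is not None:
            sel = mask.mask & comp_mask
            coh = float(coh_raster[sel].mean()) if sel.any() else float("nan")
        else:
            coh = float("nan")
        values[_name(comp, "architecture", "alignment_coherence", "value", None)] = coh
        if emap is not None:
            where = comp_mask[np.ix_(centers_r, centers_c)]
            etr = entropy_traits(emap, where=where)
        else:
            etr = {k: float("nan") for k in _ENTROPY_BASES}
        for base, v in etr.items():
            values[_name(comp, "architecture", base, "value", None)] = v
        vectors.append(TraitVector(sample_id, comp, values))
    return vectors


def traits_to_frame(per_sample: dict[str, list[TraitVector]]) -> pd.DataFrame:
    """Wide trait matrix: one row per sample, one column per trait name."""
    rows = {}
    for sample_id, vectors in per_sample.items():
        merged: dict[str, float] = {}
        for v in vectors:
            merged.update(v.values)
        rows[sample_id] = merged
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame
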