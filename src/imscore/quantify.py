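"""SUV conversion, reference-ROI placement and SUVmax extraction.

The standardized uptake value normalises tissue activity concentration by
injected dose per body weight::

    SUV = activity [mCi/mL] * body_weight [g] / injected_dose [mCi]

Units are fixed at mCi and grams internally; readers converting from
Bq-based inputs do so before constructing a :class:`PetVolume`.

Reference ROIs mimic the manual protocol used in end-of-therapy PET reading:

* gray matter / white matter: a sphere at least 1 cm in diameter, drawn as
  large as possible in the hemisphere contralateral to the lesion(s);
* CSF: a sphere (>= 1 cm) on a lateral ventricle;
* liver: a 3 cm sphere in the right hepatic lobe;
* mediastinal blood pool: a 1.5 cm cylinder over contiguous slices of the
  descending aorta, excluding the vessel wall (one-voxel erosion).

Automated placement centres each ROI at the deepest interior point of its
structure (argmax of the Euclidean distance transform; ties break to the
lowest linear voxel index), a deterministic stand-in for "drawn to be as
large as possible".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import PlacementError, ValidationError

__all__ = [
    "PetVolume",
    "LabelMap",
    "RoiSpec",
    "ReferencePanel",
    "LesionMeasurement",
    "REFERENCE_ROI_SPECS",
    "suv_field",
    "place_roi",
    "measure_reference_panel",
    "measure_lesions",
]

LESION_PREFIX = "lesion_"


@dataclass
class PetVolume:
    """3-D activity-concentration field plus acquisition metadata."""

    voxels: np.ndarray  # mCi/mL, nonnegative
    voxel_size: tuple[float, float, float]  # mm
    injected_dose: float  # mCi
    body_weight: float  # g
    modality: str = "PET_CT"  # "PET_CT" | "PET_MR"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValidationError("PET volume must be 3-D")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3  # type: ignore[assignment]
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if self.injected_dose <= 0:
            raise ValidationError(f"injected dose must be > 0 mCi, got {self.injected_dose!r}")
        if self.body_weight <= 0:
            raise ValidationError(f"body weight must be > 0 g, got {self.body_weight!r}")
        if float(self.voxels.min(initial=0.0)) < 0:
            raise ValidationError("negative activity concentration in PET volume")
        if self.modality not in ("PET_CT", "PET_MR"):
            raise ValidationError(f"unknown modality {self.modality!r}")


@dataclass
class LabelMap:
    """Integer segmentation on the same grid as its PetVolume."""

    voxels: np.ndarray  # integer labels
    labels: Mapping[str, int]  # name -> label value; 0 is background

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("label map must be 3-D")
        self.labels = dict(self.labels)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise PlacementError(f"structure {name!r} absent from label map")
        return self.voxels == self.labels[name]

    def lesion_names(self) -> list[str]:
        return sorted(n for n in self.labels if n.startswith(LESION_PREFIX))


@dataclass
class RoiSpec:
    """Geometric ROI request inside a named structure.

    ``diameter`` is the requested ROI diameter in mm; ``None`` asks for the
    largest sphere that fits.  ``min_diameter`` is the protocol floor (the
    reading rule is "always more than 1 cm").  ``erode_wall`` removes a
    one-voxel rim of the structure before placement (descending-aorta rule).
    """

    shape: str  # "sphere" | "cylinder"
    containment: str
    diameter: float | None = None
    min_diameter: float = 10.0
    height: float | None = None  # cylinders only; defaults to diameter
    erode_wall: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.min_diameter <= 0:
            raise ValidationError("min_diameter must be > 0")
        if self.diameter is not None and self.diameter < self.min_diameter:
            raise ValidationError(
                f"diameter {self.diameter} mm below the floor {self.min_diameter} mm")


@dataclass
class ReferencePanel:
    """Per-patient reference SUVmax values; body entries absent for PET/MR."""

    gm: float
    wm: float
    csf: float
    liver: float | None = None
    mediastinum: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"gm": self.gm, "wm": self.wm, "csf": self.csf}
        if self.liver is not None:
            d["liver"] = self.liver
        if self.mediastinum is not None:
            d["mediastinum"] = self.mediastinum
        return d


@dataclass
class LesionMeasurement:
    lesion_id: str
    suvmax: float
    volume_ml: float


#: Protocol ROI geometry per reference structure.  GM/WM/CSF use the 1 cm
#: protocol floor centred at the deepest interior point rather than the
#: maximal inscribed sphere: an ROI touching a hotter neighbour would report
#: spill-in as SUVmax, which manual readers deliberately avoid.
REFERENCE_ROI_SPECS: dict[str, RoiSpec] = {
    "gm": RoiSpec(shape="sphere", containment="gm", diameter=10.0, min_diameter=10.0),
    "wm": RoiSpec(shape="sphere", containment="wm", diameter=10.0, min_diameter=10.0),
    "csf": RoiSpec(shape="sphere", containment="csf_ventricle", diameter=10.0,
                   min_diameter=10.0),
    "liver": RoiSpec(shape="sphere", containment="liver", diameter=30.0,
                     min_diameter=30.0),
    "mediastinum": RoiSpec(shape="cylinder", containment="mediastinum_aorta",
                           diameter=15.0, min_diameter=15.0, erode_wall=True),
}


def suv_field(volume: PetVolume) -> np.ndarray:
    """Elementwise SUV: activity * body_weight / injected_dose."""
    return volume.voxels.astype(np.float64) * (volume.body_weight / volume.injected_dose)


def _coordinate_grids(shape: tuple[int, ...], voxel_size: tuple[float, ...]):
    axes = [np.arange(n) * s for n, s in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _sphere_mask(shape, voxel_size, center_idx, radius_mm) -> np.ndarray:
    gx, gy, gz = _coordinate_grids(shape, voxel_size)
    cx, cy, cz = (i * s for i, s in zip(center_idx, voxel_size))
    d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    return d2 <= radius_mm ** 2


def _cylinder_mask(shape, voxel_size, center_idx, radius_mm, half_height_mm) -> np.ndarray:
    # Axis-aligned cylinder along the last (z) axis.
    gx, gy, gz = _coordinate_grids(shape, voxel_size)
    cx, cy, cz = (i * s for i, s in zip(center_idx, voxel_size))
    in_plane = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius_mm ** 2
    along = np.abs(gz - cz) <= half_height_mm
    return in_plane & along


def place_roi(labels: LabelMap, spec: RoiSpec,
              voxel_size: tuple[float, float, float],
              restrict: np.ndarray | None = None) -> np.ndarray:
    """Place an ROI inside a structure; returns a boolean voxel mask.

    The centre is the structure's deepest interior point (maximum Euclidean
    distance to the boundary, computed in mm); ties resolve to the lowest
    linear voxel index.  For cylinders the depth is evaluated in-plane and
    combined over the contiguous slice span so the whole cylinder fits.
    ``restrict`` optionally limits the structure mask (e.g. to one
    hemisphere) before placement.
    """
    mask = labels.mask(spec.containment)
    if restrict is not None:
        mask = mask & restrict
    if spec.erode_wall:
        mask = ndimage.binary_erosion(mask)
    if not mask.any():
        raise PlacementError(f"structure {spec.containment!r} empty after restriction")

    if spec.shape == "sphere":
        dist = ndimage.distance_transform_edt(mask, sampling=voxel_size)
        dist_flat = dist.ravel()
        max_depth = float(dist.max())
        radius = (spec.diameter / 2.0) if spec.diameter is not None else max_depth
        if radius < spec.min_diameter / 2.0 or max_depth < radius:
            raise PlacementError(
                f"structure {spec.containment!r} too small for a "
                f"{max(2 * radius, spec.min_diameter):.1f} mm sphere "
                f"(max inscribed diameter {2 * max_depth:.1f} mm)")
        if spec.diameter is not None:
            # Deepest voxel that can host the requested sphere; np.argmax
            # returns the first (lowest-linear-index) maximum, the tie-break.
            candidates = np.flatnonzero(dist_flat >= radius)
            center_flat = int(candidates[np.argmax(dist_flat[candidates])])
        else:
            center_flat = int(np.argmax(dist_flat))
        center = np.unravel_index(center_flat, mask.shape)
        roi = _sphere_mask(mask.shape, voxel_size, center, radius)
    else:  # cylinder
        radius = (spec.diameter or spec.min_diameter) / 2.0
        height = spec.height if spec.height is not None else (spec.diameter or spec.min_diameter)
        half_h = height / 2.0
        # In-plane depth per slice, then require the full slice span to fit:
        # minimum over the z-window of the 2-D distance transforms.
        dist2d = np.stack([
            ndimage.distance_transform_edt(mask[:, :, k], sampling=voxel_size[:2])
            for k in range(mask.shape[2])], axis=2)
        win = max(int(np.ceil(height / voxel_size[2])) | 1, 1)  # odd window
        depth = ndimage.minimum_filter1d(dist2d, size=win, axis=2, mode="constant")
        if float(depth.max()) < radius:
            raise PlacementError(
                f"structure {spec.containment!r} too small for a {2 * radius:.1f} mm "
                f"cylinder over {height:.1f} mm of contiguous slices")
        center = np.unravel_index(int(np.argmax(depth == depth.max())), mask.shape)
        roi = _cylinder_mask(mask.shape, voxel_size, center, radius, half_h)

    roi &= mask  # numerical safety; by construction roi should already fit
    if not roi.any():
        raise PlacementError(f"empty ROI in structure {spec.containment!r}")
    return roi


def _lesion_centroid_x(suv: np.ndarray, labels: LabelMap) -> float | None:
    """Uptake-weighted centroid x-index over all lesion labels, or None."""
    names = labels.lesion_names()
    if not names:
        return None
    total_w = 0.0
    total_wx = 0.0
    for name in names:
        m = labels.mask(name)
        w = suv[m]
        xs = np.nonzero(m)[0].astype(float)
        total_w += float(w.sum())
        total_wx += float((w * xs).sum())
    if total_w == 0:
        return None
    return total_wx / total_w


def measure_reference_panel(volume: PetVolume, labels: LabelMap) -> ReferencePanel:
    """SUVmax of each reference structure using protocol ROIs.

    Gray- and white-matter ROIs go in the hemisphere contralateral to the
    uptake-weighted lesion centroid (either hemisphere when no lesion is
    present).  Hemispheres are halves of the grid about the midsagittal
    (x) plane.  PET/MR panels omit liver and mediastinum.
    """
    if labels.voxels.shape != volume.voxels.shape:
        raise ValidationError("label map grid differs from PET volume grid")
    suv = suv_field(volume)
    vsize = volume.voxel_size

    centroid_x = _lesion_centroid_x(suv, labels)
    restrict = None
    if centroid_x is not None:
        nx = volume.voxels.shape[0]
        half = np.zeros(volume.voxels.shape, dtype=bool)
        if centroid_x >= nx / 2.0:  # lesion right -> reference left
            half[: nx // 2] = True
        else:
            half[nx // 2:] = True
        restrict = half

    def _suvmax(name: str, hemi: bool) -> float:
        spec = REFERENCE_ROI_SPECS[name]
        roi = place_roi(labels, spec, vsize, restrict=restrict if hemi else None)
        return float(suv[roi].max())

    gm = _suvmax("gm", hemi=True)
    wm = _suvmax("wm", hemi=True)
    csf = _suvmax("csf", hemi=False)
    if volume.modality == "PET_MR":
        return ReferencePanel(gm=gm, wm=wm, csf=csf)
    for name in ("liver", "mediastinum_aorta"):
        if name not in labels.labels:
            raise ValidationError(
                f"PET_CT volume lacks required structure {name!r}")
    return ReferencePanel(gm=gm, wm=wm, csf=csf,
                          liver=_suvmax("liver", hemi=False),
                          mediastinum=_suvmax("mediastinum", hemi=False))


def measure_lesions(volume: PetVolume, labels: LabelMap) -> list[LesionMeasurement]:
    """SUVmax and volume of every lesion label; empty list when none exist."""
    if labels.voxels.shape != volume.voxels.shape:
        raise ValidationError("label map grid differs from PET volume grid")
    suv = suv_field(volume)
    voxel_ml = float(np.prod(volume.voxel_size)) / 1000.0
    out = []
    for name in labels.lesion_names():
        m = labels.mask(name)
        if not m.any():
            continue
        out.append(LesionMeasurement(
            lesion_id=name,
            suvmax=float(suv[m].max()),
            volume_ml=float(m.sum()) * voxel_ml,
        ))
    return out
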