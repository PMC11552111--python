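"""Digital FDG-PET phantom for end-of-therapy brain scans.

The phantom is deliberately schematic — analytic ellipsoids and cylinders on
an isotropic grid — because its job is to exercise ROI placement, SUV
arithmetic and score assignment, not to look like a brain:

* a spherical gray-matter shell around a white-matter core;
* two ellipsoidal lateral ventricles (CSF) carved out of the white matter;
* optional torso slab (PET/CT mode) holding a liver ellipsoid and a
  descending-aorta cylinder (mediastinal blood pool);
* up to four spherical residual lesions in the left-hemisphere white matter.

Per-structure target SUVmax values are drawn from truncated normals whose
means and SDs default to reported reference-structure statistics (gray
matter 9.45 +/- 2.01, liver 2.96 +/- 0.42, white matter 2.81 +/- 0.58,
mediastinum 1.80 +/- 0.36, CSF 1.50 +/- 0.34).  Voxel activity is set to
``SUV * dose / weight`` — the exact inverse of the SUV formula — so that
with zero noise and zero PSF the quantification stage recovers every target
exactly.  Lesion uptake is placed mid-band for the patient's true IMS level
relative to that patient's own drawn references.  Multiplicative Gaussian
noise is applied to the activity and then smoothed by an isotropic Gaussian
point-spread function, mimicking reconstruction of noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .cohort import PatientRecord
from .errors import ConfigurationError, GeometryError, ValidationError
from .quantify import LabelMap, PetVolume

__all__ = [
    "ReferenceCalibration",
    "PhantomGeometry",
    "PhantomResult",
    "draw_reference_panel",
    "simulate_phantom",
]

#: Label values used in every phantom label map.
LABELS = {
    "background": 0,
    "gm": 1,
    "wm": 2,
    "csf_ventricle": 3,
    "liver": 4,
    "mediastinum_aorta": 5,
}
_LESION_BASE = 10
_TRUNC_LO = 0.1  # SUV floor for truncated-normal reference draws


@dataclass
class ReferenceCalibration:
    """Mean/SD of reference-structure SUVmax used to drive the generator."""

    mean: dict[str, float] = field(default_factory=lambda: {
        "gm": 9.45, "liver": 2.96, "wm": 2.81, "mediastinum": 1.80, "csf": 1.50})
    sd: dict[str, float] = field(default_factory=lambda: {
        "gm": 2.01, "liver": 0.42, "wm": 0.58, "mediastinum": 0.36, "csf": 0.34})

    def validate(self) -> None:
        for s, m in self.mean.items():
            if m <= 0:
                raise ConfigurationError(f"mean SUV for {s!r} must be > 0")
            if self.sd.get(s, -1) < 0:
                raise ConfigurationError(f"SD for {s!r} must be >= 0")


@dataclass
class PhantomGeometry:
    """Analytic phantom geometry; all lengths in mm, isotropic voxels."""

    voxel_size: float = 2.0
    head_shape: tuple[int, int, int] = (128, 128, 128)
    torso_z: int = 80  # extra z slices prepended in PET/CT mode
    gm_outer_radius: float = 80.0
    wm_radius: float = 60.0
    ventricle_offset: tuple[float, float, float] = (16.0, 0.0, 5.0)
    ventricle_semiaxes: tuple[float, float, float] = (10.0, 30.0, 14.0)
    lesion_radius: float = 7.0
    #: candidate lesion centres, mm offsets from head centre (left hemisphere)
    lesion_sites: tuple[tuple[float, float, float], ...] = (
        (-34.0, 0.0, -6.0), (-30.0, 30.0, 10.0),
        (-32.0, -22.0, -12.0), (-22.0, 8.0, -28.0))
    liver_offset: tuple[float, float] = (35.0, 0.0)
    liver_semiaxes: tuple[float, float, float] = (45.0, 35.0, 30.0)
    aorta_offset: tuple[float, float] = (-40.0, 0.0)
    aorta_radius: float = 12.0
    psf_fwhm: float = 5.0
    noise_cv: float = 0.05

    @classmethod
    def coarse(cls) -> "PhantomGeometry":
        """3 mm / 64^3 variant for fast tests; same mm-scale anatomy."""
        return cls(voxel_size=3.0, head_shape=(64, 64, 64), torso_z=48)

    def validate(self) -> None:
        floor = 2.0 * self.voxel_size
        radii = {
            "wm_radius": self.wm_radius,
            "gm shell thickness": self.gm_outer_radius - self.wm_radius,
            "ventricle semiaxis": min(self.ventricle_semiaxes),
            "lesion_radius": self.lesion_radius,
            "liver semiaxis": min(self.liver_semiaxes),
            "aorta_radius": self.aorta_radius,
        }
        for name, r in radii.items():
            if r <= floor:
                raise GeometryError(
                    f"{name} = {r:.1f} mm must exceed 2 voxels ({floor:.1f} mm)")
        if self.psf_fwhm < 0 or self.noise_cv < 0:
            raise GeometryError("psf_fwhm and noise_cv must be >= 0")
        half_extent = min(self.head_shape[:2]) * self.voxel_size / 2.0
        if self.gm_outer_radius >= half_extent:
            raise GeometryError("head sphere does not fit inside the grid")


@dataclass
class PhantomResult:
    """A simulated scan plus the ground truth that produced it."""

    volume: PetVolume
    labels: LabelMap
    targets: dict[str, float]  # per-structure target SUVmax
    lesion_suv: float | None  # hottest-lesion target SUV (None if no lesion)


def draw_reference_panel(calibration: ReferenceCalibration | None = None,
                         rng: np.random.Generator | None = None,
                         structures: tuple[str, ...] = ("gm", "wm", "csf",
                                                        "liver", "mediastinum"),
                         ) -> dict[str, float]:
    """Draw per-structure target SUVmax from truncated normals (floor 0.1).

    Draws are independent across structures; no rejection or reordering is
    applied, so empirical means/SDs converge to the configured calibration.
    """
    cal = calibration or ReferenceCalibration()
    cal.validate()
    rng = rng if rng is not None else np.random.default_rng()
    out = {}
    for s in structures:
        m, sd = cal.mean[s], cal.sd[s]
        if sd == 0:
            out[s] = m
        else:
            a = (_TRUNC_LO - m) / sd
            out[s] = float(stats.truncnorm.rvs(a, np.inf, loc=m, scale=sd,
                                               random_state=rng))
    return out


def _ellipsoid(grids, center, semiaxes) -> np.ndarray:
    gx, gy, gz = grids
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


def build_label_map(geometry: PhantomGeometry, n_lesions: int,
                    include_torso: bool) -> LabelMap:
    """Construct the phantom segmentation; structures disjoint by build order."""
    geometry.validate()
    v = geometry.voxel_size
    nx, ny, nz_head = geometry.head_shape
    nz = nz_head + (geometry.torso_z if include_torso else 0)
    shape = (nx, ny, nz)
    axes = [np.arange(n) * v for n in shape]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    gx, gy, gz = grids

    torso_mm = geometry.torso_z * v if include_torso else 0.0
    head_center = (nx * v / 2.0, ny * v / 2.0, torso_mm + nz_head * v / 2.0)

    r2 = ((gx - head_center[0]) ** 2 + (gy - head_center[1]) ** 2
          + (gz - head_center[2]) ** 2)
    lab = np.zeros(shape, dtype=np.uint8)
    lab[r2 <= geometry.gm_outer_radius ** 2] = LABELS["gm"]
    wm_mask = r2 <= geometry.wm_radius ** 2
    lab[wm_mask] = LABELS["wm"]

    ox, oy, oz = geometry.ventricle_offset
    for sx in (-1.0, 1.0):
        c = (head_center[0] + sx * ox, head_center[1] + oy, head_center[2] + oz)
        vent = _ellipsoid(grids, c, geometry.ventricle_semiaxes)
        if not wm_mask[vent].all():
            raise GeometryError("ventricle extends outside the white-matter core")
        lab[vent] = LABELS["csf_ventricle"]

    names = dict(LABELS)
    if n_lesions > len(geometry.lesion_sites):
        raise GeometryError(
            f"{n_lesions} lesions requested but only "
            f"{len(geometry.lesion_sites)} candidate sites defined")
    for i in range(n_lesions):
        dxyz = geometry.lesion_sites[i]
        c = tuple(hc + d for hc, d in zip(head_center, dxyz))
        les = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
               <= geometry.lesion_radius ** 2)
        if not (lab[les] == LABELS["wm"]).all():
            raise GeometryError(
                f"lesion {i + 1} at offset {dxyz} does not fit inside "
                "lesion-free white matter")
        value = _LESION_BASE + i
        lab[les] = value
        names[f"lesion_{i + 1}"] = value

    if include_torso:
        t_center_z = torso_mm / 2.0
        lx, ly = geometry.liver_offset
        liver_c = (head_center[0] + lx, head_center[1] + ly, t_center_z)
        liver = _ellipsoid(grids, liver_c, geometry.liver_semiaxes)
        if (lab[liver] != 0).any():
            raise GeometryError("liver overlaps another structure")
        lab[liver] = LABELS["liver"]
        ax_, ay_ = geometry.aorta_offset
        ac = (head_center[0] + ax_, head_center[1] + ay_)
        aorta = (((gx - ac[0]) ** 2 + (gy - ac[1]) ** 2 <= geometry.aorta_radius ** 2)
                 & (gz < torso_mm - v) & (gz >= v))
        aorta = np.broadcast_to(aorta, shape)
        if (lab[aorta] != 0).any():
            raise GeometryError("aorta overlaps another structure")
        lab[aorta] = LABELS["mediastinum_aorta"]
    else:
        names = {k: v_ for k, v_ in names.items()
                 if k not in ("liver", "mediastinum_aorta")}

    return LabelMap(voxels=lab, labels=names)


def _lesion_band(true_ims: int, panel: dict[str, float], band: float,
                 rng: np.random.Generator) -> float:
    """Mid-band lesion target SUV for a true IMS level.

    Uptake is drawn away from the band edges (central 70%) so that simulated
    visual scores remain stable under the phantom's noise and blur.
    """
    wm, csf, gm = panel["wm"], panel["csf"], panel["gm"]
    lo_edge, hi_edge = (1 - band) * wm, (1 + band) * wm
    if not (csf < lo_edge < hi_edge < gm):
        raise ValidationError(
            "drawn reference panel cannot host the requested IMS band "
            f"(csf={csf:.3g}, wm={wm:.3g}, gm={gm:.3g}, band={band})")
    u = rng.uniform(0.15, 0.85)
    if true_ims == 2:
        return csf + u * (lo_edge - csf)
    if true_ims == 3:
        return lo_edge + u * (hi_edge - lo_edge)
    if true_ims == 4:
        return hi_edge + u * (gm - hi_edge)
    if true_ims == 5:
        return gm * rng.uniform(1.10, 1.50)
    raise ValidationError(f"no lesion band for IMS {true_ims}")


def simulate_phantom(record: PatientRecord,
                     geometry: PhantomGeometry | None = None,
                     calibration: ReferenceCalibration | None = None,
                     dose: float = 7.0,
                     weight: float = 70000.0,
                     seed: int = 0,
                     ims3_band: float = 0.10,
                     rng: np.random.Generator | None = None) -> PhantomResult:
    """Simulate one patient's end-of-therapy PET scan.

    PET/CT patients get the torso slab (liver + aorta); PET/MR patients a
    head-only volume.  Requires ``record.true_ims``; patients with IMS 1 and
    no new lesion carry no lesion label at all.  A panel whose draws cannot
    host the patient's IMS band (e.g. CSF reaching the white-matter band) is
    redrawn; the calibration itself is sampled without rejection in
    :func:`draw_reference_panel`.
    """
    if dose <= 0 or weight <= 0:
        raise ValidationError("dose and weight must be positive")
    if record.true_ims is None:
        raise ValidationError(f"patient {record.patient_id}: true_ims unset")
    geo = geometry or PhantomGeometry()
    include_torso = record.cohort == "PET_CT"
    if rng is None:
        from .rng import substream
        rng = substream(seed, "phantom", record.patient_id)

    structures = ("gm", "wm", "csf", "liver", "mediastinum") if include_torso \
        else ("gm", "wm", "csf")
    panel = draw_reference_panel(calibration, rng, structures)
    if record.true_ims >= 2:
        for _ in range(100):
            wm, csf, gm = panel["wm"], panel["csf"], panel["gm"]
            if csf < (1 - ims3_band) * wm and (1 + ims3_band) * wm < gm:
                break
            panel = draw_reference_panel(calibration, rng, structures)
        else:  # pragma: no cover - essentially impossible at default calibration
            raise ValidationError("could not draw a panel with valid scoring bands")

    n_lesions = record.n_lesions if record.true_ims >= 2 else 0
    labels = build_label_map(geo, n_lesions, include_torso)

    lesion_suv: float | None = None
    activity = np.zeros(labels.voxels.shape, dtype=np.float64)
    scale = dose / weight  # activity per unit SUV
    structure_to_label = {"gm": "gm", "wm": "wm", "csf": "csf_ventricle",
                          "liver": "liver", "mediastinum": "mediastinum_aorta"}
    for s, label_name in structure_to_label.items():
        if s in panel and label_name in labels.labels:
            activity[labels.voxels == labels.labels[label_name]] = panel[s] * scale

    if n_lesions > 0:
        lesion_suv = _lesion_band(record.true_ims, panel, ims3_band, rng)
        for i, name in enumerate(labels.lesion_names()):
            # hottest lesion carries the band value; others sit below it
            suv_i = lesion_suv if i == 0 else (
                panel["csf"] + rng.uniform(0.1, 0.9) * (lesion_suv - panel["csf"]))
            activity[labels.voxels == labels.labels[name]] = suv_i * scale

    if geo.noise_cv > 0:
        activity = activity * np.clip(
            rng.normal(1.0, geo.noise_cv, size=activity.shape), 0.0, None)
    if geo.psf_fwhm > 0:
        sigma_vox = geo.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / geo.voxel_size
        activity = ndimage.gaussian_filter(activity, sigma=sigma_vox)

    volume = PetVolume(voxels=activity.astype(np.float32),
                       voxel_size=(geo.voxel_size,) * 3,
                       injected_dose=dose, body_weight=weight,
                       modality=record.cohort)
    return PhantomResult(volume=volume, labels=labels,
                         targets=dict(panel), lesion_suv=lesion_suv)
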