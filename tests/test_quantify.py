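"""SUV arithmetic, ROI placement and SUVmax extraction."""

import numpy as np
import pytest

from imscore.cohort import PatientRecord
from imscore.errors import PlacementError, ValidationError
from imscore.phantom import simulate_phantom
from imscore.quantify import (LabelMap, PetVolume, RoiSpec, measure_lesions,
                              measure_reference_panel, place_roi, suv_field)


def _volume(activity, voxel=2.0, dose=7.0, weight=70000.0, modality="PET_CT"):
    return PetVolume(voxels=activity, voxel_size=(voxel,) * 3,
                     injected_dose=dose, body_weight=weight, modality=modality)


class TestSuvField:
    @pytest.mark.parametrize("act,weight,dose,expected", [
        (0.001, 70000.0, 7.0, 10.0),
        (0.0, 60000.0, 5.0, 0.0),
        (5.0e-4, 60000.0, 5.0, 6.0),
    ])
    def test_printed_formula_arithmetic(self, act, weight, dose, expected):
        vol = _volume(np.full((4, 4, 4), act), dose=dose, weight=weight)
        assert suv_field(vol) == pytest.approx(np.full((4, 4, 4), expected))

    @pytest.mark.parametrize("kw", [dict(dose=0.0), dict(dose=-1.0),
                                    dict(weight=0.0)])
    def test_nonpositive_dose_or_weight_rejected(self, kw):
        with pytest.raises(ValidationError):
            _volume(np.ones((2, 2, 2)), dose=kw.get("dose", 7.0),
                    weight=kw.get("weight", 70000.0))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValidationError):
            _volume(np.full((2, 2, 2), -0.1))


def _spherical_structure(radius_mm=30.0, voxel=2.0, n=40, label=4, name="liver"):
    ax = (np.arange(n) - (n - 1) / 2) * voxel
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = gx ** 2 + gy ** 2 + gz ** 2 <= radius_mm ** 2
    lab = np.where(mask, label, 0).astype(np.uint8)
    return LabelMap(voxels=lab, labels={"background": 0, name: label}), mask


class TestPlaceRoi:
    def test_sphere_in_symmetric_structure_centres_itself(self):
        labels, mask = _spherical_structure(radius_mm=30.0)
        roi = place_roi(labels, RoiSpec("sphere", "liver", diameter=30.0,
                                        min_diameter=30.0), (2.0,) * 3)
        assert roi.sum() > 0 and (labels.voxels[roi] == 4).all()
        com_roi = np.array(np.nonzero(roi)).mean(axis=1)
        com_struct = np.array(np.nonzero(mask)).mean(axis=1)
        assert np.allclose(com_roi, com_struct, atol=0.6)

    def test_structure_too_small_raises(self):
        labels, _ = _spherical_structure(radius_mm=5.0)
        with pytest.raises(PlacementError):
            place_roi(labels, RoiSpec("sphere", "liver", diameter=15.0,
                                      min_diameter=15.0), (2.0,) * 3)

    def test_absent_structure_raises(self):
        labels, _ = _spherical_structure()
        with pytest.raises(PlacementError):
            place_roi(labels, RoiSpec("sphere", "spleen"), (2.0,) * 3)

    def test_voxel_count_matches_enumeration_oracle(self):
        # independent oracle: lattice points (2i,2j,2k) with norm <= 5 mm
        # around the (voxel-centre) ROI centre; the continuum volume
        # (4/3)pi 5^3 / 8 mm^3 ~ 65 voxels underestimates the centre-in count
        offsets = np.arange(-3, 4)
        ii, jj, kk = np.meshgrid(offsets, offsets, offsets, indexing="ij")
        expected = int(((2 * ii) ** 2 + (2 * jj) ** 2 + (2 * kk) ** 2 <= 25).sum())
        labels, _ = _spherical_structure(radius_mm=25.0)
        roi = place_roi(labels, RoiSpec("sphere", "liver", diameter=10.0,
                                        min_diameter=10.0), (2.0,) * 3)
        assert roi.sum() == expected == 81

    def test_roi_contained_in_structure(self):
        labels, mask = _spherical_structure(radius_mm=20.0)
        roi = place_roi(labels, RoiSpec("sphere", "liver", diameter=16.0,
                                        min_diameter=10.0), (2.0,) * 3)
        assert (mask | ~roi).all()


def _phantom(true_ims=3, cohort="PET_CT", geometry=None, seed=5, **kw):
    rec = PatientRecord(patient_id=f"T-{true_ims}-{cohort}", age=60, sex="male",
                        ecog=1, kps=80, ldh_elevated=False,
                        csf_protein_elevated=False, deep_lesion=True,
                        n_lesions=kw.pop("n_lesions", 1), lesion_site="deep",
                        cohort=cohort, true_ims=true_ims,
                        new_lesion_flag=kw.pop("new_lesion_flag", False))
    return rec, simulate_phantom(rec, geometry, seed=seed, **kw)


class TestReferencePanel:
    def test_plateau_extraction_is_exact_without_noise(self, clean_geometry):
        _, res = _phantom(geometry=clean_geometry)
        panel = measure_reference_panel(res.volume, res.labels)
        for name, value in panel.as_dict().items():
            assert value == pytest.approx(res.targets[name], abs=1e-5)

    def test_petmr_panel_has_no_body_references(self, clean_geometry):
        _, res = _phantom(cohort="PET_MR", geometry=clean_geometry)
        panel = measure_reference_panel(res.volume, res.labels)
        assert panel.liver is None and panel.mediastinum is None
        assert panel.gm > 0 and panel.wm > 0 and panel.csf > 0

    def test_contralateral_hemisphere_rule(self, clean_geometry):
        # make ipsilateral (lesion-side, low-x) gray matter artificially hot;
        # the GM reading must come from the clean contralateral side
        _, res = _phantom(geometry=clean_geometry)
        act = res.volume.voxels.copy()
        gm = res.labels.voxels == res.labels.labels["gm"]
        nx = act.shape[0]
        hot = gm.copy()
        hot[nx // 2:] = False
        act[hot] *= 3.0
        vol = PetVolume(voxels=act, voxel_size=res.volume.voxel_size,
                        injected_dose=res.volume.injected_dose,
                        body_weight=res.volume.body_weight,
                        modality=res.volume.modality)
        panel = measure_reference_panel(vol, res.labels)
        assert panel.gm == pytest.approx(res.targets["gm"], abs=1e-5)

    def test_suvmax_scales_linearly_with_activity(self, clean_geometry):
        _, res = _phantom(geometry=clean_geometry)
        panel = measure_reference_panel(res.volume, res.labels)
        scaled = PetVolume(voxels=res.volume.voxels * 2.5,
                           voxel_size=res.volume.voxel_size,
                           injected_dose=res.volume.injected_dose,
                           body_weight=res.volume.body_weight,
                           modality=res.volume.modality)
        panel2 = measure_reference_panel(scaled, res.labels)
        for name, value in panel.as_dict().items():
            assert panel2.as_dict()[name] == pytest.approx(2.5 * value, rel=1e-6)

    def test_grid_mismatch_rejected(self, clean_geometry):
        _, res = _phantom(geometry=clean_geometry)
        small = PetVolume(voxels=np.zeros((4, 4, 4)), voxel_size=(2.0,) * 3,
                          injected_dose=7.0, body_weight=70000.0)
        with pytest.raises(ValidationError):
            measure_reference_panel(small, res.labels)


class TestMeasureLesions:
    def test_no_lesion_labels_gives_empty_list(self, clean_geometry):
        _, res = _phantom(true_ims=1, geometry=clean_geometry)
        assert measure_lesions(res.volume, res.labels) == []

    def test_plateau_lesion_suvmax_exact(self, clean_geometry):
        _, res = _phantom(true_ims=4, geometry=clean_geometry)
        lesions = measure_lesions(res.volume, res.labels)
        assert len(lesions) == 1
        assert lesions[0].suvmax == pytest.approx(res.lesion_suv, abs=1e-5)
        assert lesions[0].volume_ml > 0

    def test_hottest_of_multiple_lesions_drives_patient_maximum(self, clean_geometry):
        _, res = _phantom(true_ims=4, n_lesions=3, geometry=clean_geometry)
        lesions = measure_lesions(res.volume, res.labels)
        assert len(lesions) == 3
        assert max(m.suvmax for m in lesions) == pytest.approx(res.lesion_suv, abs=1e-5)
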