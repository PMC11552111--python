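"""IMS / Deauville assignment rules, grouping schemes and rater agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from imscore.errors import (ConfigurationError, ScoreInapplicableError,
                            ValidationError)
from imscore.quantify import LesionMeasurement, ReferencePanel
from imscore.scoring import (ScoringTolerances, assign_ds, assign_ims,
                             cohen_kappa, group_scores, score_patient)

PANEL_CT = ReferencePanel(gm=9.45, wm=2.81, csf=1.50, liver=2.96, mediastinum=1.80)
PANEL_MR = ReferencePanel(gm=9.45, wm=2.81, csf=1.50)


def _lesion(suv: float):
    return [LesionMeasurement("lesion_1", suv, 1.0)]


class TestAssignIms:
    def test_no_residual_uptake_is_level_1(self):
        assert assign_ims([], PANEL_CT) == 1

    @pytest.mark.parametrize("suv,expected", [
        (12.0, 5),     # strictly above gray matter
        (9.45, 4),     # equal to GM: ties resolve downward ("> GM" is strict)
        (2.0, 2),      # 1.5 < 2.0 < 0.9*2.81 = 2.529
        (2.81, 3),     # equal to WM: inside the similarity band
        (1.50, 1),     # at or below CSF reads as no residual uptake
    ])
    def test_band_assignment(self, suv, expected):
        assert assign_ims(_lesion(suv), PANEL_CT) == expected

    def test_new_lesion_forces_level_5(self):
        assert assign_ims([], PANEL_CT, new_lesion=True) == 5
        assert assign_ims(_lesion(0.2), PANEL_CT, new_lesion=True) == 5

    def test_missing_reference_is_an_error(self):
        broken = ReferencePanel(gm=9.45, wm=2.81, csf=None)  # type: ignore[arg-type]
        with pytest.raises(ValidationError):
            assign_ims(_lesion(2.0), broken)

    def test_degenerate_panel_rejected(self):
        # CSF reaches the lower WM band edge: bands cannot partition the axis
        bad = ReferencePanel(gm=9.45, wm=1.60, csf=1.55)
        with pytest.raises(ValidationError):
            assign_ims(_lesion(2.0), bad)

    def test_band_width_is_configurable(self):
        wide = ScoringTolerances(ims3_band=0.25)
        assert assign_ims(_lesion(2.2), PANEL_CT, tol=wide) == 3
        assert assign_ims(_lesion(2.2), PANEL_CT) == 2


class TestAssignDs:
    @pytest.mark.parametrize("suv,expected", [
        (6.5, 5),   # > 2 x liver (5.92)
        (4.0, 4),   # within (liver, 2 x liver]
        (1.7, 2),   # <= mediastinum but uptake present
        (2.5, 3),   # (mediastinum, liver]
    ])
    def test_band_assignment(self, suv, expected):
        assert assign_ds(_lesion(suv), PANEL_CT) == expected

    def test_no_residual_uptake_is_level_1(self):
        assert assign_ds([], PANEL_CT) == 1

    def test_new_lesion_forces_level_5(self):
        assert assign_ds(_lesion(0.5), PANEL_CT, new_lesion=True) == 5

    def test_head_only_panel_inapplicable(self):
        with pytest.raises(ScoreInapplicableError):
            assign_ds(_lesion(2.0), PANEL_MR)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    l1=st.floats(0.0, 20.0), l2=st.floats(0.0, 20.0),
    wm=st.floats(2.0, 4.0), gm=st.floats(6.0, 12.0),
    csf=st.floats(0.5, 1.7), liver=st.floats(2.2, 4.0),
    med=st.floats(1.2, 2.1),
)
def test_scores_monotone_in_lesion_uptake(l1, l2, wm, gm, csf, liver, med):
    """With a fixed panel, both scales are nondecreasing in lesion SUVmax."""
    panel = ReferencePanel(gm=gm, wm=wm, csf=csf, liver=liver, mediastinum=med)
    lo, hi = sorted((l1, l2))
    assert assign_ims(_lesion(lo), panel) <= assign_ims(_lesion(hi), panel)
    assert assign_ds(_lesion(lo), panel) <= assign_ds(_lesion(hi), panel)


def test_ims_bands_partition_the_axis():
    """Every nonnegative SUVmax maps to exactly one IMS level and each level's
    preimage is a contiguous interval covering [0, inf)."""
    grid = np.concatenate([np.linspace(0, 20, 4001),
                           [1.5, 2.529, 2.81, 3.091, 9.45]])  # band edges
    levels = np.array([assign_ims(_lesion(float(v)), PANEL_CT)
                       for v in np.sort(grid)])
    assert levels[0] == 1 and levels[-1] == 5
    assert ((np.diff(levels) == 0) | (np.diff(levels) == 1)).all()
    assert set(levels) == {1, 2, 3, 4, 5}


def test_cross_scale_sanity_at_default_references():
    # uptake at or below CSF (1.50) stays DS <= 2 since CSF < mediastinum (1.80)
    for suv in (0.3, 1.0, 1.50):
        assert assign_ims(_lesion(suv), PANEL_CT) == 1
        assert assign_ds(_lesion(suv), PANEL_CT) <= 2


class TestGrouping:
    @pytest.mark.parametrize("score,scheme,label", [
        (4, "1-3_vs_4-5", "4-5"),
        (4, "1-4_vs_5", "1-4"),
        (3, "1-2_3-4_5", "3-4"),
        (5, "1-2_3-4_5", "5"),
        (2, "five", "2"),
    ])
    def test_scheme_labels(self, score, scheme, label):
        assert group_scores(score, scheme) == label

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            group_scores(3, "1_vs_rest")

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            group_scores(6, "five")


class TestCohenKappa:
    def test_identical_raters(self):
        assert cohen_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_constant_identical_raters(self):
        assert cohen_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_hand_computed_values(self):
        # p_o = 0, p_e = 0.5 -> -1 ; p_o = 0.75, p_e = 0.5 -> 0.5
        assert cohen_kappa([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(-1.0)
        assert cohen_kappa([1, 2, 1, 2], [1, 2, 2, 2]) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cohen_kappa([1, 2], [1, 2, 3])

    def test_matches_sklearn_on_random_ratings(self, rng):
        a = rng.integers(1, 6, size=300)
        b = rng.integers(1, 6, size=300)
        assert cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)


def test_score_patient_combines_scales():
    res = score_patient(_lesion(4.0), PANEL_CT)
    assert (res.ims, res.ds) == (4, 4)
    assert res.groups["ims_1-3_vs_4-5"] == "4-5"
    res_mr = score_patient(_lesion(4.0), PANEL_MR)
    assert res_mr.ds is None and res_mr.ims == 4
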