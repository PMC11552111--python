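"""IMS and Deauville score assignment from SUVmax measurements.

The intracranial metabolic score (IMS) grades residual FDG uptake on
end-of-therapy brain PET against three intracranial references:

====  =======================================================
IMS   residual uptake
====  =======================================================
1     none
2     above CSF but below white matter
3     similar to white matter
4     above white matter but below or equal to gray matter
5     above gray matter, and/or any new lesion
====  =======================================================

"Similar to white matter" is a visual judgement; quantitatively we use a
symmetric relative band of +/-10% (configurable) around the white-matter
SUVmax.  The Deauville 5-point score (DS) uses the mediastinal blood pool and
liver instead, with DS 5 defined as lesion SUVmax exceeding twice the liver
SUVmax and/or a new lesion; it is inapplicable to head-only PET/MR, which
images neither reference.

Boundary ties resolve to the lower score (the level definitions use strict
"greater than"), and a patient's score is driven by the hottest lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ScoreInapplicableError, ValidationError
from .quantify import LesionMeasurement, ReferencePanel

__all__ = [
    "ScoringTolerances",
    "ScoreResult",
    "GROUPING_SCHEMES",
    "assign_ims",
    "assign_ds",
    "group_scores",
    "cohen_kappa",
    "score_patient",
]


@dataclass
class ScoringTolerances:
    """Quantitative stand-ins for the visual parts of the scales.

    ``ims3_band``: half-width, as a fraction of the white-matter SUVmax, of
    the "similar to white matter" band (IMS 3).
    """

    ims3_band: float = 0.10

    def validate(self) -> None:
        if not 0.0 <= self.ims3_band < 0.5:
            raise ConfigurationError(f"ims3_band must be in [0, 0.5), got {self.ims3_band!r}")


@dataclass
class ScoreResult:
    """Scores for one patient; ``ds`` is None when the panel lacks body references."""

    ims: int | None
    ds: int | None
    basis: str = "quantitative"
    groups: dict[str, str] = field(default_factory=dict)


def _max_lesion_suv(lesions: Sequence[LesionMeasurement]) -> float | None:
    if not lesions:
        return None
    return max(m.suvmax for m in lesions)


def assign_ims(lesions: Sequence[LesionMeasurement],
               panel: ReferencePanel,
               new_lesion: bool = False,
               tol: ScoringTolerances | None = None) -> int:
    """Assign the 5-level IMS from lesion measurements and a reference panel.

    The IMS 3 band is [(1-b)*WM, (1+b)*WM]; values strictly inside
    (CSF, (1-b)*WM) map to IMS 2, inside ((1+b)*WM, GM] to IMS 4, above GM to
    IMS 5.  A degenerate panel in which the CSF reference reaches the lower
    band edge cannot partition the axis and is rejected.
    """
    tol = tol or ScoringTolerances()
    tol.validate()
    for name in ("gm", "wm", "csf"):
        if getattr(panel, name, None) is None:
            raise ValidationError(f"reference panel lacks {name.upper()} SUVmax")
    gm, wm, csf = panel.gm, panel.wm, panel.csf
    lo, hi = (1 - tol.ims3_band) * wm, (1 + tol.ims3_band) * wm
    if csf >= lo:
        raise ValidationError(
            f"degenerate panel: CSF SUVmax {csf:.3g} reaches the lower IMS 3 "
            f"band edge {lo:.3g}; bands do not partition the axis")
    if new_lesion:
        return 5
    L = _max_lesion_suv(lesions)
    if L is None or L <= csf:
        return 1
    if L > gm:
        return 5
    if L > hi:
        return 4
    if L >= lo:
        return 3
    return 2


def assign_ds(lesions: Sequence[LesionMeasurement],
              panel: ReferencePanel,
              new_lesion: bool = False) -> int:
    """Assign the Deauville 5-point score (PET/CT panels only).

    DS 5: new lesion or SUVmax > 2x liver; DS 4: above liver; DS 3: above
    mediastinum but <= liver; DS 2: uptake present but <= mediastinum;
    DS 1: no residual uptake.
    """
    if panel.liver is None or panel.mediastinum is None:
        raise ScoreInapplicableError(
            "Deauville score inapplicable: panel lacks liver and/or mediastinal "
            "blood-pool references (head-only acquisition)")
    if new_lesion:
        return 5
    L = _max_lesion_suv(lesions)
    if L is None:
        return 1
    if L > 2.0 * panel.liver:
        return 5
    if L > panel.liver:
        return 4
    if L > panel.mediastinum:
        return 3
    return 2


#: Grouping schemes used in reporting; labels use an ASCII hyphen.
GROUPING_SCHEMES = ("five", "1-3_vs_4-5", "1-4_vs_5", "1-2_3-4_5")


def group_scores(score: int, scheme: str) -> str:
    """Map a 1-5 score onto a reporting group label for ``scheme``."""
    if not 1 <= int(score) <= 5:
        raise ValidationError(f"score {score!r} outside 1-5")
    s = int(score)
    if scheme == "five":
        return str(s)
    if scheme == "1-3_vs_4-5":
        return "1-3" if s <= 3 else "4-5"
    if scheme == "1-4_vs_5":
        return "1-4" if s <= 4 else "5"
    if scheme == "1-2_3-4_5":
        return "1-2" if s <= 2 else ("3-4" if s <= 4 else "5")
    raise ConfigurationError(f"unknown grouping scheme {scheme!r}")


def cohen_kappa(ratings_a: Sequence[int], ratings_b: Sequence[int]) -> float:
    """Unweighted Cohen's kappa between two raters on 1-5 categories.

    kappa = (p_o - p_e) / (1 - p_e).  If both raters are constant and
    identical (p_e = 1, p_o = 1) agreement is perfect and kappa is defined
    as 1.
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("ratings must be equal-length nonempty 1-D sequences")
    cats = np.arange(1, 6)
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        raise ValidationError("ratings must lie in 1-5")
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValidationError("kappa undefined: chance agreement is 1 but observed is not")
    return (p_o - p_e) / (1.0 - p_e)


def score_patient(lesions: Sequence[LesionMeasurement],
                  panel: ReferencePanel,
                  new_lesion: bool = False,
                  tol: ScoringTolerances | None = None,
                  schemes: Sequence[str] = ("1-3_vs_4-5", "1-4_vs_5")) -> ScoreResult:
    """Assign IMS and (when the panel allows) DS, plus grouping labels."""
    ims = assign_ims(lesions, panel, new_lesion=new_lesion, tol=tol)
    try:
        ds: int | None = assign_ds(lesions, panel, new_lesion=new_lesion)
    except ScoreInapplicableError:
        ds = None
    groups = {f"ims_{sch}": group_scores(ims, sch) for sch in schemes}
    if ds is not None:
        groups.update({f"ds_{sch}": group_scores(ds, sch) for sch in schemes})
    return ScoreResult(ims=ims, ds=ds, groups=groups)
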