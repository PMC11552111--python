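"""Synthetic PCNSL cohort generation.

Primary CNS lymphoma (PCNSL) response studies are small and their
patient-level data are not public, so every downstream stage of this package
is exercised on synthetic cohorts whose statistical structure matches what the
analysis assumes:

* covariates with configurable marginal prevalences (age, sex, ECOG, KPS,
  LDH, CSF protein, lesion number and site);
* the two standard clinical prognostic indices, IELSG (5 risk factors) and
  MSKCC (age/KPS recursive partitioning into classes 0/1/2);
* a "true" 5-level intracranial metabolic score (IMS) per patient, drawn from
  a configurable distribution;
* proportional-hazards progression-free and overall survival with
  score-dependent hazard ratios, independent exponential dropout and
  administrative censoring.

All draws come from per-patient substreams of one master seed
(:mod:`imscore.rng`), so cohorts are bit-reproducible and extending a cohort
does not perturb existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError
from .rng import substream

__all__ = [
    "PatientRecord",
    "CovariatePrevalences",
    "HazardConfig",
    "IELSG_THRESHOLDS",
    "PETCT_IMS_DISTRIBUTION",
    "PETMR_IMS_DISTRIBUTION",
    "simulate_covariates",
    "compute_ielsg",
    "compute_mskcc",
    "simulate_true_scores",
    "simulate_outcomes",
    "simulate_second_reader",
    "records_to_dataframe",
]

#: Empirical IMS distributions used as simulation defaults: 8/9/11/5/5 of 38
#: for an end-of-therapy PET/CT cohort and 10/9/12/9/5 of 45 for PET/MR.
PETCT_IMS_DISTRIBUTION: tuple[float, ...] = (8 / 38, 9 / 38, 11 / 38, 5 / 38, 5 / 38)
PETMR_IMS_DISTRIBUTION: tuple[float, ...] = (10 / 45, 9 / 45, 12 / 45, 9 / 45, 5 / 45)

#: IELSG risk-factor cutoffs: age > 60 years, ECOG > 1; LDH / CSF protein are
#: carried as already-dichotomised flags.
IELSG_THRESHOLDS: dict[str, float] = {"age": 60, "ecog": 1}


@dataclass
class PatientRecord:
    """One synthetic patient; outcome fields stay ``None`` until simulated."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    ecog: int  # 0-4
    kps: int  # 0-100, multiple of 10
    ldh_elevated: bool
    csf_protein_elevated: bool
    deep_lesion: bool
    n_lesions: int
    lesion_site: str  # "superficial" | "deep" | "both"
    cohort: str  # "PET_CT" | "PET_MR"
    true_ims: int | None = None
    new_lesion_flag: bool = False
    pfs_time: float | None = None
    pfs_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None


@dataclass
class CovariatePrevalences:
    """Marginal probabilities for covariate simulation.

    Defaults approximate a mixed PCNSL cohort: median age near 60 with an
    interquartile span of roughly 15 years, slight male excess, about half
    the patients with ECOG 2-3, and lesion-site mix of roughly one third
    superficial / one third deep / one third both.
    """

    p_male: float = 0.53
    age_mean: float = 59.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 85.0
    #: P(ECOG = k) for k = 0..4
    ecog_probs: tuple[float, ...] = (0.20, 0.30, 0.30, 0.15, 0.05)
    p_ldh_elevated: float = 0.35
    p_csf_protein_elevated: float = 0.45
    #: P(site = superficial, deep, both)
    site_probs: tuple[float, ...] = (0.33, 0.30, 0.37)
    p_multiple_lesions: float = 0.58
    max_lesions: int = 4

    def validate(self) -> None:
        probs = [self.p_male, self.p_ldh_elevated, self.p_csf_protein_elevated,
                 self.p_multiple_lesions, *self.ecog_probs, *self.site_probs]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p!r} outside [0, 1]")
        for name, ps in (("ecog_probs", self.ecog_probs), ("site_probs", self.site_probs)):
            if abs(sum(ps) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1, got {sum(ps)!r}")
        if self.age_sd <= 0 or self.age_min >= self.age_max:
            raise ConfigurationError("invalid age distribution parameters")


@dataclass
class HazardConfig:
    """Exponential proportional-hazards outcome model.

    ``baseline_hazard`` is the daily progression hazard for IMS 1-3 patients
    (default ln 2 / 900: median PFS around 30 months in good responders).
    ``log_hr_ims45`` is the log hazard ratio of IMS 4-5 versus 1-3 (default
    log 9.04); ``log_hr_ims5_extra`` adds on top for IMS 5.  Dropout is an
    independent exponential clock truncated at the administrative horizon.
    Overall survival for progressors is PFS plus an exponential
    post-progression survival draw (rate ``post_progression_rate``), which
    enforces os_time >= pfs_time by construction.
    """

    baseline_hazard: float = float(np.log(2) / 900.0)
    log_hr_ims45: float = float(np.log(9.04))
    log_hr_ims5_extra: float = float(np.log(9.50 / 9.04))
    censor_rate: float = 1.0 / 2500.0
    admin_horizon: float = 2000.0
    post_progression_rate: float = float(np.log(2) / 240.0)

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.admin_horizon <= 0:
            raise ConfigurationError("admin_horizon must be > 0")
        if self.censor_rate < 0 or self.post_progression_rate <= 0:
            raise ConfigurationError("rates must be positive")


def _require(record: PatientRecord, *fields_: str) -> None:
    for name in fields_:
        if getattr(record, name, None) is None:
            raise MissingDataError(
                f"patient {record.patient_id}: required covariate {name!r} is missing"
            )


def compute_ielsg(record: PatientRecord,
                  thresholds: dict[str, float] = IELSG_THRESHOLDS) -> tuple[int, str]:
    """IELSG prognostic score: count of 5 risk factors, grouped 0-1 vs 2-3.

    Factors: age > 60 years, ECOG > 1, elevated LDH, elevated CSF protein,
    deep brain lesion.  Scores of 2 or more (including the rare 4-5) fall in
    the high-risk group label "2-3".
    """
    _require(record, "age", "ecog", "ldh_elevated", "csf_protein_elevated", "deep_lesion")
    score = sum([
        record.age > thresholds.get("age", 60),
        record.ecog > thresholds.get("ecog", 1),
        bool(record.ldh_elevated),
        bool(record.csf_protein_elevated),
        bool(record.deep_lesion),
    ])
    return score, ("0-1" if score <= 1 else "2-3")


def compute_mskcc(record: PatientRecord) -> int:
    """MSKCC recursive-partitioning class from age and Karnofsky score.

    Class 0: age <= 50; class 1: age > 50 and KPS >= 70; class 2: age > 50
    and KPS < 70.
    """
    _require(record, "age", "kps")
    if record.age <= 50:
        return 0
    return 1 if record.kps >= 70 else 2


def simulate_covariates(n: int,
                        prevalences: CovariatePrevalences | None = None,
                        seed: int = 0,
                        cohort: str = "PET_CT") -> list[PatientRecord]:
    """Draw ``n`` patients' covariates (outcomes and scores left unset)."""
    if n < 1:
        raise ConfigurationError(f"cohort size must be >= 1, got {n}")
    if cohort not in ("PET_CT", "PET_MR"):
        raise ConfigurationError(f"unknown cohort {cohort!r}")
    prev = prevalences or CovariatePrevalences()
    prev.validate()

    records: list[PatientRecord] = []
    for i in range(n):
        pid = f"{cohort}-{i:04d}"
        rng = substream(seed, "covariates", pid)
        age = float(np.clip(rng.normal(prev.age_mean, prev.age_sd), prev.age_min, prev.age_max))
        ecog = int(rng.choice(len(prev.ecog_probs), p=prev.ecog_probs))
        # KPS loosely anti-correlated with ECOG, snapped to multiples of 10.
        kps = int(np.clip(round((100 - 15 * ecog + rng.normal(0, 8)) / 10) * 10, 10, 100))
        site = str(rng.choice(["superficial", "deep", "both"], p=prev.site_probs))
        multiple = bool(rng.random() < prev.p_multiple_lesions)
        n_lesions = int(rng.integers(2, prev.max_lesions + 1)) if multiple else 1
        records.append(PatientRecord(
            patient_id=pid,
            age=age,
            sex="male" if rng.random() < prev.p_male else "female",
            ecog=ecog,
            kps=kps,
            ldh_elevated=bool(rng.random() < prev.p_ldh_elevated),
            csf_protein_elevated=bool(rng.random() < prev.p_csf_protein_elevated),
            deep_lesion=site in ("deep", "both"),
            n_lesions=n_lesions,
            lesion_site=site,
            cohort=cohort,
        ))
    return records


def simulate_true_scores(records: Sequence[PatientRecord],
                         score_distribution: Sequence[float] | None = None,
                         seed: int = 0,
                         p_new_lesion_given_ims5: float = 0.3) -> list[PatientRecord]:
    """Assign each patient a true IMS level 1-5 from ``score_distribution``.

    IMS 1 means complete metabolic response: the lesion count is reset to
    zero.  A minority of IMS 5 patients carry a new-lesion flag, which forces
    the top score regardless of residual-uptake intensity.
    """
    dist = tuple(score_distribution) if score_distribution is not None else PETCT_IMS_DISTRIBUTION
    if len(dist) != 5:
        raise ConfigurationError(f"score distribution needs 5 probabilities, got {len(dist)}")
    if any(p < 0 for p in dist):
        raise ConfigurationError("score probabilities must be nonnegative")
    if abs(sum(dist) - 1.0) > 1e-9:
        raise ConfigurationError(f"score probabilities must sum to 1, got {sum(dist)!r}")

    out = []
    for rec in records:
        rng = substream(seed, "true_score", rec.patient_id)
        ims = int(rng.choice(5, p=dist)) + 1
        new_lesion = bool(ims == 5 and rng.random() < p_new_lesion_given_ims5)
        n_lesions = 0 if ims == 1 else max(rec.n_lesions, 1)
        out.append(replace(rec, true_ims=ims, new_lesion_flag=new_lesion,
                           n_lesions=n_lesions))
    return out


def simulate_outcomes(records: Sequence[PatientRecord],
                      hazard: HazardConfig | None = None,
                      seed: int = 0) -> list[PatientRecord]:
    """Attach PFS and OS (time, event) to each record.

    Progression time is exponential with hazard
    ``baseline * exp(log_hr_ims45 * [IMS>=4] + log_hr_ims5_extra * [IMS=5])``.
    The censoring clock is min(exponential dropout, administrative horizon)
    and is shared between endpoints, so a patient censored for PFS is censored
    for OS at the same time.  Progressors die an exponential post-progression
    interval later, observed only if it precedes censoring.
    """
    hz = hazard or HazardConfig()
    hz.validate()
    out = []
    for rec in records:
        if rec.true_ims is None:
            raise MissingDataError(f"patient {rec.patient_id}: true_ims unset")
        rng = substream(seed, "outcome", rec.patient_id)
        log_hr = (hz.log_hr_ims45 * (rec.true_ims >= 4)
                  + hz.log_hr_ims5_extra * (rec.true_ims == 5))
        rate = hz.baseline_hazard * float(np.exp(log_hr))
        t_prog = rng.exponential(1.0 / rate)
        t_drop = rng.exponential(1.0 / hz.censor_rate) if hz.censor_rate > 0 else np.inf
        t_cens = min(t_drop, hz.admin_horizon)
        pfs_event = t_prog <= t_cens
        pfs_time = min(t_prog, t_cens)
        if pfs_event:
            t_death = t_prog + rng.exponential(1.0 / hz.post_progression_rate)
            os_event = t_death <= t_cens
            os_time = min(t_death, t_cens)
        else:
            os_event = False
            os_time = t_cens
        out.append(replace(rec,
                           pfs_time=float(max(pfs_time, 1e-9)),
                           pfs_event=bool(pfs_event),
                           os_time=float(max(os_time, 1e-9)),
                           os_event=bool(os_event)))
    return out


def simulate_second_reader(scores: Sequence[int], agreement: float = 0.95,
                           seed: int = 0) -> list[int]:
    """Emulate a second blinded reader.

    Each score is kept with probability ``agreement``; otherwise it moves one
    level up or down (equiprobably), clamped to the 1-5 range.
    """
    if not 0.0 <= agreement <= 1.0:
        raise ConfigurationError(f"agreement must be in [0, 1], got {agreement!r}")
    rng = substream(seed, "second_reader")
    out = []
    for s in scores:
        if not 1 <= int(s) <= 5:
            raise ConfigurationError(f"score {s!r} outside 1-5")
        if rng.random() < agreement:
            out.append(int(s))
        else:
            delta = int(rng.choice([-1, 1]))
            out.append(int(np.clip(int(s) + delta, 1, 5)))
    return out


_COLUMNS = [
    "patient_id", "age", "sex", "ecog", "kps", "ldh_elevated",
    "csf_protein_elevated", "deep_lesion", "n_lesions", "lesion_site",
    "cohort", "true_ims", "new_lesion_flag", "pfs_time", "pfs_event",
    "os_time", "os_event",
]


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient; column order is the documented cohort-CSV schema."""
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])
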