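"""End-to-end orchestration: simulate -> quantify -> score -> analyze.

``run_pipeline`` executes the full chain on one synthetic cohort and writes
its outputs (cohort CSV, scored CSV, JSON report) under the configured output
directory.  Given the same config and seed the outputs are byte-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (HazardConfig, PETCT_IMS_DISTRIBUTION, PETMR_IMS_DISTRIBUTION,
                     compute_ielsg, compute_mskcc, records_to_dataframe,
                     simulate_covariates, simulate_outcomes, simulate_second_reader,
                     simulate_true_scores)
from .config import PipelineConfig
from .cox import cox_fit
from .diagnostics import contingency_from_labels, diagnostic_metrics, ordinal_roc_auc
from .errors import ImscoreError
from .io import write_cohort_csv
from .phantom import simulate_phantom
from .quantify import measure_lesions, measure_reference_panel
from .scoring import GROUPING_SCHEMES, cohen_kappa, group_scores, score_patient
from .survival import km_table, logrank_test

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    seed: int
    version: str
    mode: str
    n_patients: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    parameters: dict[str, Any] = field(default_factory=dict)
    kappa: dict[str, float] = field(default_factory=dict)
    survival: dict[str, Any] = field(default_factory=dict)
    cox: dict[str, Any] = field(default_factory=dict)
    diagnostics: dict[str, Any] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serialisable: {type(o)}")
        return json.dumps(asdict(self), indent=2, default=_default)


def _stage(name: str, patient_id: str | None = None):
    """Context tag for stage errors."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                who = f" (patient {patient_id})" if patient_id else ""
                raise ImscoreError(f"stage {name!r}{who}: {exc}") from exc
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__, mode=config.mode,
                       n_patients=config.n_patients,
                       parameters=config.model_dump())

    dist = (tuple(config.score_distribution) if config.score_distribution
            else (PETCT_IMS_DISTRIBUTION if config.mode == "PET_CT"
                  else PETMR_IMS_DISTRIBUTION))

    with _stage("simulate_cohort"):
        records = simulate_covariates(config.n_patients, seed=config.seed,
                                      cohort=config.mode)
        records = simulate_true_scores(records, dist, seed=config.seed)
        records = simulate_outcomes(records, config.hazard.build(), seed=config.seed)
    report.stage_counts["simulated"] = len(records)

    df = records_to_dataframe(records)
    df["ielsg"], df["ielsg_group"] = zip(*(compute_ielsg(r) for r in records))
    df["mskcc"] = [compute_mskcc(r) for r in records]

    tol = config.tolerances()
    if config.simulate_volumes:
        geometry = config.geometry.build()
        calibration = config.calibration.build()
        panel_rows, ims_q, ds_q = [], [], []
        for rec in records:
            with _stage("phantom_quantify_score", rec.patient_id):
                res = simulate_phantom(rec, geometry, calibration,
                                       dose=config.dose_mci, weight=config.weight_g,
                                       seed=config.seed, ims3_band=tol.ims3_band)
                panel = measure_reference_panel(res.volume, res.labels)
                lesions = measure_lesions(res.volume, res.labels)
                score = score_patient(lesions, panel, new_lesion=rec.new_lesion_flag,
                                      tol=tol)
                row = {f"suv_{k}": v for k, v in panel.as_dict().items()}
                row["suv_lesion_max"] = (max((m.suvmax for m in lesions), default=None))
                row["n_lesions_measured"] = len(lesions)
                panel_rows.append(row)
                ims_q.append(score.ims)
                ds_q.append(score.ds)
        df = pd.concat([df, pd.DataFrame(panel_rows)], axis=1)
        df["ims_reader1"] = ims_q
        if config.mode == "PET_CT":
            df["ds_reader1"] = ds_q
        report.stage_counts["quantified"] = len(panel_rows)
    else:
        # visual-simulation basis: reader 1 reads the true score
        df["ims_reader1"] = df["true_ims"]
        if config.mode == "PET_CT":
            df["ds_reader1"] = df["true_ims"]  # placeholder scale alignment

    with _stage("second_reader"):
        df["ims_reader2"] = simulate_second_reader(
            df["ims_reader1"].tolist(), config.reader_agreement, seed=config.seed)
        report.kappa["ims"] = cohen_kappa(df["ims_reader1"], df["ims_reader2"])
        if "ds_reader1" in df:
            df["ds_reader2"] = simulate_second_reader(
                df["ds_reader1"].tolist(), config.reader_agreement,
                seed=config.seed + 1)
            report.kappa["ds"] = cohen_kappa(df["ds_reader1"], df["ds_reader2"])

    for scheme in GROUPING_SCHEMES:
        df[f"ims_group_{scheme}"] = [group_scores(s, scheme) for s in df["ims_reader1"]]

    with _stage("analyze"):
        for endpoint, tcol, ecol in (("PFS", "pfs_time", "pfs_event"),
                                     ("OS", "os_time", "os_event")):
            ep: dict[str, Any] = {}
            for scheme in GROUPING_SCHEMES:
                gcol = f"ims_group_{scheme}"
                ep[scheme] = {"km": km_table(df, tcol, ecol, gcol).to_dict("records")}
                if df[gcol].nunique() >= 2:
                    lr = logrank_test(df[tcol], df[ecol], df[gcol])
                    ep[scheme]["logrank"] = {"chi2": lr.chi2, "df": lr.df, "p": lr.p}
            report.survival[endpoint] = ep

            x = (df["ims_reader1"] >= 4).astype(float).to_numpy()
            if df[ecol].sum() >= 1 and np.ptp(x) > 0:
                fit = cox_fit(df[tcol].to_numpy(), df[ecol].to_numpy(), x,
                              names=["ims_4-5_vs_1-3"])
                eff = fit.effect("ims_4-5_vs_1-3")
                report.cox[endpoint] = {
                    "hr": eff.hr if fit.converged else None,
                    "ci": [eff.ci_low, eff.ci_high] if fit.converged else None,
                    "p": eff.p if fit.converged else None,
                    "converged": fit.converged, "message": fit.message}
            else:
                report.cox[endpoint] = {"hr": None, "converged": False,
                                        "message": "insufficient events or constant group"}

            diag: dict[str, Any] = {}
            for rule, positive in (("ims_4-5", df["ims_reader1"] >= 4),
                                   ("ims_5", df["ims_reader1"] == 5)):
                outcome = df[ecol].astype(bool)
                if outcome.any() and not outcome.all():
                    table = contingency_from_labels(positive, outcome)
                    diag[rule] = diagnostic_metrics(table).rounded()
                    diag[rule]["table"] = [table.tp, table.fp, table.fn, table.tn]
            if df[ecol].astype(bool).nunique() == 2 and df["ims_reader1"].nunique() > 1:
                auc, ci = ordinal_roc_auc(df["ims_reader1"], df[ecol].astype(bool))
                diag["ordinal_auc"] = {"auc": auc, "ci": list(ci)}
            report.diagnostics[endpoint] = diag

    with _stage("write_outputs"):
        cohort_path = write_cohort_csv(df, out_dir / "cohort_scored.csv")
        report.outputs.append(str(cohort_path))
        report_path = out_dir / "report.json"
        report_path.write_text(report.to_json())
        report.outputs.append(str(report_path))

    return report
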