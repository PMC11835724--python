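"""Pipeline orchestration, run manifests and publication-style tables.

``run_pipeline`` executes step I (train the prognostic model zoo, evaluate
horizon AUC on the held-out test set, select the top family) followed by
step II (emulate the configured trials within prognostic phenotypes) and
writes a consolidated, reproducible artifact set. Every artifact directory
carries a manifest (command, config hash, seeds, package version, paths,
timestamp) so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, PatientTable, generate_base_cohort
from .emulation import EmulationResult, TrialSpec, emulate_trial, example_trial_spec
from .features import build_feature_matrix, split_train_test
from .models import HORIZON_BY_PRESET, ModelSpec, tune_and_fit
from .tdauc import td_auc
from .utils import child_seed, config_hash

log = logging.getLogger("rwemu")


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    package_version: str = __version__
    inputs: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


DEFAULT_PIPELINE_CONFIG = {
    "cohort": {"n_patients": 2000, "cancer_preset": "aNSCLC-like", "seed": 0},
    "families": ["gbm", "pcox_ridge", "cox_benchmark"],
    "trials": None,          # None -> the preset's example trial
    "emulation_mode": "key",
    "bootstrap_reps": 200,
    "seed": 0,
}


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Step I + step II end to end on a (synthetic) cohort.

    Model selection picks the family with the highest test-set AUC at the
    cancer-specific horizon; that model's risk scores drive phenotyping in
    every emulated trial. Returns a dict with the selected model, the
    model-comparison table and per-trial results; artifacts land in
    ``out_dir``.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    stage_seeds = {s: child_seed(seed, s) for s in
                   ("cohort", "split", "train", "emulate")}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        cohort_cfg = CohortConfig(**{**cfg["cohort"], "seed": stage_seeds["cohort"]})
        cohort = generate_base_cohort(cohort_cfg)
        log.info("cohort generated: n=%d preset=%s", len(cohort), cohort_cfg.cancer_preset)
    except Exception as err:
        raise RuntimeError(f"stage 'cohort' failed: {err}") from err

    try:
        matrix = build_feature_matrix(cohort)
        split = split_train_test(matrix, 0.8, "year_of_dx", stage_seeds["split"])
        train_m = matrix.loc[matrix["patient_id"].isin(split.train_ids)]
        test_m = matrix.loc[matrix["patient_id"].isin(split.test_ids)]
    except Exception as err:
        raise RuntimeError(f"stage 'features' failed: {err}") from err

    horizon = HORIZON_BY_PRESET[cohort_cfg.cancer_preset]
    comparison = []
    fitted = {}
    for fam in cfg["families"]:
        try:
            spec = ModelSpec.for_preset(fam, cohort_cfg.cancer_preset, seed=stage_seeds["train"])
            model = tune_and_fit(train_m, spec)
            scores = model.predict_risk(test_m)
            auc = td_auc(test_m["time"].to_numpy(), test_m["event"].to_numpy(), scores, horizon)
            fitted[fam] = model
            comparison.append({"family": fam, "test_auc": auc,
                               "mean_cv_auc": float(np.mean(model.fold_aucs))})
            log.info("model %s: test horizon AUC %.3f", fam, auc)
        except Exception as err:
            raise RuntimeError(f"stage 'train:{fam}' failed: {err}") from err
    comparison = pd.DataFrame(comparison).sort_values("test_auc", ascending=False)
    top_family = comparison.iloc[0]["family"]
    top_model = fitted[top_family]
    comparison.to_csv(out_dir / "model_comparison.csv", index=False)

    all_scores = pd.Series(
        top_model.predict_risk(matrix), index=pd.Index(matrix["patient_id"]), name="risk_score"
    )

    trials = cfg["trials"] or [example_trial_spec(cohort_cfg.cancer_preset)]
    trials = [t if isinstance(t, TrialSpec) else TrialSpec.from_dict(t) for t in trials]
    results = {}
    for trial in trials:
        try:
            res = emulate_trial(
                cohort, trial, all_scores, mode=cfg["emulation_mode"],
                reps=cfg["bootstrap_reps"], seed=stage_seeds["emulate"],
            )
        except Exception as err:
            raise RuntimeError(f"stage 'emulate:{trial.trial_id}' failed: {err}") from err
        results[trial.trial_id] = res
        render_report(res, out_dir / trial.trial_id)

    manifest = RunManifest(
        command="run_pipeline",
        config_hash=config_hash({k: v for k, v in cfg.items() if k != "trials"}),
        seed=seed,
        stage_seeds=stage_seeds,
        inputs={"preset": cohort_cfg.cancer_preset, "n_patients": cohort_cfg.n_patients},
        outputs=[str(p) for p in sorted(out_dir.rglob("*.csv"))],
    )
    manifest.save(out_dir / "manifest.json")
    return {
        "selected_family": top_family,
        "model_comparison": comparison,
        "model": top_model,
        "emulations": results,
        "manifest": manifest,
    }


def _fmt_months(x: float) -> str:
    return "not reached" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.1f}"


def render_report(result: EmulationResult, out_dir: str | Path) -> pd.DataFrame:
    """Tidy CSVs plus a human-readable summary for one emulated trial.

    The headline table mirrors the per-phenotype layout: treatment/control
    median survival with CIs, the between-arm difference ("Δ Arms" =
    treatment − control median), RMST difference, and the HR with its
    robust-variance CI. Medians never reached are rendered explicitly.
    Missing strata produce rows of missing markers, never a crash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy = result.estimates_frame()
    tidy.to_csv(out_dir / "estimates.csv", index=False)

    lines = [f"Emulated trial {result.trial_id} (mode={result.mode}, tau={result.tau:.1f} mo)"]
    rows = []
    for stratum in ("full", "low", "medium", "high"):
        res = result.strata.get(stratum, {})
        if res.get("skipped", True):
            rows.append({"stratum": stratum, "mos_treatment": np.nan})
            lines.append(f"  {stratum:>7}: insufficient patients")
            continue
        p, ci = res["effects"]["point"], res["effects"]["ci"]
        hr = res["hr"]
        rows.append({
            "stratum": stratum,
            "n_treatment": res["n_treatment"], "n_control": res["n_control"],
            "mos_treatment": p["mos_treatment"], "mos_control": p["mos_control"],
            "delta_arms": p["mos_difference"],
            "rmst_difference": p["rmst_difference"],
            "rmst_difference_lo": ci["rmst_difference"][0],
            "rmst_difference_hi": ci["rmst_difference"][1],
            "hr": hr["hr"], "hr_lo": hr["ci"][0], "hr_hi": hr["ci"][1],
        })
        lines.append(
            f"  {stratum:>7}: mOS {_fmt_months(p['mos_treatment'])} vs "
            f"{_fmt_months(p['mos_control'])} mo (Δ Arms {_fmt_months(p['mos_difference'])}), "
            f"ΔRMST {p['rmst_difference']:.1f} "
            f"({ci['rmst_difference'][0]:.1f}–{ci['rmst_difference'][1]:.1f}), "
            f"HR {hr['hr']:.2f} ({hr['ci'][0]:.2f}–{hr['ci'][1]:.2f})"
        )
        res["balance"].to_csv(out_dir / f"smd_{stratum}.csv", index=False)
        for arm, km in res["km"].items():
            km.to_csv(out_dir / f"km_{stratum}_{arm}.csv", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    ag = result.agreement
    lines.append(
        f"  agreement vs benchmark: significance={ag['significance']} "
        f"ci_overlap={ag['ci_overlap']} std_diff={ag['standardized_difference']:.2f}"
    )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
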