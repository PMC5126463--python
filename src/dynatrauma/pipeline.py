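"""End-to-end pipeline: exclusions -> stratification -> clinical report ->
trajectories -> DyNA, with a hashed output manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import cohort, dyna, readwrite, stratify, trajectories

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

#: Table-1-style comparison rows: (variable, test)
_REPORT_NUMERIC = ["age", "iss", "gcs", "icu_los", "hosp_los", "vent_days",
                   "sbp_admission", "hr_admission", "bd_admission"]
_REPORT_BINARY = ["transfused_24h", "surgery_24h"]


class PipelineError(RuntimeError):
    """Raised with the failing stage name when any stage aborts."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _clinical_report(patients: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per stratum with the appropriate two-group test."""
    rows = []
    g1 = patients[patients["group"] == "BD_GE4"]
    g0 = patients[patients["group"] == "BD_LT4"]
    summ = stratify.summarize_groups(patients, _REPORT_NUMERIC)
    for var in _REPORT_NUMERIC:
        u, p = stratify.mann_whitney_u(g0[var], g1[var])
        sub = summ[summ["variable"] == var].set_index("group")
        rows.append({
            "variable": var, "test": "mann_whitney",
            "n_BD_LT4": int(sub.loc["BD_LT4", "n"]),
            "mean_BD_LT4": sub.loc["BD_LT4", "mean"],
            "sem_BD_LT4": sub.loc["BD_LT4", "sem"],
            "n_BD_GE4": int(sub.loc["BD_GE4", "n"]),
            "mean_BD_GE4": sub.loc["BD_GE4", "mean"],
            "sem_BD_GE4": sub.loc["BD_GE4", "sem"],
            "statistic": u, "p": p,
        })
    for var in _REPORT_BINARY:
        a = int(g1[var].sum()); b = len(g1) - a
        c = int(g0[var].sum()); d = len(g0) - c
        tab = stratify.ContingencyTable2x2(a, b, c, d)
        chi2, p = tab.chi_square()
        rr = tab.relative_risk()
        rows.append({
            "variable": var, "test": "chi_square+rr",
            "n_BD_LT4": len(g0), "mean_BD_LT4": tab.risk_unexposed,
            "sem_BD_LT4": float("nan"),
            "n_BD_GE4": len(g1), "mean_BD_GE4": tab.risk_exposed,
            "sem_BD_GE4": float("nan"),
            "statistic": chi2, "p": p,
            "rr": rr.rr, "rr_ci_low": rr.ci_low, "rr_ci_high": rr.ci_high,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: readwrite.RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    In simulate mode the cohort is generated from ``config.simulation``
    (default study conditions when absent); otherwise the patient and
    measurement CSVs referenced by the config are loaded. All outputs are
    written under ``config.out_dir`` together with ``manifest.json``
    recording settings, seed and content hashes; identical config + seed
    give identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format=readwrite.FLOAT_FORMAT)
        written.append(p)
        return p

    # -- load or simulate ---------------------------------------------------
    try:
        if config.simulate:
            sim = config.simulation or cohort.default_config(seed=config.seed)
            if config.simulation is None:
                sim = dataclasses.replace(sim, seed=config.seed)
            patients, samples = cohort.generate_cohort(sim)
            readwrite.write_patients(patients, out / "patients.csv")
            readwrite.write_measurements(samples, out / "measurements.csv")
            written += [out / "patients.csv", out / "measurements.csv"]
        else:
            patients = readwrite.read_patients(config.patients_path)
            samples = readwrite.read_measurements(config.measurements_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", e) from e

    # -- exclusions + stratification ---------------------------------------
    try:
        retained, audit = stratify.apply_exclusions(patients, config.exclusions)
        logger.info("exclusions: %d removed, %d retained", len(audit), len(retained))
        retained = retained.copy()
        retained["group"] = stratify.stratify_by_bd(
            retained, config.exclusions.bd_cutoff
        )
        si, flag = stratify.shock_index(
            retained["hr_admission"], retained["sbp_admission"]
        )
        retained["shock_index"] = si
        retained["shock_flag"] = flag
        _write_df(audit, "exclusion_audit.csv")
        _write_df(retained, "patients_stratified.csv")
        groups = retained.set_index("patient_id")["group"]
        samples = samples[samples["patient_id"].isin(groups.index)]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stratify", e) from e

    # -- clinical comparison report ------------------------------------------
    try:
        report = _clinical_report(retained)
        _write_df(report, "clinical_report.csv")
        (out / "clinical_report.json").write_text(
            json.dumps(report.to_dict(orient="records"), indent=2, default=float)
        )
        written.append(out / "clinical_report.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("clinical_report", e) from e

    # -- trajectories ---------------------------------------------------------
    try:
        traj = trajectories.TrajectoryAnalysis(
            samples, groups, transform=config.transform,
            alpha=config.alpha, auc_method=config.auc_method,
            interval=(4.0, 20.0),
        ).fit()
        _write_df(traj.means, "trajectory_means.csv")
        _write_df(traj.ranking, "auc_fold_ranking_24h.csv")
        traj7 = trajectories.TrajectoryAnalysis(
            samples, groups, transform=config.transform,
            alpha=config.alpha, auc_method=config.auc_method,
        ).fit()
        _write_df(traj7.ranking, "auc_fold_ranking_day7.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trajectories", e) from e

    # -- DyNA -----------------------------------------------------------------
    try:
        res = dyna.DynamicNetworkAnalysis(
            samples, groups, windows=config.windows,
            threshold=config.threshold, method=config.corr_method,
            mode=config.edge_mode, node_rule=config.node_rule,
            min_pairs=config.min_pairs,
        ).fit()
        _write_df(res.density_table(), "dyna_density.csv")
        _write_df(res.edge_table(), "dyna_edges.tsv".replace(".tsv", ".csv"))
        for (grp, wlabel), net in res.networks.items():
            p = out / f"network_{grp}_{wlabel.replace('-', '_')}.graphml"
            net.to_graphml(p)
            written.append(p)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dyna", e) from e

    manifest = {
        "seed": config.seed,
        "settings": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
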