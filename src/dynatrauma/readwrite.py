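"""CSV readers/writers and run configuration.

Tables are RFC-4180 CSV. The measurement table is long-format with header
``patient_id,time_h,mediator,value_pg_ml,censored``; the patient table
carries one row per patient with the clinical covariates the stratification
step consumes. Floats are serialized with fixed precision so write-then-read
round-trips are lossless at the documented tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .cohort import SimulationConfig, PlantedBlock
from .dyna import AnalysisWindow, DEFAULT_WINDOWS
from .stratify import ExclusionRules

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_patients",
    "write_patients",
    "RunConfig",
]

_MEAS_COLS = ["patient_id", "time_h", "mediator", "value_pg_ml", "censored"]
FLOAT_FORMAT = "%.6g"


def write_measurements(samples: pd.DataFrame, path) -> None:
    out = samples.rename(columns={"value": "value_pg_ml"})[_MEAS_COLS]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_measurements(path) -> pd.DataFrame:
    """Read a long-format measurement CSV into typed records.

    Duplicate (patient, mediator, time) rows and non-positive values are
    rejected with the offending line number (header = line 1).
    """
    df = pd.read_csv(path)
    missing = set(_MEAS_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement file missing columns: {sorted(missing)}")
    df = df[_MEAS_COLS].rename(columns={"value_pg_ml": "value"})
    if len(df) == 0:
        df["censored"] = df["censored"].astype(bool)
        return df
    bad = ~(df["value"] > 0) | (df["time_h"] < 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"malformed measurement row at line {line}: "
                         "value must be > 0 and time_h >= 0")
    dup = df.duplicated(subset=["patient_id", "mediator", "time_h"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"duplicate (patient, mediator, time) at line {line}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_patients(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("patient file missing patient_id column")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in patient table")
    return df


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline settings (YAML/JSON serialisable)."""

    out_dir: str = "dynatrauma_out"
    patients_path: str | None = None
    measurements_path: str | None = None
    seed: int = 0
    # stratification
    exclusions: ExclusionRules = dataclasses.field(default_factory=ExclusionRules)
    # trajectories
    transform: str = "log10"
    alpha: float = 0.05
    auc_method: str = "trapezoid"
    # DyNA
    windows: tuple[AnalysisWindow, ...] = DEFAULT_WINDOWS
    threshold: float = 0.7
    corr_method: str = "pearson"
    edge_mode: str = "signed"
    node_rule: str = "connected"
    min_pairs: int = 8
    # simulate mode
    simulate: bool = True
    simulation: SimulationConfig | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "out_dir": self.out_dir,
            "patients_path": self.patients_path,
            "measurements_path": self.measurements_path,
            "seed": self.seed,
            "exclusions": dataclasses.asdict(self.exclusions),
            "transform": self.transform,
            "alpha": self.alpha,
            "auc_method": self.auc_method,
            "windows": [[w.start_h, w.end_h] for w in self.windows],
            "threshold": self.threshold,
            "corr_method": self.corr_method,
            "edge_mode": self.edge_mode,
            "node_rule": self.node_rule,
            "min_pairs": self.min_pairs,
            "simulate": self.simulate,
        }
        if self.simulation is not None:
            s = self.simulation
            sim = {
                "n_per_group": list(s.n_per_group),
                "mediators": list(s.mediators),
                "sampling_times_h": [float(t) for t in s.sampling_times_h],
                "log_sd": (s.log_sd if isinstance(s.log_sd, (int, float))
                           else list(map(float, s.resolved_log_sd()))),
                "lod": (dict(s.lod) if not isinstance(s.lod, (int, float))
                        else float(s.lod)),
                "missing_prob": s.missing_prob,
                "seed": s.seed,
            }
            sim["group_log_means"] = (
                None if s.group_log_means is None
                else s.resolved_log_means().tolist()
            )
            sim["planted_blocks"] = [
                {"group": b.group, "window": list(b.window),
                 "mediators": list(b.mediators), "rho": b.rho}
                for b in self.simulation.planted_blocks
            ]
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "exclusions" in d and isinstance(d["exclusions"], dict):
            d["exclusions"] = ExclusionRules(**d["exclusions"])
        if "windows" in d:
            d["windows"] = tuple(
                AnalysisWindow(float(a), float(b)) for a, b in d["windows"]
            )
        sim = d.pop("simulation", None)
        cfg = cls(**d)
        if sim is not None:
            sim = dict(sim)
            sim["mediators"] = tuple(sim.get("mediators", ()))
            sim["sampling_times_h"] = tuple(sim.get("sampling_times_h", ()))
            sim["n_per_group"] = tuple(sim.get("n_per_group", (70, 84)))
            blocks = tuple(
                PlantedBlock(b["group"], tuple(b["window"]),
                             tuple(b["mediators"]), b["rho"])
                for b in sim.get("planted_blocks", ())
            )
            sim["planted_blocks"] = blocks
            if sim.get("group_log_means") is not None:
                import numpy as np

                sim["group_log_means"] = np.asarray(sim["group_log_means"])
            if isinstance(sim.get("lod"), dict):
                sim["lod"] = dict(sim["lod"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data)
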