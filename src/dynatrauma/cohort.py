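"""Synthetic two-group longitudinal cytokine cohort generator.

Emulates a blunt-trauma biobank stratified by admission base deficit (BD):
a BD < 4 mEq/L stratum and a BD >= 4 mEq/L stratum, each patient sampled
three times within the first 24 h post-injury (nominally 4, 12, 20 h) and
then daily through day 7, with a 22-mediator plasma cytokine/chemokine
panel measured in pg/mL.

Concentrations are generated log10-normally with group- and time-dependent
means. Within configurable (group, time-window) "planted blocks" the log
residuals of a mediator subset share a common pairwise correlation rho, so
that downstream windowed-correlation network recovery is testable against
known ground truth. Values below a per-mediator lower limit of detection
(LOD) are substituted by LOD/2 and flagged as censored, mirroring standard
multiplex-immunoassay handling.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; identical configurations give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEDIATOR_PANEL",
    "GROUP_LABELS",
    "DEFAULT_SAMPLING_TIMES_H",
    "PlantedBlock",
    "SimulationConfig",
    "default_config",
    "generate_cohort",
    "sample_mediator_panel",
    "apply_censoring",
]

#: The 22-analyte inflammatory mediator panel (pg/mL).
MEDIATOR_PANEL: tuple[str, ...] = (
    "IL-1b", "IL-1RA", "IL-2", "sIL-2Ra", "IL-4", "IL-5", "IL-6", "IL-7",
    "IL-8", "IL-10", "IL-13", "IL-15", "IL-17A", "IFN-g", "IP-10", "MIG",
    "MIP-1a", "MIP-1b", "MCP-1", "GM-CSF", "Eotaxin", "TNF-a",
)

#: Stratum labels, indexed by ``group_truth``.
GROUP_LABELS: tuple[str, str] = ("BD_LT4", "BD_GE4")

#: Nominal draw grid (hours post-injury): three draws in the first 24 h,
#: then daily through day 7.
DEFAULT_SAMPLING_TIMES_H: tuple[float, ...] = (
    4.0, 12.0, 20.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0,
)

# Baseline log10 concentration (BD<4 stratum) and BD>=4 fold elevation.
# Baselines for the mediators with a reported early AUC contrast are placed
# so the group-mean concentration sits on the corresponding 0-24 h AUC/24h
# scale (lognormal mean factor exp((ln10 * 0.4)^2 / 2) ~ 1.53 at the default
# residual SD); the rest get moderate resting-plasma levels. Fold values > 1
# mark mediators elevated in the BD>=4 stratum.
_BASELINE_LOG10: dict[str, float] = {
    "IL-1RA": 1.30, "IL-7": 0.41, "IL-8": 0.45, "sIL-2Ra": 1.01,
    "MCP-1": 1.59, "IL-6": 0.60, "IL-5": 0.50, "IFN-g": 0.85,
    "IL-13": 0.55, "IL-4": 0.90, "IL-2": 0.70, "MIP-1b": 1.20,
    "TNF-a": 0.75, "IL-1b": 0.60, "IL-15": 0.70, "IL-17A": 0.55,
    "MIG": 1.60, "IL-10": 1.00, "IP-10": 1.80, "MIP-1a": 1.10,
    "GM-CSF": 0.80, "Eotaxin": 1.40,
}
_GROUP_FOLD: dict[str, float] = {
    "IL-1RA": 3.1, "IL-7": 2.2, "IL-8": 2.1, "sIL-2Ra": 1.9, "MCP-1": 1.6,
    "IL-6": 1.6, "IL-5": 1.8, "IFN-g": 1.5, "IL-13": 1.4, "IL-4": 1.4,
    "IL-2": 1.3, "MIP-1b": 1.3, "TNF-a": 1.2,
}
# Early-peak-then-decay time profile, one log10 offset per grid point.
_TIME_PROFILE: tuple[float, ...] = (
    0.30, 0.25, 0.20, 0.10, 0.05, 0.00, -0.05, -0.10, -0.15,
)

#: Mediator subset carrying the default planted correlation block.
DEFAULT_BLOCK_MEDIATORS: tuple[str, ...] = (
    "GM-CSF", "IFN-g", "IL-17A", "IL-2", "IL-4",
    "IL-7", "IL-13", "IL-15", "MIP-1a", "sIL-2Ra",
)


@dataclass(frozen=True)
class PlantedBlock:
    """Equicorrelated log-residual block for one stratum and time window.

    Draws whose time falls in ``[window[0], window[1])`` and whose patient
    belongs to stratum ``group`` have the log10 residuals of ``mediators``
    share pairwise correlation ``rho``.
    """

    group: int
    window: tuple[float, float]
    mediators: tuple[str, ...]
    rho: float

    def contains(self, time_h: float) -> bool:
        return self.window[0] <= time_h < self.window[1]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort.

    Parameters
    ----------
    n_per_group
        Patients in the (BD<4, BD>=4) strata; each must be >= 3.
    mediators
        Unique mediator names (the assay panel).
    sampling_times_h
        Nominal draw grid in hours post-injury.
    group_log_means
        Array of shape ``(len(mediators), 2, len(sampling_times_h))``:
        mean of log10 concentration (log10 pg/mL) per mediator x stratum x
        nominal time.
    log_sd
        Residual SD of log10 concentration per mediator (broadcast from a
        scalar); all entries must be > 0.
    planted_blocks
        Within-window correlation structure; all rho in [0, 1).
    lod
        Per-mediator lower limit of detection in pg/mL (scalar broadcast);
        values below it are substituted by LOD/2 and flagged censored.
    missing_prob
        Probability that a scheduled blood draw is absent (the whole panel
        for that patient-time is dropped together).
    seed
        Seed for the run-owned random generator.
    """

    n_per_group: tuple[int, int] = (70, 84)
    mediators: tuple[str, ...] = MEDIATOR_PANEL
    sampling_times_h: tuple[float, ...] = DEFAULT_SAMPLING_TIMES_H
    group_log_means: np.ndarray | None = None
    log_sd: float | np.ndarray = 0.4
    planted_blocks: tuple[PlantedBlock, ...] = ()
    lod: float | Mapping[str, float] = 1.0
    missing_prob: float = 0.1
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field when invalid."""
        if len(self.n_per_group) != 2 or any(n < 3 for n in self.n_per_group):
            raise ValueError("n_per_group: need two strata with n >= 3 each")
        if len(set(self.mediators)) != len(self.mediators):
            raise ValueError("mediators: names must be unique")
        times = np.asarray(self.sampling_times_h, dtype=float)
        if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError(
                "sampling_times_h: must be nonnegative and strictly increasing"
            )
        mu = self.resolved_log_means()
        want = (len(self.mediators), 2, times.size)
        if mu.shape != want:
            raise ValueError(f"group_log_means: shape {mu.shape} != {want}")
        sd = self.resolved_log_sd()
        if np.any(sd <= 0):
            raise ValueError("log_sd: all SDs must be > 0")
        for blk in self.planted_blocks:
            if not 0.0 <= blk.rho < 1.0:
                raise ValueError("planted_blocks: rho must be in [0, 1)")
            if blk.group not in (0, 1):
                raise ValueError("planted_blocks: group must be 0 or 1")
            unknown = set(blk.mediators) - set(self.mediators)
            if unknown:
                raise ValueError(f"planted_blocks: unknown mediators {sorted(unknown)}")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob: must be in [0, 1)")
        lod = self.resolved_lod()
        if np.any(lod < 0):
            raise ValueError("lod: detection limits must be >= 0")

    # -- resolved parameter arrays --------------------------------------
    def resolved_log_means(self) -> np.ndarray:
        if self.group_log_means is not None:
            return np.asarray(self.group_log_means, dtype=float)
        return _default_log_means(self.mediators, self.sampling_times_h)

    def resolved_log_sd(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.log_sd, dtype=float), (len(self.mediators),)
        ).astype(float)

    def resolved_lod(self) -> np.ndarray:
        if isinstance(self.lod, Mapping):
            return np.array([float(self.lod.get(m, 0.0)) for m in self.mediators])
        return np.full(len(self.mediators), float(self.lod))


def _default_log_means(
    mediators: Sequence[str], times: Sequence[float]
) -> np.ndarray:
    """Baseline + early-peak profile + BD>=4 fold elevation, on log10."""
    n_t = len(times)
    if n_t == len(_TIME_PROFILE):
        profile = np.asarray(_TIME_PROFILE)
    else:  # interpolate the default shape onto a custom grid
        profile = np.interp(
            np.asarray(times, dtype=float),
            DEFAULT_SAMPLING_TIMES_H,
            _TIME_PROFILE,
        )
    mu = np.empty((len(mediators), 2, n_t))
    for i, med in enumerate(mediators):
        base = _BASELINE_LOG10.get(med, 1.0)
        fold = _GROUP_FOLD.get(med, 1.0)
        mu[i, 0, :] = base + profile
        mu[i, 1, :] = base + profile + math.log10(fold)
    return mu


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions: 70 vs 84 patients, 22 mediators, one
    rho=0.85 block of 10 mediators planted in the BD>=4 stratum during the
    first two 8 h windows."""
    cfg = SimulationConfig(
        planted_blocks=(
            PlantedBlock(1, (0.0, 8.0), DEFAULT_BLOCK_MEDIATORS, 0.85),
            PlantedBlock(1, (8.0, 16.0), DEFAULT_BLOCK_MEDIATORS, 0.85),
        ),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# clinical covariates: normal draws calibrated to published stratum summaries
# (mean +/- SEM at n=70/84), clipped to admissible ranges.
# ---------------------------------------------------------------------------

_CLINICAL = {
    # var: ((mean0, sd0), (mean1, sd1), lo, hi)
    "age": ((49.3, 20.1), (45.8, 18.3), 18.0, 90.0),
    "iss": ((21.0, 10.9), (23.0, 11.0), 1.0, 75.0),
    "gcs": ((12.7, 4.4), (12.6, 5.1), 3.0, 15.0),
    "sbp_admission": ((130.0, 25.1), (114.0, 27.5), 60.0, 220.0),
    "hr_admission": ((89.0, 16.7), (104.0, 27.5), 40.0, 180.0),
    "icu_los": ((6.6, 6.6), (9.9, 8.8), 0.0, 60.0),
    "hosp_los": ((11.9, 8.1), (17.4, 11.0), 0.0, 90.0),
    "vent_days": ((3.0, 4.7), (5.5, 8.0), 0.0, 60.0),
}
_BD = ((1.7, 0.84), (6.7, 3.67))  # stratum-conditional, truncated at 4
_P_TRANSFUSED = (22 / 70, 43 / 84)
_P_SURGERY = (29 / 70, 51 / 84)
_P_MALE = (55 / 70, 55 / 84)
_DISPOSITIONS = ("home", "home_with_service", "inpatient_rehab",
                 "outpatient_rehab", "skilled_nursing", "other")
_P_DISPO = (
    (0.486, 0.029, 0.086, 0.157, 0.229, 0.014),
    (0.274, 0.012, 0.012, 0.202, 0.464, 0.036),
)
_AIS_REGIONS = ("head", "face", "chest", "abdomen", "extremity", "external")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far from the mean, so the
    acceptance rate is high; loop guards the pathological case)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


def _make_patients(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid = 0
    for g, n in enumerate(config.n_per_group):
        bd_mean, bd_sd = _BD[g]
        lo, hi = ((-25.0, 4.0) if g == 0 else (4.0, 40.0))
        bd = _truncnorm(rng, bd_mean, bd_sd, lo, hi, n)
        clin = {}
        for var, (p0, p1, vlo, vhi) in _CLINICAL.items():
            mean, sd = (p0, p1)[g]
            clin[var] = _truncnorm(rng, mean, sd, vlo, vhi, n)
        sex = np.where(rng.random(n) < _P_MALE[g], "M", "F")
        dispo = rng.choice(_DISPOSITIONS, size=n, p=np.asarray(_P_DISPO[g]) /
                           np.sum(_P_DISPO[g]))
        ais = {f"ais_{r}": rng.integers(0, 5, n) for r in _AIS_REGIONS}
        # daily organ-dysfunction scores: BD>=4 stays elevated through day 7
        mod_means = ([3.0, 2.6, 2.2, 1.8, 1.5, 1.2, 1.0] if g == 0
                     else [3.4, 3.4, 3.2, 3.0, 2.7, 2.4, 2.2])
        mods = {
            f"modscore_d{d}": np.clip(rng.normal(m, 1.2, n), 0, 24).round(1)
            for d, m in enumerate(mod_means, start=1)
        }
        for i in range(n):
            row = {
                "patient_id": f"P{pid:04d}",
                "group_truth": g,
                "group": GROUP_LABELS[g],
                "age": round(float(clin["age"][i]), 1),
                "sex": sex[i],
                "iss": int(round(clin["iss"][i])),
                "gcs": int(round(clin["gcs"][i])),
                "bd_admission": round(float(bd[i]), 2),
                "ethanol": round(float(rng.uniform(0.0, 8.0)), 2),
                "prehospital_fluids": round(float(rng.uniform(0.0, 1.8)), 2),
                "sbp_admission": round(float(clin["sbp_admission"][i]), 0),
                "hr_admission": round(float(clin["hr_admission"][i]), 0),
                "transfused_24h": bool(rng.random() < _P_TRANSFUSED[g]),
                "surgery_24h": bool(rng.random() < _P_SURGERY[g]),
                "icu_los": round(float(clin["icu_los"][i]), 1),
                "hosp_los": round(float(clin["hosp_los"][i]), 1),
                "vent_days": round(float(clin["vent_days"][i]), 1),
                "disposition": dispo[i],
            }
            row.update({k: int(v[i]) for k, v in ais.items()})
            row.update({k: float(v[i]) for k, v in mods.items()})
            rows.append(row)
            pid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mediator panel sampling
# ---------------------------------------------------------------------------

def _panel_noise(
    config: SimulationConfig, group: int, time_h: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal residual vector across the panel, equicorrelated
    within any planted block covering (group, time_h)."""
    n_med = len(config.mediators)
    z = rng.standard_normal(n_med)
    idx = {m: i for i, m in enumerate(config.mediators)}
    for blk in config.planted_blocks:
        if blk.group != group or not blk.contains(time_h):
            continue
        cols = [idx[m] for m in blk.mediators]
        shared = rng.standard_normal()
        z[cols] = (math.sqrt(blk.rho) * shared
                   + math.sqrt(1.0 - blk.rho) * rng.standard_normal(len(cols)))
    return z


def sample_mediator_panel(
    patient: Mapping,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the full longitudinal mediator panel for one patient.

    ``patient`` needs ``patient_id`` and ``group_truth``. Scheduled draws
    are skipped with probability ``missing_prob`` (whole panel at once).
    Returns a long-format frame: patient_id, time_h, mediator, value, censored
    (censoring not yet applied; see :func:`apply_censoring`).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = int(patient["group_truth"])
    if g not in (0, 1):
        raise ValueError(f"patient {patient['patient_id']}: unknown stratum {g}")
    mu = config.resolved_log_means()
    sd = config.resolved_log_sd()
    times = np.asarray(config.sampling_times_h, dtype=float)
    rows = []
    for j, t in enumerate(times):
        drawn = rng.random() >= config.missing_prob
        z = _panel_noise(config, g, float(t), rng)  # consume RNG regardless,
        if not drawn:                               # so missingness does not
            continue                                # reshuffle later draws
        log_vals = mu[:, g, j] + sd * z
        for i, med in enumerate(config.mediators):
            rows.append(
                (patient["patient_id"], float(t), med,
                 float(10.0 ** log_vals[i]), False)
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "time_h", "mediator", "value", "censored"]
    )


def apply_censoring(
    samples: pd.DataFrame, lod: float | Mapping[str, float]
) -> pd.DataFrame:
    """Substitute values below the detection limit by LOD/2, flag censored.

    ``lod`` is a scalar or a mediator->LOD mapping in pg/mL; limits must be
    nonnegative. Records at or above the limit are untouched.
    """
    if isinstance(lod, Mapping):
        lod_ser = samples["mediator"].map(lambda m: float(lod.get(m, 0.0)))
    else:
        lod_ser = pd.Series(float(lod), index=samples.index)
    if (lod_ser < 0).any():
        raise ValueError("lod: detection limits must be >= 0")
    out = samples.copy()
    below = out["value"] < lod_ser
    out.loc[below, "value"] = lod_ser[below] / 2.0
    out.loc[below, "censored"] = True
    return out


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full synthetic cohort.

    Returns
    -------
    patients : DataFrame
        One row per patient (clinical covariates, admission BD, stratum).
    samples : DataFrame
        Long-format mediator measurements with LOD censoring applied:
        columns patient_id, time_h, mediator, value, censored.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _make_patients(config, rng)
    panels = [
        sample_mediator_panel(row, config, rng)
        for row in patients.to_dict("records")
    ]
    samples = pd.concat(panels, ignore_index=True) if panels else pd.DataFrame(
        columns=["patient_id", "time_h", "mediator", "value", "censored"]
    )
    lod_map = dict(zip(config.mediators, config.resolved_lod()))
    samples = apply_censoring(samples, lod_map)
    samples["value"] = samples["value"].round(6)
    return patients, samples
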