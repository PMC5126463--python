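"""Cohort exclusion, base-deficit stratification, and clinical statistics.

The exclusion rules mirror the study design for an admission-BD stratified
trauma cohort: patients with documented alcohol intoxication (serum ethanol
> 10 ng/dL) or large prehospital fluid/blood volumes (> 2 L) are removed,
and the remainder is split at a BD cutoff of 4 mEq/L into a BD_LT4 and a
BD_GE4 stratum (cutoff inclusive above).

The 2x2 contingency machinery follows the ``statsmodels.stats.Table2x2``
idiom: a small class holding the counts with methods for the relative risk
(Katz log confidence interval), Pearson chi-square, and the Fisher exact
test. Group comparisons of continuous variables use the Mann-Whitney U test
(exact by enumeration for small tie-free samples, normal approximation with
tie correction otherwise) and mean +/- SEM summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionRules",
    "apply_exclusions",
    "stratify_by_bd",
    "shock_index",
    "ContingencyTable2x2",
    "RelativeRiskResult",
    "relative_risk",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "summarize_groups",
]


@dataclass(frozen=True)
class ExclusionRules:
    """Admission confounder thresholds (strict '>' semantics).

    max_ethanol is in ng/dL, max_prehospital_fluids in liters; bd_cutoff
    (mEq/L) is carried here for convenience of downstream stratification.
    """

    max_prehospital_fluids: float = 2.0
    max_ethanol: float = 10.0
    bd_cutoff: float = 4.0

    def __post_init__(self) -> None:
        for name in ("max_prehospital_fluids", "max_ethanol", "bd_cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.bd_cutoff <= 0:
            raise ValueError("bd_cutoff must be > 0")


def _require_field(patients: pd.DataFrame, fields: Sequence[str]) -> None:
    for f in fields:
        if f not in patients.columns:
            raise ValueError(f"missing required column: {f}")
        bad = patients[f].isna()
        if bad.any():
            pid = patients.loc[bad, "patient_id"].iloc[0]
            raise ValueError(f"patient {pid}: missing value for {f}")


def apply_exclusions(
    patients: pd.DataFrame, rules: ExclusionRules = ExclusionRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop intoxicated and heavily pre-resuscitated patients.

    A patient is retained iff ethanol <= max_ethanol AND
    prehospital_fluids <= max_prehospital_fluids (boundary values retained).
    Missing values are an error, never silently retained.

    Returns the retained patients and an audit log with one row per
    exclusion (patient_id, rule, value, threshold).
    """
    _require_field(patients, ["ethanol", "prehospital_fluids"])
    audit_rows = []
    keep = np.ones(len(patients), dtype=bool)
    for i, row in enumerate(patients.itertuples(index=False)):
        if row.ethanol > rules.max_ethanol:
            keep[i] = False
            audit_rows.append(
                (row.patient_id, "alcohol_intoxication", row.ethanol,
                 rules.max_ethanol)
            )
        if row.prehospital_fluids > rules.max_prehospital_fluids:
            keep[i] = False
            audit_rows.append(
                (row.patient_id, "prehospital_fluids", row.prehospital_fluids,
                 rules.max_prehospital_fluids)
            )
    audit = pd.DataFrame(
        audit_rows, columns=["patient_id", "rule", "value", "threshold"]
    )
    return patients.loc[keep].reset_index(drop=True), audit


def stratify_by_bd(patients: pd.DataFrame, cutoff: float = 4.0) -> pd.Series:
    """Label each patient BD_GE4 if bd_admission >= cutoff, else BD_LT4.

    The partition is exhaustive and disjoint; missing BD is an error.
    """
    _require_field(patients, ["bd_admission"])
    labels = np.where(patients["bd_admission"] >= cutoff, "BD_GE4", "BD_LT4")
    return pd.Series(labels, index=patients.index, name="group")


def shock_index(hr, sbp) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Shock Index = heart rate / systolic blood pressure.

    An index strictly greater than 1 flags hypovolemic shock. Accepts
    scalars or arrays; sbp must be positive.
    """
    hr_a = np.asarray(hr, dtype=float)
    sbp_a = np.asarray(sbp, dtype=float)
    if np.any(sbp_a <= 0):
        raise ValueError("sbp must be > 0")
    si = hr_a / sbp_a
    flag = si > 1.0
    if np.isscalar(hr) or (si.ndim == 0):
        return float(si), bool(flag)
    return si, flag


@dataclass(frozen=True)
class RelativeRiskResult:
    rr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


class ContingencyTable2x2:
    """2x2 counts: (a, b) exposed event/non-event, (c, d) unexposed.

    Exposure here is typically the BD_GE4 stratum, the event an in-hospital
    outcome (surgery, transfusion) within 24 h.
    """

    def __init__(self, a: int, b: int, c: int, d: int):
        counts = (a, b, c, d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be nonnegative integers")
        self.a, self.b, self.c, self.d = (int(x) for x in counts)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ContingencyTable2x2(a={self.a}, b={self.b}, "
                f"c={self.c}, d={self.d})")

    @property
    def risk_exposed(self) -> float:
        if self.a + self.b == 0:
            raise ValueError("exposed row total is zero")
        return self.a / (self.a + self.b)

    @property
    def risk_unexposed(self) -> float:
        if self.c + self.d == 0:
            raise ValueError("unexposed row total is zero")
        return self.c / (self.c + self.d)

    def relative_risk(self, alpha: float = 0.05) -> RelativeRiskResult:
        """Risk ratio with the Katz log-method confidence interval.

        CI = exp(ln RR +/- z_{1-alpha/2} * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
        Zero event counts are rejected; add 0.5 to every cell yourself if a
        continuity-corrected variant is wanted (documented, off by default).
        """
        if self.a == 0 or self.c == 0:
            raise ValueError(
                "zero event count: the log CI is undefined; apply a "
                "continuity correction (add 0.5 to all cells) explicitly "
                "if desired"
            )
        rr = self.risk_exposed / self.risk_unexposed
        se = math.sqrt(
            1 / self.a - 1 / (self.a + self.b)
            + 1 / self.c - 1 / (self.c + self.d)
        )
        z = stats.norm.ppf(1 - alpha / 2)
        return RelativeRiskResult(
            rr=rr,
            ci_low=rr * math.exp(-z * se),
            ci_high=rr * math.exp(z * se),
            alpha=alpha,
        )

    def chi_square(self, correction: bool = False) -> tuple[float, float]:
        """Pearson chi-square (df=1); Yates correction off by default."""
        obs = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
            raise ValueError("degenerate margins: a zero row or column total")
        res = stats.chi2_contingency(obs, correction=correction)
        return float(res.statistic), float(res.pvalue)

    def fisher_exact(self) -> float:
        """Two-sided Fisher exact p (sum of hypergeometric probabilities
        no larger than the observed table's)."""
        obs = [[self.a, self.b], [self.c, self.d]]
        return float(stats.fisher_exact(obs, alternative="two-sided")[1])

    def summary(self) -> pd.DataFrame:
        rr = self.relative_risk()
        chi2, p_chi = self.chi_square()
        return pd.DataFrame(
            {
                "risk_exposed": [self.risk_exposed],
                "risk_unexposed": [self.risk_unexposed],
                "rr": [rr.rr],
                "ci_low": [rr.ci_low],
                "ci_high": [rr.ci_high],
                "chi2": [chi2],
                "p_chi2": [p_chi],
                "p_fisher": [self.fisher_exact()],
            }
        )


# -- functional surface over the class --------------------------------------

def relative_risk(
    table: ContingencyTable2x2, alpha: float = 0.05
) -> RelativeRiskResult:
    return table.relative_risk(alpha=alpha)


def chi_square_2x2(
    table: ContingencyTable2x2, correction: bool = False
) -> tuple[float, float]:
    return table.chi_square(correction=correction)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    return table.fisher_exact()


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U of x, p). U uses midranks for ties. The p-value is exact by
    enumeration when n1 + n2 <= 12 and the pooled sample is tie-free,
    otherwise a normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def summarize_groups(
    patients: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group n, mean and SEM (sd with n-1 denominator / sqrt(n)).

    SEM is reported as missing (NaN) when n = 1, never as zero.
    """
    rows = []
    for var in variables:
        if not pd.api.types.is_numeric_dtype(patients[var]):
            raise ValueError(f"variable {var} is not numeric")
        for grp, sub in patients.groupby(group_col, sort=True):
            vals = sub[var].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                continue
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append((var, grp, n, mean, sem))
    return pd.DataFrame(rows, columns=["variable", "group", "n", "mean", "sem"])
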