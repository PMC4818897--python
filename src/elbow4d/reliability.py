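"""Reliability and cohort statistics for the simulation workflow.

Intraclass correlation coefficients quantify how reproducible the measured
bony overlap volumes are when the landmarking (and hence the axis) is
repeated: the one-way random, single-measure form ICC(1,1) for repeat
sessions of one observer, and the two-way random, absolute-agreement,
single-measure form ICC(2,1) between observers.  Both come from the ANOVA
decomposition of an n subjects x k sessions/raters grid.

Reliability labels follow the conventional thresholds: excellent above
0.75, fair to good between 0.4 and 0.75, poor below 0.4.

Cohort helpers summarize range-of-motion and outcome-score tables
(mean, sample SD, paired and Welch t-tests).  Extension deficits are signed
negative, so the flexion-extension arc is ``flexion + extension``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, UndefinedICCError


@dataclass
class RatingsMatrix:
    """Complete n x k grid of measurements: rows subjects, columns raters/sessions."""

    values: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D grid")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters/sessions")
        if np.isnan(self.values).any():
            bad = [tuple(map(int, ij)) for ij in np.argwhere(np.isnan(self.values))]
            raise ValueError(f"missing cells at (row, col): {bad}")
        if not self.row_labels:
            self.row_labels = [str(i + 1) for i in range(n)]
        if not self.col_labels:
            self.col_labels = [f"rater{j + 1}" for j in range(k)]

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "RatingsMatrix":
        """CSV with a leading subject-id column and one column per rater."""
        df = pd.read_csv(path)
        return cls(
            df.iloc[:, 1:].to_numpy(dtype=float),
            row_labels=[str(v) for v in df.iloc[:, 0]],
            col_labels=[str(c) for c in df.columns[1:]],
        )


@dataclass
class ICCResult:
    model: str
    estimate: float
    ci95: tuple[float, float]
    interpretation: str
    anova_table: dict

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimate": float(self.estimate),
            "ci95_lower": float(self.ci95[0]),
            "ci95_upper": float(self.ci95[1]),
            "interpretation": self.interpretation,
            "anova_table": {k: float(v) for k, v in self.anova_table.items()},
        }


def interpret_icc(estimate: float) -> str:
    """Conventional reliability label for an ICC estimate."""
    if estimate > 0.75:
        return "excellent"
    if estimate >= 0.4:
        return "fair to good"
    return "poor"


def _anova_components(values: np.ndarray) -> dict:
    """Mean squares of the two-way subjects x raters decomposition."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows  # one-way residual (cols + error)
    return {
        "n": n,
        "k": k,
        "BMS": ss_rows / (n - 1),
        "JMS": ss_cols / (k - 1),
        "EMS": ss_err / ((n - 1) * (k - 1)),
        "WMS": ss_within / (n * (k - 1)),
        "SS_total": ss_total,
    }


def icc_oneway_random(m: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(1,1): one-way random effects, single measure.

    ICC = (BMS - WMS) / (BMS + (k-1) WMS); the 95% CI follows the exact
    F-distribution bounds for the one-way model.
    """
    c = _anova_components(m.values)
    if c["SS_total"] <= 0:
        raise UndefinedICCError("ratings have zero total variance")
    n, k, bms, wms = c["n"], c["k"], c["BMS"], c["WMS"]
    if bms + (k - 1) * wms == 0:
        raise UndefinedICCError("degenerate variance decomposition")
    est = (bms - wms) / (bms + (k - 1) * wms)
    if wms > 0:
        f = bms / wms
        fl = f / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = f * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        ci = (1.0, 1.0)
    return ICCResult(
        model="oneway_random",
        estimate=float(est),
        ci95=(float(ci[0]), float(min(ci[1], 1.0))),
        interpretation=interpret_icc(est),
        anova_table={"BMS": bms, "WMS": wms, "n": n, "k": k},
    )


def icc_twoway_random(m: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ICC = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n); the CI uses
    the Satterthwaite-style approximation standard for this form.
    """
    c = _anova_components(m.values)
    if c["SS_total"] <= 0:
        raise UndefinedICCError("ratings have zero total variance")
    n, k = c["n"], c["k"]
    bms, jms, ems = c["BMS"], c["JMS"], c["EMS"]
    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    if denom == 0:
        raise UndefinedICCError("degenerate variance decomposition")
    est = (bms - ems) / denom
    if ems > 0:
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * jms + b * ems) ** 2 / (
                (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
            )
            f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_star2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (bms - f_star * ems) / (
                f_star * (k * jms + (k * n - k - n) * ems) + n * bms
            )
            upper_f = f_star2
            upper = n * (upper_f * bms - ems) / (
                k * jms + (k * n - k - n) * ems + n * upper_f * bms
            )
            ci = (lower, upper)
        else:
            ci = (1.0, 1.0)
    else:
        ci = (1.0, 1.0)
    return ICCResult(
        model="twoway_random",
        estimate=float(est),
        ci95=(float(ci[0]), float(min(ci[1], 1.0))),
        interpretation=interpret_icc(est),
        anova_table={"BMS": bms, "JMS": jms, "EMS": ems, "n": n, "k": k},
    )


# -- cohort statistics -----------------------------------------------------


def cohort_summary(values) -> tuple[float, float, int]:
    """(mean, sample SD, n); SD is NaN for n = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd, int(values.size)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (printed convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def paired_t(pre, post) -> tuple[float, int, float]:
    """Paired two-sided t-test on within-subject differences: (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("pre and post must be equal-length vectors of n >= 2")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, int(pre.size - 1), 1.0
        raise DegenerateTestError(
            "zero difference variance with nonzero mean difference"
        )
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), int(pre.size - 1), float(res.pvalue)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unpaired two-sided t-test between groups: (t, df, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# -- ROM tables ------------------------------------------------------------

ARC_TOLERANCE_DEG = 1e-6


def load_rom_table(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load a ROM table CSV; default is the bundled 11-patient example cohort.

    Checks the arc-consistency convention arc = flexion + extension (signed)
    for every pre- and postoperative record.
    """
    if path is None:
        source = resources.files("elbow4d.data") / "rom_table.csv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for stage in ("pre", "post"):
        flex, ext, arc = (f"{c}_{stage}" for c in ("flexion", "extension", "arc"))
        if {flex, ext, arc} <= set(df.columns):
            bad = df.index[
                (df[flex] + df[ext] - df[arc]).abs() > ARC_TOLERANCE_DEG
            ]
            if len(bad):
                raise ValueError(
                    f"arc != flexion + extension ({stage}-op) at rows {list(bad)}"
                )
    return df


def rom_report(df: pd.DataFrame) -> dict:
    """Cohort means/SDs and pre-vs-post paired tests for each ROM measure."""
    report = {}
    for measure in ("extension", "flexion", "arc"):
        pre = df[f"{measure}_pre"].to_numpy(float)
        post = df[f"{measure}_post"].to_numpy(float)
        m_pre, sd_pre, n = cohort_summary(pre)
        m_post, sd_post, _ = cohort_summary(post)
        t, dof, p = paired_t(pre, post)
        report[measure] = {
            "pre_mean": m_pre,
            "pre_sd": sd_pre,
            "post_mean": m_post,
            "post_sd": sd_post,
            "n": n,
            "t": t,
            "df": dof,
            "p": p,
        }
    if "surgery" in df.columns:
        groups = {}
        for name, sub in df.groupby("surgery"):
            groups[str(name)] = {
                "n": int(len(sub)),
                "arc_pre_mean": float(sub["arc_pre"].mean()),
                "arc_post_mean": float(sub["arc_post"].mean()),
            }
        report["groups"] = groups
    return report
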