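"""Acute-coronary-event (ACE) risk from mean heart dose, and cohort statistics.

The risk model is the linear no-threshold relationship of Darby et al.
between mean heart dose (MHD) and the rate of major coronary events:
the rate increases by 7.4% per Gy of MHD, relative to a baseline absolute
risk.  For a 50-year-old woman with no preexisting cardiac risk factors,
the absolute risk of at least one ACE by attained age 80 without
radiotherapy is 4.5%, so

    total_risk(MHD)  = 4.5% * (1 + 0.074 * MHD)
    excess_risk(MHD) = total_risk - 4.5%  =  4.5% * 0.074 * MHD

with MHD in Gy (or GyRBE when a variable-RBE weighted dose is used).  Risk
arithmetic is carried at full precision; one-decimal half-up rounding is
applied only when a report is rendered.  The fixed Darby scenario (age 50 at
treatment, attained age 80, no risk factors) is report metadata, not a
modelled covariate.

Cohort statistics use the sample median (midpoint of the two central order
statistics for even n).  The paired comparison between dose variants is a
Wilcoxon signed-rank test: exact p by enumeration of all 2^n sign
assignments for n <= 12 non-zero differences, normal approximation with tie
correction otherwise, two-sided throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "DARBY_BASELINE_PCT",
    "DARBY_SLOPE_PER_GY",
    "DARBY_SCENARIO",
    "RiskEstimate",
    "CohortTable",
    "ace_risk",
    "cohort_summary",
    "paired_signed_rank",
    "risk_report",
    "round_half_up",
]

DARBY_BASELINE_PCT = 4.5
DARBY_SLOPE_PER_GY = 0.074
DARBY_SCENARIO = (
    "ACE risk for women treated at age 50 with no preexisting cardiac risk "
    "factors, attained age 80 (Darby linear no-threshold model)"
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), unlike banker's rounding."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RiskEstimate:
    """ACE risk for one mean heart dose, at full precision."""

    mhd_Gy: float
    baseline_risk_pct: float = DARBY_BASELINE_PCT
    slope_per_Gy: float = DARBY_SLOPE_PER_GY
    total_risk_pct: float = field(init=False)
    excess_risk_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mhd_Gy < 0:
            raise ValueError("mhd_Gy must be >= 0")
        total = self.baseline_risk_pct * (1.0 + self.slope_per_Gy * self.mhd_Gy)
        object.__setattr__(self, "total_risk_pct", total)
        object.__setattr__(self, "excess_risk_pct", total - self.baseline_risk_pct)


def ace_risk(
    mhd: float,
    baseline_pct: float = DARBY_BASELINE_PCT,
    slope: float = DARBY_SLOPE_PER_GY,
) -> RiskEstimate:
    """Total and excess absolute ACE risk (%) for a mean heart dose in Gy(RBE)."""
    return RiskEstimate(mhd_Gy=float(mhd), baseline_risk_pct=baseline_pct, slope_per_Gy=slope)


class CohortTable:
    """Long-format per-patient metric records: one row per
    (patient, group, structure, model, metric), each key at most once."""

    COLUMNS = ("patient_id", "group", "structure", "model", "metric", "value")

    def __init__(self, records: pd.DataFrame | None = None) -> None:
        if records is None:
            records = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"records frame is missing columns {sorted(missing)}")
        self._rows: list[tuple] = [tuple(r) for r in records[list(self.COLUMNS)].itertuples(index=False)]
        self._keys = {(r[0], r[2], r[3], r[4]) for r in self._rows}
        if len(self._keys) != len(self._rows):
            raise ValueError("duplicate (patient, structure, model, metric) records")
        self._frame: pd.DataFrame | None = None

    def add(self, patient_id: str, group: str, structure: str, model: str,
            metric: str, value: float) -> None:
        key = (patient_id, structure, model, metric)
        if key in self._keys:
            raise ValueError(f"duplicate record for {key}")
        self._keys.add(key)
        self._rows.append((patient_id, group, structure, model, metric, float(value)))
        self._frame = None

    @property
    def records(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(self._rows, columns=list(self.COLUMNS))
        return self._frame

    def __len__(self) -> int:
        return len(self._rows)

    def select(self, metric: str, model: str, structure: str | None = None,
               group: str = "all") -> pd.DataFrame:
        df = self.records
        sel = (df["metric"] == metric) & (df["model"] == model)
        if structure is not None:
            sel &= df["structure"] == structure
        if group != "all":
            sel &= df["group"] == group
        return df[sel].sort_values("patient_id").reset_index(drop=True)


def cohort_summary(
    table: CohortTable,
    metric: str,
    model: str,
    structure: str | None = None,
    group: str = "all",
) -> tuple[float, float, float]:
    """(median, min, max) of one metric over the selected patients."""
    df = table.select(metric, model, structure=structure, group=group)
    if not len(df):
        raise ValueError(
            f"no records for metric={metric!r}, model={model!r}, group={group!r}"
        )
    vals = df["value"].to_numpy(dtype=float)
    return float(np.median(vals)), float(vals.min()), float(vals.max())


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns ``(W_plus, p)`` where ``W_plus`` is the sum of ranks of positive
    differences.  Zero differences are dropped; at least 5 non-zero pairs are
    required.  Ties among absolute differences receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate input: all paired differences are zero")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero paired differences, got {n}")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 12:
        # exact two-sided p by enumerating all 2^n sign assignments with the
        # same (possibly tied) ranks
        sums = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((False, True), repeat=n)
        ])
        n_total = sums.size
        p_le = np.count_nonzero(sums <= w_plus + 1e-9) / n_total
        p_ge = np.count_nonzero(sums >= w_plus - 1e-9) / n_total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = 2.0 * float(norm.sf(abs(z)))
        p = min(1.0, p)
    return w_plus, p


def risk_report(
    table: CohortTable,
    baseline_pct: float = DARBY_BASELINE_PCT,
    slope: float = DARBY_SLOPE_PER_GY,
    heart_structure: str = "heart",
    mhd_metric: str = "mean_dose",
) -> pd.DataFrame:
    """Per-patient excess ACE risk per model, plus grouped medians/ranges.

    Requires an MHD record for every (patient, model) pair present in the
    table.  Returns a long-format frame with per-patient rows (excess risk
    rounded to one decimal percent for reporting; ``excess_risk_pct_full``
    keeps full precision) followed by summary rows per model and group.
    """
    models = sorted(table.records["model"].unique())
    patients = sorted(table.records["patient_id"].unique())
    rows = []
    for model in models:
        df = table.select(mhd_metric, model, structure=heart_structure)
        missing = set(patients) - set(df["patient_id"])
        if missing:
            raise ValueError(
                f"missing MHD ({mhd_metric}/{heart_structure}) for model {model!r}, "
                f"patients {sorted(missing)}"
            )
        for _, rec in df.iterrows():
            est = ace_risk(rec["value"], baseline_pct=baseline_pct, slope=slope)
            rows.append({
                "kind": "patient",
                "patient_id": rec["patient_id"],
                "group": rec["group"],
                "model": model,
                "mhd_GyRBE": rec["value"],
                "total_risk_pct": round_half_up(est.total_risk_pct),
                "excess_risk_pct": round_half_up(est.excess_risk_pct),
                "excess_risk_pct_full": est.excess_risk_pct,
            })
    report = pd.DataFrame(rows)
    summaries = []
    for model in models:
        for group in ["all"] + sorted(report["group"].unique()):
            part = report if group == "all" else report[report["group"] == group]
            part = part[part["model"] == model]
            if not len(part):
                continue
            vals = part["excess_risk_pct_full"].to_numpy()
            summaries.append({
                "kind": "summary",
                "patient_id": "",
                "group": group,
                "model": model,
                "mhd_GyRBE": float(np.median(part["mhd_GyRBE"])),
                "total_risk_pct": round_half_up(float(np.median(part["total_risk_pct"]))),
                "excess_risk_pct": round_half_up(float(np.median(vals))),
                "excess_risk_pct_full": float(np.median(vals)),
                "excess_min_pct": round_half_up(float(vals.min())),
                "excess_max_pct": round_half_up(float(vals.max())),
            })
    out = pd.concat([report, pd.DataFrame(summaries)], ignore_index=True)
    out.attrs["scenario"] = DARBY_SCENARIO
    return out
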