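"""Longitudinal monitoring: therapy lines, paired start-vs-PD test, nadir rule.

Serial plasma samples are grouped into therapy lines. Two readouts follow:

* a paired comparison of the marker at the start of a line versus its first
  radiologic progressive-disease (PD) timepoint (Wilcoxon signed-rank);
* a prospective molecular-progression call: walking forward in time, the
  running nadir is the minimum marker value over strictly earlier timepoints
  of the line, and the call fires at the first timepoint whose value is at
  least (1 + rise_frac) times that nadir (default rise 25%). The call is
  causal by construction — it never uses later timepoints.

Lead time is the calendar-day gap from the molecular call to radiologic PD; a
call after radiologic PD counts as missed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RISE_FRAC = 0.25
REQUIRED_COLUMNS = ["patient_id", "date", "therapy_line", "radiology"]


@dataclass
class TherapyLine:
    """One patient's contiguous treatment period, date-sorted."""

    patient_id: str
    line_id: str
    timepoints: pd.DataFrame
    end_reason: str = "censored"  # switch | death | censored


def segment_therapy_lines(timepoints: pd.DataFrame) -> list[TherapyLine]:
    """Group one or more patients' timepoints into date-sorted therapy lines.

    Expects columns patient_id, date (parseable), therapy_line, radiology
    (PD/SD/PR/NA) plus marker columns; an optional ``end_reason`` column
    (constant within a line) is carried onto the line.
    """
    df = timepoints.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"sample sheet lacks columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    dup = df.duplicated(subset=["patient_id", "date", "therapy_line"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate timepoint: patient {row['patient_id']!r} on "
            f"{row['date'].date()} in line {row['therapy_line']!r}"
        )
    lines = []
    for (pid, lid), grp in df.groupby(["patient_id", "therapy_line"], sort=True):
        grp = grp.sort_values("date", kind="stable").reset_index(drop=True)
        end_reason = "censored"
        if "end_reason" in grp.columns and grp["end_reason"].notna().any():
            end_reason = str(grp["end_reason"].dropna().iloc[-1])
        lines.append(TherapyLine(str(pid), str(lid), grp, end_reason))
    return lines


@dataclass
class PairedPDResult:
    pairs: pd.DataFrame  # per line: start value, pd value, delta
    n_increased: int
    n_pairs: int
    p_value: float


def paired_start_vs_pd(
    lines: Iterable[TherapyLine],
    marker: str = "score_5mc",
    require_end_reason: bool = True,
) -> PairedPDResult:
    """Marker at therapy-line start versus first radiologic PD of the line.

    A line qualifies when both the first timepoint and at least one radiologic
    PD timepoint have the marker, and (by default) the line ended in a therapy
    switch or death. Reports per-pair deltas, the count of increases, and the
    two-sided Wilcoxon signed-rank p (exact for small n, with a warning below
    6 pairs).
    """
    rows = []
    for line in lines:
        tp = line.timepoints
        if require_end_reason and line.end_reason not in ("switch", "death"):
            continue
        pd_rows = tp[tp["radiology"] == "PD"]
        if pd_rows.empty:
            continue
        start_val = tp[marker].iloc[0]
        pd_val = pd_rows[marker].iloc[0]
        if pd.isna(start_val) or pd.isna(pd_val):
            continue
        if pd_rows.index[0] == tp.index[0]:
            continue  # PD at line start: no on-treatment pair
        rows.append(
            {
                "patient_id": line.patient_id,
                "line_id": line.line_id,
                "start": float(start_val),
                "pd": float(pd_val),
                "delta": float(pd_val) - float(start_val),
            }
        )
    if not rows:
        raise ValueError("no qualifying therapy lines with start and PD samples")
    pairs = pd.DataFrame(rows)
    deltas = pairs["delta"].values
    n_increased = int((deltas > 0).sum())
    if np.all(deltas == 0):
        p = 1.0
    else:
        if len(deltas) < 6:
            warnings.warn("fewer than 6 pairs; exact signed-rank p is coarse")
        p = float(
            stats.wilcoxon(deltas, alternative="two-sided", method="auto").pvalue
        )
    return PairedPDResult(pairs=pairs, n_increased=n_increased, n_pairs=len(pairs), p_value=p)


@dataclass
class ProgressionCall:
    line_id: str
    patient_id: str
    nadir_value: float | None
    nadir_date: pd.Timestamp | None
    call_date: pd.Timestamp | None
    percent_rise: float | None

    @property
    def called(self) -> bool:
        return self.call_date is not None


def call_molecular_progression(
    line: TherapyLine,
    rise_frac: float = DEFAULT_RISE_FRAC,
    marker: str = "score_5mc",
) -> ProgressionCall:
    """First timepoint rising >= rise_frac above the running therapy-line nadir.

    The nadir at each step is the minimum marker value over strictly earlier
    timepoints, making the call prospective. A nadir of exactly 0 makes the
    ratio undefined; by convention any later positive value then triggers the
    call (a rise from undetectable is maximal evidence), with the rise
    reported as infinite.
    """
    tp = line.timepoints
    vals = tp[marker].astype(float)
    present = vals.notna()
    if present.sum() < 2:
        raise ValueError("need >=2 timepoints with the marker present")
    nadir = np.inf
    nadir_date = None
    for i in tp.index[present]:
        v = float(vals[i])
        date = tp.loc[i, "date"]
        if np.isfinite(nadir):
            if nadir == 0.0:
                triggered, rise = v > 0.0, float("inf")
            else:
                rise = (v - nadir) / nadir
                triggered = v >= nadir * (1.0 + rise_frac)
            if triggered:
                return ProgressionCall(
                    line_id=line.line_id,
                    patient_id=line.patient_id,
                    nadir_value=nadir,
                    nadir_date=nadir_date,
                    call_date=date,
                    percent_rise=100.0 * rise,
                )
        if v < nadir:
            nadir, nadir_date = v, date
    return ProgressionCall(
        line_id=line.line_id,
        patient_id=line.patient_id,
        nadir_value=None if not np.isfinite(nadir) else nadir,
        nadir_date=nadir_date,
        call_date=None,
        percent_rise=None,
    )


def lead_time(call: ProgressionCall, radiologic_pd_date) -> int | None:
    """Calendar days from the molecular call to radiologic PD; None if missed.

    A call on the PD date gives a lead time of 0; a call after radiologic PD
    (or no call) is a miss and excluded from lead-time summaries.
    """
    if not call.called:
        return None
    pd_date = pd.to_datetime(radiologic_pd_date)
    days = (pd_date - call.call_date).days
    return int(days) if days >= 0 else None


def cohort_lead_times(
    lines: Iterable[TherapyLine],
    rise_frac: float = DEFAULT_RISE_FRAC,
    marker: str = "score_5mc",
) -> pd.DataFrame:
    """Per-line molecular calls and lead times to the line's first radiologic PD.

    Lines without a radiologic PD or without >=2 marked timepoints are
    skipped. Columns: patient_id, line_id, called, call_date, pd_date,
    lead_days (NaN when missed).
    """
    rows = []
    for line in lines:
        tp = line.timepoints
        pd_rows = tp[tp["radiology"] == "PD"]
        if pd_rows.empty or tp[marker].notna().sum() < 2:
            continue
        call = call_molecular_progression(line, rise_frac=rise_frac, marker=marker)
        pd_date = pd_rows["date"].iloc[0]
        lt = lead_time(call, pd_date)
        rows.append(
            {
                "patient_id": line.patient_id,
                "line_id": line.line_id,
                "called": call.called,
                "call_date": call.call_date,
                "pd_date": pd_date,
                "lead_days": np.nan if lt is None else lt,
            }
        )
    return pd.DataFrame(rows)
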