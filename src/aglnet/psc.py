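"""Percent signal change (PSC) relative to the fixation baseline.

PSC[t, r] = (signal[t, r] - baseline[r]) / baseline[r] * 100, where
baseline[r] is the mean signal of ROI r over the fixation scans of the
run.  The per-ROI task activation summary is the mean PSC over task
scans.  Instruction scans (the first 2 s of each block) count as task
scans by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ROITimeSeries

__all__ = ["PSCSummary", "percent_signal_change", "group_psc_table"]


@dataclass(frozen=True)
class PSCSummary:
    roi_names: tuple[str, ...]
    psc_per_scan: np.ndarray  # T x p percent values
    psc_task_mean: np.ndarray  # p
    baseline: np.ndarray  # p fixation means


def percent_signal_change(
    series: ROITimeSeries,
    include_instruction: bool = True,
    baseline_condition: str = "fixation",
) -> PSCSummary:
    """PSC of every scan against the run-wise fixation baseline.

    Raises if any ROI's fixation mean is zero (the formula divides by it)
    or if the series has no fixation scans.
    """
    schedule = series.schedule
    fix = schedule.mask(baseline_condition)
    if not fix.any():
        raise ValueError(f"series has no {baseline_condition!r} scans")
    baseline = series.data[fix].mean(axis=0)
    zero = np.isclose(baseline, 0.0)
    if zero.any():
        bad = [series.roi_names[i] for i in np.flatnonzero(zero)]
        raise ZeroDivisionError(f"zero fixation baseline for ROI(s) {bad}")
    psc = (series.data - baseline) / baseline * 100.0
    task = schedule.mask("task")
    if not include_instruction:
        task = task & ~np.array(schedule.instruction_scans)
    return PSCSummary(
        roi_names=series.roi_names,
        psc_per_scan=psc,
        psc_task_mean=psc[task].mean(axis=0),
        baseline=baseline,
    )


def group_psc_table(
    group: list[ROITimeSeries], include_instruction: bool = True
) -> pd.DataFrame:
    """Per-subject, per-ROI task-mean PSC (long format)."""
    rows = []
    for series in group:
        summary = percent_signal_change(series, include_instruction)
        for roi, value in zip(summary.roi_names, summary.psc_task_mean):
            rows.append(
                {"subject_id": series.subject_id, "roi": roi, "psc_task_mean": value}
            )
    return pd.DataFrame(rows)
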