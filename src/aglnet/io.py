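"""Delimited-text I/O for ROI series, ground-truth networks and edge lists.

Group ROI series travel as a long CSV (subject_id, scan_index, condition,
one column per ROI) with a JSON sidecar holding the sampling interval and
block count, from which the schedule is reconstructed and checked against
the stored condition labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    ConnectivityGroundTruth,
    ROITimeSeries,
    make_schedule,
)
from .usem import NetworkEdge, NetworkReport, FitIndices

__all__ = [
    "save_truth",
    "load_truth",
    "save_group_series",
    "load_group_series",
    "save_network",
    "load_network",
]


def save_truth(truth: ConnectivityGroundTruth, path: str | Path) -> None:
    doc = {
        "roi_names": list(truth.roi_names),
        "A": truth.A.tolist(),
        "Phi": truth.Phi.tolist(),
        "noise_sd": truth.noise_sd.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_truth(path: str | Path) -> ConnectivityGroundTruth:
    doc = json.loads(Path(path).read_text())
    return ConnectivityGroundTruth(
        A=np.asarray(doc["A"], dtype=float),
        Phi=np.asarray(doc["Phi"], dtype=float),
        noise_sd=np.asarray(doc["noise_sd"], dtype=float),
        roi_names=tuple(doc["roi_names"]),
    )


def save_group_series(group: list[ROITimeSeries], path: str | Path) -> None:
    """Long CSV plus a '<path>.meta.json' sidecar."""
    path = Path(path)
    frame = pd.concat([s.to_frame() for s in group], ignore_index=True)
    frame.to_csv(path, index=False)
    schedule = group[0].schedule
    meta = {
        "tr_seconds": schedule.tr_seconds,
        "n_blocks": schedule.n_blocks,
        "roi_names": list(group[0].roi_names),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_group_series(path: str | Path) -> list[ROITimeSeries]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    schedule = make_schedule(meta["n_blocks"], meta["tr_seconds"])
    roi_names = tuple(meta["roi_names"])
    frame = pd.read_csv(path)
    out = []
    for subject_id, sub in frame.groupby("subject_id", sort=False):
        sub = sub.sort_values("scan_index")
        if tuple(sub["condition"]) != schedule.condition_labels:
            raise ValueError(
                f"stored condition labels for {subject_id} do not match the "
                "schedule reconstructed from the sidecar metadata"
            )
        out.append(
            ROITimeSeries(
                subject_id=str(subject_id),
                data=sub[list(roi_names)].to_numpy(),
                tr_seconds=meta["tr_seconds"],
                schedule=schedule,
                roi_names=roi_names,
            )
        )
    return out


def save_network(report: NetworkReport, path: str | Path) -> None:
    """Edge list CSV at full float precision (round-trips to 1e-12)."""
    df = report.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    fit_doc = {
        "chi2": report.fit.chi2,
        "df": report.fit.df,
        "rmsea": report.fit.rmsea,
        "srmr": report.fit.srmr,
        "nnfi": report.fit.nnfi,
        "cfi": report.fit.cfi,
        "n_effective": report.fit.n_effective,
        "saturated": report.fit.saturated,
        "roi_names": list(report.roi_names),
    }
    p = Path(path)
    p.with_suffix(p.suffix + ".fit.json").write_text(json.dumps(fit_doc, indent=1))


def load_network(path: str | Path) -> NetworkReport:
    p = Path(path)
    df = pd.read_csv(p)
    doc = json.loads(p.with_suffix(p.suffix + ".fit.json").read_text())
    fit = FitIndices(
        chi2=doc["chi2"],
        df=doc["df"],
        rmsea=doc["rmsea"],
        srmr=doc["srmr"],
        nnfi=doc["nnfi"],
        cfi=doc["cfi"],
        n_effective=doc["n_effective"],
        saturated=doc["saturated"],
    )
    edges = tuple(
        NetworkEdge(
            source=row.source,
            target=row.target,
            kind=row.kind,
            weight=float(row.weight),
            se=float(row.se),
        )
        for row in df.itertuples()
    )
    return NetworkReport(edges=edges, fit=fit, roi_names=tuple(doc["roi_names"]))
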