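"""File formats: nuclei tables (CSV), module files (JSON), QC reports.

Nuclei tables are plain CSV with a header comment carrying the slide
dimensions::

    # wsi_dims=1000.0,800.0
    wsi_id,x,y,is_debris,f_000,f_001,...

Module files are a single JSON document holding the calibrated references
(histogram columns, reduction index lists, weights), the shared bounds, the
parameter combination and the format version; they round-trip exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationReport, QcModule, ReferenceModel
from .data import NucleusTable, WsiBatch, default_feature_ids
from .qc import QcReport
from .representation import (
    DistributionMatrix,
    NormalizationBounds,
    ReductionMatrix,
)
from .search_params import ParamCombination

MODULE_FORMAT_VERSION = 1
_DIMS_PREFIX = "# wsi_dims="


def write_nuclei_table(table: NucleusTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"{_DIMS_PREFIX}{table.width},{table.height}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["wsi_id", "x", "y", "is_debris"] + default_feature_ids(table.n_feat)
        )
        for k in range(table.n):
            writer.writerow(
                [table.wsi_id, repr(float(table.x[k])), repr(float(table.y[k])),
                 int(table.is_debris[k])]
                + [repr(float(v)) for v in table.features[k]]
            )


def write_batch(batch: WsiBatch, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in batch.tables:
        p = directory / f"{table.wsi_id}.csv"
        write_nuclei_table(table, p)
        paths.append(p)
    return paths


def _read_one_file(path: Path) -> list[NucleusTable]:
    with path.open() as fh:
        first = fh.readline()
    if not first.startswith(_DIMS_PREFIX):
        raise ValueError(f"{path}: missing '{_DIMS_PREFIX}' header comment")
    width, height = (float(v) for v in first[len(_DIMS_PREFIX):].strip().split(","))
    df = pd.read_csv(path, skiprows=1)
    required = ["wsi_id", "x", "y", "is_debris"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    feat_cols = [c for c in df.columns if c not in required]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns found")
    values = df[feat_cols].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"{path}: non-finite feature value at row {int(bad[0, 0])}")
    tables = []
    for wsi_id, group in df.groupby("wsi_id", sort=False):
        tables.append(
            NucleusTable(
                wsi_id=str(wsi_id),
                x=group["x"].to_numpy(dtype=float),
                y=group["y"].to_numpy(dtype=float),
                is_debris=group["is_debris"].to_numpy(dtype=int).astype(bool),
                features=group[feat_cols].to_numpy(dtype=float),
                width=width,
                height=height,
            )
        )
    return tables


def read_nuclei_tables(paths: list[str | Path], pipeline_id: str = "input") -> WsiBatch:
    """Assemble one batch from nuclei-table files (one table per WSI group)."""
    if not paths:
        raise ValueError("no input files")
    tables: list[NucleusTable] = []
    n_feat: int | None = None
    for p in sorted(Path(p) for p in paths):
        for t in _read_one_file(p):
            if n_feat is None:
                n_feat = t.n_feat
            elif t.n_feat != n_feat:
                raise ValueError(
                    f"{p}: feature count {t.n_feat} differs from {n_feat}"
                )
            tables.append(t)
    return WsiBatch(pipeline_id=pipeline_id, tables=tables)


def _dist_to_json(F: DistributionMatrix) -> dict:
    return {
        "columns": F.columns.tolist(),
        "feature_ids": F.feature_ids,
        "in_range_counts": F.in_range_counts.tolist(),
    }


def _dist_from_json(d: dict) -> DistributionMatrix:
    F = DistributionMatrix(
        columns=np.asarray(d["columns"], dtype=float),
        feature_ids=list(d["feature_ids"]),
        in_range_counts=np.asarray(d["in_range_counts"], dtype=int),
    )
    sums = F.columns.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("loaded histogram columns are not column-stochastic")
    return F


def save_module(module: QcModule, path: str | Path) -> None:
    doc = {
        "format_version": MODULE_FORMAT_VERSION,
        "params": module.params.to_dict(),
        "beta": module.beta,
        "n_bin": module.n_bin,
        "bounds": {
            "lower": module.bounds.lower.tolist(),
            "upper": module.bounds.upper.tolist(),
        },
        "references": [
            {
                "id": r.reference_id,
                "reduction": list(r.P.indices),
                "n_feat_in": r.P.n_feat_in,
                "alpha": r.alpha,
                "R": _dist_to_json(r.R),
            }
            for r in module.references
        ],
        "validation_full": (
            None
            if module.validation_full is None
            else [_dist_to_json(F) for F in module.validation_full]
        ),
        "diagnostics": (
            None
            if module.diagnostics is None
            else {
                "distance_matrix": module.diagnostics.distance_matrix.tolist(),
                "diagonal_ok": module.diagnostics.diagonal_ok.tolist(),
                "accuracy": module.diagnostics.accuracy,
                "alerts": [list(a) for a in module.diagnostics.alerts],
            }
        ),
    }
    Path(path).write_text(json.dumps(doc))


def load_module(path: str | Path) -> QcModule:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODULE_FORMAT_VERSION:
        raise ValueError(f"unsupported module format: {doc.get('format_version')}")
    bounds = NormalizationBounds(
        lower=np.asarray(doc["bounds"]["lower"], dtype=float),
        upper=np.asarray(doc["bounds"]["upper"], dtype=float),
    )
    references = [
        ReferenceModel(
            reference_id=r["id"],
            R=_dist_from_json(r["R"]),
            P=ReductionMatrix(
                indices=tuple(int(i) for i in r["reduction"]),
                n_feat_in=int(r["n_feat_in"]),
            ),
            alpha=float(r["alpha"]),
            bounds=bounds,
        )
        for r in doc["references"]
    ]
    diagnostics = None
    if doc.get("diagnostics") is not None:
        d = doc["diagnostics"]
        diagnostics = CalibrationReport(
            distance_matrix=np.asarray(d["distance_matrix"], dtype=float),
            diagonal_ok=np.asarray(d["diagonal_ok"], dtype=bool),
            accuracy=float(d["accuracy"]),
            alerts=[tuple(a) for a in d["alerts"]],
        )
    validation_full = None
    if doc.get("validation_full") is not None:
        validation_full = [_dist_from_json(F) for F in doc["validation_full"]]
    return QcModule(
        references=references,
        params=ParamCombination.from_dict(doc["params"]),
        beta=float(doc["beta"]),
        n_bin=int(doc["n_bin"]),
        diagnostics=diagnostics,
        validation_full=validation_full,
    )


def append_report(report: QcReport, path: str | Path) -> None:
    """Append one QC report as a JSON line."""
    with Path(path).open("a") as fh:
        fh.write(json.dumps(report.to_dict()) + "\n")


def read_reports(path: str | Path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


def reports_to_csv(reports: list[dict], path: str | Path) -> pd.DataFrame:
    """Flatten a report stream into a per-batch CSV (quality time series)."""
    rows = []
    for rep in reports:
        row = {
            "batch_id": rep["batch_id"],
            "tested_reference": rep.get("tested_reference"),
            "compatibility": rep.get("compatibility"),
            "quality": rep.get("quality"),
            "best_reference": rep.get("best_reference"),
            "alerts": ";".join(a[0] for a in rep.get("alerts", [])),
        }
        for ref_id, d, feat in zip(
            rep["reference_ids"], rep["distance_vector"], rep["argmax_features"]
        ):
            row[f"d_{ref_id}"] = d
            row[f"argmax_{ref_id}"] = feat
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
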