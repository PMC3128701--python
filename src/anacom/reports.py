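"""Tabular outputs: region reports and group summary tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .core import AnacomResult
from .subjects import control_scores, measure_columns, validate_subject_table

REGION_COLUMNS = ["label", "x", "y", "z", "p_raw", "H", "n_patients",
                  "size_mm3"]


def regions_to_frame(result: AnacomResult) -> pd.DataFrame:
    """Significant regions as a table (MNI mm, raw p, Holm threshold)."""
    rows = [
        {"label": r.label, "x": r.mni_xyz[0], "y": r.mni_xyz[1],
         "z": r.mni_xyz[2], "p_raw": r.p_raw, "H": result.holm.H,
         "n_patients": r.n_patients, "size_mm3": r.size_mm3}
        for r in result.regions
    ]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def report_metadata(result: AnacomResult) -> dict:
    return {
        "measure": result.measure,
        "alpha": result.alpha,
        "min_overlap": result.min_overlap,
        "n_subregions": len(result.subregions),
        "n_tested": len(result.tested),
        "n_skipped": len(result.skipped),
        "n_significant": len(result.regions),
        "holm": {
            "m": result.holm.m,
            "H": result.holm.H,
            "largest_rejected_p": result.holm.largest_rejected_p,
        },
        "warnings": list(result.warnings),
    }


def write_region_report(result: AnacomResult, csv_path: str | Path,
                        json_path: str | Path) -> None:
    frame = regions_to_frame(result)
    frame.to_csv(csv_path, index=False)
    payload = {
        "metadata": report_metadata(result),
        "regions": frame.to_dict(orient="records"),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def group_summary(subjects: pd.DataFrame,
                  measures: list[str] | None = None) -> pd.DataFrame:
    """Patients-vs-controls Mann-Whitney summary, one row per measure."""
    validate_subject_table(subjects)
    measures = measures or measure_columns(subjects)
    rows = []
    patients = subjects[subjects["group"] == "patient"]
    for m in measures:
        p_vals = patients[m].dropna().to_numpy(float)
        c_vals = control_scores(subjects, m)
        row = {
            "measure": m,
            "n_patients": len(p_vals), "n_controls": len(c_vals),
            "patient_mean": float(np.mean(p_vals)) if len(p_vals) else np.nan,
            "patient_sd": float(np.std(p_vals, ddof=1)) if len(p_vals) > 1 else np.nan,
            "control_mean": float(np.mean(c_vals)) if len(c_vals) else np.nan,
            "control_sd": float(np.std(c_vals, ddof=1)) if len(c_vals) > 1 else np.nan,
        }
        if len(p_vals) >= 2 and len(c_vals) >= 2:
            t = stats.rank_sum(p_vals, c_vals)
            row.update(U=t.statistic, z=t.z, p=t.p)
        else:
            row.update(U=np.nan, z=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Stable hash of a run configuration for report provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
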