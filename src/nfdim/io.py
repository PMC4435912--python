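"""Reading core TIFFs and clinical tables; writing result artifacts.

The pixel calibration is always taken from configuration, never from TIFF
tags; a conflicting resolution tag is logged but not trusted, because TMA
export pipelines frequently write stale metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cohort import CoreRecord, PatientRecord
from .errors import InvalidImageError
from .fractal import CoreImage, QCInfo, ThresholdSweepResult

log = logging.getLogger(__name__)

#: Expected clinical CSV columns (one row per patient).
CLINICAL_COLUMNS = [
    "patient_id", "time_months", "dss_event",
    "gender", "pt_stage", "pn_status", "smoking", "alcohol",
    "differentiation", "treatment", "ki67_group",
]


def read_core_tiff(
    path: str | Path,
    pixel_size_um: float,
    core_id: str | None = None,
    patient_id: str = "",
    qc: QCInfo | None = None,
) -> CoreImage:
    """Load a single-channel grayscale TIFF as a calibrated CoreImage."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        page = tif.pages[0]
        if page.tags.get("XResolution") is not None:
            log.info("%s: TIFF resolution tags present; using configured "
                     "pixel size %.4f um/px", path.name, pixel_size_um)
    if pixels.ndim != 2:
        raise InvalidImageError(
            f"{path.name}: expected single-channel grayscale, got shape {pixels.shape}"
        )
    return CoreImage(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        core_id=core_id or path.stem,
        patient_id=patient_id,
        qc=qc or QCInfo(),
    )


def write_core_tiff(path: str | Path, image: CoreImage) -> None:
    tifffile.imwrite(str(path), image.pixels)


def sweep_to_json(result: ThresholdSweepResult) -> dict:
    """Full sweep as a JSON-serializable audit record."""
    return {
        "nfd": result.nfd,
        "argmax_threshold": result.argmax_threshold,
        "n_thresholds_fit": int(len(result.thresholds)),
        "n_skipped": int(result.n_skipped),
        "min_r_squared": result.min_r_squared,
        "points": [
            {
                "threshold": int(t),
                "fd": float(fd),
                "box_sizes_px": result.curves[int(t)].box_sizes_px.tolist(),
                "counts": result.curves[int(t)].counts.tolist(),
                "r_squared": result.curves[int(t)].r_squared,
            }
            for t, fd in zip(result.thresholds.tolist(), result.fd_values.tolist())
        ],
    }


def core_results_frame(rows: list[dict]) -> pd.DataFrame:
    """Per-core results table with a stable column order."""
    return pd.DataFrame(
        rows,
        columns=["core_id", "patient_id", "nfd", "argmax_threshold",
                 "n_thresholds_fit", "min_r_squared"],
    )


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "time_months", "dss_event")
               if c not in df.columns]
    if missing:
        raise InvalidImageError(  # surfaced by the CLI as a data error
            f"clinical table {Path(path).name} lacks required columns {missing}"
        )
    return df


def read_core_csv(path: str | Path) -> list[CoreRecord]:
    """Per-core CSV (core_id, patient_id, nfd[, li_grade, qc flags])."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CoreRecord(
                core_id=str(d["core_id"]),
                patient_id=str(d["patient_id"]),
                nfd=None if pd.isna(d.get("nfd")) else float(d["nfd"]),
                li_grade=(
                    None if pd.isna(d.get("li_grade", np.nan))
                    else int(d["li_grade"])
                ),
                qc=QCInfo(
                    in_focus=bool(d.get("in_focus", True)),
                    not_folded=bool(d.get("not_folded", True)),
                    tumor_cell_count=int(d.get("tumor_cell_count", 10_000)),
                ),
            )
        )
    return records


def merge_clinical(
    patients: list[PatientRecord], clinical: pd.DataFrame
) -> list[PatientRecord]:
    """Attach covariates and outcome from the clinical table, in place."""
    indexed = clinical.set_index("patient_id")
    covariate_cols = [
        c for c in clinical.columns
        if c not in ("patient_id", "time_months", "dss_event", "li_grade")
    ]
    for p in patients:
        if p.patient_id not in indexed.index:
            continue
        row = indexed.loc[p.patient_id]
        p.time_months = float(row["time_months"])
        p.dss_event = bool(row["dss_event"])
        p.covariates = {
            c: (None if pd.isna(row[c]) else row[c]) for c in covariate_cols
        }
    return patients


def patients_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "mean_nfd": p.mean_nfd,
            "nfd_group": p.nfd_group,
            "li_max": p.li_max,
            "li_group": p.li_group,
            "time_months": p.time_months,
            "dss_event": p.dss_event,
        }
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
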