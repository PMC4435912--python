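"""End-to-end pipeline stages behind the command-line interface.

Each stage is a plain function over paths and configuration so that the
analysis drivers, the tests and the CLI all share one implementation:

* :func:`score_directory` — nFD per core image -> per-core CSV + sweep JSON
* :func:`analyze` — per-core CSV + clinical CSV -> patient table, cut-point
  audit, association table, Cox table, KM step functions
* :func:`simulate` — synthetic cohort (+ optional image panel) -> fixture
  bundle on disk
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, io, survival
from .errors import NfdimError, NoSignalError
from .fractal import QCInfo, sweep_nfd
from .synthetic import SyntheticCohortConfig, SyntheticImageConfig, generate_cohort, render_core

log = logging.getLogger(__name__)

#: Table-1-style covariates tested for association with nFD group.
ASSOCIATION_COVARIATES = [
    "gender", "pt_stage", "pn_status", "smoking", "alcohol",
    "differentiation", "treatment", "ki67_group", "li_group",
]

MULTIVARIATE_SET = ["nfd_group", "pt_stage", "pn_status"]
MULTIVARIATE_SET_RT = MULTIVARIATE_SET + ["treatment"]


@dataclasses.dataclass
class RunConfig:
    """Round-trippable run parameters shared by the pipeline commands."""

    image_dir: str | None = None
    clinical_csv: str | None = None
    core_csv: str | None = None
    out_dir: str = "results"
    pixel_size_um: float = 0.468
    min_group_fraction: float = 0.10
    adjust_for_rt: bool = False
    rank_test: str = "wilcoxon"
    seed: int = 0

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, data: dict) -> "RunConfig":
        return cls(**{k: v for k, v in data.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_json(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def score_directory(config: RunConfig) -> pd.DataFrame:
    """Score every TIFF under ``image_dir``; write per-core CSV + sweep JSON.

    QC metadata is joined from an optional ``qc.csv`` in the image
    directory (core_id, patient_id, in_focus, not_folded,
    tumor_cell_count); unreadable images are logged and skipped.
    """
    image_dir = Path(config.image_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(image_dir.glob("*.tif")) + sorted(image_dir.glob("*.tiff"))
    if not paths:
        raise NfdimError(f"no TIFF images under {image_dir}")
    qc_meta = _read_qc(image_dir / "qc.csv")
    log.info("scoring %d cores (config %s)", len(paths), config.config_hash())

    rows, sweeps, n_failed = [], {}, 0
    for path in paths:
        meta = qc_meta.get(path.stem, {})
        try:
            image = io.read_core_tiff(
                path,
                pixel_size_um=config.pixel_size_um,
                patient_id=str(meta.get("patient_id", "")),
                qc=QCInfo(
                    in_focus=bool(meta.get("in_focus", True)),
                    not_folded=bool(meta.get("not_folded", True)),
                    tumor_cell_count=int(meta.get("tumor_cell_count", 10_000)),
                ),
            )
            result = sweep_nfd(image)
        except NoSignalError as exc:
            log.warning("flagged (no signal): %s", exc)
            rows.append({"core_id": path.stem,
                         "patient_id": str(meta.get("patient_id", "")),
                         "nfd": np.nan, "argmax_threshold": np.nan,
                         "n_thresholds_fit": 0, "min_r_squared": np.nan})
            continue
        except NfdimError as exc:
            log.warning("skipping %s: %s", path.name, exc)
            n_failed += 1
            continue
        rows.append({
            "core_id": image.core_id,
            "patient_id": image.patient_id,
            "nfd": result.nfd,
            "argmax_threshold": result.argmax_threshold,
            "n_thresholds_fit": len(result.thresholds),
            "min_r_squared": result.min_r_squared,
        })
        sweeps[image.core_id] = io.sweep_to_json(result)
    if n_failed == len(paths):
        raise NfdimError("all images failed to score")
    frame = io.core_results_frame(rows)
    frame.to_csv(out_dir / "core_nfd.csv", index=False)
    io.write_json(out_dir / "sweeps.json", sweeps)
    return frame


def _read_qc(path: Path) -> dict[str, dict]:
    if not path.exists():
        return {}
    df = pd.read_csv(path)
    return {str(r["core_id"]): dict(r) for _, r in df.iterrows()}


def analyze(config: RunConfig) -> dict[str, Path]:
    """Aggregate, dichotomize and test; write the report artifacts.

    Returns a name -> path map of everything written: patients.csv,
    cutpoint.json, association.csv, cox.csv and the Kaplan-Meier step
    functions for the whole cohort and the treatment subgroups.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cores = io.read_core_csv(config.core_csv)
    clinical = io.read_clinical_csv(config.clinical_csv)

    kept, dropped = cohort.qc_filter(cores)
    for core, reason in dropped:
        log.info("QC drop %s: %s", core.core_id, reason)
    by_patient: dict[str, list] = {}
    for core in kept:
        by_patient.setdefault(core.patient_id, []).append(core)
    patients = [cohort.aggregate_patient(cs) for cs in by_patient.values()]
    io.merge_clinical(patients, clinical)
    cohort.dichotomize_li(patients)

    cut = cohort.optimal_cutpoint(patients, config.min_group_fraction)
    cohort.apply_cutpoint(patients, cut.cut_value)

    artifacts: dict[str, Path] = {}
    frame = io.patients_frame(patients)
    frame.to_csv(out_dir / "patients.csv", index=False)
    artifacts["patients"] = out_dir / "patients.csv"

    io.write_json(out_dir / "cutpoint.json", {
        "cut_value": cut.cut_value,
        "chi_square": cut.chi_square,
        "n_low": cut.n_low,
        "n_high": cut.n_high,
        "advisory_corrected_p": cut.advisory_corrected_p,
        "scanned": cut.scanned,
    })
    artifacts["cutpoint"] = out_dir / "cutpoint.json"

    assoc = association_table(patients, rank_test=config.rank_test)
    assoc.to_csv(out_dir / "association.csv", index=False)
    artifacts["association"] = out_dir / "association.csv"

    cox = cox_table(patients, adjust_for_rt=config.adjust_for_rt)
    cox.to_csv(out_dir / "cox.csv", index=False)
    artifacts["cox"] = out_dir / "cox.csv"

    for name, path in km_tables(patients, out_dir).items():
        artifacts[name] = path
    return artifacts


def association_table(patients, rank_test: str = "wilcoxon") -> pd.DataFrame:
    """Table-1-shaped association report: one row per covariate level."""
    rows = []
    for covariate in ASSOCIATION_COVARIATES:
        try:
            table = association.crosstab(patients, covariate)
        except NfdimError:
            continue
        if table.degenerate:
            rows.append({"covariate": covariate, "level": "(degenerate)",
                         "test": "none", "p": np.nan})
            continue
        p, test_name = association.exact_rxc(table)
        total = table.counts.sum()
        for i, level in enumerate(table.row_labels):
            n_low, n_high = table.counts[i]
            rows.append({
                "covariate": covariate, "level": level,
                "n": int(n_low + n_high),
                "pct_of_cohort": 100.0 * (n_low + n_high) / total,
                "n_low": int(n_low), "n_high": int(n_high),
                "test": test_name, "p": p,
            })
    # continuous nFD against Ki67 and LI groups
    for covariate in ("ki67_group", "li_group"):
        groups = _nfd_by_group(patients, covariate)
        if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
            stat, p = association.rank_compare(
                groups["low"], groups["high"], method=rank_test
            )
            rows.append({"covariate": f"nfd_by_{covariate}", "level": "low vs high",
                         "n": sum(len(v) for v in groups.values()),
                         "test": rank_test, "p": p})
    return pd.DataFrame(rows)


def _nfd_by_group(patients, covariate: str) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for r in patients:
        value = r.li_group if covariate == "li_group" else r.covariates.get(covariate)
        if value is not None and r.mean_nfd is not None:
            groups.setdefault(str(value), []).append(r.mean_nfd)
    return groups


def cox_table(patients, adjust_for_rt: bool = False) -> pd.DataFrame:
    """Univariate fits for nFD, pT-stage and pN-status plus the
    multivariate model (optionally also adjusted for radiotherapy)."""
    surv = survival.prepare_dss([p for p in patients if p.time_months is not None])
    rows = []
    for covariate in ("nfd_group", "pt_stage", "pn_status"):
        try:
            res = survival.cox_fit(surv, [covariate])
        except NfdimError as exc:
            log.warning("univariate %s: %s", covariate, exc)
            continue
        rows.append(_cox_row("univariate", covariate, res))
    multi = MULTIVARIATE_SET_RT if adjust_for_rt else MULTIVARIATE_SET
    try:
        res = survival.cox_fit(surv, multi)
        for covariate in multi:
            rows.append(_cox_row("multivariate", covariate, res))
    except NfdimError as exc:
        log.warning("multivariate model: %s", exc)
    return pd.DataFrame(rows)


def _cox_row(model: str, covariate: str, res) -> dict:
    t = res.table.loc[covariate]
    return {"model": model, "covariate": covariate,
            "hazard_ratio": t["hazard_ratio"], "ci_low": t["ci_low"],
            "ci_high": t["ci_high"], "p": t["p"],
            "n": res.n, "n_events": res.n_events}


def km_tables(patients, out_dir: Path) -> dict[str, Path]:
    """KM step functions by nFD group: all patients and RT subgroups."""
    out: dict[str, Path] = {}
    surv = survival.prepare_dss([p for p in patients if p.time_months is not None])
    subsets = {"km_all": surv}
    if any(r.covariates.get("treatment") is not None for r in surv):
        subsets["km_rt"] = [r for r in surv
                            if r.covariates.get("treatment") == "surgery+RT"]
        subsets["km_no_rt"] = [r for r in surv
                               if r.covariates.get("treatment") == "surgery"]
    else:
        log.warning("no treatment column: radiotherapy subgroup curves skipped")
    for name, records in subsets.items():
        frames = []
        for grp in ("low", "high"):
            grp_records = [r for r in records if r.group == grp]
            if not grp_records:
                continue
            df = survival.km_estimate(grp_records)
            df.insert(0, "nfd_group", grp)
            frames.append(df)
        if not frames:
            continue
        path = out_dir / f"{name}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        out[name] = path
    return out


def simulate(
    out_dir: str | Path,
    cohort_config: SyntheticCohortConfig | None = None,
    n_images: int = 0,
    image_config: SyntheticImageConfig | None = None,
) -> dict[str, Path]:
    """Write a synthetic fixture bundle: cohort CSVs, truth CSV, images."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or SyntheticCohortConfig()
    patients, cores, truth = generate_cohort(cohort_config)

    artifacts: dict[str, Path] = {}
    clinical = io.patients_frame(patients).drop(
        columns=["mean_nfd", "nfd_group", "li_max", "li_group"]
    )
    clinical.to_csv(out_dir / "clinical.csv", index=False)
    artifacts["clinical"] = out_dir / "clinical.csv"

    pd.DataFrame(
        [{"core_id": c.core_id, "patient_id": c.patient_id, "nfd": c.nfd,
          "li_grade": c.li_grade, "in_focus": c.qc.in_focus,
          "not_folded": c.qc.not_folded,
          "tumor_cell_count": c.qc.tumor_cell_count} for c in cores]
    ).to_csv(out_dir / "cores.csv", index=False)
    artifacts["cores"] = out_dir / "cores.csv"

    pd.DataFrame(truth.patients).to_csv(out_dir / "truth.csv", index=False)
    artifacts["truth"] = out_dir / "truth.csv"
    (out_dir / "config.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in sorted(
            dataclasses.asdict(cohort_config).items()))
    )
    artifacts["config"] = out_dir / "config.txt"

    if n_images > 0:
        image_dir = out_dir / "images"
        image_dir.mkdir(exist_ok=True)
        base = image_config or SyntheticImageConfig(size_px=512, n_nuclei=300)
        for k in range(n_images):
            cfg = dataclasses.replace(base, seed=base.seed + k)
            image, _ = render_core(cfg)
            io.write_core_tiff(image_dir / f"core_{k:03d}.tif", image)
        artifacts["images"] = image_dir
    return artifacts
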