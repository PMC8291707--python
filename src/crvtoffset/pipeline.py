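"""Pipeline orchestration: generate → measure → exclude → analyse → report.

``run_pipeline`` composes the package's stages into a reproducible run.
In synthetic mode the cohort's offset indices and trunk angles are routed
through the geometry engine — per-eye delineations are synthesised and
re-measured — rather than copied from the generator's targets, so every
run exercises the full measurement path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import Calibration, load_calibration
from .cohort import apply_exclusions, generate_cohort, synthesize_eye_geometry
from .geometry import measure_crvt
from .io import read_cohort_csv, write_cohort_csv
from .stats import (
    DEFAULT_PREDICTORS,
    MatchedPairLogit,
    OffsetIndexGEE,
    angle_correlation,
    cubic_argmin,
    loess_curve,
    paired_compare,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "measure_synthetic_eyes", "analyse_cohort"]

log = logging.getLogger("crvtoffset")

#: Variables reported in the paired-comparison table, in display order.
TABLE1_VARIABLES = [
    "baseline_iop_mmhg",
    "axial_length_mm",
    "angular_deviation_deg",
    "offset_index",
    "bmo_area_mm2",
    "beta_ppa_mm2",
    "gamma_ppa_mm2",
    "rnfl_thickness_um",
    "mrw_um",
    "md_db",
    "psd_db",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "from_files"
    calibration_path: Optional[str] = None  # packaged default when None
    n_patients: Optional[int] = None
    seed: int = 42
    cohort_csv: Optional[str] = None
    out_dir: str = "crvtoffset_run"
    loess_span: float = 0.75
    al_range: Tuple[float, float] = (20.0, 30.0)
    run_table1: bool = True
    run_table2: bool = True
    run_table3: bool = True
    run_loess: bool = True
    run_angles: bool = True
    make_plots: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "from_files"):
            raise ValueError(f"mode must be synthetic or from_files, got {self.mode!r}")
        if self.mode == "from_files" and not self.cohort_csv:
            raise ValueError("from_files mode requires cohort_csv")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "al_range" in data:
            data["al_range"] = tuple(data["al_range"])
        return cls(**data)


@dataclass
class RunReport:
    """What a run produced: seeds, tallies, outputs, provenance."""

    mode: str
    seed: int
    n_patients: int
    package_version: str
    calibration_checksum: Optional[str]
    exclusion_tally: Dict[str, int]
    n_included_patients: int
    n_forced_offset_eyes: int
    outputs: Dict[str, str]
    row_counts: Dict[str, int]
    gee_argmin_al_mm: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def measure_synthetic_eyes(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Replace generator targets with geometry-engine measurements.

    For every eye a 48-point delineation is synthesised at the target
    offset/angle (or with the trunk outside the BMO) and measured with
    the same operations an observer's delineations would go through; the
    measured offset index and angular deviation overwrite the targets.
    """
    rng_seeds = np.random.SeedSequence([int(seed), 0x9E0]).generate_state(len(cohort))
    out = cohort.copy()
    offsets = np.empty(len(out))
    angles = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        bmo_area = max(float(row["bmo_area_mm2"]), 0.5)
        delin = synthesize_eye_geometry(
            target_index=float(row["offset_index"]),
            target_angle_deg=float(row["angular_deviation_deg"]),
            laterality=row["laterality"],
            bmo_area=bmo_area,
            seed=int(rng_seeds[i]),
            crvt_outside=bool(row["crvt_outside"]),
            patient_id=row["patient_id"],
        )
        m = measure_crvt(delin)
        offsets[i] = m.offset_index
        angles[i] = m.angular_deviation_deg
    out["offset_index"] = offsets
    out["angular_deviation_deg"] = angles
    return out


def _loess_table(cohort: pd.DataFrame, span: float) -> pd.DataFrame:
    frames = []
    for role, grp in cohort.groupby("eye_role"):
        sub = grp[["axial_length_mm", "offset_index"]].dropna()
        x = sub["axial_length_mm"].to_numpy(float)
        y = sub["offset_index"].to_numpy(float)
        grid = np.linspace(x.min(), x.max(), 100)
        fitted = loess_curve(x, y, span=span, query_points=grid)
        frames.append(
            pd.DataFrame(
                {"eye_role": role, "axial_length_mm": grid, "offset_index_fit": fitted}
            )
        )
    return pd.concat(frames, ignore_index=True)


def analyse_cohort(
    cohort: pd.DataFrame,
    out_dir: Path,
    config: RunConfig,
    calibration: Optional[Calibration] = None,
) -> Tuple[Dict[str, str], Dict[str, int], Optional[float]]:
    """Run the enabled statistical stages and write their tables."""
    outputs: Dict[str, str] = {}
    rows: Dict[str, int] = {"cohort_eyes": len(cohort)}
    argmin_al = None

    if config.run_table1:
        recs = []
        for var in TABLE1_VARIABLES:
            if var not in cohort.columns:
                continue
            try:
                pc = paired_compare(cohort, var)
            except (ValueError, KeyError) as exc:
                log.warning("paired comparison skipped for %s: %s", var, exc)
                continue
            recs.append(dataclasses.asdict(pc) | {"flags": ";".join(pc.flags)})
        table1 = pd.DataFrame(recs)
        path = out_dir / "table1.csv"
        table1.to_csv(path, index=False)
        outputs["table1"] = str(path)
        rows["table1"] = len(table1)
        log.info("table1: %d paired comparisons", len(table1))

    if config.run_table2:
        predictors = [p for p in DEFAULT_PREDICTORS if p in cohort.columns]
        res = MatchedPairLogit(cohort, predictors).fit()
        uni = res.univariable[["or", "ci_low", "ci_high", "p"]].add_prefix("uni_")
        multi = res.multivariable[["or", "ci_low", "ci_high", "p"]].add_prefix("multi_")
        table2 = uni.join(multi, how="left")
        table2.index.name = "predictor"
        path = out_dir / "table2.csv"
        table2.to_csv(path)
        outputs["table2"] = str(path)
        rows["table2"] = len(table2)
        log.info("table2: selected predictors %s", res.selected)

    if config.run_table3:
        res3 = OffsetIndexGEE(cohort).fit()
        table3 = res3.to_frame()
        table3.index.name = "term"
        path = out_dir / "table3.csv"
        table3.to_csv(path)
        outputs["table3"] = str(path)
        rows["table3"] = len(table3)
        am = res3.argmin(config.al_range)
        argmin_al = am.al_mm
        log.info(
            "table3: fitted cubic minimum at AL = %.2f mm (%s)",
            am.al_mm, "interior" if am.interior else am.flag,
        )

    if config.run_loess:
        loess = _loess_table(cohort, config.loess_span)
        path = out_dir / "fig2_loess.csv"
        loess.to_csv(path, index=False)
        outputs["loess"] = str(path)
        rows["loess"] = len(loess)
        if config.make_plots:
            outputs["loess_plot"] = _plot_loess(cohort, loess, out_dir)

    if config.run_angles and "rnfl_defect_angle_deg" in cohort.columns:
        recs = []
        for sub in ("all", "temporal_crvt", "nasal_crvt"):
            try:
                ac = angle_correlation(cohort, sub)
                recs.append({"subgroup": sub, "r": ac.r, "p": ac.p, "n": ac.n})
            except ValueError as exc:
                log.warning("angle correlation skipped for %s: %s", sub, exc)
                recs.append({"subgroup": sub, "r": np.nan, "p": np.nan, "n": 0})
        angles = pd.DataFrame(recs)
        path = out_dir / "angle_correlations.csv"
        angles.to_csv(path, index=False)
        outputs["angles"] = str(path)
        rows["angles"] = len(angles)

    return outputs, rows, argmin_al


def _plot_loess(cohort: pd.DataFrame, loess: pd.DataFrame, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"glaucoma": "tab:red", "control": "tab:blue"}
    for role, grp in cohort.groupby("eye_role"):
        ax.scatter(
            grp["axial_length_mm"], grp["offset_index"],
            s=12, alpha=0.5, color=colors[role], label=f"{role} eyes",
        )
    for role, grp in loess.groupby("eye_role"):
        ax.plot(
            grp["axial_length_mm"], grp["offset_index_fit"],
            color=colors[role], lw=2,
        )
    ax.set_xlabel("axial length (mm)")
    ax.set_ylabel("offset index")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = out_dir / "fig2_loess.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run and write all outputs under ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> RunReport:
    outputs: Dict[str, str] = {}
    calibration = None
    checksum = None

    if config.mode == "synthetic":
        calibration = load_calibration(config.calibration_path)
        checksum = calibration.source_sha256
        log.info("calibration %s (sha256 %s)", calibration.source_path, checksum)
        cohort = generate_cohort(calibration, config.n_patients, seed=config.seed)
        log.info("generated %d eyes (%d patients), seed %d",
                 len(cohort), cohort["patient_id"].nunique(), config.seed)
        cohort = measure_synthetic_eyes(cohort, seed=config.seed)
        full_path = out_dir / "cohort_full.csv"
        write_cohort_csv(cohort, full_path)
        outputs["cohort_full"] = str(full_path)
    else:
        cohort = read_cohort_csv(config.cohort_csv)
        if config.cohort_csv:
            checksum = hashlib.sha256(Path(config.cohort_csv).read_bytes()).hexdigest()
        log.info("loaded cohort %s: %d eyes", config.cohort_csv, len(cohort))

    if "exclusion_flag" in cohort.columns:
        included, tally = apply_exclusions(cohort)
    else:
        included, tally = cohort, {}
    n_forced = int(
        ((included.get("exclusion_flag") == "invisible_confirmed")
         & included.get("crvt_outside", False)).sum()
    ) if "exclusion_flag" in included.columns else 0
    log.info("exclusions: %s; %d patients included",
             tally, included["patient_id"].nunique())

    incl_path = out_dir / "cohort_included.csv"
    write_cohort_csv(included, incl_path)
    outputs["cohort_included"] = str(incl_path)

    stage_outputs, row_counts, argmin_al = analyse_cohort(
        included, out_dir, config, calibration
    )
    outputs.update(stage_outputs)

    report = RunReport(
        mode=config.mode,
        seed=config.seed,
        n_patients=int(cohort["patient_id"].nunique()),
        package_version=__version__,
        calibration_checksum=checksum,
        exclusion_tally=tally,
        n_included_patients=int(included["patient_id"].nunique()),
        n_forced_offset_eyes=n_forced,
        outputs=outputs,
        row_counts=row_counts,
        gee_argmin_al_mm=argmin_al,
    )
    (out_dir / "run_report.json").write_text(report.to_json())
    log.info("run complete: %d outputs", len(outputs))
    return report
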