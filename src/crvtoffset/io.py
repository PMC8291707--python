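"""Reading and writing delineation records, measurements and cohort tables.

Delineations travel as JSON (a list of per-eye records) or as a long CSV
with one margin point per row; measurements and cohorts are flat CSV.
All coordinates are millimetres, all angles degrees.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import (
    EyeDelineation,
    bmo_center_and_area,
    measure_crvt,
    ppa_areas,
    rnfl_defect_angle,
)

__all__ = [
    "read_delineations_json",
    "write_delineations_json",
    "read_delineations_csv",
    "measure_delineations",
    "write_cohort_csv",
    "read_cohort_csv",
]

PathLike = Union[str, Path]

#: Columns of a measurement table (one row per eye).
MEASUREMENT_COLUMNS = [
    "patient_id",
    "laterality",
    "offset_index",
    "angular_deviation_deg",
    "rnfl_defect_angle_deg",
    "rnfl_defect_width_deg",
    "bmo_area_mm2",
    "beta_ppa_mm2",
    "gamma_ppa_mm2",
    "flags",
]


def _delineation_to_record(d: EyeDelineation) -> dict:
    return {
        "patient_id": d.patient_id,
        "laterality": d.laterality,
        "margin": [[float(x), float(y)] for x, y in d.margin_points],
        "crvt": None if d.crvt_point is None else [d.crvt_point[0], d.crvt_point[1]],
        "crvt_outside_bmo": d.crvt_outside_bmo,
        "rnfl_defects": [[a, b] for a, b in d.rnfl_defects],
        "rpeo_area": d.rpeo_area,
        "cdm_area": d.cdm_area,
        "bmo_area": d.bmo_area_input,
    }


def _record_to_delineation(rec: dict) -> EyeDelineation:
    crvt = rec.get("crvt")
    return EyeDelineation(
        patient_id=str(rec["patient_id"]),
        laterality=rec["laterality"],
        margin_points=np.asarray(rec["margin"], dtype=float),
        crvt_point=None if crvt is None else (float(crvt[0]), float(crvt[1])),
        crvt_outside_bmo=bool(rec.get("crvt_outside_bmo", False)),
        rnfl_defects=tuple(
            (float(a), float(b)) for a, b in rec.get("rnfl_defects") or ()
        ),
        rpeo_area=rec.get("rpeo_area"),
        cdm_area=rec.get("cdm_area"),
        bmo_area_input=rec.get("bmo_area"),
    )


def write_delineations_json(delineations: Sequence[EyeDelineation], path: PathLike) -> None:
    records = [_delineation_to_record(d) for d in delineations]
    Path(path).write_text(json.dumps(records, indent=1))


def read_delineations_json(path: PathLike) -> List[EyeDelineation]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data["eyes"]
    return [_record_to_delineation(rec) for rec in data]


def read_delineations_csv(path: PathLike) -> List[EyeDelineation]:
    """Long-format CSV: one margin point per row.

    Required columns: ``patient_id, laterality, x_mm, y_mm``; point order
    is row order within each eye.  Optional eye-level columns (repeated
    on every row of the eye): ``crvt_x_mm, crvt_y_mm, crvt_outside_bmo,
    rpeo_area_mm2, cdm_area_mm2``.  RNFL defects are JSON-only.
    """
    df = pd.read_csv(path)
    out: List[EyeDelineation] = []
    for (pid, lat), grp in df.groupby(["patient_id", "laterality"], sort=False):
        margin = grp[["x_mm", "y_mm"]].to_numpy(float)
        outside = bool(grp["crvt_outside_bmo"].iloc[0]) if "crvt_outside_bmo" in grp else False
        crvt = None
        if not outside and "crvt_x_mm" in grp:
            cx, cy = grp["crvt_x_mm"].iloc[0], grp["crvt_y_mm"].iloc[0]
            if not (pd.isna(cx) or pd.isna(cy)):
                crvt = (float(cx), float(cy))
        def _opt(col):
            if col in grp and not pd.isna(grp[col].iloc[0]):
                return float(grp[col].iloc[0])
            return None
        out.append(
            EyeDelineation(
                patient_id=str(pid),
                laterality=str(lat),
                margin_points=margin,
                crvt_point=crvt,
                crvt_outside_bmo=outside,
                rpeo_area=_opt("rpeo_area_mm2"),
                cdm_area=_opt("cdm_area_mm2"),
            )
        )
    return out


def measure_delineations(delineations: Sequence[EyeDelineation]) -> pd.DataFrame:
    """Run the geometric measurements on each delineation.

    Returns one row per eye with the offset index, angular deviation,
    BMO area, RNFL-defect angles and PPA areas (where the input areas are
    available), and the accumulated measurement flags.
    """
    rows = []
    for d in delineations:
        m = measure_crvt(d)
        _, bmo_area = bmo_center_and_area(d.margin_points)
        flags = list(m.flags)
        defect = rnfl_defect_angle(d.rnfl_defects, d.laterality)
        beta_ppa = gamma_ppa = float("nan")
        if d.rpeo_area is not None and d.cdm_area is not None:
            ppa = ppa_areas(d.rpeo_area, d.cdm_area, d.bmo_area_input
                            if d.bmo_area_input is not None else bmo_area)
            beta_ppa, gamma_ppa = ppa.beta_zone_area, ppa.gamma_zone_area
            flags.extend(ppa.flags)
        rows.append(
            {
                "patient_id": d.patient_id,
                "laterality": d.laterality,
                "offset_index": m.offset_index,
                "angular_deviation_deg": m.angular_deviation_deg,
                "rnfl_defect_angle_deg": defect.midpoint_angle_deg if defect else math.nan,
                "rnfl_defect_width_deg": defect.angular_width_deg if defect else math.nan,
                "bmo_area_mm2": bmo_area,
                "beta_ppa_mm2": beta_ppa,
                "gamma_ppa_mm2": gamma_ppa,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_cohort_csv(cohort: pd.DataFrame, path: PathLike) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "crvt_outside" in df.columns:
        df["crvt_outside"] = df["crvt_outside"].astype(bool)
    return df
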