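"""Synthetic paired-eye cohort generation.

Every analysis stage in this package runs on eye-level tables with one
glaucoma and one fellow control eye per patient.  No patient data ship
with the package; this module generates cohorts with the statistical
structure those analyses assume — calibrated group moments, a cubic
axial-length model for the offset index with a shared pair intercept,
a bivariate angle model, a conditional-logistic label mechanism, and the
study's exclusion categories — plus per-eye delineation geometry so the
full measurement path can be exercised end to end.

A cohort is an ordinary :class:`pandas.DataFrame` with two rows per
patient (columns documented on :data:`COHORT_COLUMNS`).
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import ALL_FLAGS, Calibration, CubicCoefficients, REMOVING_FLAGS
from .geometry import EyeDelineation, bmo_center_and_area, boundary_distance

__all__ = [
    "COHORT_COLUMNS",
    "generate_cohort",
    "synthesize_eye_geometry",
    "apply_exclusions",
    "simulate_cubic_cohort",
    "generate_conditional_label_cohort",
]

#: Column order of a cohort table (one row per eye).
COHORT_COLUMNS = [
    "patient_id",
    "eye_role",            # "glaucoma" | "control"
    "laterality",          # "OD" | "OS"
    "axial_length_mm",
    "offset_index",
    "angular_deviation_deg",
    "rnfl_defect_angle_deg",  # glaucoma eyes only; NaN for controls
    "crvt_outside",           # trunk outside the BMO in this eye
    "baseline_iop_mmhg",
    "bmo_area_mm2",
    "beta_ppa_mm2",
    "gamma_ppa_mm2",
    "rnfl_thickness_um",
    "mrw_um",
    "md_db",
    "psd_db",
    "exclusion_flag",      # "none" or one of the exclusion categories
]

_GROUPS = ("glaucoma", "control")


def _paired_normal(rng, mean_a, sd_a, mean_b, sd_b, corr, n):
    """Draw n correlated pairs from a bivariate normal."""
    z1 = rng.standard_normal(n)
    z2 = corr * z1 + math.sqrt(max(0.0, 1.0 - corr**2)) * rng.standard_normal(n)
    return mean_a + sd_a * z1, mean_b + sd_b * z2


def _draw_axial_lengths(calibration: Calibration, rng, n: int):
    mg, sg = calibration.moments("axial_length_mm", "glaucoma")
    mc, sc = calibration.moments("axial_length_mm", "control")
    return _paired_normal(rng, mg, sg, mc, sc, calibration.al_pair_correlation, n)


def _offset_from_cubic(
    cubic: CubicCoefficients,
    al_g,
    al_c,
    rng,
    sigma_resid: float,
    sigma_pair: float,
    clip: Optional[Tuple[float, float]],
):
    n = len(al_g)
    u = sigma_pair * rng.standard_normal(n)
    off_g = cubic.predict(al_g, 1.0) + u + sigma_resid * rng.standard_normal(n)
    off_c = cubic.predict(al_c, 0.0) + u + sigma_resid * rng.standard_normal(n)
    if clip is not None:
        off_g = np.clip(off_g, *clip)
        off_c = np.clip(off_c, *clip)
    return off_g, off_c


def generate_cohort(
    calibration: Calibration,
    n_patients: Optional[int] = None,
    seed: Optional[int] = None,
    assign_flags: bool = True,
) -> pd.DataFrame:
    """Generate a paired-eye cohort with the calibrated structure.

    Per patient: axial lengths for both eyes are drawn with the calibrated
    within-pair correlation and inter-eye mean offset; the offset index is
    the calibrated cubic in axial length plus the diagnosis effect, a
    shared pair intercept and an eye-level Gaussian residual, clipped to
    ``[0.01, 1.0]``; the glaucoma eye's trunk angle and RNFL-defect angle
    are bivariate normal at the calibrated correlation; all remaining
    variables are per-group Gaussian at the calibrated moments.

    When ``assign_flags`` is set (default) the calibrated exclusion
    categories are assigned to the first patients, in calibration order;
    patients in the ``invisible_confirmed`` category get a trunk outside
    the BMO in the glaucoma eye, the ``outside_both_eyes`` category in
    both eyes.  Fully reproducible from *seed*.
    """
    if n_patients is None:
        n_patients = calibration.n_patients
    if n_patients < 1:
        raise ValueError("n_patients must be positive")
    total_flagged = sum(calibration.exclusions.values())
    if assign_flags and n_patients < total_flagged:
        raise ValueError(
            f"n_patients={n_patients} is smaller than the "
            f"{total_flagged} flagged patients in the calibration"
        )
    rng = np.random.default_rng(seed)

    al_g, al_c = _draw_axial_lengths(calibration, rng, n_patients)
    off_g, off_c = _offset_from_cubic(
        calibration.cubic_generative,
        al_g,
        al_c,
        rng,
        calibration.sigma_resid,
        calibration.sigma_pair_intercept,
        clip=(0.01, 1.0),
    )

    # angles: glaucoma trunk angle correlated with the RNFL-defect angle.
    # Out-of-range draws (beyond +/-180, ~3 sigma) are redrawn rather than
    # wrapped: a +/-360 wrap would create extreme outliers that attenuate
    # the calibrated Pearson correlation.
    ma, sa = calibration.moments("angular_deviation_deg", "glaucoma")
    alpha_g, beta_defect = _paired_normal(
        rng,
        ma,
        sa,
        calibration.rnfl_defect_angle_mean_deg,
        calibration.rnfl_defect_angle_sd_deg,
        calibration.r_angle,
        n_patients,
    )
    for _ in range(100):
        bad = (np.abs(alpha_g) > 180.0) | (np.abs(beta_defect) > 180.0)
        if not bad.any():
            break
        a_new, b_new = _paired_normal(
            rng, ma, sa,
            calibration.rnfl_defect_angle_mean_deg,
            calibration.rnfl_defect_angle_sd_deg,
            calibration.r_angle,
            int(bad.sum()),
        )
        alpha_g[bad], beta_defect[bad] = a_new, b_new
    mc, sc = calibration.moments("angular_deviation_deg", "control")
    alpha_c = mc + sc * rng.standard_normal(n_patients)
    for _ in range(100):
        bad = np.abs(alpha_c) > 180.0
        if not bad.any():
            break
        alpha_c[bad] = mc + sc * rng.standard_normal(int(bad.sum()))

    other_vars = [
        "baseline_iop_mmhg",
        "bmo_area_mm2",
        "beta_ppa_mm2",
        "gamma_ppa_mm2",
        "rnfl_thickness_um",
        "mrw_um",
        "md_db",
        "psd_db",
    ]
    draws: Dict[Tuple[str, str], np.ndarray] = {}
    for var in other_vars:
        for grp in _GROUPS:
            m, s = calibration.moments(var, grp)
            draws[(var, grp)] = m + s * rng.standard_normal(n_patients)

    glaucoma_is_od = rng.random(n_patients) < 0.5

    flags = np.array(["none"] * n_patients, dtype=object)
    if assign_flags:
        pos = 0
        for flag in ALL_FLAGS:
            k = calibration.exclusions.get(flag, 0)
            flags[pos : pos + k] = flag
            pos += k
    outside_g = (flags == "invisible_confirmed") | (flags == "outside_both_eyes")
    outside_c = flags == "outside_both_eyes"

    width = max(3, len(str(n_patients)))
    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:0{width}d}"
        for role in _GROUPS:
            g = role == "glaucoma"
            rows.append(
                {
                    "patient_id": pid,
                    "eye_role": role,
                    "laterality": ("OD" if glaucoma_is_od[i] else "OS")
                    if g
                    else ("OS" if glaucoma_is_od[i] else "OD"),
                    "axial_length_mm": al_g[i] if g else al_c[i],
                    "offset_index": off_g[i] if g else off_c[i],
                    "angular_deviation_deg": alpha_g[i] if g else alpha_c[i],
                    "rnfl_defect_angle_deg": beta_defect[i] if g else np.nan,
                    "crvt_outside": bool(outside_g[i]) if g else bool(outside_c[i]),
                    **{var: draws[(var, role)][i] for var in other_vars},
                    "exclusion_flag": flags[i],
                }
            )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    # an eye with the trunk outside the BMO has offset 1.0 and no angle
    outside = df["crvt_outside"]
    df.loc[outside, "offset_index"] = 1.0
    df.loc[outside, "angular_deviation_deg"] = np.nan
    return df


def apply_exclusions(cohort: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop excluded patients and tally them per category.

    Patients flagged ``poor_quality``, ``bifurcation``,
    ``invisible_no_angio`` or ``outside_both_eyes`` are removed.  Patients
    flagged ``invisible_confirmed`` are retained, with the offset index of
    the eye whose trunk is outside the BMO forced to 1.0 (its angular
    deviation undefined).  The tally counts *removed* patients, so
    ``n_input_patients == n_included_patients + sum(tally.values())``.
    """
    if cohort.empty:
        return cohort.copy(), {flag: 0 for flag in REMOVING_FLAGS}
    per_patient = cohort.drop_duplicates("patient_id").set_index("patient_id")["exclusion_flag"]
    tally = {flag: int((per_patient == flag).sum()) for flag in REMOVING_FLAGS}
    keep = ~cohort["exclusion_flag"].isin(REMOVING_FLAGS)
    included = cohort.loc[keep].copy()
    force = (included["exclusion_flag"] == "invisible_confirmed") & included["crvt_outside"]
    included.loc[force, "offset_index"] = 1.0
    included.loc[force, "angular_deviation_deg"] = np.nan
    return included, tally


# ---------------------------------------------------------------------------
# Per-eye geometry synthesis (inverse construction)
# ---------------------------------------------------------------------------


def synthesize_eye_geometry(
    target_index: float,
    target_angle_deg: float,
    laterality: str,
    bmo_area: float = 2.7,
    seed: Optional[int] = None,
    crvt_outside: bool = False,
    patient_id: str = "synthetic",
    n_points: int = 48,
) -> EyeDelineation:
    """Build a delineation whose measurement recovers the given targets.

    Emits a 48-point near-elliptical BMO margin of exactly the requested
    area (a randomly tilted ellipse with a small smooth radial
    perturbation, rescaled to the target area) and places the CRVT on the
    ray from the polygon centroid at the target angle, at the target
    fraction of the centre-to-margin distance — so the measurement
    operation recovers ``(target_index, target_angle_deg)`` exactly up to
    floating-point error.  With ``crvt_outside`` the trunk is omitted and
    flagged outside (measured offset 1.0, angle undefined).  OS output is
    mirrored into the eye's native (left-eye) coordinates.
    """
    if not crvt_outside and not 0.0 <= target_index <= 1.0:
        raise ValueError("target_index must lie in [0, 1]")
    if bmo_area <= 0:
        raise ValueError("bmo_area must be positive")
    rng = np.random.default_rng(seed)

    aspect = 0.94 / 0.90  # near-circular, slightly horizontally elongated
    a_semi = math.sqrt(bmo_area * aspect / math.pi)
    b_semi = math.sqrt(bmo_area / (math.pi * aspect))
    theta = 2.0 * math.pi * np.arange(n_points) / n_points
    phase = rng.uniform(0.0, 2.0 * math.pi)
    radial = 1.0 + 0.03 * np.cos(2.0 * theta + phase)  # smooth, keeps convexity
    pts = np.column_stack(
        (a_semi * np.cos(theta) * radial, b_semi * np.sin(theta) * radial)
    )
    tilt = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array([[math.cos(tilt), -math.sin(tilt)], [math.sin(tilt), math.cos(tilt)]])
    pts = pts @ rot.T
    (cx, cy), area = bmo_center_and_area(pts)
    pts = (pts - (cx, cy)) * math.sqrt(bmo_area / area) + (cx, cy)

    if crvt_outside:
        crvt = None
    else:
        (cx, cy), _ = bmo_center_and_area(pts)
        angle = 0.0 if (target_index == 0.0 or math.isnan(target_angle_deg)) else target_angle_deg
        if target_index == 0.0:
            crvt = (cx, cy)
        else:
            b = boundary_distance((cx, cy), angle, pts)
            t = math.radians(angle)
            crvt = (
                cx + target_index * b * math.cos(t),
                cy + target_index * b * math.sin(t),
            )

    if laterality == "OS":  # back to native left-eye coordinates
        pts = pts * np.array([-1.0, 1.0])
        if crvt is not None:
            crvt = (-crvt[0], crvt[1])

    return EyeDelineation(
        patient_id=patient_id,
        laterality=laterality,
        margin_points=pts,
        crvt_point=crvt,
        crvt_outside_bmo=crvt_outside,
    )


# ---------------------------------------------------------------------------
# Focused simulators for parameter-recovery studies
# ---------------------------------------------------------------------------


def simulate_cubic_cohort(
    calibration: Calibration,
    n_pairs: int,
    seed: Optional[int] = None,
    sigma_resid: Optional[float] = None,
    clip: Optional[Tuple[float, float]] = (0.0, 1.0),
    cubic: Optional[CubicCoefficients] = None,
) -> pd.DataFrame:
    """Simulate (axial length, offset index) pairs from the cubic model.

    A reduced cohort — columns ``patient_id``, ``eye_role``,
    ``axial_length_mm``, ``offset_index`` — for validating the regression
    stage: offset index is the cubic in axial length plus the diagnosis
    effect, a shared pair intercept (SD ``sigma_resid * sqrt(rho/(1-rho))``)
    and an eye-level residual.  ``sigma_resid=0`` with ``clip=None`` gives
    noise-free data lying exactly on the generative surface.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    if sigma_resid is None:
        sigma_resid = calibration.sigma_resid
    if cubic is None:
        cubic = calibration.cubic_generative
    sigma_pair = (
        sigma_resid * math.sqrt(calibration.rho_pair / (1.0 - calibration.rho_pair))
        if sigma_resid > 0
        else 0.0
    )
    al_g, al_c = _draw_axial_lengths(calibration, rng, n_pairs)
    off_g, off_c = _offset_from_cubic(
        cubic, al_g, al_c, rng, sigma_resid, sigma_pair, clip
    )
    width = max(3, len(str(n_pairs)))
    pid = [f"P{i + 1:0{width}d}" for i in range(n_pairs)]
    return pd.DataFrame(
        {
            "patient_id": np.repeat(pid, 2),
            "eye_role": np.tile(["glaucoma", "control"], n_pairs),
            "axial_length_mm": np.column_stack((al_g, al_c)).ravel(),
            "offset_index": np.column_stack((off_g, off_c)).ravel(),
        }
    )


def generate_conditional_label_cohort(
    calibration: Calibration,
    n_pairs: int,
    seed: Optional[int] = None,
    log_or: Optional[float] = None,
    between_pair_sd: float = 0.15,
) -> pd.DataFrame:
    """Pairs whose glaucoma label follows a conditional logistic model.

    Each pair gets two offset indices (a shared pair level plus
    independent eye-level spread, clipped to ``[0.01, 1]``); which eye is
    labelled glaucoma is then drawn from the matched-pair conditional
    model: given offsets ``(x1, x2)``,
    ``P(eye 1 is the case) = exp(b*x1) / (exp(b*x1) + exp(b*x2))`` with
    ``b = log_or`` (the calibrated matched log-odds by default).  Designed
    for verifying that conditional logistic fitting recovers ``b``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    if log_or is None:
        log_or = calibration.matched_logit_log_or
    mg = calibration.moments("offset_index", "glaucoma")[0]
    mc = calibration.moments("offset_index", "control")[0]
    grand_mean = 0.5 * (mg + mc)
    pair_level = grand_mean + between_pair_sd * rng.standard_normal(n_pairs)
    x = pair_level[:, None] + calibration.sigma_resid * rng.standard_normal((n_pairs, 2))
    x = np.clip(x, 0.01, 1.0)
    p_first = 1.0 / (1.0 + np.exp(-log_or * (x[:, 0] - x[:, 1])))
    first_is_case = rng.random(n_pairs) < p_first
    width = max(3, len(str(n_pairs)))
    rows = []
    for i in range(n_pairs):
        pid = f"P{i + 1:0{width}d}"
        roles = ("glaucoma", "control") if first_is_case[i] else ("control", "glaucoma")
        for j, role in enumerate(roles):
            rows.append(
                {"patient_id": pid, "eye_role": role, "offset_index": x[i, j]}
            )
    return pd.DataFrame(rows)
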