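"""Calibration container for the synthetic paired-eye cohort generator.

A :class:`Calibration` bundles every number the generator needs: per-group
moments of the eye-level variables, the cubic generative model linking
offset index to diagnosis and axial length, correlation and noise
parameters, the matched-design effect size, and the exclusion tallies.
The packaged default (``calibration/study_calibration.yaml``) reproduces
the summary statistics of the unilateral normal-tension-glaucoma study
this package emulates; see ``docs/methods.md`` for how the generative
cubic was calibrated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["Calibration", "CubicCoefficients", "load_calibration", "packaged_calibration_path"]

_PACKAGED = "study_calibration.yaml"

#: exclusion categories that remove a patient from analysis; the
#: ``invisible_confirmed`` category is *retained* with the affected-eye
#: offset index fixed at 1.0.
REMOVING_FLAGS = ("poor_quality", "bifurcation", "invisible_no_angio", "outside_both_eyes")
RETAINED_FLAGS = ("invisible_confirmed",)
ALL_FLAGS = REMOVING_FLAGS + RETAINED_FLAGS


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of ``offset = c0 + c_diag*diag + c1*AL + c2*AL² + c3*AL³``."""

    c0: float
    c_diag: float
    c1: float
    c2: float
    c3: float

    def predict(self, axial_length, diagnosis):
        import numpy as np

        al = np.asarray(axial_length, dtype=float)
        d = np.asarray(diagnosis, dtype=float)
        return self.c0 + self.c_diag * d + self.c1 * al + self.c2 * al**2 + self.c3 * al**3


@dataclass(frozen=True)
class Calibration:
    """All generator parameters, loadable from and serialisable to YAML."""

    n_patients: int
    default_seed: int
    group_moments: Dict[str, Dict[str, Tuple[float, float]]]
    cubic_printed: CubicCoefficients
    cubic_printed_alt_intercept: float
    cubic_generative: CubicCoefficients
    argmin_al_mm: float
    rho_pair: float
    sigma_resid: float
    al_pair_correlation: float
    matched_logit_or: float
    r_angle: float
    rnfl_defect_angle_mean_deg: float
    rnfl_defect_angle_sd_deg: float
    exclusions: Dict[str, int]
    source_path: Optional[str] = None
    source_sha256: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_pair < 1.0:
            raise ValueError("rho_pair must lie in [0, 1)")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be positive")
        for var, groups in self.group_moments.items():
            for grp, (mean, sd) in groups.items():
                if sd <= 0:
                    raise ValueError(f"SD must be positive for {var}/{grp}")
        if sum(self.exclusions.values()) > self.n_patients:
            raise ValueError("exclusion counts exceed n_patients")
        unknown = set(self.exclusions) - set(ALL_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict, source_path: Optional[str] = None,
                  source_sha256: Optional[str] = None) -> "Calibration":
        moments = {
            var: {grp: (float(m), float(s)) for grp, (m, s) in groups.items()}
            for var, groups in data["group_moments"].items()
        }
        cp = data["cubic_printed"]
        cg = data["cubic_generative"]
        return cls(
            n_patients=int(data["n_patients"]),
            default_seed=int(data["default_seed"]),
            group_moments=moments,
            cubic_printed=CubicCoefficients(
                c0=float(cp["intercept"]), c_diag=float(cp["diagnosis"]),
                c1=float(cp["al"]), c2=float(cp["al2"]), c3=float(cp["al3"]),
            ),
            cubic_printed_alt_intercept=float(cp.get("intercept_alt", cp["intercept"])),
            cubic_generative=CubicCoefficients(
                c0=float(cg["intercept"]), c_diag=float(cg["diagnosis"]),
                c1=float(cg["al"]), c2=float(cg["al2"]), c3=float(cg["al3"]),
            ),
            argmin_al_mm=float(data["argmin_al_mm"]),
            rho_pair=float(data["rho_pair"]),
            sigma_resid=float(data["sigma_resid"]),
            al_pair_correlation=float(data["al_pair_correlation"]),
            matched_logit_or=float(data["matched_logit_or"]),
            r_angle=float(data["r_angle"]),
            rnfl_defect_angle_mean_deg=float(data["rnfl_defect_angle_mean_deg"]),
            rnfl_defect_angle_sd_deg=float(data["rnfl_defect_angle_sd_deg"]),
            exclusions={k: int(v) for k, v in data["exclusions"].items()},
            source_path=source_path,
            source_sha256=source_sha256,
        )

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "default_seed": self.default_seed,
            "group_moments": {
                var: {grp: list(ms) for grp, ms in groups.items()}
                for var, groups in self.group_moments.items()
            },
            "cubic_printed": {
                "intercept": self.cubic_printed.c0,
                "intercept_alt": self.cubic_printed_alt_intercept,
                "diagnosis": self.cubic_printed.c_diag,
                "al": self.cubic_printed.c1,
                "al2": self.cubic_printed.c2,
                "al3": self.cubic_printed.c3,
            },
            "cubic_generative": {
                "intercept": self.cubic_generative.c0,
                "diagnosis": self.cubic_generative.c_diag,
                "al": self.cubic_generative.c1,
                "al2": self.cubic_generative.c2,
                "al3": self.cubic_generative.c3,
            },
            "argmin_al_mm": self.argmin_al_mm,
            "rho_pair": self.rho_pair,
            "sigma_resid": self.sigma_resid,
            "al_pair_correlation": self.al_pair_correlation,
            "matched_logit_or": self.matched_logit_or,
            "r_angle": self.r_angle,
            "rnfl_defect_angle_mean_deg": self.rnfl_defect_angle_mean_deg,
            "rnfl_defect_angle_sd_deg": self.rnfl_defect_angle_sd_deg,
            "exclusions": dict(self.exclusions),
        }

    # -- derived quantities --------------------------------------------------

    @property
    def sigma_pair_intercept(self) -> float:
        """SD of the shared pair intercept implied by ``rho_pair``/``sigma_resid``.

        With intercept variance s_u² and residual variance s², the
        within-pair correlation of the noise is s_u² / (s_u² + s²) = rho.
        """
        import math

        return self.sigma_resid * math.sqrt(self.rho_pair / (1.0 - self.rho_pair))

    @property
    def matched_logit_log_or(self) -> float:
        import math

        return math.log(self.matched_logit_or)

    def moments(self, variable: str, group: str) -> Tuple[float, float]:
        return self.group_moments[variable][group]

    @property
    def n_removed(self) -> int:
        return sum(self.exclusions[k] for k in REMOVING_FLAGS)


def packaged_calibration_path() -> Path:
    """Filesystem path of the packaged default calibration."""
    return Path(resources.files("crvtoffset") / "calibration" / _PACKAGED)


def load_calibration(path: Optional[str] = None) -> Calibration:
    """Load a calibration YAML (the packaged default when *path* is None)."""
    p = Path(path) if path is not None else packaged_calibration_path()
    raw = p.read_bytes()
    data = yaml.safe_load(raw)
    return Calibration.from_dict(
        data, source_path=str(p), source_sha256=hashlib.sha256(raw).hexdigest()
    )
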