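"""Paired-eye inference on cohort tables.

The analysis chain mirrors a matched ocular case-control design with one
glaucoma and one fellow control eye per patient:

* paired comparisons (paired t-test with a Wilcoxon signed-rank
  companion) of each eye-level variable;
* matched-pair logistic modelling of the glaucoma label on eye-level
  predictors — a conditional likelihood on within-pair differences
  (classic 1:1 matched case-control logistic regression), with the
  conventional p < 0.20 univariable screen before the multivariable fit;
* a linear GEE of offset index on a diagnosis indicator plus first-,
  second- and third-order axial-length terms, exchangeable working
  correlation within patients and robust (sandwich) standard errors;
* the closed-form argmin of the fitted cubic over a clinical
  axial-length range;
* LOESS (tricube-weighted local linear regression with iterative
  bisquare robustness reweighting);
* Pearson correlation between the trunk's angular deviation and the
  RNFL-defect location among glaucoma eyes.

Model classes follow the statsmodels convention: construct from data,
``fit()`` returns a results object carrying estimates, uncertainties and
``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from .calibration import CubicCoefficients

__all__ = [
    "PairedComparison",
    "paired_compare",
    "MatchedPairLogit",
    "MatchedPairLogitResults",
    "OffsetIndexGEE",
    "OffsetIndexGEEResults",
    "CubicArgmin",
    "cubic_argmin",
    "loess_curve",
    "AngleCorrelation",
    "angle_correlation",
    "DEFAULT_PREDICTORS",
]

#: Eye-level predictors offered to the matched logistic stage by default.
DEFAULT_PREDICTORS = [
    "baseline_iop_mmhg",
    "axial_length_mm",
    "angular_deviation_deg",
    "offset_index",
    "bmo_area_mm2",
    "beta_ppa_mm2",
    "gamma_ppa_mm2",
]

SCREEN_ALPHA = 0.20  # univariable screen for the multivariable model


def _paired_pivot(cohort: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Wide table with one row per complete pair for *variable*."""
    if variable not in cohort.columns:
        raise KeyError(f"variable {variable!r} not in cohort")
    wide = cohort.pivot_table(
        index="patient_id", columns="eye_role", values=variable, aggfunc="first"
    )
    if "glaucoma" not in wide.columns or "control" not in wide.columns:
        raise ValueError("cohort must contain both glaucoma and control eyes")
    return wide.dropna()


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    """Intra-individual comparison of one variable between fellow eyes."""

    variable: str
    n_pairs: int
    mean_glaucoma: float
    sd_glaucoma: float
    mean_control: float
    sd_control: float
    mean_difference: float
    sd_difference: float
    t_stat: float
    p_t: float
    wilcoxon_stat: float
    p_wilcoxon: float
    flags: Tuple[str, ...] = ()


def paired_compare(cohort: pd.DataFrame, variable: str) -> PairedComparison:
    """Paired t-test (glaucoma minus control) with a Wilcoxon companion.

    Pairs with a missing value in either eye are dropped.  Zero-variance
    differences make the t statistic undefined; the comparison is then
    flagged (with p = 1 when every difference is exactly zero).
    """
    wide = _paired_pivot(cohort, variable)
    if len(wide) < 2:
        raise ValueError(f"need >= 2 complete pairs for {variable!r}, have {len(wide)}")
    g = wide["glaucoma"].to_numpy(float)
    c = wide["control"].to_numpy(float)
    d = g - c
    n = len(d)
    sd_d = float(np.std(d, ddof=1))
    flags: List[str] = []
    if sd_d == 0.0:
        flags.append("zero_variance_differences")
        t_stat = float("nan")
        p_t = 1.0 if np.all(d == 0.0) else float("nan")
    else:
        t_stat, p_t = scipy.stats.ttest_rel(g, c)
        t_stat, p_t = float(t_stat), float(p_t)
    nonzero = d[d != 0.0]
    if len(nonzero) == 0:
        w_stat, p_w = float("nan"), float("nan")
        flags.append("wilcoxon_all_zero_differences")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w_stat, p_w = scipy.stats.wilcoxon(g, c, zero_method="wilcox")
        w_stat, p_w = float(w_stat), float(p_w)
    return PairedComparison(
        variable=variable,
        n_pairs=n,
        mean_glaucoma=float(np.mean(g)),
        sd_glaucoma=float(np.std(g, ddof=1)),
        mean_control=float(np.mean(c)),
        sd_control=float(np.std(c, ddof=1)),
        mean_difference=float(np.mean(d)),
        sd_difference=sd_d,
        t_stat=t_stat,
        p_t=p_t,
        wilcoxon_stat=w_stat,
        p_wilcoxon=p_w,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Matched-pair (conditional) logistic model
# ---------------------------------------------------------------------------


class MatchedPairLogit:
    """Matched-pair logistic model of the glaucoma label on eye-level predictors.

    With exactly one case and one control per patient the conditional
    likelihood on within-pair differences is the standard exact treatment
    of the pairing; only within-pair contrasts of the predictors are
    informative, so the odds ratios are invariant to adding any
    patient-level constant to both eyes.

    Parameters
    ----------
    cohort
        Eye-level table with ``patient_id``, ``eye_role`` and the
        predictor columns.
    predictors
        Candidate predictors (default :data:`DEFAULT_PREDICTORS`
        restricted to the available columns).
    screen_alpha
        Univariable p-value threshold for entering the multivariable
        model (default 0.20).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        predictors: Optional[Sequence[str]] = None,
        screen_alpha: float = SCREEN_ALPHA,
    ):
        if predictors is None:
            predictors = [p for p in DEFAULT_PREDICTORS if p in cohort.columns]
        missing = [p for p in predictors if p not in cohort.columns]
        if missing:
            raise KeyError(f"predictors not in cohort: {missing}")
        counts = cohort.groupby("patient_id")["eye_role"].agg(
            lambda s: tuple(sorted(s))
        )
        bad = counts[counts != ("control", "glaucoma")]
        if len(bad):
            raise ValueError(
                "each patient must contribute exactly one glaucoma and one "
                f"control eye; offending patients: {list(bad.index[:5])}"
            )
        self.cohort = cohort
        self.predictors = list(predictors)
        self.screen_alpha = float(screen_alpha)

    def _fit_one(self, columns: Sequence[str]) -> Tuple[pd.DataFrame, bool]:
        data = self.cohort[["patient_id", "eye_role", *columns]].dropna()
        complete = data.groupby("patient_id").size() == 2
        data = data[data["patient_id"].map(complete)]
        y = (data["eye_role"] == "glaucoma").astype(int).to_numpy()
        X = data[list(columns)].to_numpy(float)
        groups = data["patient_id"].to_numpy()
        # no within-pair discordance in any predictor: the conditional
        # likelihood is constant, so the matched odds ratio is 1 by
        # definition and carries no information (p = 1, unbounded CI)
        case = data["eye_role"].to_numpy() == "glaucoma"
        diffs = (
            pd.DataFrame(X, index=groups)[case].sort_index().to_numpy()
            - pd.DataFrame(X, index=groups)[~case].sort_index().to_numpy()
        )
        if np.all(diffs == 0.0):
            return (
                pd.DataFrame(
                    {
                        "or": 1.0,
                        "ci_low": 0.0,
                        "ci_high": np.inf,
                        "p": 1.0,
                        "log_or": 0.0,
                        "se": np.inf,
                        "converged": False,
                    },
                    index=list(columns),
                ),
                False,
            )
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ConditionalLogit(y, X, groups=groups)
            try:
                res = model.fit(disp=False, maxiter=200)
                retvals = getattr(res, "mle_retvals", None)
                converged = bool(retvals.get("converged", True)) if retvals else True
                params = np.asarray(res.params, float)
                bse = np.asarray(res.bse, float)
                pvals = np.asarray(res.pvalues, float)
            except Exception:
                converged = False
                params = np.full(len(columns), np.nan)
                bse = np.full(len(columns), np.nan)
                pvals = np.full(len(columns), np.nan)
        if not converged or not np.all(np.isfinite(bse)):
            # e.g. complete separation: report unbounded uncertainty
            converged = False
        z = scipy.stats.norm.ppf(0.975)
        table = pd.DataFrame(
            {
                "or": np.exp(params),
                "ci_low": np.exp(params - z * bse),
                "ci_high": np.exp(params + z * bse),
                "p": pvals,
                "log_or": params,
                "se": bse,
                "converged": converged,
            },
            index=list(columns),
        )
        return table, converged

    def fit(self) -> "MatchedPairLogitResults":
        uni_rows = []
        for pred in self.predictors:
            table, _ = self._fit_one([pred])
            uni_rows.append(table)
        univariable = pd.concat(uni_rows)
        pvals = univariable["p"]
        selected = [
            p for p in self.predictors
            if np.isfinite(pvals.loc[p]) and pvals.loc[p] < self.screen_alpha
        ]
        if selected:
            multivariable, _ = self._fit_one(selected)
        else:
            multivariable = univariable.iloc[0:0].copy()
        return MatchedPairLogitResults(
            model=self, univariable=univariable, multivariable=multivariable,
            selected=selected,
        )


@dataclass
class MatchedPairLogitResults:
    """Univariable and multivariable matched odds ratios with 95% CIs."""

    model: MatchedPairLogit
    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    selected: List[str]

    def summary(self) -> str:
        lines = ["Matched-pair conditional logistic regression", ""]
        lines.append("Univariable analysis (one predictor at a time):")
        lines.append(
            self.univariable[["or", "ci_low", "ci_high", "p"]].to_string(
                float_format=lambda v: f"{v:.3f}"
            )
        )
        lines.append("")
        lines.append(
            f"Multivariable analysis (univariable p < {self.model.screen_alpha:g}: "
            f"{', '.join(self.selected) if self.selected else 'no predictor selected'}):"
        )
        if len(self.multivariable):
            lines.append(
                self.multivariable[["or", "ci_low", "ci_high", "p"]].to_string(
                    float_format=lambda v: f"{v:.3f}"
                )
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# GEE with cubic axial-length terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CubicArgmin:
    """Axial length minimising a cubic over a range, with context flags."""

    al_mm: float
    value: float
    interior: bool
    flag: str = ""


def cubic_argmin(
    coefs: CubicCoefficients, al_range: Tuple[float, float] = (20.0, 30.0)
) -> CubicArgmin:
    """Closed-form argmin of ``c0 + c1·x + c2·x² + c3·x³`` on a range.

    Solves the derivative quadratic exactly.  If an interior stationary
    point with positive second derivative lies inside the range it is the
    minimiser (against the boundary values); a monotone cubic returns the
    minimising boundary with a flag.  The diagnosis term is a level shift
    and does not move the argmin.
    """
    lo, hi = float(al_range[0]), float(al_range[1])
    if not lo < hi:
        raise ValueError("al_range must satisfy lo < hi")
    if coefs.c3 == 0.0:
        raise ValueError("c3 must be nonzero for the cubic argmin analysis")

    def f(x: float) -> float:
        return coefs.c0 + coefs.c1 * x + coefs.c2 * x**2 + coefs.c3 * x**3

    candidates: List[Tuple[float, bool]] = [(lo, False), (hi, False)]
    disc = 4.0 * coefs.c2**2 - 12.0 * coefs.c3 * coefs.c1
    interior_found = False
    if disc > 0.0:
        sq = math.sqrt(disc)
        for root in ((-2.0 * coefs.c2 + sq) / (6.0 * coefs.c3),
                     (-2.0 * coefs.c2 - sq) / (6.0 * coefs.c3)):
            second = 6.0 * coefs.c3 * root + 2.0 * coefs.c2
            if lo < root < hi and second > 0.0:
                candidates.append((root, True))
                interior_found = True
    best_x, best_interior = min(candidates, key=lambda c: f(c[0]))
    flag = "" if best_interior else (
        "no_interior_minimum" if not interior_found else "boundary_below_interior"
    )
    return CubicArgmin(al_mm=best_x, value=f(best_x), interior=best_interior, flag=flag)


class OffsetIndexGEE:
    """Linear GEE of offset index on diagnosis and cubic axial length.

    The mean model is ``offset = c0 + c_diag·diag + c1·AL + c2·AL² +
    c3·AL³`` with an exchangeable working correlation within patients
    (natural for two-eye clusters) and robust sandwich standard errors.
    Coefficients are reported on the raw axial-length scale; internally
    the polynomial is built in the axial length centred at its sample
    mean — the raw cubic design has a condition number around 10⁹ at
    these magnitudes, and the centred parametrisation removes that
    ill-conditioning before mapping the estimates (and their covariance)
    back exactly.
    """

    TERMS = ["intercept", "diagnosis", "al", "al2", "al3"]

    def __init__(self, cohort: pd.DataFrame):
        need = {"patient_id", "eye_role", "axial_length_mm", "offset_index"}
        missing = need - set(cohort.columns)
        if missing:
            raise KeyError(f"cohort lacks columns: {sorted(missing)}")
        data = cohort[list(need)].dropna()
        self.data = data.sort_values("patient_id", kind="stable")
        self.al_center = float(self.data["axial_length_mm"].mean())
        if self.data["axial_length_mm"].nunique() < 4:
            raise ValueError("rank-deficient design: need >= 4 distinct axial lengths")

    def _design(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        al = self.data["axial_length_mm"].to_numpy(float) - self.al_center
        diag = (self.data["eye_role"] == "glaucoma").to_numpy(float)
        X = np.column_stack((np.ones_like(al), diag, al, al**2, al**3))
        y = self.data["offset_index"].to_numpy(float)
        groups = self.data["patient_id"].to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        return X, y, groups

    def _uncenter(self) -> np.ndarray:
        """Matrix T with raw_params = T @ centred_params."""
        m = self.al_center
        # centred: d0 + dd*diag + d1*(x-m) + d2*(x-m)^2 + d3*(x-m)^3
        T = np.array(
            [
                [1.0, 0.0, -m, m**2, -(m**3)],
                [0.0, 1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, -2.0 * m, 3.0 * m**2],
                [0.0, 0.0, 0.0, 1.0, -3.0 * m],
                [0.0, 0.0, 0.0, 0.0, 1.0],
            ]
        )
        return T

    def fit(self) -> "OffsetIndexGEEResults":
        X, y, groups = self._design()
        T = self._uncenter()
        beta_ls, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ls
        if np.max(np.abs(resid)) < 1e-10:
            # exact interpolation: the GEE moment equations degenerate
            # (zero scale), so report the exact least-squares solution
            params = T @ beta_ls
            cov = np.zeros((5, 5))
            return OffsetIndexGEEResults(
                model=self, params=params, cov=cov, scale=0.0,
                working_correlation=float("nan"), converged=True,
                flags=("degenerate_exact_fit",), nobs=len(y),
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                y, X, groups=groups,
                family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            try:
                res = model.fit()
                converged = True
            except Exception:
                res = None
                converged = False
        if not converged:
            return OffsetIndexGEEResults(
                model=self, params=np.full(5, np.nan), cov=np.full((5, 5), np.nan),
                scale=float("nan"), working_correlation=float("nan"),
                converged=False, flags=("non_convergence",), nobs=len(y),
            )
        params = T @ np.asarray(res.params, float)
        cov = T @ np.asarray(res.cov_params(), float) @ T.T
        dep = res.cov_struct.dep_params
        return OffsetIndexGEEResults(
            model=self, params=params, cov=cov, scale=float(res.scale),
            working_correlation=float(np.atleast_1d(dep)[0]),
            converged=True, flags=(), nobs=len(y),
        )


@dataclass
class OffsetIndexGEEResults:
    """GEE coefficients on the raw axial-length scale, with sandwich CIs."""

    model: OffsetIndexGEE
    params: np.ndarray  # intercept, diagnosis, al, al2, al3
    cov: np.ndarray
    scale: float
    working_correlation: float
    converged: bool
    flags: Tuple[str, ...]
    nobs: int

    @property
    def coefficients(self) -> CubicCoefficients:
        p = self.params
        return CubicCoefficients(c0=p[0], c_diag=p[1], c1=p[2], c2=p[3], c3=p[4])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return np.column_stack((self.params - z * se, self.params + z * se))

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2.0 * scipy.stats.norm.sf(np.abs(z))

    def argmin(self, al_range: Tuple[float, float] = (20.0, 30.0)) -> CubicArgmin:
        """Axial length minimising the fitted offset-index curve."""
        return cubic_argmin(self.coefficients, al_range)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=OffsetIndexGEE.TERMS,
        )

    def summary(self) -> str:
        lines = [
            "GEE: offset index ~ diagnosis + AL + AL^2 + AL^3",
            f"n eyes = {self.nobs}; exchangeable working correlation = "
            f"{self.working_correlation:.3f}; scale = {self.scale:.5f}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        lines.append(self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"))
        am = self.argmin()
        lines.append(
            f"fitted curve minimum at AL = {am.al_mm:.2f} mm"
            + ("" if am.interior else f" ({am.flag})")
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def _local_linear(x0, x, y, weights):
    w = weights
    sw = w.sum()
    if sw <= 0:
        return float("nan")
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 1e-300:
        return float(ym)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    return float(ym + slope * (x0 - xm))


def _tricube(u):
    out = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, 1.0) ** 3
    return out


def loess_curve(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    query_points: Optional[Sequence[float]] = None,
    robustness_iterations: int = 3,
) -> np.ndarray:
    """LOESS: tricube-weighted local linear fits with bisquare robustness.

    For each query point the ``ceil(span·n)`` nearest observations get
    tricube weights in distance, multiplied by bisquare robustness
    weights from ``robustness_iterations`` rounds of residual
    down-weighting on the training points.  Exactly reproduces any
    globally linear signal.

    Returns fitted values at *query_points* (default: at the data x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    k = max(2, int(math.ceil(span * n)))
    if n < max(5, k):
        raise ValueError(f"need at least max(5, span*n)={max(5, k)} points, have {n}")
    query = x if query_points is None else np.asarray(query_points, float)

    def fit_at(points, delta):
        out = np.empty(len(points))
        for i, x0 in enumerate(points):
            d = np.abs(x - x0)
            dmax = np.partition(d, k - 1)[k - 1]
            if dmax == 0.0:
                w = (d == 0.0).astype(float) * delta
            else:
                w = _tricube(d / dmax) * delta
            out[i] = _local_linear(x0, x, y, w)
        return out

    delta = np.ones(n)
    for _ in range(robustness_iterations):
        fitted = fit_at(x, delta)
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 1e-300:
            break
        delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
    return fit_at(query, delta)


# ---------------------------------------------------------------------------
# Angle correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AngleCorrelation:
    """Pearson correlation of trunk angle with RNFL-defect angle."""

    r: float
    p: float
    n: int
    subgroup: str = "all"


def angle_correlation(cohort: pd.DataFrame, subgroup: str = "all") -> AngleCorrelation:
    """Correlate trunk angular deviation with RNFL-defect location.

    Uses glaucoma eyes with both angles defined.  Subgroups split on the
    trunk's side: ``temporal_crvt`` keeps eyes with |angular deviation| >
    90° (trunk on the temporal side), ``nasal_crvt`` the rest.
    """
    if subgroup not in ("all", "temporal_crvt", "nasal_crvt"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    eyes = cohort[cohort["eye_role"] == "glaucoma"]
    alpha = eyes["angular_deviation_deg"].to_numpy(float)
    beta = eyes["rnfl_defect_angle_deg"].to_numpy(float)
    ok = np.isfinite(alpha) & np.isfinite(beta)
    alpha, beta = alpha[ok], beta[ok]
    if subgroup == "temporal_crvt":
        sel = np.abs(alpha) > 90.0
    elif subgroup == "nasal_crvt":
        sel = np.abs(alpha) <= 90.0
    else:
        sel = np.ones(len(alpha), bool)
    alpha, beta = alpha[sel], beta[sel]
    if len(alpha) < 3:
        raise ValueError(f"need >= 3 eyes with both angles, have {len(alpha)}")
    r, p = scipy.stats.pearsonr(alpha, beta)
    return AngleCorrelation(r=float(r), p=float(p), n=len(alpha), subgroup=subgroup)
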