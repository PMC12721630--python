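"""One-sample cis-Mendelian randomization: instrument validation, causal
estimation, MR-Egger pleiotropy sensitivity, and mediation through vascular
superoxide.

The instrument is an individual-level LPA genetic risk score; the three
instrumental-variable assumptions are screened as in applied practice:
relevance by the first-stage F-statistic (F > 10), independence by
confounder contrasts across score groups, and the exclusion restriction by
the cis design plus the MR-Egger intercept.  Because per-variant exposure
and outcome associations are computed in the same cohort as the causal
estimate, the Egger diagnostics are winner's-curse-prone; they are a
sensitivity analysis, not an unbiased two-sample estimator.

Mediation follows the nested-Cox-model procedure: the exposure effect on
cardiovascular death is fit with and without log basal superoxide, and the
attenuation of the exposure log-hazard quantifies how much of the effect the
mediator absorbs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DataError, FitError
from .genetics import MISSING, GenotypeMatrix, GrsResult
from .inference import (
    CoxFit,
    TestResult,
    correlate,
    cox_fit,
    two_group_test,
)

__all__ = [
    "InstrumentCheck",
    "MrEstimate",
    "EggerFit",
    "MediationResult",
    "validate_instrument",
    "mr_estimate",
    "per_variant_associations",
    "mr_egger",
    "ivw_estimate",
    "mediation_cox",
]


@dataclass
class InstrumentCheck:
    f_statistic: float
    relevance_pass: bool
    independence_table: list[tuple[str, TestResult]]
    egger_intercept_p: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "relevance_pass": self.relevance_pass,
            "independence": {name: tr.to_dict() for name, tr in self.independence_table},
            "egger_intercept_p": self.egger_intercept_p,
            "n": self.n,
        }


@dataclass
class MrEstimate:
    method: str
    estimate: float  # outcome units per mg/dL Lp(a)
    se: float | None
    ci: tuple[float, float] | None
    p: float | None
    n: int
    bootstrap_reps: int = 0

    def to_dict(self) -> dict:
        return {"method": self.method, "estimate": self.estimate, "se": self.se,
                "ci": list(self.ci) if self.ci else None, "p": self.p,
                "n": self.n, "bootstrap_reps": self.bootstrap_reps}


@dataclass
class EggerFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    intercept_p: float
    weights: np.ndarray
    n_variants: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "slope_se": self.slope_se,
                "intercept": self.intercept, "intercept_se": self.intercept_se,
                "intercept_p": self.intercept_p, "n_variants": self.n_variants}


@dataclass
class MediationResult:
    unadjusted: tuple[float, tuple[float, float], float]  # (hr, ci, p)
    mediator_adjusted: tuple[float, tuple[float, float], float]
    attenuation_pct: float
    exposure_mediator_rho: TestResult
    n: int
    n_events: int
    n_dropped_missing_mediator: int = 0
    unadjusted_fit: CoxFit | None = None
    adjusted_fit: CoxFit | None = None

    def to_dict(self) -> dict:
        u, a = self.unadjusted, self.mediator_adjusted
        return {
            "unadjusted": {"hr": u[0], "ci": list(u[1]), "p": u[2]},
            "mediator_adjusted": {"hr": a[0], "ci": list(a[1]), "p": a[2]},
            "attenuation_pct": self.attenuation_pct,
            "exposure_mediator_rho": self.exposure_mediator_rho.to_dict(),
            "n": self.n,
            "n_events": self.n_events,
            "n_dropped_missing_mediator": self.n_dropped_missing_mediator,
        }


# ---------------------------------------------------------------------------
# instrument validation
# ---------------------------------------------------------------------------


def first_stage_f(instrument, log_exposure) -> float:
    """Single-predictor first-stage F: F = (n-2) R^2 / (1 - R^2)."""
    x = np.asarray(instrument, dtype=float).ravel()
    y = np.asarray(log_exposure, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DataError("first-stage F needs n >= 3")
    if np.std(x) == 0:
        raise DataError("instrument is constant")
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    if r2 >= 1.0:
        return math.inf
    return (n - 2) * r2 / (1.0 - r2)


def validate_instrument(
    grs: GrsResult,
    lpa,
    confounders: pd.DataFrame | None = None,
    genotypes: GenotypeMatrix | None = None,
    outcome=None,
) -> InstrumentCheck:
    """Screen the three IV assumptions for the GRS instrument.

    Relevance: F from the regression of log-Lp(a) on the carrier count
    (F > 10 passes).  Independence: each confounder contrasted across the
    reference/alternative groups with the auto-selected two-group test.
    Exclusion restriction: when genotypes and an outcome are supplied, the
    MR-Egger intercept p from in-sample per-variant associations.
    """
    lpa = np.asarray(lpa, dtype=float).ravel()
    if np.any(lpa <= 0):
        raise DataError("Lp(a) must be positive")
    ref = grs.group == "reference"
    alt = grs.group == "alternative"
    if ref.sum() == 0 or alt.sum() == 0:
        raise DataError("both GRS groups must be nonempty")
    f = first_stage_f(grs.carrier_count, np.log(lpa))

    independence: list[tuple[str, TestResult]] = []
    if confounders is not None:
        for name in confounders.columns:
            v = confounders[name].to_numpy(dtype=float)
            tr = two_group_test(v[alt], v[ref])
            independence.append((name, tr))

    egger_p = None
    if genotypes is not None and outcome is not None:
        bx, sx, by, sy, _ = per_variant_associations(genotypes, lpa, outcome)
        egger_p = mr_egger(bx, sx, by, sy).intercept_p

    return InstrumentCheck(
        f_statistic=float(f),
        relevance_pass=bool(f > 10),
        independence_table=independence,
        egger_intercept_p=egger_p,
        n=int(np.isfinite(lpa).sum()),
    )


# ---------------------------------------------------------------------------
# causal estimation
# ---------------------------------------------------------------------------


def _grs_contrast(group: np.ndarray, exposure: np.ndarray, outcome: np.ndarray) -> float:
    alt, ref = group == "alternative", group == "reference"
    dx = exposure[alt].mean() - exposure[ref].mean()
    dy = outcome[alt].mean() - outcome[ref].mean()
    scale = max(abs(exposure[alt].mean()), abs(exposure[ref].mean()), 1.0)
    if abs(dx) < 1e-10 * scale:
        raise FitError("weak instrument: exposure difference between GRS groups is ~0")
    return dy / dx


def _two_stage(instr: np.ndarray, exposure: np.ndarray, outcome: np.ndarray) -> float:
    x = instr.astype(float)
    if np.std(x) == 0:
        raise FitError("weak instrument: instrument is constant")
    xc = x - x.mean()
    b1 = float(xc @ (exposure - exposure.mean())) / float(xc @ xc)
    if abs(b1) < 1e-12:
        raise FitError("weak instrument: first-stage slope is ~0")
    fitted = exposure.mean() + b1 * xc
    fc = fitted - fitted.mean()
    return float(fc @ (outcome - outcome.mean())) / float(fc @ fc)


def mr_estimate(
    grs: GrsResult,
    exposure,
    outcome,
    method: str = "two_stage",
    n_boot: int = 2000,
    seed: int = 0,
    subset=None,
) -> MrEstimate:
    """Causal effect of the exposure (Lp(a), mg/dL) on the outcome.

    ``grs_contrast``: Wald ratio of group mean differences,
    (mean outcome alt − ref) / (mean exposure alt − ref).
    ``two_stage``: regress the outcome on the first-stage fitted exposure
    (instrument = carrier count).  With a binary instrument and no covariates
    the two coincide.  The se/CI come from a seeded nonparametric bootstrap
    over subjects (skipped when ``n_boot`` is 0).  ``subset`` restricts the
    analysis (e.g. to nondiabetics).
    """
    exposure = np.asarray(exposure, dtype=float).ravel()
    outcome = np.asarray(outcome, dtype=float).ravel()
    group = np.asarray(grs.group)
    instr = np.asarray(grs.carrier_count, dtype=float)
    keep = np.isfinite(exposure) & np.isfinite(outcome)
    if subset is not None:
        keep &= np.asarray(subset, dtype=bool)
    group, instr = group[keep], instr[keep]
    exposure, outcome = exposure[keep], outcome[keep]

    if method == "grs_contrast":
        def estimator(g, i, e, o):
            return _grs_contrast(g, e, o)
    elif method == "two_stage":
        def estimator(g, i, e, o):
            return _two_stage(i, e, o)
    else:
        raise ValueError(f"unknown MR method {method!r}")

    est = estimator(group, instr, exposure, outcome)
    se = ci = p = None
    reps = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(exposure)
        boots = np.empty(n_boot)
        b = 0
        attempts = 0
        while b < n_boot and attempts < 10 * n_boot:
            idx = rng.integers(0, n, n)
            attempts += 1
            try:
                boots[b] = estimator(group[idx], instr[idx], exposure[idx], outcome[idx])
            except FitError:
                continue
            b += 1
        boots = boots[:b]
        if b < max(100, n_boot // 2):
            raise FitError("bootstrap failed: instrument too weak under resampling")
        se = float(np.std(boots, ddof=1))
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        p = float(min(1.0, max(2.0 * sps.norm.sf(abs(est) / se), 1e-300))) if se > 0 else 1.0
        reps = b
    return MrEstimate(method=method, estimate=float(est), se=se, ci=ci, p=p,
                      n=len(exposure), bootstrap_reps=reps)


def per_variant_associations(gm: GenotypeMatrix, exposure, outcome, subset=None):
    """In-sample per-variant summary statistics for MR-Egger.

    Simple regressions of exposure and outcome on dosage per variant,
    complete case; betas are oriented to the exposure-increasing allele
    (variants with a negative exposure beta have both betas sign-flipped).
    Returns (beta_x, se_x, beta_y, se_y, rsids).
    """
    exposure = np.asarray(exposure, dtype=float).ravel()
    outcome = np.asarray(outcome, dtype=float).ravel()
    base = np.isfinite(exposure) & np.isfinite(outcome)
    if subset is not None:
        base &= np.asarray(subset, dtype=bool)
    bx, sx, by, sy, rsids = [], [], [], [], []
    for j, rsid in enumerate(gm.rsids):
        d = gm.dosage[:, j]
        keep = base & (d != MISSING)
        x = d[keep].astype(float)
        if len(x) < 3 or np.all(x == x[0]):
            continue
        xc = x - x.mean()
        sxx = float(xc @ xc)
        df = len(x) - 2
        out = []
        for y in (exposure[keep], outcome[keep]):
            yc = y - y.mean()
            b = float(xc @ yc) / sxx
            resid = yc - b * xc
            s = math.sqrt(max(float(resid @ resid) / df, 0.0) / sxx)
            out.append((b, s))
        (b_x, s_x), (b_y, s_y) = out
        flip = -1.0 if b_x < 0 else 1.0
        bx.append(flip * b_x)
        by.append(flip * b_y)
        sx.append(s_x)
        sy.append(s_y)
        rsids.append(rsid)
    return (np.array(bx), np.array(sx), np.array(by), np.array(sy), rsids)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares with *fixed* weights: coefficient vector and
    covariance (X' W X)^{-1} (no residual-variance rescaling)."""
    W = np.diag(w)
    xtw = X.T @ W
    cov = np.linalg.inv(xtw @ X)
    coef = cov @ (xtw @ y)
    return coef, cov

def ivw_estimate(beta_x, se_x, beta_y, se_y) -> tuple[float, float]:
    """Inverse-variance-weighted estimate: Egger slope with the intercept
    constrained to zero.  Returns (slope, se)."""
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    w = 1.0 / np.asarray(se_y, dtype=float) ** 2
    coef, cov = _wls(bx[:, None], by, w)
    return float(coef[0]), float(math.sqrt(cov[0, 0]))


def mr_egger(beta_x, se_x, beta_y, se_y, intercept: bool = True) -> EggerFit:
    """MR-Egger regression: WLS of per-variant outcome betas on exposure
    betas, weighted by 1/se_y^2, with an unconstrained intercept whose
    two-sided normal p tests directional pleiotropy.

    Needs >= 3 variants for intercept inference.  With a single variant and
    ``intercept=False`` the slope reduces to the Wald ratio beta_y/beta_x.
    """
    bx = np.asarray(beta_x, dtype=float).ravel()
    by = np.asarray(beta_y, dtype=float).ravel()
    sy = np.asarray(se_y, dtype=float).ravel()
    if not (len(bx) == len(by) == len(sy)):
        raise DataError("per-variant vectors must align")
    if np.any(sy <= 0):
        raise DataError("outcome standard errors must be positive")
    w = 1.0 / sy**2
    if not intercept:
        slope, slope_se = ivw_estimate(bx, None, by, sy)
        return EggerFit(slope=slope, slope_se=slope_se, intercept=0.0,
                        intercept_se=math.nan, intercept_p=math.nan,
                        weights=w, n_variants=len(bx))
    if len(bx) < 3:
        raise DataError("MR-Egger intercept inference needs >= 3 variants")
    X = np.column_stack([np.ones_like(bx), bx])
    coef, cov = _wls(X, by, w)
    inter, slope = float(coef[0]), float(coef[1])
    inter_se = math.sqrt(cov[0, 0])
    slope_se = math.sqrt(cov[1, 1])
    p = float(min(1.0, max(2.0 * sps.norm.sf(abs(inter) / inter_se), 1e-300)))
    return EggerFit(slope=slope, slope_se=slope_se, intercept=inter,
                    intercept_se=inter_se, intercept_p=p, weights=w,
                    n_variants=len(bx))


# ---------------------------------------------------------------------------
# mediation through vascular superoxide
# ---------------------------------------------------------------------------


def mediation_cox(
    time,
    event,
    exposure_group,
    mediator,
    covariates: pd.DataFrame | None = None,
    ties: str = "efron",
) -> MediationResult:
    """Nested Cox models for mediation by adjustment.

    Fits the exposure (+ covariates) model, then adds the mediator (log basal
    superoxide), on the same complete-case subjects.  Reports both (HR, CI, p)
    triples, the attenuation of the exposure log-HR,
    100·(1 − ln HR_adj / ln HR_unadj), and the exposure–mediator Spearman
    correlation as collinearity context.  Subjects missing the mediator are
    dropped complete-case with the count reported.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    expo = np.asarray(exposure_group, dtype=float).ravel()
    med = np.asarray(mediator, dtype=float).ravel()
    n_total = len(time)
    keep = np.isfinite(time) & np.isfinite(event) & np.isfinite(expo) & np.isfinite(med)
    C = None
    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
        keep &= np.all(np.isfinite(C), axis=1)
    dropped = int(n_total - keep.sum())

    t, e, x, m = time[keep], event[keep].astype(int), expo[keep], med[keep]
    cov_names: list[str] = list(covariates.columns) if covariates is not None else []
    Ck = C[keep] if C is not None else None

    X1 = x[:, None] if Ck is None else np.column_stack([x, Ck])
    fit1 = cox_fit(t, e, X1, names=["exposure"] + cov_names, ties=ties)
    X2 = np.column_stack([x, m]) if Ck is None else np.column_stack([x, m, Ck])
    fit2 = cox_fit(t, e, X2, names=["exposure", "mediator"] + cov_names, ties=ties)

    un = fit1.triple("exposure")
    ad = fit2.triple("exposure")
    if abs(math.log(un[0])) < 1e-12:
        atten = math.nan  # undefined when the unadjusted HR is 1
    else:
        atten = 100.0 * (1.0 - math.log(ad[0]) / math.log(un[0]))
    rho = correlate(x, m, method="spearman")
    return MediationResult(
        unadjusted=un,
        mediator_adjusted=ad,
        attenuation_pct=float(atten),
        exposure_mediator_rho=rho,
        n=int(keep.sum()),
        n_events=int(e.sum()),
        n_dropped_missing_mediator=dropped,
        unadjusted_fit=fit1,
        adjusted_fit=fit2,
    )
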