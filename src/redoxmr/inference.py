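"""Statistical core: two-group tests, correlations, linear models with
standardized betas, bootstrap, moderation, Cox partial-likelihood fitting,
Wald utilities, FDR and power.

All estimators here are written against their textbook definitions — the
partial likelihood is maximized by an explicit Newton–Raphson, the
Mann-Whitney test enumerates arrangements exactly for small samples, the
Benjamini–Hochberg step-up is spelled out — because the surrounding causal
analysis leans on their small-sample behaviour.  scipy supplies only
distribution functions and the auxiliary Kolmogorov–Smirnov / Levene trigger
tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._errors import DataError, FitError

__all__ = [
    "TestResult",
    "LinearFit",
    "ModerationResult",
    "CoxFit",
    "WaldTriple",
    "PowerSpec",
    "two_group_test",
    "correlate",
    "bh_fdr",
    "linear_model",
    "moderation",
    "cox_fit",
    "wald_complete",
    "coef_from_ci",
    "power_two_sample",
]

#: two-sided 97.5% normal quantile used for every Wald interval
Z975: float = float(sps.norm.ppf(0.975))

_TINY_P = 1e-300


def _clip_p(p: float) -> float:
    """Keep p-values in the half-open interval (0, 1]."""
    return float(min(1.0, max(p, _TINY_P)))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """Outcome of a two-group test or a correlation."""

    method: str
    statistic: float
    p: float
    n: tuple[int, ...]
    estimate: float | None = None  # e.g. the correlation coefficient

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "n": list(self.n),
            "estimate": self.estimate,
        }


@dataclass
class LinearFit:
    names: list[str]
    coefficients: np.ndarray
    standardized_betas: np.ndarray
    ses: np.ndarray
    ps: np.ndarray
    r2: float
    n: int
    bootstrap_used: bool = False
    bootstrap_reps: int = 0
    bootstrap_cis: np.ndarray | None = None
    heteroscedastic: bool = False
    levene_p: float | None = None
    zero_residual: bool = False

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "coefficients": self.coefficients.tolist(),
            "standardized_betas": self.standardized_betas.tolist(),
            "ses": self.ses.tolist(),
            "ps": self.ps.tolist(),
            "r2": self.r2,
            "n": self.n,
            "bootstrap_used": self.bootstrap_used,
            "bootstrap_reps": self.bootstrap_reps,
            "heteroscedastic": self.heteroscedastic,
            "levene_p": self.levene_p,
        }


@dataclass
class ModerationResult:
    interaction_b: float
    ci: tuple[float, float]
    p: float
    bootstrap_reps: int
    fit: LinearFit | None = None

    def to_dict(self) -> dict:
        return {
            "interaction_b": self.interaction_b,
            "ci": list(self.ci),
            "p": self.p,
            "bootstrap_reps": self.bootstrap_reps,
        }


@dataclass
class CoxFit:
    names: list[str]
    log_hrs: np.ndarray
    ses: np.ndarray
    ties_method: str
    n: int
    n_events: int
    log_partial_likelihood: float
    null_log_partial_likelihood: float
    iterations: int
    max_score: float

    @property
    def hrs(self) -> np.ndarray:
        return np.exp(self.log_hrs)

    @property
    def wald_cis(self) -> np.ndarray:
        lo = np.exp(self.log_hrs - Z975 * self.ses)
        hi = np.exp(self.log_hrs + Z975 * self.ses)
        return np.column_stack([lo, hi])

    @property
    def wald_ps(self) -> np.ndarray:
        z = np.abs(self.log_hrs) / self.ses
        return np.maximum(2.0 * sps.norm.sf(z), _TINY_P)

    def triple(self, name: str) -> tuple[float, tuple[float, float], float]:
        """(HR, 95% CI, p) for one covariate."""
        i = self.names.index(name)
        ci = self.wald_cis[i]
        return float(self.hrs[i]), (float(ci[0]), float(ci[1])), float(self.wald_ps[i])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "log_hrs": self.log_hrs.tolist(),
            "hrs": self.hrs.tolist(),
            "ses": self.ses.tolist(),
            "wald_cis": self.wald_cis.tolist(),
            "wald_ps": self.wald_ps.tolist(),
            "ties_method": self.ties_method,
            "n": self.n,
            "n_events": self.n_events,
            "log_partial_likelihood": self.log_partial_likelihood,
        }


@dataclass
class WaldTriple:
    """A completed (estimate, CI, p) triple on the hazard-ratio scale."""

    hr: float
    ci: tuple[float, float]
    p: float
    log_hr: float
    se: float

    def to_dict(self) -> dict:
        return {"hr": self.hr, "ci": list(self.ci), "p": self.p,
                "log_hr": self.log_hr, "se": self.se}


@dataclass
class PowerSpec:
    delta: float
    sd: float
    n1: int
    n2: int
    alpha: float
    power: float

    def to_dict(self) -> dict:
        return {"delta": self.delta, "sd": self.sd, "n1": self.n1,
                "n2": self.n2, "alpha": self.alpha, "power": self.power}


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------


def _ks_normal_p(x: np.ndarray) -> float:
    """Kolmogorov–Smirnov test of normality against N(mean, sd) of the sample."""
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(mu, sd)).pvalue)


def _student_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError("Student t test needs at least 2 observations per group")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 and v2 == 0:
        raise DataError("both groups have zero variance; t statistic undefined")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (float(np.mean(x)) - float(np.mean(y))) / se
    p = _clip_p(2.0 * sps.t.sf(abs(t), df))
    return TestResult("student_t", float(t), p, (n1, n2))


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for group x, from midranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(np.sum(ranks[: len(x)]))
    return r1 - len(x) * (len(x) + 1) / 2.0


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> TestResult:
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise DataError("Mann-Whitney needs at least 1 observation per group")
    u = _mw_u(x, y)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= 12:
        # exact two-sided p by full enumeration of which n1 of the pooled
        # values land in group one; ties handled through midranks
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        obs_dev = abs(u - mu)
        total = 0
        extreme = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(comb)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
        method = "mann_whitney_exact"
    else:
        n = n1 + n2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return TestResult("mann_whitney_normal", float(u), 1.0, (n1, n2))
        z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)  # continuity corrected
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
        method = "mann_whitney_normal"
    return TestResult(method, float(u), _clip_p(p), (n1, n2))


def two_group_test(
    x,
    y,
    auto_select: bool = True,
    method: str | None = None,
    normality_alpha: float = 0.05,
) -> TestResult:
    """Compare two independent samples.

    With ``auto_select`` the Kolmogorov–Smirnov normality test at
    ``normality_alpha`` on each group picks the unpaired Student t test (both
    groups compatible with normality) or the Mann-Whitney U test; an explicit
    ``method`` ("t" or "mannwhitney") overrides the selection.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if method is None:
        if auto_select:
            both_normal = (
                len(x) >= 3
                and len(y) >= 3
                and _ks_normal_p(x) > normality_alpha
                and _ks_normal_p(y) > normality_alpha
            )
            method = "t" if both_normal else "mannwhitney"
        else:
            method = "t"
    if method == "t":
        return _student_t(x, y)
    if method == "mannwhitney":
        return _mann_whitney(x, y)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise DataError("correlation undefined for constant input")
    return float(xc @ yc) / denom


def correlate(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman rank correlation with a t-approximation p-value.

    Spearman is Pearson computed on midranks, so tied values are handled by
    the midrank convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if n != len(y):
        raise DataError("x and y must have equal length")
    if n < 3:
        raise DataError("correlation needs n >= 3")
    if method == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r = _pearson_r(x, y)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = _TINY_P
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = _clip_p(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(method, r, p, (n,), estimate=r)


# ---------------------------------------------------------------------------
# false discovery rate
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (capped at 1, monotone)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise DataError("bh_fdr needs at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


def _design(X: np.ndarray, names: list[str] | None) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def _aliased_columns(M: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that do not add rank (greedy left-to-right scan)."""
    aliased = []
    kept: list[int] = []
    for j in range(M.shape[1]):
        cand = M[:, kept + [j]]
        if np.linalg.matrix_rank(cand) <= len(kept):
            aliased.append(names[j])
        else:
            kept.append(j)
    return aliased


def linear_model(
    y,
    X,
    names: list[str] | None = None,
    bootstrap_policy: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
    levene_alpha: float = 0.05,
) -> LinearFit:
    """Ordinary least squares with an intercept, standardized betas, and a
    Levene-triggered percentile bootstrap.

    Standardized betas rescale each slope by sd(x_j)/sd(y), so the
    standardized beta of a univariate model equals the Pearson correlation.
    When ``bootstrap_policy`` is "auto", a Levene test across terciles of the
    fitted values significant at ``levene_alpha`` flags heteroscedasticity and
    replaces the normal-theory intervals by a seeded percentile bootstrap;
    "always"/"never" force the choice.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, xnames = _design(X, names)
    n, k = X.shape
    if n != len(y):
        raise DataError("y and X must have the same number of rows")
    if n <= k + 1:
        raise DataError(f"need n > p: n={n}, p={k + 1} (incl. intercept)")
    M = np.column_stack([np.ones(n), X])
    all_names = ["intercept"] + xnames
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise FitError(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(_aliased_columns(M, all_names))
        )

    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    fitted = M @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    df = n - M.shape[1]
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(M.T @ M)
    ses = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    zero_resid = rss <= 1e-12 * max(tss, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(ses > 0, coef / ses, np.inf * np.sign(coef))
    ps = np.array([_clip_p(2.0 * sps.t.sf(abs(t), df)) for t in tvals])

    sd_y = float(np.std(y, ddof=1))
    sd_x = np.std(X, axis=0, ddof=1)
    std_betas = np.concatenate([[np.nan], coef[1:] * sd_x / sd_y if sd_y > 0 else
                                np.full(k, np.nan)])

    # Levene trigger across fitted-value terciles
    levene_p = None
    hetero = False
    if not zero_resid and bootstrap_policy != "never":
        cuts = np.quantile(fitted, [1 / 3, 2 / 3])
        g = np.digitize(fitted, cuts, right=True)
        groups = [resid[g == j] for j in range(3) if np.sum(g == j) >= 2]
        if len(groups) >= 2:
            levene_p = float(sps.levene(*groups).pvalue)
            hetero = levene_p < levene_alpha

    use_boot = bootstrap_policy == "always" or (bootstrap_policy == "auto" and hetero)
    boot_cis = None
    reps = 0
    if use_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, M.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            Mb = M[idx]
            if np.linalg.matrix_rank(Mb) < Mb.shape[1]:
                boots[b] = boots[b - 1] if b else coef
                continue
            boots[b], _, _, _ = np.linalg.lstsq(Mb, y[idx], rcond=None)
        boot_cis = np.column_stack(
            [np.percentile(boots, 2.5, axis=0), np.percentile(boots, 97.5, axis=0)]
        )
        reps = n_boot

    return LinearFit(
        names=all_names,
        coefficients=coef,
        standardized_betas=std_betas,
        ses=ses,
        ps=ps,
        r2=r2,
        n=n,
        bootstrap_used=use_boot,
        bootstrap_reps=reps,
        bootstrap_cis=boot_cis,
        heteroscedastic=hetero,
        levene_p=levene_p,
        zero_residual=zero_resid,
    )


def moderation(
    y,
    x,
    m,
    covariates=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> ModerationResult:
    """Interaction (moderation) analysis: fit ``y ~ x + m + x·m (+ covariates)``
    with a binary moderator ``m`` and report the interaction coefficient with a
    seeded percentile-bootstrap CI (normal-theory CI when ``n_boot`` is 0).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    strata = np.unique(m)
    if strata.size < 2:
        raise DataError("moderator has a single stratum")
    if min(np.sum(m == s) for s in strata) < 10:
        raise DataError("each moderator stratum needs n >= 10")
    cols = [x, m, x * m]
    names = ["x", "m", "x_m"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for j in range(C.shape[1]):
            cols.append(C[:, j])
            names.append(f"c{j}")
    X = np.column_stack(cols)
    fit = linear_model(y, X, names=names, bootstrap_policy="never")
    j = fit.names.index("x_m")
    b = float(fit.coefficients[j])
    p = float(fit.ps[j])
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        M = np.column_stack([np.ones(n), X])
        boots = np.empty(n_boot)
        for it in range(n_boot):
            idx = rng.integers(0, n, n)
            cb, _, _, _ = np.linalg.lstsq(M[idx], y[idx], rcond=None)
            boots[it] = cb[j]  # names include the intercept at position 0
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        half = Z975 * float(fit.ses[j])
        ci = (b - half, b + half)
    return ModerationResult(interaction_b=b, ci=ci, p=p,
                            bootstrap_reps=n_boot, fit=fit)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


class _CoxData:
    """Pre-sorted data plus the event-time grouping reused every iteration."""

    def __init__(self, times: np.ndarray, events: np.ndarray, X: np.ndarray):
        self.X = X
        self.times = times
        ev_pos = np.flatnonzero(events)
        # risk-set start: first subject with time >= the event's time
        starts = np.searchsorted(times, times[ev_pos], side="left")
        uniq_start, first, counts = np.unique(starts, return_index=True,
                                              return_counts=True)
        single = counts == 1
        self.single_ev = ev_pos[first[single]]
        self.single_start = uniq_start[single]
        self.tied: list[tuple[int, np.ndarray]] = []
        for s, f, c in zip(uniq_start[~single], first[~single], counts[~single]):
            self.tied.append((int(s), ev_pos[f : f + c]))


def _cox_loglik_score_info(beta, data: _CoxData, ties: str):
    """Log partial likelihood, score and observed information.

    Risk sets are suffix sums over subjects sorted by ascending time; untied
    event times are handled fully vectorized, tied blocks with the Efron or
    Breslow correction in a short loop.
    """
    X = data.X
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)  # columns are centered upstream; eta stays moderate
    wX = X * w[:, None]
    wXX = X[:, :, None] * X[:, None, :] * w[:, None, None]

    # suffix (risk-set) sums at each index
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))

    ev, st = data.single_ev, data.single_start
    if ev.size:
        s0 = S0[st]
        mean1 = S1[st] / s0[:, None]
        loglik += float(eta[ev].sum() - np.log(s0).sum())
        score += X[ev].sum(axis=0) - mean1.sum(axis=0)
        info += np.einsum("ipq,i->pq", S2[st], 1.0 / s0) - mean1.T @ mean1

    for start, evs in data.tied:
        d = evs.size
        s0, s1, s2 = S0[start], S1[start], S2[start]
        xd = X[evs].sum(axis=0)
        loglik += float(eta[evs].sum())
        if ties == "breslow":
            loglik -= d * math.log(s0)
            mean1 = s1 / s0
            score += xd - d * mean1
            info += d * (s2 / s0 - np.outer(mean1, mean1))
        else:  # efron
            wd = w[evs].sum()
            wd1 = wX[evs].sum(axis=0)
            wd2 = wXX[evs].sum(axis=0)
            for ell in range(d):
                f = ell / d
                a0 = s0 - f * wd
                a1 = s1 - f * wd1
                a2 = s2 - f * wd2
                loglik -= math.log(a0)
                mean1 = a1 / a0
                score += xd / d - mean1
                info += a2 / a0 - np.outer(mean1, mean1)
    return loglik, score, info


def cox_fit(
    time,
    event,
    X,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson on the partial
    likelihood (Efron tie correction by default, Breslow by flag).

    Convergence requires the maximum absolute score component to fall below
    ``tol``.  A coefficient diverging beyond \\|beta\\|>20 is reported as
    non-identifiable (monotone likelihood / complete separation).
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(bool).ravel()
    X, xnames = _design(X, names)
    n, p = X.shape
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if len(time) != n or len(event) != n:
        raise DataError("time, event and X must align")
    if np.any(time < 0) or np.any(~np.isfinite(time)):
        raise DataError("times must be finite and nonnegative")
    n_events = int(event.sum())
    if n_events == 0:
        raise FitError("no events: the partial likelihood is constant")
    for j in range(p):
        if np.std(X[event, j]) == 0 and np.std(X[:, j]) == 0:
            raise FitError(f"covariate {xnames[j]!r} is constant")

    order = np.argsort(time, kind="stable")
    ts, ev, Xs = time[order], event[order], X[order]

    # center columns for conditioning; estimates are unaffected
    mu = Xs.mean(axis=0)
    Xc = Xs - mu
    data = _CoxData(ts, ev, Xc)

    beta = np.zeros(p)
    ll0, _, _ = _cox_loglik_score_info(beta, data, ties)
    ll = ll0
    it = 0
    max_score = np.inf
    for it in range(1, max_iter + 1):
        ll, score, info = _cox_loglik_score_info(beta, data, ties)
        max_score = float(np.max(np.abs(score)))
        if max_score < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix in Cox fit") from exc
        # step-halving to keep the likelihood nondecreasing
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_new, _, _ = _cox_loglik_score_info(cand, data, ties)
            if ll_new >= ll - 1e-12:
                beta = cand
                break
            lam *= 0.5
        else:
            break
        if np.max(np.abs(beta)) > 20:
            raise FitError(
                "non-identifiable fit: |beta| diverged beyond 20 "
                "(monotone partial likelihood / complete separation)"
            )
    else:
        if max_score > 1e-6:
            raise FitError(f"Cox fit did not converge (max score {max_score:.2e})")

    ll, score, info = _cox_loglik_score_info(beta, data, ties)
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxFit(
        names=xnames,
        log_hrs=beta,
        ses=ses,
        ties_method=ties,
        n=n,
        n_events=n_events,
        log_partial_likelihood=float(ll),
        null_log_partial_likelihood=float(ll0),
        iterations=it,
        max_score=float(np.max(np.abs(score))),
    )


# ---------------------------------------------------------------------------
# Wald utilities
# ---------------------------------------------------------------------------


def wald_complete(
    hr: float | None = None,
    ci: tuple[float, float] | None = None,
    log_hr: float | None = None,
    se: float | None = None,
) -> WaldTriple:
    """Complete a printed (HR, 95% CI, p) triple from any sufficient subset.

    From a CI alone: ``hr = exp((ln lo + ln hi)/2)`` and
    ``se = (ln hi − ln lo)/(2 z_0.975)``; the p-value is the two-sided normal
    tail of ``|ln hr|/se``.
    """
    if ci is not None:
        lo, hi = float(ci[0]), float(ci[1])
        if lo <= 0 or hi <= 0:
            raise DataError("hazard-ratio CI bounds must be positive")
        if lo >= hi:
            raise DataError("degenerate CI: lower bound must be below upper bound")
        if se is None:
            se = (math.log(hi) - math.log(lo)) / (2.0 * Z975)
        if log_hr is None and hr is None:
            log_hr = 0.5 * (math.log(lo) + math.log(hi))
    if log_hr is None:
        if hr is None:
            raise DataError("need an estimate (hr or log_hr) or a CI")
        if hr <= 0:
            raise DataError("hazard ratio must be positive")
        log_hr = math.log(hr)
    if se is None:
        raise DataError("need a CI or an se to complete the triple")
    if se <= 0:
        raise DataError("se must be positive")
    hr_out = math.exp(log_hr)
    ci_out = (math.exp(log_hr - Z975 * se), math.exp(log_hr + Z975 * se))
    p = _clip_p(2.0 * sps.norm.sf(abs(log_hr) / se))
    return WaldTriple(hr=hr_out, ci=ci_out, p=p, log_hr=log_hr, se=se)


def coef_from_ci(lo: float, hi: float) -> tuple[float, float, float]:
    """Recover (estimate, se, two-sided p) from a symmetric Wald CI on the
    identity scale (e.g. a printed regression/moderation coefficient)."""
    if lo >= hi:
        raise DataError("degenerate CI: lower bound must be below upper bound")
    b = 0.5 * (lo + hi)
    se = (hi - lo) / (2.0 * Z975)
    p = _clip_p(2.0 * sps.norm.sf(abs(b) / se))
    return b, se, p


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def power_two_sample(delta: float, sd: float, n1: int, n2: int,
                     alpha: float = 0.05) -> PowerSpec:
    """Two-sided normal-approximation power for a two-sample mean difference."""
    if sd <= 0:
        raise DataError("sd must be positive")
    if n1 < 2 or n2 < 2:
        raise DataError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    se = sd * math.sqrt(1.0 / n1 + 1.0 / n2)
    z_a = float(sps.norm.ppf(1.0 - alpha / 2.0))
    ncp = abs(delta) / se
    power = float(sps.norm.cdf(ncp - z_a) + sps.norm.cdf(-ncp - z_a))
    return PowerSpec(delta=delta, sd=sd, n1=n1, n2=n2, alpha=alpha, power=power)
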