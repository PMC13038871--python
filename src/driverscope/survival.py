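"""Pathway-level prognostic modeling.

The survival stages of the discovery pipeline: landmark-stratified cohort
splitting, a Breslow Cox solver, univariate screening with
Benjamini-Hochberg control, bootstrap elastic-net stability selection,
Harrell's C and IPCW time-dependent AUC, Kaplan-Meier/log-rank utilities
with optimal-cutpoint stratification, a learner-agnostic benchmarking
harness with seeded random hyperparameter search, and Monte-Carlo Shapley
attribution.

Times are in days throughout; risk scores follow the convention
"higher = worse" (shorter expected survival).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SurvivalTable
from .scoring import PathwayScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSplit",
    "CoxFit",
    "ScreenResult",
    "StabilitySelectionResult",
    "BenchmarkReport",
    "AttributionMatrix",
    "ConvergenceError",
    "SeparationError",
    "LearnerContractError",
    "LearnerSpec",
    "PenalizedCoxLearner",
    "landmark_stratified_split",
    "fit_cox",
    "univariate_cox_screen",
    "stability_selection",
    "concordance_index",
    "time_dependent_auc",
    "km_logrank",
    "optimal_cutpoint",
    "benchmark_models",
    "shapley_importance",
]

DEFAULT_LANDMARKS = (365.0, 1095.0, 1825.0)  # ~1, 3, 5 years in days
DEFAULT_HORIZONS = (365.0, 1095.0, 1825.0)


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    pass


class LearnerContractError(RuntimeError):
    pass


def _as_feature_frame(features) -> pd.DataFrame:
    """Accept a samples x features DataFrame or a PathwayScoreMatrix
    (whose NES matrix is transposed into that orientation)."""
    if isinstance(features, PathwayScoreMatrix):
        return features.nes.T
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError(f"unsupported feature container {type(features).__name__}")


# ---------------------------------------------------------------------------
# Cohort splitting
# ---------------------------------------------------------------------------


@dataclass
class CohortSplit:
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    ratio: float
    landmarks: tuple[float, ...]
    landmark_tolerance: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation sets overlap")


def landmark_stratified_split(
    surv: SurvivalTable,
    ratio: float = 0.7,
    landmarks: Sequence[float] = DEFAULT_LANDMARKS,
    tolerance: float = 90.0,
    seed: int = 0,
) -> CohortSplit:
    """Train/validation split guaranteeing landmark representation.

    For every landmark time with at least two subjects whose follow-up lies
    within ``tolerance`` days of it, at least one such subject is placed in
    each partition.  All remaining subjects are split at ``ratio``,
    stratified by event status as far as integer counts allow.
    """
    n = len(surv)
    if n < 10:
        raise ValueError(f"need >= 10 subjects to split, got {n}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(surv.subject_ids, dtype=object)
    time, event = surv.time, surv.event

    target_train = int(round(ratio * n))
    assigned: dict[str, str] = {}
    for lm in landmarks:
        eligible = [
            ids[i] for i in range(n) if abs(time[i] - lm) <= tolerance
        ]
        free = [s for s in eligible if s not in assigned]
        have_train = any(assigned.get(s) == "train" for s in eligible)
        have_val = any(assigned.get(s) == "validation" for s in eligible)
        if len(eligible) >= 2:
            rng.shuffle(free)
            if not have_train and free:
                assigned[free.pop()] = "train"
            if not have_val and free:
                assigned[free.pop()] = "validation"

    n_train_pinned = sum(1 for v in assigned.values() if v == "train")
    remaining_train = target_train - n_train_pinned
    pool_mask = ~np.isin(ids, list(assigned))
    train_rest: list = []
    val_rest: list = []
    pool_ids = ids[pool_mask]
    pool_event = event[pool_mask]
    # Event-stratified allocation with largest-remainder rounding against
    # the global remaining-train quota.
    strata = [pool_ids[pool_event == 1], pool_ids[pool_event == 0]]
    quotas = []
    total_pool = len(pool_ids)
    for s in strata:
        quotas.append(remaining_train * len(s) / total_pool if total_pool else 0.0)
    base = [int(np.floor(q)) for q in quotas]
    short = remaining_train - sum(base)
    order = np.argsort([-(q - b) for q, b in zip(quotas, base)], kind="stable")
    for k in range(short):
        base[order[k]] += 1
    for s, take in zip(strata, base):
        s = s.copy()
        rng.shuffle(s)
        take = int(np.clip(take, 0, len(s)))
        train_rest.extend(s[:take])
        val_rest.extend(s[take:])

    train = [s for s, part in assigned.items() if part == "train"] + train_rest
    val = [s for s, part in assigned.items() if part == "validation"] + val_rest
    return CohortSplit(
        train_ids=tuple(sorted(train)),
        validation_ids=tuple(sorted(val)),
        ratio=ratio,
        landmarks=tuple(landmarks),
        landmark_tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Breslow Cox solver
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Breslow ties)."""

    summary: pd.DataFrame  # beta, se, z, p, hr, hr_lo, hr_hi per covariate
    log_partial_likelihood: float
    n_iterations: int
    ties: str = "breslow"

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["beta"]

    def predict_risk(self, covariates: pd.DataFrame) -> np.ndarray:
        x = covariates[self.summary.index].to_numpy(float)
        return x @ self.summary["beta"].to_numpy()


def _breslow_quantities(x, time, event, beta, penalty=0.0):
    """Log partial likelihood, gradient and Hessian under Breslow ties,
    optionally with a ridge penalty 0.5 * penalty * ||beta||^2."""
    order = np.argsort(time, kind="stable")
    x = x[order]
    time = time[order]
    event = event[order].astype(bool)
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    # Reverse cumulative sums give risk-set aggregates for each index i
    # (risk set = subjects with time >= time_i; ties enter via searchsorted).
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (x[:, :, None] * x[:, None, :]))[::-1], axis=0)[::-1]

    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    event_times = np.unique(time[event])
    for t in event_times:
        at_risk = np.searchsorted(time, t, side="left")
        in_tie = event & (time == t)
        d = int(in_tie.sum())
        s0, s1, s2 = S0[at_risk], S1[at_risk], S2[at_risk]
        ll += eta[in_tie].sum() - d * np.log(s0)
        grad += x[in_tie].sum(axis=0) - d * s1 / s0
        hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
    if penalty > 0:
        ll -= 0.5 * penalty * float(beta @ beta)
        grad -= penalty * beta
        hess -= penalty * np.eye(p)
    return ll, grad, hess


def fit_cox(
    covariates: pd.DataFrame,
    surv: SurvivalTable,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
    penalty: float = 0.0,
) -> CoxFit:
    """Newton maximization of the Breslow partial likelihood.

    Converges when the gradient norm drops below ``tol``; fails with
    :class:`ConvergenceError` after ``max_iter`` iterations and with
    :class:`SeparationError` when any coefficient exceeds 20 in magnitude
    (monotone likelihood / perfect separation).
    """
    if ties != "breslow":
        raise ValueError("only Breslow tie handling is supported")
    cov = covariates.loc[surv.subject_ids]
    x = cov.to_numpy(float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than covariates ({p})")
    variances = x.var(axis=0)
    if penalty == 0.0 and (variances == 0).any():
        name = cov.columns[int(np.argmax(variances == 0))]
        raise ValueError(f"constant covariate {name!r}")
    if surv.event.sum() == 0:
        raise ValueError("no events observed")

    beta = np.zeros(p)
    time, event = surv.time, surv.event
    ll, grad, hess = _breslow_quantities(x, time, event, beta, penalty)
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(hess, -grad)
        # Backtracking in case a full Newton step overshoots.
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            new_ll, new_grad, new_hess = _breslow_quantities(
                x, time, event, candidate, penalty
            )
            if new_ll >= ll - 1e-12:
                beta, ll, grad, hess = candidate, new_ll, new_grad, new_hess
                break
            factor /= 2.0
        else:
            raise ConvergenceError(f"step halving failed at iteration {it}")
        if np.abs(beta).max() > 20.0:
            raise SeparationError(
                "coefficient magnitude exceeded 20; likely monotone likelihood"
            )
    else:
        raise ConvergenceError(
            f"Newton solver did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )

    cov_beta = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov_beta))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "hr": np.exp(beta),
            "hr_lo": np.exp(beta - crit * se),
            "hr_hi": np.exp(beta + crit * se),
        },
        index=cov.columns,
    )
    return CoxFit(summary=summary, log_partial_likelihood=float(ll), n_iterations=it)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    table: pd.DataFrame  # beta, p, q, retained per feature
    skipped: dict[str, str]
    fdr: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def univariate_cox_screen(
    features, surv: SurvivalTable, fdr: float = 0.05
) -> ScreenResult:
    """One single-covariate Cox fit per feature with BH adjustment.

    Zero-variance (and numerically unfittable) features are reported as
    skipped rather than failed; retained features satisfy q <= ``fdr``.
    """
    feats = _as_feature_frame(features)
    common = [s for s in surv.subject_ids if s in feats.index]
    if not common:
        raise ValueError("no subjects shared between features and survival table")
    sub = surv.loc(common)
    feats = feats.loc[common]

    rows, skipped = [], {}
    for name in feats.columns:
        col = feats[[name]]
        if float(col[name].var()) == 0.0:
            skipped[name] = "zero variance"
            continue
        try:
            fit = fit_cox(col, sub)
        except (ConvergenceError, SeparationError) as exc:
            skipped[name] = str(exc)
            continue
        rows.append((name, fit.summary.at[name, "beta"], fit.summary.at[name, "p"]))
    if not rows:
        raise ValueError("no feature could be screened")
    table = pd.DataFrame(rows, columns=["feature", "beta", "p"]).set_index("feature")
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    table["retained"] = table["q"] <= fdr
    return ScreenResult(table=table, skipped=skipped, fdr=fdr)


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


@dataclass
class StabilitySelectionResult:
    frequencies: pd.Series  # per-feature selection frequency in [0, 1]
    n_resamples: int
    subsample_fraction: float
    l1_ratio: float
    lambda_path: str

    def __post_init__(self) -> None:
        f = self.frequencies.to_numpy()
        if (f < 0).any() or (f > 1).any():
            raise ValueError("selection frequencies must lie in [0, 1]")


def stability_selection(
    features,
    surv: SurvivalTable,
    n_resamples: int = 1000,
    subsample: float = 0.7,
    l1_ratio: float = 0.1,
    n_lambdas: int = 50,
    seed: int = 0,
) -> StabilitySelectionResult:
    """Bootstrap stability selection for an elastic-net-penalized Cox model.

    Each resample draws ``subsample`` of the training subjects with
    replacement and fits the penalized Cox path over ``n_lambdas``
    log-spaced values from the data-derived lambda_max down to
    0.01 * lambda_max; a feature counts as selected when its coefficient is
    non-zero at any lambda.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    feats = _as_feature_frame(features)
    if feats.shape[1] < 2:
        raise ValueError("need >= 2 features for stability selection")
    feats = feats.loc[surv.subject_ids]
    x = feats.to_numpy(float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    time, event = surv.time, surv.event

    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    rng = np.random.default_rng(seed)
    n = len(surv)
    m = int(round(subsample * n))
    counts = np.zeros(feats.shape[1])
    done = 0
    attempts = 0
    while done < n_resamples:
        attempts += 1
        if attempts > 20 * n_resamples:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=m)
        ev = event[idx]
        if ev.sum() < 2 or len(np.unique(time[idx][ev == 1])) < 2:
            continue
        y = Surv.from_arrays(event=ev.astype(bool), time=time[idx])
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            n_alphas=n_lambdas,
            alpha_min_ratio=0.01,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(x[idx], y)
            except (ArithmeticError, ValueError):
                continue
        counts += (np.abs(model.coef_) > 0).any(axis=1)
        done += 1
    freqs = pd.Series(counts / n_resamples, index=feats.columns, name="frequency")
    return StabilitySelectionResult(
        frequencies=freqs,
        n_resamples=n_resamples,
        subsample_fraction=subsample,
        l1_ratio=l1_ratio,
        lambda_path=f"{n_lambdas} log-spaced values, lambda_min = 0.01 * lambda_max",
    )


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------


def concordance_index(risk: np.ndarray, surv: SurvivalTable) -> float:
    """Harrell's C over event-anchored comparable pairs, risk ties = 0.5.

    A pair (i, j) is comparable when subject i has an event and either
    dies strictly earlier than j's follow-up or dies at j's censoring time.
    Returns 0.5 (with a warning) when no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(surv):
        raise ValueError("risk vector length does not match survival table")
    time, event = surv.time, surv.event
    num = den = 0.0
    for i in np.flatnonzero(event == 1):
        comparable = (time > time[i]) | ((time == time[i]) & (event == 0))
        den += comparable.sum()
        num += (risk[i] > risk[comparable]).sum() + 0.5 * (
            risk[i] == risk[comparable]
        ).sum()
    if den == 0:
        logger.warning("no comparable pairs; returning 0.5")
        return 0.5
    return float(num / den)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Kaplan-Meier estimator of the censoring distribution G, returned as
    a function evaluating the LEFT limit G(t-)."""
    order = np.argsort(time, kind="stable")
    t, c = time[order], 1 - event[order]
    uniq = np.unique(t)
    surv_vals = []
    g = 1.0
    for u in uniq:
        at_risk = (t >= u).sum()
        d = int(c[(t == u)].sum())
        g *= 1.0 - d / at_risk
        surv_vals.append(g)
    uniq = np.asarray(uniq)
    surv_vals = np.asarray(surv_vals)

    def g_minus(q: np.ndarray) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        idx = np.searchsorted(uniq, q, side="left") - 1  # strictly before q
        out = np.where(idx >= 0, surv_vals[np.clip(idx, 0, None)], 1.0)
        return out

    return g_minus


def time_dependent_auc(
    risk: np.ndarray,
    surv: SurvivalTable,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> pd.Series:
    """Cumulative-case/dynamic-control AUC with IPCW case weights.

    At horizon t, cases are subjects with an observed event by t (weighted
    by the inverse censoring survival at their event time), controls are
    subjects still under observation beyond t.  Horizons at or beyond the
    maximum follow-up are reported as NaN (undefined).
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(surv):
        raise ValueError("risk vector length does not match survival table")
    time, event = surv.time, surv.event
    g_minus = _censoring_survival(time, event)
    out = {}
    for t in horizons:
        if t >= time.max():
            out[t] = np.nan
            continue
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            out[t] = np.nan
            continue
        w = 1.0 / g_minus(time[cases])
        r_case, r_ctrl = risk[cases], risk[controls]
        conc = (r_case[:, None] > r_ctrl[None, :]).astype(float)
        conc += 0.5 * (r_case[:, None] == r_ctrl[None, :])
        out[t] = float((w[:, None] * conc).sum() / (w.sum() * controls.sum()))
    return pd.Series(out, name="td_auc")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / cutpoint
# ---------------------------------------------------------------------------


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) table
    chi_square: float
    p_value: float


def km_logrank(surv: SurvivalTable, group: Sequence) -> KmResult:
    """Product-limit curves per group and the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    group = np.asarray(group)
    if len(group) != len(surv):
        raise ValueError("group labels do not match survival table")
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(levels)}")
    time, event = surv.time, surv.event
    curves = {}
    for lv in levels:
        mask = group == lv
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[str(lv)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    mask = group == levels[0]
    res = logrank_test(time[mask], time[~mask], event[mask], event[~mask])
    return KmResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def _logrank_statistic(time, event, mask) -> float:
    """Two-group log-rank chi-square; own O-E implementation used for the
    cutpoint scan (lifelines provides the dual route in km_logrank)."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & mask).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & mask).sum())
        o_minus_e += d1 - d * n1 / n_tot
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


@dataclass
class CutpointResult:
    cutpoint: float
    labels: pd.Series  # "high"/"low" per subject
    chi_square: float
    p_value: float
    selection_biased: bool = True  # p maximized over cutpoints; not nominal


def optimal_cutpoint(
    marker: pd.Series,
    surv: SurvivalTable,
    min_group_fraction: float = 0.1,
) -> CutpointResult:
    """Cutpoint maximizing the log-rank statistic over admissible midpoints.

    Candidate cutpoints are midpoints between consecutive sorted unique
    marker values leaving at least ``min_group_fraction`` of subjects in
    each arm.  The reported p-value is selection-biased (maximally selected
    statistic) and flagged as such.
    """
    marker = marker.loc[surv.subject_ids]
    vals = marker.to_numpy(float)
    uniq = np.unique(vals)
    if len(uniq) < 2:
        raise ValueError("marker must have >= 2 distinct values")
    n = len(vals)
    time, event = surv.time, surv.event
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = vals > cut
        if min(high.sum(), n - high.sum()) < min_group_fraction * n:
            continue
        chi2 = _logrank_statistic(time, event, high)
        if best is None or chi2 > best[1]:
            best = (cut, chi2)
    if best is None:
        raise ValueError("no admissible cutpoint under min_group_fraction")
    cut, chi2 = best
    labels = pd.Series(
        np.where(vals > cut, "high", "low"), index=marker.index, name="group"
    )
    return CutpointResult(
        cutpoint=float(cut),
        labels=labels,
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


# ---------------------------------------------------------------------------
# Learner contract and benchmarking harness
# ---------------------------------------------------------------------------


@runtime_checkable
class SurvivalLearner(Protocol):
    """Contract: fit on (features, survival), emit a real risk score per
    subject with higher = worse."""

    def fit(self, features: pd.DataFrame, surv: SurvivalTable) -> "SurvivalLearner": ...

    def risk(self, features: pd.DataFrame) -> np.ndarray: ...


@dataclass
class LearnerSpec:
    """A named learner factory with a hyperparameter search space.

    ``space`` maps parameter name to ("uniform", lo, hi),
    ("loguniform", lo, hi), ("int", lo, hi) or ("choice", [values]).
    """

    name: str
    factory: Callable[..., SurvivalLearner]
    space: Mapping[str, tuple] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> dict:
        params = {}
        for key, spec in self.space.items():
            kind = spec[0]
            if kind == "uniform":
                params[key] = float(rng.uniform(spec[1], spec[2]))
            elif kind == "loguniform":
                params[key] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
            elif kind == "int":
                params[key] = int(rng.integers(spec[1], spec[2] + 1))
            elif kind == "choice":
                params[key] = spec[1][int(rng.integers(0, len(spec[1])))]
            else:
                raise ValueError(f"unknown space kind {kind!r}")
        return params


class PenalizedCoxLearner:
    """Ridge-penalized Cox model on standardized features (the shipped
    reference learner for the benchmarking harness)."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = float(alpha)
        self._fit: CoxFit | None = None
        self._center: pd.Series | None = None
        self._scale: pd.Series | None = None

    def fit(self, features: pd.DataFrame, surv: SurvivalTable) -> "PenalizedCoxLearner":
        feats = features.loc[surv.subject_ids]
        self._center = feats.mean()
        scale = feats.std(ddof=0)
        self._scale = scale.where(scale > 0, 1.0)
        z = (feats - self._center) / self._scale
        self._fit = fit_cox(z, surv, penalty=self.alpha)
        return self

    def risk(self, features: pd.DataFrame) -> np.ndarray:
        if self._fit is None:
            raise RuntimeError("learner not fitted")
        z = (features - self._center) / self._scale
        return self._fit.predict_risk(z)


@dataclass
class BenchmarkReport:
    per_learner: dict[str, dict]  # name -> {best_params, cv_cindex, evaluations}

    def best_learner(self) -> str:
        return max(self.per_learner, key=lambda k: self.per_learner[k]["cv_cindex"])


def _check_risk(name: str, risk, n: int) -> np.ndarray:
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (n,) or not np.all(np.isfinite(risk)):
        raise LearnerContractError(
            f"learner {name!r} returned an invalid risk vector"
        )
    return risk


def benchmark_models(
    features,
    surv: SurvivalTable,
    learners: Sequence[LearnerSpec],
    n_folds: int = 5,
    n_search: int = 10,
    seed: int = 0,
    cohorts: Mapping[str, tuple] | None = None,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> BenchmarkReport:
    """Seeded random hyperparameter search with k-fold CV model selection.

    For each learner, ``n_search`` parameter draws are scored by mean
    ``n_folds``-fold cross-validated C-index on the training cohort; the
    winner is refit on the full training data and evaluated (C-index and
    time-dependent AUC) on the training cohort plus every cohort supplied
    in ``cohorts`` (name -> (features, survival)).
    """
    feats = _as_feature_frame(features).loc[surv.subject_ids]
    n = len(surv)
    if n_folds > n:
        raise ValueError(f"n_folds ({n_folds}) exceeds cohort size ({n})")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    from sklearn.model_selection import KFold

    report: dict[str, dict] = {}
    for li, spec in enumerate(learners):
        rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31) + li)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
        candidates = [spec.sample(rng) for _ in range(max(1, n_search))]
        best_params, best_cv = None, -np.inf
        for params in candidates:
            scores = []
            for tr_idx, te_idx in kf.split(feats):
                tr_ids = feats.index[tr_idx]
                te_ids = feats.index[te_idx]
                try:
                    learner = spec.factory(**params)
                    learner.fit(feats.loc[tr_ids], surv.loc(tr_ids))
                    risk = _check_risk(
                        spec.name, learner.risk(feats.loc[te_ids]), len(te_ids)
                    )
                except LearnerContractError:
                    raise
                except Exception as exc:
                    raise LearnerContractError(
                        f"learner {spec.name!r} failed during CV: {exc}"
                    ) from exc
                scores.append(concordance_index(risk, surv.loc(te_ids)))
            mean_score = float(np.mean(scores))
            if mean_score > best_cv:
                best_cv, best_params = mean_score, params
        final = spec.factory(**best_params)
        final.fit(feats, surv)
        evals = {}
        all_cohorts = {"train": (feats, surv), **(cohorts or {})}
        for cname, (cfeat, csurv) in all_cohorts.items():
            cfeat = _as_feature_frame(cfeat).loc[csurv.subject_ids]
            risk = _check_risk(spec.name, final.risk(cfeat), len(csurv))
            evals[cname] = {
                "c_index": concordance_index(risk, csurv),
                "td_auc": time_dependent_auc(risk, csurv, horizons).to_dict(),
            }
        report[spec.name] = {
            "best_params": best_params,
            "cv_cindex": best_cv,
            "evaluations": evals,
            "model": final,
        }
    return BenchmarkReport(per_learner=report)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionMatrix:
    contributions: pd.DataFrame  # patients x features
    global_importance: pd.Series  # mean over patients per feature
    n_permutations: int
    baseline: pd.Series


def shapley_importance(
    model: Callable[[pd.DataFrame], np.ndarray],
    features: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
    baseline: pd.Series | None = None,
) -> AttributionMatrix:
    """Monte-Carlo Shapley attribution of per-patient predicted risk.

    For each sampled feature ordering, features are switched one by one
    from the baseline (training mean by default) to the patient's value;
    the marginal change in model output is credited to the switched
    feature.  Per permutation the credits sum exactly to
    prediction - baseline prediction, so the average retains additivity.
    Positive mean attribution = risk-increasing.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if baseline is None:
        baseline = features.mean()
    rng = np.random.default_rng(seed)
    n, p = features.shape
    x = features.to_numpy(float)
    base = baseline[features.columns].to_numpy(float)

    def evaluate(mat: np.ndarray) -> np.ndarray:
        out = np.asarray(
            model(pd.DataFrame(mat, index=features.index, columns=features.columns)),
            dtype=float,
        )
        if out.shape != (n,) or not np.all(np.isfinite(out)):
            raise ValueError("model produced non-finite or misshapen output")
        return out

    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        z = np.tile(base, (n, 1))
        prev = evaluate(z)
        for j in order:
            z[:, j] = x[:, j]
            cur = evaluate(z)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_permutations
    contributions = pd.DataFrame(phi, index=features.index, columns=features.columns)
    return AttributionMatrix(
        contributions=contributions,
        global_importance=contributions.mean(axis=0),
        n_permutations=n_permutations,
        baseline=baseline[features.columns],
    )
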