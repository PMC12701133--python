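"""Prognostic-factor statistics for the seven-day survival outcome.

Three analyses mirror the standard clinical-report tables:

* :func:`group_comparison` — died-vs-survived group means with a two-sided
  Welch two-sample p-value (Mann-Whitney selectable);
* :func:`logistic_fit` — binary logistic regression by iteratively
  reweighted least squares (IRLS), reporting coefficient B, SE (observed
  information), standardized Beta, Wald t, 95% Wald CI and odds ratio;
* :func:`feature_impact_ranking` — model-agnostic permutation importance:
  the mean absolute change in predicted probability when one feature column
  is shuffled, averaged over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import ClinicalRecord, INDICATOR_NAMES

__all__ = [
    "GroupComparisonRow", "LogisticRow", "LogisticFit", "group_comparison",
    "group_comparison_table", "logistic_fit", "feature_impact_ranking",
    "benjamini_hochberg",
]


@dataclass
class GroupComparisonRow:
    variable: str
    mean_died: float
    mean_survived: float
    p_value: float


@dataclass
class LogisticRow:
    variable: str
    b: float
    se: float
    beta_standardized: float
    t: float
    ci_low: float
    ci_high: float
    odds_ratio: float


@dataclass
class LogisticFit:
    rows: list[LogisticRow]
    intercept: LogisticRow
    log_likelihood_trace: list[float]
    converged: bool
    separation_flag: bool
    dropped_columns: list[str]

    def row(self, variable: str) -> LogisticRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


def group_comparison(cohort: list[ClinicalRecord], variable: str,
                     test: str = "welch") -> GroupComparisonRow:
    """Compare one indicator between the died (label 1) and survived groups."""
    if variable not in INDICATOR_NAMES:
        raise KeyError(f"unknown indicator {variable!r}")
    values = np.array([r.indicators[variable] for r in cohort])
    labels = np.array([r.label for r in cohort])
    died = values[(labels == 1) & np.isfinite(values)]
    surv = values[(labels == 0) & np.isfinite(values)]
    if len(died) < 2 or len(surv) < 2:
        raise ValueError(
            f"degenerate group for {variable!r}: "
            f"died n={len(died)}, survived n={len(surv)}")
    if test == "welch":
        res = sps.ttest_ind(died, surv, equal_var=False)
        p = float(res.pvalue)
    elif test == "mannwhitney":
        p = float(sps.mannwhitneyu(died, surv,
                                   alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparisonRow(variable=variable, mean_died=float(died.mean()),
                              mean_survived=float(surv.mean()), p_value=p)


def group_comparison_table(cohort: list[ClinicalRecord], test: str = "welch",
                           adjust: bool = False) -> list[GroupComparisonRow]:
    rows = [group_comparison(cohort, v, test=test) for v in INDICATOR_NAMES]
    if adjust:
        adj = benjamini_hochberg(np.array([r.p_value for r in rows]))
        rows = [GroupComparisonRow(r.variable, r.mean_died, r.mean_survived,
                                   float(p)) for r, p in zip(rows, adj)]
    return rows


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; rows are marginal)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * eta) + 1.0)


def logistic_fit(x: np.ndarray, y: np.ndarray,
                 names: list[str] | None = None, max_iter: int = 100,
                 tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with step halving.

    Zero-variance columns are dropped with a warning.  Quasi-perfect
    separation is flagged (huge coefficients / vanishing working weights)
    and the fit reported as non-converged.  The log-likelihood trace is
    non-decreasing by construction (steps are halved until they improve).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    sds = x.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = [names[j] for j in range(p) if not keep[j]]
    if dropped:
        import warnings
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    xk = x[:, keep]
    kept_names = [nm for nm, k in zip(names, keep) if k]
    design = np.column_stack([xk, np.ones(n)])
    q = design.shape[1]
    betas = np.zeros(q)
    betas[-1] = np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12))

    def loglik(b):
        eta = design @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    trace = [loglik(betas)]
    converged = False
    for _ in range(max_iter):
        eta = design @ betas
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(q), grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the log-likelihood non-decreasing
        scale = 1.0
        ll_old = trace[-1]
        for _ in range(30):
            cand = betas + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        betas = betas + scale * step
        trace.append(max(ll_new, ll_old))
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + tol):
            converged = True
            break
    eta = design @ betas
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    info = design.T @ (design * w[:, None])
    sd_floor = max(sds[keep].min(), 1e-6) if keep.any() else 1.0
    separation = bool(np.abs(betas).max() > 20.0 / sd_floor
                      or w.max() < 1e-8)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
        separation = True
    if separation:
        converged = False

    def make_row(name, b, s, sd_col):
        return LogisticRow(
            variable=name, b=float(b), se=float(s),
            beta_standardized=float(b * sd_col),
            t=float(b / s) if s > 0 else np.nan,
            ci_low=float(b - 1.96 * s), ci_high=float(b + 1.96 * s),
            odds_ratio=float(np.exp(b)))

    rows = [make_row(nm, betas[j], se[j], sds[keep][j])
            for j, nm in enumerate(kept_names)]
    intercept = make_row("constant", betas[-1], se[-1], 1.0)
    return LogisticFit(rows=rows, intercept=intercept,
                       log_likelihood_trace=trace, converged=converged,
                       separation_flag=separation, dropped_columns=dropped)


def feature_impact_ranking(predict_fn, x: np.ndarray,
                           feature_names: list[str] | None = None,
                           n_permutations: int = 10, seed: int = 0,
                           top_k: int | None = 20) -> list[tuple[str, float]]:
    """Permutation importance of each feature for a probability model.

    For each feature column, the column is shuffled within itself and the
    mean absolute change of ``predict_fn``'s output probability is recorded,
    averaged over ``n_permutations`` draws.  Constant columns therefore have
    impact exactly zero.  Returns ``(feature, mean |impact|)`` sorted
    descending, truncated to ``top_k``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    names = (list(feature_names) if feature_names is not None
             else [f"x{j}" for j in range(p)])
    rng = np.random.default_rng(seed)
    base = np.asarray(predict_fn(x), dtype=float)
    impacts = np.zeros(p)
    for j in range(p):
        col = x[:, j]
        if np.nanstd(col) == 0:
            continue  # permuting a constant is the identity
        acc = 0.0
        for _ in range(n_permutations):
            xp = x.copy()
            xp[:, j] = col[rng.permutation(n)]
            acc += np.mean(np.abs(np.asarray(predict_fn(xp)) - base))
        impacts[j] = acc / n_permutations
    order = np.argsort(-impacts, kind="stable")
    ranked = [(names[j], float(impacts[j])) for j in order]
    return ranked[:top_k] if top_k else ranked
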