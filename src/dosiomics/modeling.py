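"""Bootstrap logistic-regression screening and two-feature model selection.

Procedure (fixed before any feature is seen):

1. Draw ``n_replicates`` bootstrap samples of the n patients (with
   replacement); replicates whose outcome is single-class are redrawn with an
   advanced sub-seed so every feature sees the same usable replicates.
2. Univariate: fit intercept+slope by maximum likelihood (IRLS) on every
   replicate, record the in-bag ("training") AUC, rank features by mean
   training AUC.  The final model per feature takes the median intercept and
   slope over converged replicates and is validated once on the entire
   original dataset — no refit.
3. Multivariate: traverse all unordered feature pairs, gate out pairs whose
   mean per-replicate Spearman correlation falls outside [-0.8, 0.8], and
   select the gated pair with maximal mean training AUC.

Odds ratios are ``exp(coefficient)``; medians and 10th/90th percentiles use
linear-interpolation quantiles.  Separated / non-converged replicate fits are
excluded from coefficient summaries and counted (warning above 10%).
Ties in mean training AUC break lexicographically on feature name.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata, spearmanr

from .core import (
    DegenerateOutcomeError,
    FeatureTable,
    NoAdmissiblePairError,
    UndefinedCorrelationError,
)

log = logging.getLogger(__name__)

_NONCONVERGED_WARN_FRACTION = 0.10


# ---------------------------------------------------------------- bootstrap

@dataclass(frozen=True)
class BootstrapPlan:
    """Pre-drawn bootstrap replicate indices, shared by every model fit."""

    indices: np.ndarray  # (n_replicates, n) ints in [0, n)
    seed: int
    n: int

    @property
    def n_replicates(self) -> int:
        return self.indices.shape[0]


def make_plan(y, n_replicates: int = 1000, seed: int = 0) -> BootstrapPlan:
    """Draw replicates; single-class replicates are redrawn (sub-seed advanced)."""
    y = np.asarray(y, dtype=int)
    n = y.size
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single class; cannot bootstrap")
    indices = np.empty((n_replicates, n), dtype=np.int64)
    for rep in range(n_replicates):
        for attempt in range(1000):
            rng = np.random.default_rng([seed, rep, attempt])
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                indices[rep] = idx
                break
        else:  # pragma: no cover - astronomically unlikely for valid y
            raise DegenerateOutcomeError(f"replicate {rep}: could not draw both classes")
    return BootstrapPlan(indices, seed, n)


# ------------------------------------------------------------ logistic MLE

@dataclass(frozen=True)
class LogisticFit:
    """Coefficients (intercept first) plus convergence diagnostics."""

    coef: np.ndarray
    converged: bool
    separated: bool
    n_iter: int


def _fit_logistic_batch(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 100):
    """Newton/IRLS over a batch of problems.

    X: (B, n, p) including the intercept column; y: (B, n) in {0, 1}.
    Returns (coefs (B, p), converged (B,), n_iter (B,)).
    """
    B, n, p = X.shape
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    eye = np.eye(p) * 1e-10  # numerical jitter only; below any statistical scale
    active = np.arange(B)
    for it in range(max_iter):
        Xa, ya, ba = X[active], y[active], beta[active]
        eta = np.einsum("bnp,bp->bn", Xa, ba)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.einsum("bnp,bn->bp", Xa, ya - mu)
        hess = np.einsum("bnp,bn,bnq->bpq", Xa, w, Xa) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta[active] = ba + step
        n_iter[active] = it + 1
        done = np.max(np.abs(step), axis=1) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return beta, converged, n_iter


def fit_logistic_mle(x, y, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``x`` is the (n, p) predictor matrix without intercept (1D accepted).
    Never silently returns a non-converged fit: the ``converged`` /
    ``separated`` flags must be honoured by the caller.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single class")
    X = np.concatenate([np.ones((x.shape[0], 1)), x], axis=1)
    coefs, conv, iters = _fit_logistic_batch(X[None], y[None], tol, max_iter)
    separated = bool(not conv[0] or np.max(np.abs(coefs[0])) > 1e2)
    return LogisticFit(coefs[0], bool(conv[0]), separated, int(iters[0]))


# -------------------------------------------------------------------- AUC

def roc_auc(scores, y) -> float:
    """Mann-Whitney AUC: P(score_event > score_nonevent), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateOutcomeError("AUC needs both outcome classes")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _roc_auc_batch(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC. scores, y: (B, n); rows must be two-class."""
    ranks = rankdata(scores, axis=1)
    n1 = y.sum(axis=1)
    n0 = y.shape[1] - n1
    pos_rank_sum = (ranks * y).sum(axis=1)
    return (pos_rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def spearman_rho(x1, x2) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size != x2.size or x1.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(spearmanr(x1, x2).statistic)


def _spearman_batch(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Row-wise Spearman; constant rows yield NaN (handled by callers)."""
    r1 = rankdata(x1, axis=1)
    r2 = rankdata(x2, axis=1)
    r1 = r1 - r1.mean(axis=1, keepdims=True)
    r2 = r2 - r2.mean(axis=1, keepdims=True)
    denom = np.sqrt((r1**2).sum(axis=1) * (r2**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r1 * r2).sum(axis=1) / denom


# ------------------------------------------------------------- summaries

def summarize_or(coefs) -> dict[str, float]:
    """Median and 10th/90th percentile odds ratios from replicate coefficients."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size < 10:
        raise ValueError("OR summary needs at least 10 replicate coefficients")
    ors = np.exp(coefs)
    return {
        "median": float(np.percentile(ors, 50, method="linear")),
        "p10": float(np.percentile(ors, 10, method="linear")),
        "p90": float(np.percentile(ors, 90, method="linear")),
    }


@dataclass
class UnivariateFit:
    """Bootstrap result for one feature."""

    feature: str
    mean_train_auc: float
    median_coef: np.ndarray  # (intercept, slope)
    or_intercept: dict[str, float]
    or_slope: dict[str, float]
    full_auc: float
    n_nonconverged: int
    n_replicates: int
    oob_auc: float | None = None
    coef_replicates: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PairFit:
    """Bootstrap result for one feature pair."""

    features: tuple[str, str]
    mean_train_auc: float
    median_coef: np.ndarray  # (intercept, slope1, slope2)
    or_intercept: dict[str, float]
    or_slopes: tuple[dict[str, float], dict[str, float]]
    full_auc: float
    mean_rho: float
    sd_rho: float
    gated: bool  # True if |mean_rho| within the admissible band
    n_nonconverged: int
    n_replicates: int
    coef_replicates: np.ndarray | None = field(default=None, repr=False)


def _check_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    if table.outcome is None:
        raise ValueError("feature table has no outcome column")
    if not table.normalized:
        raise ValueError("screening requires a z-scored feature table")
    return table.features.to_numpy(float), table.outcome.to_numpy(int)


def _bootstrap_fit(F_cols: np.ndarray, y: np.ndarray, plan: BootstrapPlan):
    """Fit intercept + columns on every replicate.

    F_cols: (n, p) predictor columns.  Returns (coefs (B, p+1),
    converged (B,), train_auc (B,)).
    """
    idx = plan.indices
    B, n = idx.shape
    xb = F_cols[idx]  # (B, n, p)
    yb = y[idx]
    X = np.concatenate([np.ones((B, n, 1)), xb], axis=2)
    coefs, conv, _ = _fit_logistic_batch(X, yb.astype(float))
    scores = np.einsum("bnp,bp->bn", X, coefs)
    train_auc = _roc_auc_batch(scores, yb)
    return coefs, conv, train_auc


def _median_model(coefs: np.ndarray, conv: np.ndarray) -> np.ndarray:
    kept = coefs[conv] if conv.any() else coefs
    return np.median(kept, axis=0)


def univariate_screen(
    table: FeatureTable,
    plan: BootstrapPlan,
    features: list[str] | None = None,
    keep_replicates: bool = False,
    oob: bool = False,
) -> list[UnivariateFit]:
    """Screen every feature with bootstrap univariate logistic regression.

    Returns fits sorted by mean training AUC (descending), ties broken by
    feature name.  The final per-feature model is the median-coefficient
    model, validated once on the entire original dataset.
    """
    F, y = _check_table(table)
    names = features if features is not None else table.columns
    col_of = {c: k for k, c in enumerate(table.columns)}
    fits: list[UnivariateFit] = []
    for name in names:
        x = F[:, [col_of[name]]]
        coefs, conv, train_auc = _bootstrap_fit(x, y, plan)
        n_bad = int((~conv).sum())
        if n_bad > _NONCONVERGED_WARN_FRACTION * plan.n_replicates:
            warnings.warn(
                f"feature {name!r}: {n_bad}/{plan.n_replicates} bootstrap fits "
                "did not converge (possible separation)",
                stacklevel=2,
            )
        kept = conv if conv.sum() >= min(10, plan.n_replicates) else np.ones(len(conv), dtype=bool)
        med = _median_model(coefs, conv)
        full_auc = roc_auc(med[0] + med[1] * x[:, 0], y)
        oob_auc = None
        if oob:
            oob_auc = _oob_auc(x, y, plan, coefs, conv)
        fits.append(
            UnivariateFit(
                feature=name,
                mean_train_auc=float(train_auc[kept].mean()),
                median_coef=med,
                or_intercept=summarize_or(coefs[kept, 0]),
                or_slope=summarize_or(coefs[kept, 1]),
                full_auc=full_auc,
                n_nonconverged=n_bad,
                n_replicates=plan.n_replicates,
                oob_auc=oob_auc,
                coef_replicates=coefs if keep_replicates else None,
            )
        )
    fits.sort(key=lambda f: (-f.mean_train_auc, f.feature))
    return fits


def _oob_auc(x: np.ndarray, y: np.ndarray, plan: BootstrapPlan,
             coefs: np.ndarray, conv: np.ndarray) -> float | None:
    """Optional out-of-bag diagnostic: AUC of each replicate's model on the
    patients it never sampled, averaged over usable replicates."""
    aucs = []
    all_idx = np.arange(plan.n)
    for rep in range(plan.n_replicates):
        if not conv[rep]:
            continue
        out = np.setdiff1d(all_idx, plan.indices[rep], assume_unique=False)
        if out.size == 0 or len(np.unique(y[out])) < 2:
            continue
        scores = coefs[rep, 0] + x[out] @ coefs[rep, 1:]
        aucs.append(roc_auc(scores, y[out]))
    return float(np.mean(aucs)) if aucs else None


def multivariate_search(
    table: FeatureTable,
    plan: BootstrapPlan,
    candidates: list[str] | None = None,
    rho_gate: float = 0.8,
    max_predictors: int = 2,
    keep_all: bool = False,
):
    """Exhaustive two-feature search with the Spearman correlation gate.

    The Spearman gate is evaluated first: pairs whose mean per-replicate
    Spearman correlation exceeds ``rho_gate`` in magnitude are excluded from
    selection, so their logistic fits are never needed (this also sidesteps
    the singular designs of duplicate features such as Dissimilarity /
    DifferenceAverage, whose correlation is exactly 1).  Admissible pairs are
    fitted on every replicate and the winner maximises mean training AUC
    (ties break on the sorted pair name).

    Returns the winning :class:`PairFit`, or ``(winner, all_fits)`` when
    ``keep_all`` is set (gated-out pairs carry NaN fit fields).
    """
    if max_predictors != 2:
        raise ValueError(
            "only two-predictor search is supported (events-per-variable cap)"
        )
    F, y = _check_table(table)
    names = candidates if candidates is not None else table.columns
    if len(names) < 2:
        raise ValueError("pair search needs at least 2 candidate features")
    col_of = {c: k for k, c in enumerate(table.columns)}
    idx = plan.indices
    nan_or = {"median": float("nan"), "p10": float("nan"), "p90": float("nan")}
    results: list[PairFit] = []
    for a, b in itertools.combinations(sorted(names), 2):
        cols = F[:, [col_of[a], col_of[b]]]
        rho = _spearman_batch(cols[idx][:, :, 0], cols[idx][:, :, 1])
        rho = rho[np.isfinite(rho)]
        mean_rho = float(rho.mean()) if rho.size else 0.0
        sd_rho = float(rho.std(ddof=1)) if rho.size > 1 else 0.0
        gated = bool(abs(mean_rho) <= rho_gate)
        if not gated:
            results.append(
                PairFit(
                    features=(a, b), mean_train_auc=float("nan"),
                    median_coef=np.full(3, np.nan), or_intercept=nan_or,
                    or_slopes=(nan_or, nan_or), full_auc=float("nan"),
                    mean_rho=mean_rho, sd_rho=sd_rho, gated=False,
                    n_nonconverged=0, n_replicates=plan.n_replicates,
                )
            )
            continue
        coefs, conv, train_auc = _bootstrap_fit(cols, y, plan)
        n_bad = int((~conv).sum())
        if n_bad > _NONCONVERGED_WARN_FRACTION * plan.n_replicates:
            warnings.warn(
                f"pair ({a}, {b}): {n_bad}/{plan.n_replicates} bootstrap fits "
                "did not converge (possible separation/collinearity)",
                stacklevel=2,
            )
        kept = conv if conv.sum() >= min(10, plan.n_replicates) else np.ones(len(conv), dtype=bool)
        med = _median_model(coefs, conv)
        full_auc = roc_auc(med[0] + cols @ med[1:], y)
        results.append(
            PairFit(
                features=(a, b),
                mean_train_auc=float(train_auc[kept].mean()),
                median_coef=med,
                or_intercept=summarize_or(coefs[kept, 0]),
                or_slopes=(summarize_or(coefs[kept, 1]), summarize_or(coefs[kept, 2])),
                full_auc=full_auc,
                mean_rho=mean_rho,
                sd_rho=sd_rho,
                gated=True,
                n_nonconverged=n_bad,
                n_replicates=plan.n_replicates,
                coef_replicates=coefs if keep_all else None,
            )
        )
    admissible = [r for r in results if r.gated]
    if not admissible:
        raise NoAdmissiblePairError(
            f"all {len(results)} candidate pairs exceed |Spearman| > {rho_gate}"
        )
    admissible.sort(key=lambda r: (-r.mean_train_auc, r.features))
    winner = admissible[0]
    return (winner, results) if keep_all else winner
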