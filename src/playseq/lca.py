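"""Bernoulli-mixture latent class analysis (LCA).

The model: each child belongs to one of K unobserved classes with mixing
proportions pi_k; given the class, the I binary behavior indicators are
independent Bernoulli variables with class-conditional probabilities
theta_ik:

    P(x) = sum_k pi_k prod_i theta_ik**x_i (1 - theta_ik)**(1 - x_i)

Estimation is by EM with random restarts (log-sum-exp responsibilities,
closed-form M-step, theta floored at 1e-6).  Model selection over a range
of K uses BIC/AIC, the relative entropy of classification, and the
Lo-Mendell-Rubin adjusted likelihood-ratio test comparing adjacent class
counts, with a parametric-bootstrap LRT as the robust alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ParameterError

__all__ = [
    "IndicatorMatrix",
    "LCAModel",
    "ModelSelectionTable",
    "binarize_indicators",
    "fit_lca",
    "information_criteria",
    "lmr_test",
    "bootstrap_lrt",
    "select_classes",
    "assign_classes",
    "match_labels",
    "sample_indicators",
]

_THETA_FLOOR = 1e-6


@dataclass
class IndicatorMatrix:
    """n x I binary indicator matrix with column names and provenance."""

    X: np.ndarray
    columns: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ParameterError("X must be 2-D (children x indicators)")
        if not np.isin(self.X, (0, 1)).all():
            raise ParameterError("indicator matrix must be binary (0/1)")
        self.X = self.X.astype(np.int8)
        if len(self.columns) != self.X.shape[1]:
            raise ParameterError("column names must match indicator count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def I(self) -> int:  # noqa: E743 - the field's conventional symbol
        return self.X.shape[1]


@dataclass
class LCAModel:
    """Fitted Bernoulli-mixture model."""

    K: int
    pi: np.ndarray  # (K,)
    theta: np.ndarray  # (I, K) class-conditional Bernoulli probabilities
    loglik: float
    posteriors: np.ndarray  # (n, K)
    n: int
    bic: float = math.nan
    aic: float = math.nan
    rel_entropy: float = math.nan
    converged: bool = False
    seed_count: int = 0  # restarts actually run
    loglik_trace: np.ndarray | None = None  # per-iteration loglik of the best run

    @property
    def n_params(self) -> int:
        return self.K * self.theta.shape[0] + (self.K - 1)


@dataclass
class ModelSelectionTable:
    """Fit indices per scanned K and the chosen class count."""

    table: pd.DataFrame  # columns: k, loglik, bic, aic, entropy, lmr_p, converged
    chosen_k: int
    models: dict[int, LCAModel]
    rule: str = "min BIC + LMR support"


def binarize_indicators(
    freqs: pd.DataFrame,
    rule: Literal["median", "z>0"] | Mapping[str, float] = "median",
) -> IndicatorMatrix:
    """Dichotomize per-child indicator frequencies into a binary matrix.

    ``"median"`` splits each column at its median (ties low: values <= median
    map to 0); ``"z>0"`` thresholds at the column mean; an explicit mapping
    ``{column: threshold}`` marks values strictly above the threshold.  The
    rule applied is recorded in the matrix provenance.
    """
    if freqs.isna().any().any():
        bad = [c for c in freqs.columns if freqs[c].isna().any()]
        raise ParameterError(f"missing values in indicator column(s) {bad}")
    X = np.zeros(freqs.shape, dtype=np.int8)
    for j, col in enumerate(freqs.columns):
        v = freqs[col].to_numpy(dtype=float)
        if rule == "median":
            if np.allclose(v, v[0]):
                raise ParameterError(f"column {col!r} is constant; median split undefined")
            thr = float(np.median(v))
        elif rule == "z>0":
            thr = float(np.mean(v))
        elif isinstance(rule, Mapping):
            if col not in rule:
                raise ParameterError(f"no threshold given for column {col!r}")
            thr = float(rule[col])
        else:
            raise ParameterError(f"unknown binarization rule {rule!r}")
        X[:, j] = (v > thr).astype(np.int8)
    desc = rule if isinstance(rule, str) else "explicit thresholds"
    return IndicatorMatrix(X=X, columns=tuple(map(str, freqs.columns)), source=f"rule={desc}")


def _loglik_matrix(X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log P(x_row | class k)."""
    log_t = np.log(theta)
    log_1mt = np.log1p(-theta)
    return X @ log_t + (1 - X) @ log_1mt


def _em(
    X: np.ndarray,
    K: int,
    pi0: np.ndarray,
    theta0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, np.ndarray]:
    n = X.shape[0]
    pi = pi0.copy()
    theta = np.clip(theta0, _THETA_FLOOR, 1 - _THETA_FLOOR)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step (log-sum-exp responsibilities)
        log_joint = np.log(pi)[None, :] + _loglik_matrix(X, theta)
        norm = logsumexp(log_joint, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_joint - norm[:, None])
        trace.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = loglik
        # M step (closed form)
        nk = resp.sum(axis=0)
        pi = nk / n
        theta = np.clip((X.T @ resp) / nk[None, :], _THETA_FLOOR, 1 - _THETA_FLOOR)
    return pi, theta, trace[-1], resp, converged, np.asarray(trace)


def fit_lca(
    X: IndicatorMatrix | np.ndarray,
    K: int,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> LCAModel:
    """Fit a K-class Bernoulli mixture by EM with random restarts.

    The best restart by final log-likelihood is kept.  ``K = 1`` has the
    closed-form solution (theta = column means).  If no restart converged
    the returned model is flagged ``converged=False``.
    """
    if isinstance(X, IndicatorMatrix):
        data = X.X.astype(float)
    else:
        data = np.asarray(X, dtype=float)
        if not np.isin(data, (0.0, 1.0)).all():
            raise ParameterError("indicator matrix must be binary (0/1)")
    n, I = data.shape
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if n <= K:
        raise ParameterError(f"need more observations ({n}) than classes ({K})")
    if restarts < 1:
        raise ParameterError(f"restarts must be >= 1, got {restarts}")
    if K == 1:
        theta = np.clip(data.mean(axis=0), _THETA_FLOOR, 1 - _THETA_FLOOR)[:, None]
        loglik = float(_loglik_matrix(data, theta).sum())
        model = LCAModel(
            K=1,
            pi=np.array([1.0]),
            theta=theta,
            loglik=loglik,
            posteriors=np.ones((n, 1)),
            n=n,
            converged=True,
            seed_count=0,
            loglik_trace=np.array([loglik]),
        )
        model.bic, model.aic, model.rel_entropy = information_criteria(model)
        return model
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best = None
    for _ in range(restarts):
        pi0 = rng.dirichlet(np.full(K, 5.0))
        # initialize theta near the data column means with class-specific jitter
        base = data.mean(axis=0)[:, None]
        theta0 = np.clip(base + rng.uniform(-0.3, 0.3, size=(I, K)), 0.05, 0.95)
        pi, theta, loglik, resp, conv, trace = _em(data, K, pi0, theta0, tol, max_iter)
        if best is None or loglik > best[2]:
            best = (pi, theta, loglik, resp, conv, trace)
    pi, theta, loglik, resp, conv, trace = best
    model = LCAModel(
        K=K,
        pi=pi,
        theta=theta,
        loglik=loglik,
        posteriors=resp,
        n=n,
        converged=conv,
        seed_count=restarts,
        loglik_trace=trace,
    )
    model.bic, model.aic, model.rel_entropy = information_criteria(model)
    return model


def information_criteria(model: LCAModel) -> tuple[float, float, float]:
    """(BIC, AIC, relative classification entropy) for a fitted model.

    BIC = -2 LL + q ln(n), AIC = -2 LL + 2q with q = K*I + (K-1).
    Relative entropy = 1 - [-sum_nk p_nk ln p_nk] / (n ln K) in [0, 1]
    (1 = crisp assignment; defined as 1 for K = 1).
    """
    q = model.n_params
    bic = -2.0 * model.loglik + q * math.log(model.n)
    aic = -2.0 * model.loglik + 2.0 * q
    if model.K == 1:
        rel = 1.0
    else:
        p = np.clip(model.posteriors, 1e-12, 1.0)
        en = float(-(p * np.log(p)).sum())
        rel = 1.0 - en / (model.n * math.log(model.K))
    return float(bic), float(aic), float(rel)


def lmr_test(
    model_k: LCAModel,
    model_km1: LCAModel,
    variant: Literal["lmr_approx", "bootstrap"] = "lmr_approx",
    B: int = 100,
    X: IndicatorMatrix | np.ndarray | None = None,
    restarts: int = 5,
    seed: int | np.random.Generator | None = None,
) -> float:
    """p-value comparing a K-class against a (K-1)-class solution.

    ``"lmr_approx"``: the Lo-Mendell-Rubin adjusted likelihood-ratio test —
    the LR statistic 2*(LL_K - LL_{K-1}) divided by the correction factor
    1 + 1/(d ln n) (d = parameter-count difference), referred to a
    chi-square with d degrees of freedom.  ``"bootstrap"``: parametric
    bootstrap of the LR under the (K-1)-class fit with B refits (requires
    the data ``X``); p is the fraction of bootstrap LRs at or above the
    observed one, so B = 1 gives a degenerate p in {0, 1} (smoke use only).
    """
    if model_k.K != model_km1.K + 1:
        raise ParameterError(
            f"models must have adjacent class counts, got K={model_k.K} vs {model_km1.K}"
        )
    if model_k.n != model_km1.n:
        raise ParameterError("models were fitted on different sample sizes")
    lr = 2.0 * (model_k.loglik - model_km1.loglik)
    d = model_k.n_params - model_km1.n_params
    if variant == "lmr_approx":
        if lr <= 0:
            return 1.0
        adj = lr / (1.0 + 1.0 / (d * math.log(model_k.n)))
        return float(stats.chi2.sf(adj, d))
    if variant == "bootstrap":
        if X is None:
            raise ParameterError("bootstrap variant needs the indicator data X")
        if B < 1:
            raise ParameterError(f"B must be >= 1, got {B}")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        exceed = 0
        for _ in range(B):
            Xb = sample_indicators(model_km1.pi, model_km1.theta, model_k.n, rng)
            fit0 = fit_lca(Xb, model_km1.K, restarts=restarts, seed=rng)
            fit1 = fit_lca(Xb, model_k.K, restarts=restarts, seed=rng)
            if 2.0 * (fit1.loglik - fit0.loglik) >= lr:
                exceed += 1
        return exceed / B
    raise ParameterError(f"unknown variant {variant!r}")


bootstrap_lrt = lmr_test  # alias; call with variant="bootstrap"


def select_classes(
    X: IndicatorMatrix | np.ndarray,
    kmin: int = 2,
    kmax: int = 5,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> ModelSelectionTable:
    """Scan K = kmin..kmax and pick the class count.

    Two-stage rule: ``chosen_k`` is the converged K minimizing BIC; it is
    stepped down to K-1 only when the LMR test at ``chosen_k`` fails
    (p > alpha) while the LMR test at ``chosen_k - 1`` supports it
    (p <= alpha).  Each row's LMR p compares that K against K-1 (fitting
    K = kmin-1 internally when needed).
    """
    data = X.X if isinstance(X, IndicatorMatrix) else np.asarray(X)
    n = data.shape[0]
    if not 1 <= kmin <= kmax:
        raise ParameterError(f"need 1 <= kmin <= kmax, got {kmin}..{kmax}")
    if kmax >= n:
        raise ParameterError(f"kmax ({kmax}) must be below the sample size ({n})")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    models: dict[int, LCAModel] = {}
    for k in range(max(kmin - 1, 1), kmax + 1):
        models[k] = fit_lca(data, k, restarts=restarts, tol=tol, max_iter=max_iter, seed=rng)
    rows = []
    for k in range(kmin, kmax + 1):
        m = models[k]
        lmr_p = math.nan
        if k - 1 in models:
            lmr_p = lmr_test(m, models[k - 1])
        rows.append(
            {
                "k": k,
                "loglik": m.loglik,
                "bic": m.bic,
                "aic": m.aic,
                "entropy": m.rel_entropy,
                "lmr_p": lmr_p,
                "converged": m.converged,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise ParameterError("no scanned class count converged")
    chosen = int(usable.loc[usable["bic"].idxmin(), "k"])
    row = table.loc[table["k"] == chosen].iloc[0]
    if chosen - 1 >= kmin and not math.isnan(row["lmr_p"]) and row["lmr_p"] > alpha:
        prev = table.loc[table["k"] == chosen - 1].iloc[0]
        if not math.isnan(prev["lmr_p"]) and prev["lmr_p"] <= alpha:
            chosen = chosen - 1
    return ModelSelectionTable(
        table=table, chosen_k=chosen, models={k: models[k] for k in range(kmin, kmax + 1)}
    )


def assign_classes(
    model: LCAModel, X: IndicatorMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Modal class labels and posteriors for data under a fitted model.

    Posterior ties break toward the lower class index (argmax convention),
    deterministically.
    """
    data = (X.X if isinstance(X, IndicatorMatrix) else np.asarray(X)).astype(float)
    if data.shape[1] != model.theta.shape[0]:
        raise ParameterError("indicator count does not match the fitted model")
    log_joint = np.log(model.pi)[None, :] + _loglik_matrix(data, model.theta)
    post = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
    return post.argmax(axis=1), post


def match_labels(theta_est: np.ndarray, theta_true: np.ndarray) -> np.ndarray:
    """Permutation aligning estimated classes to reference classes.

    Returns ``perm`` such that estimated class ``perm[k]`` corresponds to
    reference class ``k``, minimizing the total absolute theta difference.
    Exhaustive over K! permutations; refuses K > 8.
    """
    est = np.asarray(theta_est, dtype=float)
    true = np.asarray(theta_true, dtype=float)
    if est.shape != true.shape:
        raise ParameterError("theta matrices must have identical shapes")
    K = est.shape[1]
    if K > 8:
        raise ParameterError("exhaustive label matching refuses K > 8")
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        cost = float(np.abs(est[:, list(perm)] - true).sum())
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return np.asarray(best_perm)


def sample_indicators(
    pi: np.ndarray, theta: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n binary indicator rows from a Bernoulli mixture (pi, theta)."""
    pi = np.asarray(pi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    z = rng.choice(pi.size, size=n, p=pi / pi.sum())
    return (rng.random((n, theta.shape[0])) < theta[:, z].T).astype(np.int8)
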