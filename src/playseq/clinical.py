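"""Clinical outcomes: responder definition, stratified rates, regression.

Intervention response is a reduction of at least 20% in the ADOS-2 total
score from baseline.  Response rates are reported per latent class; a
logistic model quantifies the odds of response by class (adjusting for
age), an ANCOVA-style linear model gives covariate-adjusted group
differences on continuous outcomes (e.g. SRS-2 totals), and a product-of-
coefficients mediation analysis tests whether behavioral entropy carries
part of the class effect on response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ParameterError, RecordError, SeparationError

__all__ = [
    "ResponseResult",
    "LogisticFit",
    "MediationResult",
    "read_clinical",
    "response_flags",
    "response_rates",
    "logistic_fit",
    "adjusted_mean_difference",
    "mediation_product",
]

CLINICAL_COLUMNS = (
    "child_id",
    "group",
    "age_months",
    "iq",
    "module",
    "ados_baseline",
    "ados_post",
    "srs2_total",
)


@dataclass
class ResponseResult:
    """Responder flags and per-class response rates."""

    flags: pd.Series  # bool per child (aligned to input order)
    counts: dict  # class -> (responders, total)
    rates: dict  # class -> integer percent (round-half-up); None for empty class

    def rate_of(self, cls) -> int | None:
        return self.rates[cls]


@dataclass
class LogisticFit:
    """Logistic regression of responder status on class (and age)."""

    params: pd.Series
    conf_int: pd.DataFrame
    odds_ratios: pd.Series
    or_conf_int: pd.DataFrame
    converged: bool
    reference: object


@dataclass
class MediationResult:
    """Product-of-coefficients mediation: class -> mediator -> outcome."""

    a: float  # class -> mediator path (linear)
    b: float  # mediator -> outcome path (logistic, class-adjusted)
    indirect: float  # a * b
    ci: tuple[float, float]  # percentile bootstrap interval for a*b
    B: int


def read_clinical(path, sep: str = ",") -> pd.DataFrame:
    """Read the clinical-records table, checking required columns."""
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordError(f"{path}: missing clinical column(s) {missing}")
    return frame


def response_flags(records: pd.DataFrame, threshold: float = 0.20) -> pd.Series:
    """Responder flag per child: (baseline - post)/baseline >= threshold.

    The boundary is inclusive (an exact 20% drop is a response).  A
    non-positive baseline is a record error, not a silent non-response.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    base = records["ados_baseline"].to_numpy(dtype=float)
    post = records["ados_post"].to_numpy(dtype=float)
    if (base <= 0).any():
        bad = records.loc[base <= 0, "child_id"].tolist()
        raise RecordError(f"non-positive ADOS-2 baseline for child(ren) {bad}")
    rel_drop = (base - post) / base
    return pd.Series(rel_drop >= threshold - 1e-12, index=records.index, name="responder")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def response_rates(labels: Sequence, flags: Sequence[bool]) -> ResponseResult:
    """Per-class responder counts and integer percentage rates (round-half-up)."""
    labels = pd.Series(list(labels))
    flags = pd.Series(list(flags), dtype=bool)
    if len(labels) != len(flags):
        raise ParameterError(
            f"labels ({len(labels)}) and flags ({len(flags)}) must be aligned"
        )
    counts: dict = {}
    rates: dict = {}
    for cls in sorted(labels.unique().tolist()):
        mask = labels == cls
        total = int(mask.sum())
        resp = int(flags[mask].sum())
        counts[cls] = (resp, total)
        rates[cls] = _round_half_up(100.0 * resp / total) if total else None
    return ResponseResult(flags=flags, counts=counts, rates=rates)


def logistic_fit(
    y: Sequence[bool],
    category: Sequence,
    age: Sequence[float] | None = None,
    reference=None,
) -> LogisticFit:
    """Logistic regression log(p/(1-p)) = b0 + b1*Category (+ b2*Age).

    ``category`` is dummy-coded against ``reference`` (default: the first
    level in sorted order), so each class coefficient is a log-odds ratio
    versus the reference class.  Fitted by IRLS/Newton maximum likelihood;
    complete separation raises :class:`SeparationError` rather than being
    silently penalized.  Wald 95% intervals; odds ratios are exp(beta).
    """
    y = np.asarray(list(y), dtype=float)
    if len(np.unique(y)) < 2:
        raise ParameterError("outcome has a single level; logistic fit undefined")
    cat = pd.Series(list(category))
    levels = sorted(cat.unique().tolist())
    ref = levels[0] if reference is None else reference
    if ref not in levels:
        raise ParameterError(f"reference level {ref!r} not among {levels}")
    design = pd.DataFrame({"const": np.ones(len(cat))})
    for lev in levels:
        if lev != ref:
            design[f"class[{lev}]"] = (cat == lev).astype(float)
    if age is not None:
        design["age"] = np.asarray(list(age), dtype=float)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"complete separation in logistic fit: {exc}") from exc
    if np.abs(res.params).max() > 20:
        raise SeparationError(
            "quasi-complete separation suspected (|beta| > 20); "
            "coefficients are not interpretable"
        )
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return LogisticFit(
        params=res.params,
        conf_int=ci,
        odds_ratios=np.exp(res.params),
        or_conf_int=np.exp(ci),
        converged=bool(res.mle_retvals.get("converged", True)),
        reference=ref,
    )


def adjusted_mean_difference(
    score: Sequence[float],
    group: Sequence,
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
    reference=None,
) -> tuple[float, tuple[float, float], float]:
    """Covariate-adjusted group difference on a continuous outcome (ANCOVA).

    Fits ``score ~ group + covariates`` by OLS and returns the group
    coefficient (non-reference minus reference level), its 95% CI and
    p-value.  The group must have exactly two levels.  Collinear covariates
    raise an error naming the offending pair.
    """
    y = np.asarray(list(score), dtype=float)
    g = pd.Series(list(group))
    levels = sorted(g.unique().tolist())
    if len(levels) != 2:
        raise ParameterError(f"group must have exactly 2 levels, got {levels}")
    ref = levels[0] if reference is None else reference
    other = [lev for lev in levels if lev != ref][0]
    design = pd.DataFrame({"const": np.ones(len(g)), "group": (g == other).astype(float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        varying = [c for c in cov.columns if cov[c].nunique() > 1]
        for i, c1 in enumerate(varying):
            for c2 in varying[i + 1 :]:
                r = np.corrcoef(cov[c1], cov[c2])[0, 1]
                if abs(r) > 1 - 1e-10:
                    raise ParameterError(f"collinear covariates: {c1!r} and {c2!r}")
        for c in varying:
            design[c] = cov[c].to_numpy(dtype=float)
    res = sm.OLS(y, design).fit()
    ci = res.conf_int().loc["group"]
    return float(res.params["group"]), (float(ci[0]), float(ci[1])), float(res.pvalues["group"])


def mediation_product(
    class_score: Sequence[float],
    mediator: Sequence[float],
    outcome: Sequence[bool],
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MediationResult:
    """Mediation of the class effect on response through a mediator.

    Path a: OLS of mediator on the (numeric) class score.  Path b: logistic
    regression of the outcome on the mediator, adjusting for class.  The
    indirect effect is a*b with a percentile bootstrap interval over B
    resamples of children.
    """
    c = np.asarray(list(class_score), dtype=float)
    m = np.asarray(list(mediator), dtype=float)
    y = np.asarray(list(outcome), dtype=float)
    if not (len(c) == len(m) == len(y)):
        raise ParameterError("class, mediator and outcome must be aligned")
    if B < 100:
        raise ParameterError(f"B must be >= 100, got {B}")
    if np.std(m) == 0:
        raise ParameterError("mediator has zero variance")

    def paths(ci, mi, yi) -> tuple[float, float]:
        da = sm.add_constant(ci)
        a = float(sm.OLS(mi, da).fit().params[1])
        db = np.column_stack([np.ones_like(ci), mi, ci])
        try:
            b = float(sm.Logit(yi, db).fit(disp=0, maxiter=200).params[1])
        except Exception:
            b = math.nan
        return a, b

    a, b = paths(c, m, y)
    if math.isnan(b):
        raise ParameterError("outcome model failed on the observed data")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(c)
    draws = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        ab, bb = paths(c[idx], m[idx], y[idx])
        if not math.isnan(bb):
            draws.append(ab * bb)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return MediationResult(a=a, b=b, indirect=a * b, ci=(float(lo), float(hi)), B=B)
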