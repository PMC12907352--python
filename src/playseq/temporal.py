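"""Lag-sequential analysis and sequence-complexity metrics.

Given an event log, the lag-1 transition matrix counts how often behavior j
immediately follows behavior i within a session; the row-normalized matrix
P(j|i) = N(i->j) / N(i) is the first-order Markov description of the
behavior stream.  On top of it this module provides multi-step (decayed)
transition matrices, Shannon entropy of the sequence (default support: the
lag-1 bigram distribution), average sequence length over gap-delimited
episodes, cyclicity/transitivity, frequent-chain mining, and the two
group-difference statistics used in cohort comparisons (Welch/pooled t from
summaries, chi-square with adjusted residuals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import BehaviorAlphabet, EventLog
from .errors import ParameterError

__all__ = [
    "TransitionMatrix",
    "MultiStepTransition",
    "SequenceMetrics",
    "GroupSummary",
    "ChiSquareResult",
    "transition_counts",
    "transition_probabilities",
    "k_step_transition",
    "stationary_distribution",
    "behavioral_entropy",
    "average_sequence_length",
    "cyclicity",
    "mine_chains",
    "welch_t",
    "chi_square",
]


@dataclass
class TransitionMatrix:
    """Transition counts N(i->j) and, once normalized, P(j|i) over an alphabet."""

    alphabet: BehaviorAlphabet
    counts: np.ndarray  # (K, K) int
    probs: np.ndarray | None = None  # (K, K) float; NaN rows are undefined
    alpha: float = 0.0  # pseudo-count used for normalization

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def undefined_rows(self) -> np.ndarray:
        """Boolean mask of rows with no outgoing transitions (and no smoothing)."""
        if self.probs is None:
            return self.row_totals == 0
        return np.isnan(self.probs).any(axis=1)

    def probs_frame(self) -> pd.DataFrame:
        if self.probs is None:
            raise ParameterError("probabilities not computed; call transition_probabilities first")
        codes = list(self.alphabet.codes)
        return pd.DataFrame(self.probs, index=codes, columns=codes)

    def counts_frame(self) -> pd.DataFrame:
        codes = list(self.alphabet.codes)
        return pd.DataFrame(self.counts, index=codes, columns=codes)


@dataclass
class MultiStepTransition:
    """T-step transition matrix scaled by the decay weight lam**T."""

    T: int
    lam: float
    matrix: np.ndarray


@dataclass
class SequenceMetrics:
    """Sequence-complexity bundle: entropy H (bits), ASL, cyclicity, transitivity."""

    H: float | None = None
    support: Literal["unigram", "bigram"] | None = None
    n_cells: int | None = None
    p: np.ndarray | None = None
    asl: float | None = None
    cyclicity: float | None = None
    transitivity: float | None = None


@dataclass
class GroupSummary:
    """Summary statistics (mean, sd, n) of one group for a metric."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ParameterError(f"sd must be >= 0, got {self.sd}")


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


def transition_counts(log: EventLog, lag: int = 1) -> TransitionMatrix:
    """Count lag-``lag`` transitions, never crossing child/session boundaries."""
    if lag < 1:
        raise ParameterError(f"lag must be >= 1, got {lag}")
    if len(log) == 0:
        raise ParameterError("empty event log")
    k = log.alphabet.size
    counts = np.zeros((k, k), dtype=np.int64)
    index = {c: i for i, c in enumerate(log.alphabet.codes)}
    for seq in log.code_sequences().values():
        idx = [index[c] for c in seq]
        for a, b in zip(idx, idx[lag:]):
            counts[a, b] += 1
    return TransitionMatrix(alphabet=log.alphabet, counts=counts)


def transition_probabilities(tm: TransitionMatrix, alpha: float = 0.0) -> TransitionMatrix:
    """Row-normalize counts into P(j|i) = (N(i->j)+alpha) / (N(i)+alpha*K).

    With ``alpha = 0`` (raw ratios), rows with N(i) = 0 are undefined (NaN)
    and excluded from aggregate metrics downstream.
    """
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    k = tm.alphabet.size
    totals = tm.row_totals.astype(float)
    denom = totals + alpha * k
    probs = np.full((k, k), np.nan)
    ok = denom > 0
    probs[ok] = (tm.counts[ok] + alpha) / denom[ok, None]
    return TransitionMatrix(alphabet=tm.alphabet, counts=tm.counts, probs=probs, alpha=alpha)


def k_step_transition(tm: TransitionMatrix, T: int, lam: float = 1.0) -> MultiStepTransition:
    """Decayed T-step transition matrix lam**T * P**T (Chapman-Kolmogorov).

    With ``lam = 1`` and ``T = 1`` this is the lag-1 matrix itself; with
    ``lam = 1`` every row of the result sums to 1.
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    if not 0 < lam <= 1:
        raise ParameterError(f"lam must be in (0, 1], got {lam}")
    if tm.probs is None:
        raise ParameterError("transition probabilities not computed")
    if np.isnan(tm.probs).any():
        raise ParameterError(
            "transition matrix has undefined rows; apply pseudo-count smoothing first"
        )
    return MultiStepTransition(T=T, lam=lam, matrix=lam**T * np.linalg.matrix_power(tm.probs, T))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    w = np.real(vecs[:, i])
    w = np.abs(w)
    return w / w.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def behavioral_entropy(
    log: EventLog, support: Literal["bigram", "unigram"] = "bigram"
) -> SequenceMetrics:
    """Shannon entropy H = -sum p(x) log2 p(x) of the behavior stream, in bits.

    ``support="bigram"`` (default) uses the empirical distribution of lag-1
    category pairs (pairs never cross session boundaries; at most K**2
    cells), which distinguishes a rigidly alternating stream from a diverse
    one even when their category frequencies agree.  ``support="unigram"``
    uses single-category frequencies.  The convention 0*log(0) = 0 applies.
    """
    if len(log) == 0:
        raise ParameterError("empty event log")
    k = log.alphabet.size
    index = {c: i for i, c in enumerate(log.alphabet.codes)}
    if support == "unigram":
        counts = np.zeros(k)
        for ev in log.events:
            counts[index[ev.category]] += 1
        n_cells = k
    elif support == "bigram":
        counts = np.zeros((k, k))
        n_pairs = 0
        for seq in log.code_sequences().values():
            for a, b in zip(seq, seq[1:]):
                counts[index[a], index[b]] += 1
                n_pairs += 1
        if n_pairs == 0:
            raise ParameterError("bigram entropy needs at least 2 events in one session")
        counts = counts.ravel()
        n_cells = k * k
    else:
        raise ParameterError(f"support must be 'bigram' or 'unigram', got {support!r}")
    p = counts / counts.sum()
    return SequenceMetrics(H=_entropy_bits(p), support=support, n_cells=n_cells, p=p)


def average_sequence_length(log: EventLog, gap_threshold: float = 5.0) -> float:
    """Mean number of events per episode (gap-delimited behavior sequence).

    Within each session, a new episode starts whenever the gap between an
    event's onset and the previous event's offset exceeds ``gap_threshold``
    seconds.
    """
    if gap_threshold <= 0:
        raise ParameterError(f"gap_threshold must be > 0, got {gap_threshold}")
    if len(log) == 0:
        raise ParameterError("empty event log")
    lengths: list[int] = []
    for events in log.sessions().values():
        length = 0
        prev_offset = None
        for ev in events:
            if prev_offset is not None and ev.onset - prev_offset > gap_threshold:
                lengths.append(length)
                length = 0
            length += 1
            prev_offset = ev.offset
        lengths.append(length)
    return float(np.mean(lengths))


def cyclicity(tm: TransitionMatrix, weights: np.ndarray | None = None) -> float:
    """Weighted probability of behavior repetition: sum_i w_i P(i|i).

    ``weights`` defaults to the stationary distribution of P; an empirical
    state-frequency vector may be supplied instead.  Weights not summing to 1
    are normalized.  Transitivity (probability of switching category) is the
    complement ``1 - cyclicity``.
    """
    if tm.probs is None:
        raise ParameterError("transition probabilities not computed")
    if weights is None:
        if np.isnan(tm.probs).any():
            raise ParameterError("stationary weights need a fully defined matrix")
        w = stationary_distribution(tm.probs)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (tm.alphabet.size,):
            raise ParameterError("weights must have one entry per category")
        if not np.isclose(w.sum(), 1.0):
            w = w / w.sum()
    diag = np.diag(tm.probs)
    active = w > 0
    if np.isnan(diag[active]).any():
        raise ParameterError("undefined transition row has positive weight")
    return float(np.nansum(w * np.where(active, diag, 0.0)))


def mine_chains(
    logs: Iterable[EventLog] | EventLog,
    order: int = 2,
    min_support: float = 0.0,
    gap_threshold: float | None = None,
) -> pd.DataFrame:
    """Mine high-frequency behavior chains (category n-grams).

    Pools n-gram counts over all children and reports, for every n-gram
    attaining ``min_support`` (fraction of children exhibiting it at least
    once), the pooled count, the conditional probability of the chain given
    its first state (count of the n-gram over the count of all n-grams
    starting in that state), and the support.  Sorted by probability,
    descending.  If ``gap_threshold`` is given, n-grams never span gaps
    longer than the threshold (episode-delimited mining).
    """
    if order < 2:
        raise ParameterError(f"order must be >= 2, got {order}")
    if isinstance(logs, EventLog):
        logs = [logs]
    gram_counts: dict[tuple[str, ...], int] = {}
    first_counts: dict[str, int] = {}
    gram_children: dict[tuple[str, ...], set[str]] = {}
    children: set[str] = set()
    for log in logs:
        for (child, _session), events in log.sessions().items():
            children.add(child)
            # split into episode runs if requested
            runs: list[list[str]] = [[]]
            prev_offset = None
            for ev in events:
                if (
                    gap_threshold is not None
                    and prev_offset is not None
                    and ev.onset - prev_offset > gap_threshold
                ):
                    runs.append([])
                runs[-1].append(ev.category)
                prev_offset = ev.offset
            for run in runs:
                for i in range(len(run) - order + 1):
                    gram = tuple(run[i : i + order])
                    gram_counts[gram] = gram_counts.get(gram, 0) + 1
                    first_counts[gram[0]] = first_counts.get(gram[0], 0) + 1
                    gram_children.setdefault(gram, set()).add(child)
    n_children = max(len(children), 1)
    rows = []
    for gram, count in gram_counts.items():
        support = len(gram_children[gram]) / n_children
        if support < min_support:
            continue
        rows.append(
            {
                "chain": " -> ".join(gram),
                "count": count,
                "probability": count / first_counts[gram[0]],
                "support": support,
            }
        )
    table = pd.DataFrame(rows, columns=["chain", "count", "probability", "support"])
    return table.sort_values("probability", ascending=False, ignore_index=True)


def welch_t(
    a: GroupSummary, b: GroupSummary, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test from group summaries; Welch (unequal variances) by default.

    Returns (t, df, two-sided p).  ``equal_var=True`` gives the pooled-variance
    variant.
    """
    if a.sd == 0 and b.sd == 0:
        raise ParameterError("both groups have zero variance; t is undefined")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2.0
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def chi_square(observed: np.ndarray | Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, with adjusted residuals.

    chi2 = sum (O - E)^2 / E with E from the independence model;
    df = (r-1)(c-1).  Adjusted residual per cell:
    (O - E) / sqrt(E (1 - row_margin/n) (1 - col_margin/n)); cells with
    |residual| > ~2 mark the paths driving the association.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ParameterError("observed must be a 2-D table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ParameterError("contingency table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    row_p = obs.sum(axis=1, keepdims=True) / n
    col_p = obs.sum(axis=0, keepdims=True) / n
    denom = np.sqrt(expected * (1 - row_p) * (1 - col_p))
    adj = (obs - expected) / denom
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p=float(p), expected=expected, adjusted_residuals=adj
    )
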