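"""Physiological-signal smoothing and HRV-behavior coupling.

A physiological channel (HRV, SCR, EMG) is consumed as a uniformly sampled
series already derived from the acquisition chain.  Coupling with the
behavior stream is quantified two ways: a normalized cross-correlation
between the signal and a 0/1 behavior-indicator series over a range of lags
(statistics recomputed per lag on the overlapping region, so |CC| <= 1
always holds), and an event-locked contrast of signal means in windows
before vs after behavior onsets.

Sign convention: ``CC(tau) = corr(HRV_t, B_{t+tau})``, so a positive peak
lag means the behavior follows the physiological change; a physiological
response that lags behavior onset by L samples peaks at ``tau = -L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .behavior import EventLog
from .errors import ParameterError

__all__ = [
    "PhysioSignal",
    "SmoothedSignal",
    "EventSeries",
    "CouplingResult",
    "EventLockedContrast",
    "moving_average",
    "behavior_indicator",
    "cross_correlation",
    "event_locked_contrast",
]


@dataclass
class PhysioSignal:
    """Sampled physiological series with its rate (Hz) and session-clock offset."""

    values: np.ndarray
    rate: float
    channel: Literal["HRV", "SCR", "EMG"] = "HRV"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"rate must be > 0, got {self.rate}")
        if not np.isfinite(self.values).all():
            raise ParameterError("signal contains non-finite values")


@dataclass
class SmoothedSignal:
    """Moving-average output; same length as the input."""

    values: np.ndarray
    M: int


@dataclass
class EventSeries:
    """0/1 behavior-occurrence indicator per sample."""

    values: np.ndarray
    rate: float

    @property
    def mean_occurrence(self) -> float:
        return float(self.values.mean())


@dataclass
class CouplingResult:
    """Cross-correlation CC(tau) over lags, with the peak-|CC| lag."""

    lags: np.ndarray  # sample offsets
    cc: np.ndarray
    n: int
    peak_lag: int

    @property
    def peak_cc(self) -> float:
        return float(self.cc[np.where(self.lags == self.peak_lag)[0][0]])


@dataclass
class EventLockedContrast:
    """Pre/post window means around behavior onsets and their paired t test."""

    pre_means: np.ndarray
    post_means: np.ndarray
    mean_pre: float
    mean_post: float
    difference: float  # mean_post - mean_pre
    t: float
    p: float
    n_events: int


def moving_average(signal: PhysioSignal, M: int) -> SmoothedSignal:
    """Causal moving average y[n] = mean of the last M samples.

    The first M-1 outputs average over the samples available so far
    (partial-window normalization), so the output has the input's length and
    no padding values are invented.
    """
    if M < 1:
        raise ParameterError(f"window length M must be >= 1, got {M}")
    x = signal.values
    if M > x.size:
        raise ParameterError(f"window length M={M} exceeds series length {x.size}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = np.arange(1, x.size + 1)
    lo = np.maximum(n - M, 0)
    y = (csum[n] - csum[lo]) / (n - lo)
    return SmoothedSignal(values=y, M=M)


def behavior_indicator(log: EventLog, category: str, rate: float, length: int) -> EventSeries:
    """Rasterize a category's events into a 0/1 series at the given rate.

    Sample ``t`` is 1 iff session time ``t / rate`` falls inside any event of
    the category (half-open event intervals).
    """
    log.alphabet.index(category)
    if rate <= 0:
        raise ParameterError(f"rate must be > 0, got {rate}")
    if length < 1:
        raise ParameterError(f"length must be >= 1, got {length}")
    values = np.zeros(length, dtype=float)
    for ev in log.events:
        if ev.category != category:
            continue
        lo = int(np.ceil(ev.onset * rate - 1e-9))
        hi = int(np.ceil(ev.offset * rate - 1e-9))
        values[max(lo, 0) : min(hi, length)] = 1.0
    return EventSeries(values=values, rate=rate)


def cross_correlation(
    hrv: PhysioSignal, b: EventSeries, max_lag: int
) -> CouplingResult:
    """Normalized cross-correlation CC(tau) for tau in [-max_lag, max_lag].

    For each lag the Pearson correlation is computed on the overlapping
    region only, with means and variances recomputed there, which keeps
    every coefficient in [-1, 1].  Lags whose overlap degenerates (zero
    variance on the slice) yield NaN and are excluded from the peak search.
    """
    x = hrv.values
    y = np.asarray(b.values, dtype=float)
    if x.size != y.size:
        raise ParameterError(f"series lengths differ: {x.size} vs {y.size}")
    if max_lag < 0 or max_lag >= x.size:
        raise ParameterError(f"max_lag must be in [0, {x.size - 1}], got {max_lag}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero-variance series; cross-correlation undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.full(lags.size, np.nan)
    for i, tau in enumerate(lags):
        if tau >= 0:
            xs, ys = x[: x.size - tau], y[tau:]
        else:
            xs, ys = x[-tau:], y[: y.size + tau]
        if xs.size < 2 or np.std(xs) == 0 or np.std(ys) == 0:
            continue
        cc[i] = float(np.corrcoef(xs, ys)[0, 1])
    if np.isnan(cc).all():
        raise ParameterError("no lag had a well-defined correlation")
    peak = int(lags[np.nanargmax(np.abs(cc))])
    return CouplingResult(lags=lags, cc=cc, n=x.size, peak_lag=peak)


def event_locked_contrast(
    signal: PhysioSignal,
    log: EventLog,
    category: str,
    pre_window: float,
    post_window: float,
) -> EventLockedContrast:
    """Signal means in [onset - pre, onset) vs [onset, onset + post) per event.

    Events whose windows do not fit inside the recorded series are skipped.
    Returns per-event means, the across-event mean difference (post - pre)
    and a paired t statistic; with zero variance of the differences the t
    and p are NaN (flat-signal case).
    """
    log.alphabet.index(category)
    if pre_window <= 0 or post_window <= 0:
        raise ParameterError("pre_window and post_window must be > 0")
    x = signal.values
    rate = signal.rate
    pre_means, post_means = [], []
    for ev in log.events:
        if ev.category != category:
            continue
        onset = ev.onset - signal.t0
        lo = int(round((onset - pre_window) * rate))
        mid = int(round(onset * rate))
        hi = int(round((onset + post_window) * rate))
        if lo < 0 or hi > x.size or mid <= lo or hi <= mid:
            continue
        pre_means.append(float(x[lo:mid].mean()))
        post_means.append(float(x[mid:hi].mean()))
    if not pre_means:
        raise ParameterError(f"no event of category {category!r} has usable windows")
    pre = np.array(pre_means)
    post = np.array(post_means)
    diff = post - pre
    if pre.size > 1 and np.std(diff, ddof=1) > 0:
        t, p = stats.ttest_rel(post, pre)
    else:
        t, p = float("nan"), float("nan")
    return EventLockedContrast(
        pre_means=pre,
        post_means=post,
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        difference=float(diff.mean()),
        t=float(t),
        p=float(p),
        n_events=pre.size,
    )
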