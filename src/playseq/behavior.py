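"""Coded behavior streams: domain types, I/O, preprocessing, reliability.

The unit of observation is a timestamped behavior event produced by video
coding of a structured play session: a category from a fixed behavior
alphabet together with onset/offset in seconds from session start.  Intervals
are half-open ``[onset, offset)``; events of one child/session never overlap.

The default alphabet holds the six socially-directed categories used for the
lag-1 transition matrices; a seven-category preset adds stereotyped actions
(needed for the avoidance->stereotypy chain analyses).  Each category carries
the minimum credible duration used by the preprocessing filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, RecordError

__all__ = [
    "BehaviorCategory",
    "BehaviorAlphabet",
    "BehaviorEvent",
    "EventLog",
    "DurationSummary",
    "ReliabilityResult",
    "default_alphabet",
    "read_event_log",
    "write_event_log",
    "segment_events",
    "mean_duration",
    "cohens_kappa",
    "icc_agreement",
]


@dataclass(frozen=True)
class BehaviorCategory:
    """One coded behavior category.

    Parameters
    ----------
    code : str
        Short unique label used in event files and matrices.
    display_name : str
        Human-readable name.
    min_duration : float
        Shortest duration (seconds) at which an occurrence is considered a
        real instance of the behavior; shorter events are dropped by
        :func:`segment_events`.
    """

    code: str
    display_name: str
    min_duration: float

    def __post_init__(self) -> None:
        if self.min_duration < 0:
            raise ParameterError(f"min_duration must be >= 0, got {self.min_duration}")


# Coding-manual categories with their minimum credible durations (seconds).
_CATEGORY_TABLE = [
    ("nonverbal_initiation", "Nonverbal initiation", 1.0),
    ("responsive", "Responsive behavior", 0.5),
    ("emotion_sharing", "Emotional sharing", 2.0),
    ("joint_attention", "Joint attention", 1.5),
    ("speech_initiation", "Speech initiation", 1.0),
    ("avoidance", "Avoidance behavior", 3.0),
    ("stereotypy", "Stereotyped actions", 2.5),
]


@dataclass(frozen=True)
class BehaviorAlphabet:
    """Ordered collection of behavior categories (the Markov state space)."""

    categories: tuple[BehaviorCategory, ...]

    def __post_init__(self) -> None:
        codes = [c.code for c in self.categories]
        if len(set(codes)) != len(codes):
            raise ParameterError(f"duplicate category codes in alphabet: {codes}")

    @property
    def size(self) -> int:
        return len(self.categories)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.categories)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise ParameterError(f"unknown category code: {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def min_duration(self, code: str) -> float:
        return self.categories[self.index(code)].min_duration

    def __iter__(self) -> Iterator[BehaviorCategory]:
        return iter(self.categories)


def default_alphabet(n_categories: int = 6) -> BehaviorAlphabet:
    """Return the standard 6-category alphabet or the 7-category preset.

    The 6-category alphabet matches the row/column labels of the group-level
    transition matrix; the 7-category preset adds stereotyped actions.
    """
    if n_categories not in (6, 7):
        raise ParameterError(f"alphabet preset must be 6 or 7, got {n_categories}")
    cats = tuple(BehaviorCategory(*row) for row in _CATEGORY_TABLE[:n_categories])
    return BehaviorAlphabet(cats)


@dataclass(frozen=True)
class BehaviorEvent:
    """A single coded behavior occurrence, half-open interval [onset, offset)."""

    child_id: str
    session: str
    category: str
    onset: float
    offset: float
    score: int | None = None  # optional 0-2 ordinal quality score; not used downstream

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise RecordError(
                f"event offset must exceed onset (child {self.child_id}, "
                f"session {self.session}, category {self.category}: "
                f"[{self.onset}, {self.offset}))"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventLog:
    """Events of one or more children/sessions, sorted by onset.

    Invariants (checked at construction): events sorted by (onset, offset),
    all categories belong to the alphabet, and no two events of the same
    child/session overlap.
    """

    events: list[BehaviorEvent]
    alphabet: BehaviorAlphabet

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.child_id, e.session, e.onset, e.offset))
        last: dict[tuple[str, str], BehaviorEvent] = {}
        for ev in self.events:
            if ev.category not in self.alphabet:
                raise RecordError(f"category {ev.category!r} not in alphabet {self.alphabet.codes}")
            key = (ev.child_id, ev.session)
            prev = last.get(key)
            if prev is not None and ev.onset < prev.offset:
                raise RecordError(
                    f"overlapping events for child {ev.child_id} session {ev.session}: "
                    f"[{prev.onset}, {prev.offset}) and [{ev.onset}, {ev.offset})"
                )
            last[key] = ev

    def __len__(self) -> int:
        return len(self.events)

    def sessions(self) -> dict[tuple[str, str], list[BehaviorEvent]]:
        """Events grouped per (child_id, session), each list in onset order."""
        out: dict[tuple[str, str], list[BehaviorEvent]] = {}
        for ev in self.events:
            out.setdefault((ev.child_id, ev.session), []).append(ev)
        return out

    def code_sequences(self) -> dict[tuple[str, str], list[str]]:
        """Category-code sequences per (child_id, session)."""
        return {k: [e.category for e in v] for k, v in self.sessions().items()}

    def total_coded_time(self) -> float:
        return float(sum(e.duration for e in self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "child_id": [e.child_id for e in self.events],
                "session": [e.session for e in self.events],
                "category": [e.category for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "offset_s": [e.offset for e in self.events],
            }
        )


@dataclass
class DurationSummary:
    """Per-category event durations: mean T, count N, raw durations D_i."""

    category: str
    N: int
    durations: list[float]
    T: float | None  # None (undefined) when N == 0

    @property
    def defined(self) -> bool:
        return self.N > 0


@dataclass
class ReliabilityResult:
    """Inter-coder agreement: Cohen's kappa and/or ICC on n_items items."""

    kappa: float | None
    icc: float | None
    n_items: int


_REQUIRED_COLUMNS = ("child_id", "session", "category", "onset_s", "offset_s")


def read_event_log(path, alphabet: BehaviorAlphabet, sep: str = ",") -> EventLog:
    """Read a delimiter-separated event file into an :class:`EventLog`.

    The file must have a header with columns
    ``child_id,session,category,onset_s,offset_s``.  Unknown categories and
    non-positive intervals are reported with their row number.
    """
    frame = pd.read_csv(path, sep=sep, dtype={"child_id": str, "session": str, "category": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    events = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based incl. header
        if row.category not in alphabet:
            raise RecordError(f"{path}:{i}: unknown category {row.category!r}")
        if not float(row.offset_s) > float(row.onset_s):
            raise RecordError(
                f"{path}:{i}: offset_s ({row.offset_s}) must exceed onset_s ({row.onset_s})"
            )
        events.append(
            BehaviorEvent(
                child_id=str(row.child_id),
                session=str(row.session),
                category=row.category,
                onset=float(row.onset_s),
                offset=float(row.offset_s),
            )
        )
    return EventLog(events=events, alphabet=alphabet)


def write_event_log(log: EventLog, path, sep: str = ",") -> None:
    """Write an event log in the same format accepted by :func:`read_event_log`."""
    log.to_frame().to_csv(path, sep=sep, index=False)


def _doomed(ev: BehaviorEvent, alphabet: BehaviorAlphabet) -> bool:
    return ev.duration < alphabet.min_duration(ev.category)


def segment_events(log: EventLog, min_interval: float = 0.5) -> EventLog:
    """Merge fragmented events and drop sub-threshold ones.

    Consecutive same-category events whose separating gap is shorter than
    ``min_interval`` are merged into one event spanning both (merging happens
    before duration filtering, so a long behavior split by a coding glitch
    survives).  Events shorter than their category's minimum duration are then
    dropped.  The operation is idempotent: a merge may bridge over an
    intervening event only when that event is itself below its own minimum
    duration (and is dropped as part of the merge), so a second pass finds
    nothing left to do.
    """
    if min_interval < 0:
        raise ParameterError(f"min_interval must be >= 0, got {min_interval}")
    out: list[BehaviorEvent] = []
    for _, events in log.sessions().items():
        kept: list[BehaviorEvent] = []
        for ev in events:
            j = len(kept) - 1
            # Look back across events that will not survive the duration filter.
            while j >= 0 and kept[j].category != ev.category and _doomed(kept[j], log.alphabet):
                j -= 1
            if (
                j >= 0
                and kept[j].category == ev.category
                and ev.onset - kept[j].offset < min_interval
            ):
                merged = replace(kept[j], offset=max(ev.offset, kept[j].offset))
                del kept[j:]
                kept.append(merged)
            else:
                kept.append(ev)
        kept = [e for e in kept if not _doomed(e, log.alphabet)]
        out.extend(kept)
    return EventLog(events=out, alphabet=log.alphabet)


def mean_duration(log: EventLog, category: str) -> DurationSummary:
    """Mean duration T = sum(D_i)/N of the given category's events.

    With no events of the category, N = 0 and T is None (flagged undefined).
    """
    log.alphabet.index(category)  # raises ParameterError if unknown
    durations = [e.duration for e in log.events if e.category == category]
    n = len(durations)
    t = float(np.mean(durations)) if n else None
    return DurationSummary(category=category, N=n, durations=durations, T=t)


def cohens_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Cohen's kappa between two aligned categorical codings.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal products.  When both coders are constant and identical
    (p_e = 1), kappa is defined as 1.
    """
    if len(codes_a) != len(codes_b):
        raise ParameterError(
            f"codings must have equal length, got {len(codes_a)} and {len(codes_b)}"
        )
    if len(codes_a) == 0:
        raise ParameterError("codings are empty")
    a = pd.Categorical(list(codes_a))
    b = pd.Categorical(list(codes_b))
    labels = sorted(set(a.categories) | set(b.categories))
    n = len(codes_a)
    pa = np.array([(np.asarray(codes_a) == lab).mean() for lab in labels])
    pb = np.array([(np.asarray(codes_b) == lab).mean() for lab in labels])
    p_o = float(np.mean(np.asarray(codes_a) == np.asarray(codes_b)))
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def icc_agreement(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-way random, single-measure, absolute-agreement ICC (ICC(2,1)).

    Used for continuous reliability ratings (e.g. behavior durations coded by
    two raters).  A constant shift between raters lowers the ICC because the
    rater variance component enters the denominator.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("values_a and values_b must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ParameterError(f"ICC needs at least 2 items, got {n}")
    if np.array_equal(a, b):
        return 1.0
    import pingouin as pg

    long = pd.DataFrame(
        {
            "item": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": np.concatenate([a, b]),
        }
    )
    table = pg.intraclass_corr(data=long, targets="item", raters="rater", ratings="score")
    return float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])


def reliability(
    codes_a: Sequence | None = None,
    codes_b: Sequence | None = None,
    values_a: Sequence[float] | None = None,
    values_b: Sequence[float] | None = None,
) -> ReliabilityResult:
    """Bundle kappa (categorical) and ICC (continuous) agreement statistics."""
    kappa = cohens_kappa(codes_a, codes_b) if codes_a is not None else None
    icc = icc_agreement(values_a, values_b) if values_a is not None else None
    n_items = len(codes_a) if codes_a is not None else (len(values_a) if values_a is not None else 0)
    return ReliabilityResult(kappa=kappa, icc=icc, n_items=n_items)
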