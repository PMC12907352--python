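import numpy as np
import pytest

from playseq.behavior import BehaviorEvent, EventLog, default_alphabet


@pytest.fixture
def alphabet6():
    return default_alphabet(6)


@pytest.fixture
def alphabet7():
    return default_alphabet(7)


@pytest.fixture
def make_log(alphabet6):
    """Build an EventLog from (category, onset, offset) triples, one session."""

    def _make(triples, child="c1", session="s1", alphabet=None):
        alpha = alphabet or alphabet6
        events = [
            BehaviorEvent(child_id=child, session=session, category=c, onset=a, offset=b)
            for c, a, b in triples
        ]
        return EventLog(events=events, alphabet=alpha)

    return _make


@pytest.fixture
def seq_log(alphabet6):
    """EventLog realizing a given category-code sequence with unit spacing."""

    def _make(codes, child="c1", session="s1", alphabet=None, gap=1.0, dur=1.0):
        alpha = alphabet or alphabet6
        events = []
        t = 0.0
        for c in codes:
            events.append(
                BehaviorEvent(child_id=child, session=session, category=c, onset=t, offset=t + dur)
            )
            t += dur + gap
        return EventLog(events=events, alphabet=alpha)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
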