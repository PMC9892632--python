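import pytest
from hypothesis import settings

from soothe.collaborative import build_interaction_store
from soothe.corpus import Corpus, MusicTrack

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def five_track_corpus() -> Corpus:
    """Small hand-checkable library spanning all categories and levels."""
    return Corpus(
        [
            MusicTrack("t1", "relaxed", "gentle", "Calm sea, calm mind"),
            MusicTrack("t2", "relaxed", "gentle", "Gentle rain on the sea"),
            MusicTrack("t3", "excited", "high", "Bright drums! Fast drums!"),
            MusicTrack("t4", "normal", "moderate", "Soft piano waves"),
            MusicTrack("t5", "normal", "moderate", ""),
        ]
    )


@pytest.fixture()
def eight_user_store():
    """Eight patients over six tracks with varied overlap."""
    likes = {
        "u1": ["a", "b", "c"],
        "u2": ["b", "c", "d"],
        "u3": ["a", "b", "c"],
        "u4": ["d", "e"],
        "u5": ["a", "e", "f"],
        "u6": ["b", "d", "f"],
        "u7": ["c"],
        "u8": ["a", "b", "c", "d", "e", "f"],
    }
    records = [(u, y) for u, items in likes.items() for y in items]
    return build_interaction_store(records)
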