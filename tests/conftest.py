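import pytest

from pocketmotion import analyze_pair
from pocketmotion import synthetic as syn


@pytest.fixture(scope="session")
def pocket_suite():
    """The default 10-pair fixture suite (2 exemplars per pocket class)."""
    pairs, truths, table = syn.make_corpus(10, seed=1)
    return pairs, truths, table


@pytest.fixture(scope="session")
def classified_suite(pocket_suite):
    """The suite run through the full pipeline once per session."""
    pairs, truths, _table = pocket_suite
    analyses = [analyze_pair(p) for p in pairs]
    return list(zip(pairs, truths, analyses))
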