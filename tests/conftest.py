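import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from medintel.store_query import ResourceStore
from medintel.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def demo_corpus():
    """One mid-size generated hospital reused across the suite."""
    envelopes, truth = generate_corpus(SynthConfig(n_patients=600, seed=20260101))
    return envelopes, truth


@pytest.fixture(scope="session")
def demo_store(demo_corpus) -> ResourceStore:
    envelopes, _ = demo_corpus
    return ResourceStore.from_envelopes(envelopes)


@pytest.fixture(scope="session")
def demo_truth(demo_corpus):
    _, truth = demo_corpus
    return truth
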