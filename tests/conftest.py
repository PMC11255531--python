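import numpy as np
import pytest

from newsframing.corpus import Article, VictimAnnotation
from newsframing.embedding import HashEmbedder
from newsframing.lexicon import FrameLexicon, default_lexicons
from newsframing.synthetic import SyntheticSpec, synthetic_lexicons


@pytest.fixture
def hash_backend():
    return HashEmbedder(dimension=256, seed=0)


@pytest.fixture
def seed_lexicons():
    return default_lexicons()


@pytest.fixture
def synth_lexicons():
    return synthetic_lexicons()


@pytest.fixture
def small_spec():
    return SyntheticSpec(
        n_victims={"cis_male": 20, "cis_female": 20}, seed=7
    )


class FixedBackend:
    """Test double mapping known strings to fixed vectors."""

    def __init__(self, table, dimension=2):
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        self.name = "fixed"
        self.dimension = dimension

    def embed_text(self, text):
        if not text.strip():
            raise ValueError("empty")
        return self.table[text]


@pytest.fixture
def fixed_backend_cls():
    return FixedBackend


@pytest.fixture
def article():
    return Article(
        article_id="a1",
        text="First sentence about things. Second sentence with more words.",
        source="test",
    )


def make_annotation(article_id="a1", victim_id="v1", gender="cis_male",
                    circumstances=("unspecified",), span=None):
    return VictimAnnotation(
        article_id=article_id,
        victim_id=victim_id,
        gender=gender,
        circumstances=frozenset(circumstances),
        span=span,
    )


@pytest.fixture
def annotation_factory():
    return make_annotation
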