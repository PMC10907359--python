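import sys
from datetime import datetime
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

from opinionflow.corpus import Corpus, Document, GeneratorConfig, generate_corpus

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_corpus(token_lists, event="toy"):
    """Build a corpus directly from lists of tokens (test scaffolding)."""
    docs = [
        Document(
            doc_id=f"{event}-{i}",
            event=event,
            platform="weibo",
            timestamp=datetime(2022, 11, 23),
            tokens=tuple(tokens),
        )
        for i, tokens in enumerate(token_lists)
    ]
    return Corpus(documents=docs)


@pytest.fixture(scope="session")
def recovery_corpus():
    """Well-separated synthetic corpus for parameter-recovery checks."""
    config = GeneratorConfig(
        event_name="recovery",
        n_docs=2000,
        dimension_weights=(0.6, 0.2, 0.1, 0.1),
        separation=0.95,
        seed=42,
    )
    return generate_corpus(config)
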