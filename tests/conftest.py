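import datetime as dt
import random

import pytest
from hypothesis import settings

from treatyinf.corpus import Corpus, TreatyRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

VOCAB_SMALL = [
    "investment", "health", "protect", "measures", "agreement", "party",
    "policy", "safeguard", "dispute", "treaty",
]

COUNTRIES = [
    "Germany", "Canada", "Brazil", "Turkey", "Finland", "Spain", "Nigeria",
    "Singapore", "Ghana", "Ecuador", "Japan", "Chile",
]


def make_record(i, a, b, text, year=2000, categories=("defensive",)):
    return TreatyRecord(
        treaty_id=f"T{i:03d}",
        country_a=a,
        country_b=b,
        date_signed=dt.date(year, 1, 1),
        categories=frozenset(categories),
        clause_text=text,
    )


@pytest.fixture
def five_treaty_corpus():
    """Five dyadic treaties with one dominant clause wording (Canada hub-ish)."""
    clause = "the contracting parties shall protect public health measures"
    other = "tariffs apply to imported steel goods under quota rules"
    return Corpus(
        records=(
            make_record(1, "Canada", "Nigeria", clause, 1995),
            make_record(2, "Canada", "Singapore", clause, 1999),
            make_record(3, "Canada", "Spain", clause, 2003),
            make_record(4, "Nigeria", "Singapore", clause, 2007),
            make_record(5, "Spain", "Ghana", other, 2011),
        ),
        label="five",
    )


@pytest.fixture
def random_corpus_factory():
    """Factory of small random corpora (seeded): tokens from a 10-term vocab."""

    def make(n_docs, seed, vocab=None, doc_len=(4, 9)):
        rng = random.Random(seed)
        vocab = vocab or VOCAB_SMALL
        records = []
        for i in range(n_docs):
            a, b = rng.sample(COUNTRIES, 2)
            tokens = [rng.choice(vocab) for _ in range(rng.randint(*doc_len))]
            records.append(
                make_record(
                    i + 1, a, b, " ".join(tokens),
                    year=rng.randint(1960, 2019),
                    categories=rng.sample(
                        ["defensive", "neutral", "offensive"], rng.randint(1, 2)
                    ),
                )
            )
        return Corpus(records=tuple(records), label=f"random-{seed}")

    return make
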