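"""Shared fixtures: the printed worked example and small random inputs."""

import numpy as np
import pytest

from pfpfm import PFPFMIndex, TriggerPolicy, build_parse

# The 41-character worked-example text, its trigger policy, dictionary and
# parse (all printed values, re-derived by brute force in the tests below).
EXAMPLE_TEXT = "TCCAGAAGAGTATCTCCTCGACATGTTGAAGACATATGAT$"
EXAMPLE_TRIGGERS = frozenset({"AA", "CG", "TA"})
EXAMPLE_DICT = ("$TCCAGAA", "AAGACATA", "AAGAGTA",
                "CGACATGTTGAA", "TATCTCCTCG", "TATGAT$T")
EXAMPLE_PARSE = (0, 2, 4, 3, 1, 5)
EXAMPLE_QUERY = "CAGAAGAGTATCTCCTCGACATGTTGAAGACATAT"


@pytest.fixture(scope="session")
def example_policy():
    return TriggerPolicy.explicit(EXAMPLE_TRIGGERS)


@pytest.fixture(scope="session")
def example_parse(example_policy):
    return build_parse(EXAMPLE_TEXT, example_policy)


@pytest.fixture(scope="session")
def example_index(example_policy):
    return PFPFMIndex.build(EXAMPLE_TEXT, example_policy)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_text(rng, n, alphabet="ACGT"):
    """A random terminated text of total length n."""
    body = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n - 1))
    return body + "$"


def occurrences(text, pattern):
    """Independent overlapping-occurrence oracle (terminator excluded)."""
    body = text[:-1] if text.endswith("$") else text
    return sum(1 for i in range(len(body) - len(pattern) + 1)
               if body[i : i + len(pattern)] == pattern)
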