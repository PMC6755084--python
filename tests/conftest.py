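import pytest

import ligscan as ls


@pytest.fixture(scope="session")
def f1star():
    return ls.f1star_template()


@pytest.fixture(scope="session")
def minf1():
    return ls.minf1_template()


@pytest.fixture(scope="session")
def sub_library(f1star):
    """WT + all single and double substitutions of the F1*-like core."""
    return ls.build_library(f1star, ["sub1", "sub2"])


@pytest.fixture(scope="session")
def minf1_library(minf1):
    """WT + substitutions and deletions of the minF1-like core."""
    return ls.build_library(minf1, ["sub1", "sub2", "del1", "del2", "del3"])


def make_template(sequence, **kwargs):
    """Small ad-hoc template with every position mutable unless overridden."""
    kwargs.setdefault("mutable_positions", frozenset(range(1, len(sequence) + 1)))
    return ls.CoreTemplate(name="toy", sequence=sequence, **kwargs)
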