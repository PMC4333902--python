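import numpy as np
import pytest

from senrna.decoys import FixtureSpec, random_structure, synthetic_structured_alignment
from senrna.engines.toy import ToyEngine
from senrna.structures import Sequence, parse_dot_bracket


@pytest.fixture(scope="session")
def toy():
    return ToyEngine()


@pytest.fixture(scope="session")
def hairpin():
    """The toy engine's canonical worked example."""
    return Sequence("GGGAAACCC"), parse_dot_bracket("(((...)))")


@pytest.fixture()
def fixture_alignment():
    """Small covarying structured alignment for contract tests."""
    struct = random_structure(40, np.random.default_rng(11))
    return synthetic_structured_alignment(FixtureSpec(struct, 5, 0.15, True, 11))
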