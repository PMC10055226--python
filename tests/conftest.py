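import numpy as np
import pytest

from cathi.scoring import ScoringParams


@pytest.fixture
def analysis_params() -> ScoringParams:
    """Genome-analysis parameters: 75-nt window, step 1, 1.5 GGTGG penalty."""
    return ScoringParams(window_size=75, step=1, ggtgg_penalty=1.5,
                         cluster_threshold=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230320)


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT",
               p=None) -> str:
    return "".join(rng.choice(list(alphabet), size=n, p=p))
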