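import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from secrete import SimulationSpec, generate_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_transcriptome():
    """60 + 60 genes with planted 10-14 runs vs 5-9 decoys (seed fixed)."""
    spec = SimulationSpec(n_secretome=60, n_non_secretome=60, seed=11)
    transcripts, truth = generate_transcriptome(spec)
    return spec, transcripts, truth
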