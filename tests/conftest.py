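import numpy as np
import pytest
from hypothesis import settings

from ribostat import pipeline
from ribostat.core import TranscriptModel
from ribostat.simulate import SimulationConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_transcript(utr5: str, cds: str, utr3: str, tid: str = "T1",
                    gene: str = "G1") -> TranscriptModel:
    """Assemble a TranscriptModel from region sequences."""
    a, b, c = len(utr5), len(utr5) + len(cds), len(utr5) + len(cds) + len(utr3)
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, sequence=utr5 + cds + utr3,
        utr5=(0, a), cds=(a, b), utr3=(b, c),
    )


@pytest.fixture(scope="session")
def demo_config() -> SimulationConfig:
    """A small but fully featured synthetic study (shared, read-only)."""
    return SimulationConfig(n_transcripts=150, seed=7, utr3_length_range=(120, 700))


@pytest.fixture(scope="session")
def demo_study(demo_config):
    return pipeline.run_synthetic_study(demo_config, n_resamples=500)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
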