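import numpy as np
import pytest

from quadloop.sequence_model import TranscriptRecord


@pytest.fixture
def make_transcript():
    """Factory for small transcripts with controllable UTRs."""

    def _make(
        utr5: str = "A" * 30,
        cds: str = "AUG" + "C" * 27,
        utr3: str = "U" * 30,
        accession: str = "NM_TEST01",
        gene: str = "TESTG",
    ) -> TranscriptRecord:
        seq = utr5 + cds + utr3
        return TranscriptRecord(
            accession, gene, seq, len(utr5), len(utr5) + len(cds)
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240818)


def random_rna(rng, n: int, g_fraction: float = 0.4) -> str:
    p_other = (1 - g_fraction) / 3
    return "".join(
        rng.choice(list("ACGU"), size=n, p=[p_other, p_other, g_fraction, p_other])
    )
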