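import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from probekit.fixtures import FixtureSpec, PlantSpec, generate_fixture
from probekit.reference import Biotype, Transcriptome, TranscriptRecord
from probekit.tiling import CandidateProbe, revcomp


def make_probe(seq: str, probe_id: str = "p0", target_id: str = "T0", start: int = 0) -> CandidateProbe:
    return CandidateProbe(probe_id=probe_id, target_id=target_id, start=start, sequence=seq)


def probe_for_window(target: TranscriptRecord, start: int, length: int = 20) -> CandidateProbe:
    window = target.sequence[start : start + length]
    return CandidateProbe(
        probe_id=f"{target.transcript_id}_p{start}",
        target_id=target.transcript_id,
        start=start,
        sequence=revcomp(window),
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_transcriptome(rng):
    return Transcriptome(
        [
            TranscriptRecord("T1", "G1", random_dna(rng, 120), Biotype.MRNA),
            TranscriptRecord("T2", "G1", random_dna(rng, 90), Biotype.MRNA),
            TranscriptRecord("R1", "GR", random_dna(rng, 100), Biotype.RRNA),
        ],
        {"G1": 4, "GR": 1},
    )


@pytest.fixture
def planted_fixture():
    spec = FixtureSpec(
        seed=7,
        n_targets=1,
        target_length_nt=(300, 300),
        n_decoys=4,
        decoy_length_nt=(200, 300),
        planted=[
            PlantSpec(window_start=40, window_len=20, decoy=0, identity_nt=16),
            PlantSpec(window_start=120, window_len=20, decoy=1, identity_nt=15),
            PlantSpec(window_start=200, window_len=20, decoy=2, identity_nt=14),
        ],
    )
    return generate_fixture(spec)
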