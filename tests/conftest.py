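import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for helpers.py

from xplatseq.reference import GeneModel, TranscriptRecord, build_contaminants, merge_references
from xplatseq.align import ReferenceIndex


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def tiny_reference():
    """Three transcripts over two genes, deterministic sequences."""
    ref = {
        "T1": TranscriptRecord("T1", random_sequence(1000, 11)),
        "T2": TranscriptRecord("T2", random_sequence(1200, 12)),
        "T3": TranscriptRecord("T3", random_sequence(500, 13)),
    }
    genes = [GeneModel("G1", ("T1", "T2")), GeneModel("G2", ("T3",))]
    return ref, genes


@pytest.fixture
def tiny_index(tiny_reference):
    ref, _ = tiny_reference
    return ReferenceIndex(merge_references(ref, build_contaminants()))
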