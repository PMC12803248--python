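import numpy as np
import pytest

from splitpool.demux import BarcodeCorrector
from splitpool.schema import BarcodeWhitelist, ReadLayout
from splitpool.simulate import random_whitelist

LINKER_A = "ACGTACGTACGTACGTACGTACGTACGTAC"
LINKER_B = "TGCATGCATGCATGCATGCATGCATGCATG"


@pytest.fixture(scope="session")
def layout() -> ReadLayout:
    """Default 94-nt layout with fixed 30-nt linkers."""
    return ReadLayout.default(LINKER_A, LINKER_B)


@pytest.fixture(scope="session")
def whitelists(layout) -> list[BarcodeWhitelist]:
    """Three seeded 16-well whitelists with min pairwise distance >= 3,
    so single-substitution correction is guaranteed unambiguous."""
    rng = np.random.default_rng(1234)
    wls = [random_whitelist(rng, r, 16, min_distance=3) for r in (1, 2, 3)]
    for wl in wls:
        assert wl.min_pairwise_distance >= 3
    return wls


@pytest.fixture(scope="session")
def correctors(whitelists):
    def make(e: int = 1, metric: str = "hamming"):
        return {
            wl.round_id: BarcodeCorrector(wl, e, metric) for wl in whitelists
        }

    return make


def build_read2(layout: ReadLayout, bc1: str, bc2: str, bc3: str, umi: str) -> str:
    """Assemble a read 2 from segment contents at the layout offsets."""
    chars = ["A"] * layout.min_read2_length
    pieces = {
        "umi": umi,
        "bc3": bc3,
        "bc2": bc2,
        "bc1": bc1,
        "linker_a": layout.linker_a_sequence,
        "linker_b": layout.linker_b_sequence,
    }
    for kind, piece in pieces.items():
        seg = layout.find(kind)
        assert len(piece) == seg.length
        chars[seg.start : seg.end] = piece
    return "".join(chars)


@pytest.fixture(scope="session")
def make_read2(layout):
    def make(bc1: str, bc2: str, bc3: str, umi: str = "T" * 10) -> str:
        return build_read2(layout, bc1, bc2, bc3, umi)

    return make
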