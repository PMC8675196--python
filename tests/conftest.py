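import numpy as np
import pytest

from ihrdkit.cn_features import CNSegment, CNSegmentProfile
from ihrdkit.contexts import CONTEXTS_96
from ihrdkit.signatures import SignatureMatrix


@pytest.fixture(scope="session")
def small_sigs() -> SignatureMatrix:
    """Four analytically simple signatures: two block-uniform profiles, a
    flat HRRd-like CSig3 and a half-flat CSig8.  Overlapping supports make
    the fit non-trivial while the exact optimum stays computable."""
    profiles = np.zeros((96, 4))
    blocks = {k: i // 16 for i, k in enumerate(CONTEXTS_96)}  # 6 blocks of 16
    for i, key in enumerate(CONTEXTS_96):
        b = blocks[key]
        profiles[i, 0] = 1 / 16 if b == 0 else 0.0        # C>A block
        profiles[i, 1] = 1 / 16 if b == 2 else 0.0        # C>T block
        profiles[i, 2] = 1 / 96                            # flat
        profiles[i, 3] = 1 / 32 if b in (3, 4) else 0.0   # T>A + T>C
    return SignatureMatrix(("CSigA", "CSig1", "CSig3", "CSig8"), profiles)


def mb_profile(spec, chrom_lengths_mb, sample_id="T", ploidy=2.0):
    """Build a CNSegmentProfile from megabase-unit tuples
    ``(chrom, start_mb, end_mb, total_cn, minor_cn)`` (end exclusive)."""
    segs = [
        CNSegment(c, s * 1_000_000 + 1, e * 1_000_000, t, m)
        for c, s, e, t, m in spec
    ]
    return CNSegmentProfile(
        sample_id, segs, ploidy, 0.8,
        {c: n * 1_000_000 for c, n in chrom_lengths_mb.items()},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211208)
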