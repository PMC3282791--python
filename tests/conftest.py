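from __future__ import annotations

import numpy as np
import pytest

from cytocn.segmentation import MarkerTrack, Segment, SegState


@pytest.fixture
def rng():
    return np.random.default_rng(20120220)


def make_track(sample: str, cn=None, baf=None, chrom: int = 1,
               spacing: int = 10_000, lrr=None) -> MarkerTrack:
    """Small MarkerTrack with evenly spaced markers for unit tests."""
    if lrr is None:
        lrr = np.log2(np.asarray(cn, dtype=float) / 2.0)
    n = len(lrr)
    if baf is None:
        baf = np.full(n, 0.5)
    return MarkerTrack(
        sample,
        np.full(n, chrom, dtype=np.int64),
        np.arange(1, n + 1, dtype=np.int64) * spacing,
        np.asarray(baf, dtype=float),
        np.asarray(lrr, dtype=float),
    )


def make_segment(sample="S", chrom=1, start=1, end=1_000_000, state=SegState.AMPLIFIED,
                 cn=2.8, n_markers=100, profile=None) -> Segment:
    return Segment(sample=sample, chrom=chrom, start=start, end=end,
                   n_markers=n_markers, geo_mean_cn=cn, state=state,
                   band_profile=profile)
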