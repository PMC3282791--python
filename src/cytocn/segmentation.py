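"""Paired per-marker copy number and recursive genomic segmentation.

Copy number at each marker is derived from the log-R ratio difference between
tumor and matched normal: CN = 2 * 2^(LRR_tumor - LRR_normal), so the matched
normal is the diploid reference. Each chromosome is then partitioned by
recursive binary splitting on log2(CN): at every step the candidate breakpoint
maximising the two-sample Welch t statistic between the flanking runs is
accepted iff both sides hold at least ``min_markers`` markers and the
two-sided p-value is below ``p_threshold``. Segment state is called from the
geometric-mean CN (amplified >= 2.5, deleted <= 1.5, copy-neutral only within
the conservative 1.9-2.1 band).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import stats

from .allelic import MechanismCall
from .bands import BafBandProfile

__all__ = [
    "SegState",
    "MarkerTrack",
    "SegmentationParams",
    "Segment",
    "paired_cn",
    "geometric_mean_cn",
    "segment_track",
    "call_state",
    "filter_segments",
]

AUTOSOMES = frozenset(range(1, 23))


class SegState(str, Enum):
    AMPLIFIED = "AMPLIFIED"
    DELETED = "DELETED"
    NEUTRAL = "NEUTRAL"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class MarkerTrack:
    """Ordered per-marker signal for one sample (autosomes only).

    ``is_het`` flags markers heterozygous in the matched normal; it may be
    absent on a raw track and filled in by the pipeline from the normal BAF.
    """

    sample: str
    chrom: np.ndarray      # int, 1..22
    pos: np.ndarray        # 1-based bp, strictly increasing within chromosome
    baf: np.ndarray        # in [0, 1]
    lrr: np.ndarray        # log2 ratio
    names: np.ndarray | None = None
    is_het: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "baf", "lrr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        bad = set(np.unique(self.chrom)) - AUTOSOMES
        if bad:
            raise ValueError(f"non-autosomal chromosomes in track: {sorted(bad)}")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise ValueError("BAF values outside [0, 1]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.chrom))


@dataclass(frozen=True)
class SegmentationParams:
    """Settings of the segmentation and state calls.

    ``min_markers`` is 25 for ~620k-marker maps and 10 for ~300k maps in the
    published settings; state thresholds: amplified >= ``amp_cn``, deleted
    <= ``del_cn``, copy-neutral only inside [neutral_lo, neutral_hi]. Segments
    shorter than ``min_length_bp`` are discarded from downstream analyses.
    """

    min_markers: int = 25
    p_threshold: float = 0.001
    amp_cn: float = 2.5
    del_cn: float = 1.5
    neutral_lo: float = 1.9
    neutral_hi: float = 2.1
    min_length_bp: int = 500_000

    def __post_init__(self) -> None:
        if not (self.del_cn < self.neutral_lo < self.neutral_hi < self.amp_cn):
            raise ValueError("need del_cn < neutral_lo < neutral_hi < amp_cn")
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")


@dataclass
class Segment:
    """Contiguous marker run on one chromosome of one sample."""

    sample: str
    chrom: int
    start: int                 # 1-based position of first marker
    end: int                   # 1-based position of last marker (inclusive)
    n_markers: int
    geo_mean_cn: float
    state: SegState
    start_idx: int = 0         # marker index range [start_idx, end_idx) within chromosome
    end_idx: int = 0
    band_profile: BafBandProfile | None = None
    mechanism: MechanismCall | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def paired_cn(tumor: MarkerTrack, normal: MarkerTrack) -> np.ndarray:
    """Per-marker copy number of the tumor relative to its matched normal."""
    if len(tumor) != len(normal):
        raise ValueError(f"marker count mismatch: {len(tumor)} vs {len(normal)}")
    mism = (tumor.chrom != normal.chrom) | (tumor.pos != normal.pos)
    if np.any(mism):
        i = int(np.argmax(mism))
        name = tumor.names[i] if tumor.names is not None else f"index {i}"
        raise ValueError(f"tumor/normal marker sets differ at {name} "
                         f"(chr{tumor.chrom[i]}:{tumor.pos[i]})")
    return 2.0 * np.exp2(tumor.lrr - normal.lrr)


def geometric_mean_cn(cn: np.ndarray) -> float:
    """exp(mean(log CN)); invariant to marker order within the segment."""
    cn = np.asarray(cn, dtype=float)
    if np.any(cn <= 0):
        raise ValueError("copy number must be positive for the geometric mean")
    return float(np.exp(np.mean(np.log(cn))))


def _welch_scan(x: np.ndarray, min_markers: int) -> tuple[int, float, float] | None:
    """Best single split of ``x`` by Welch t between left and right parts.

    Returns (split index k, |t|, two-sided p); None when no admissible split.
    On noise-free steps both variances vanish and the statistic is infinite;
    such splits are accepted with p = 0.
    """
    n = x.size
    if n < 2 * min_markers:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    ks = np.arange(min_markers, n - min_markers + 1)  # left sizes
    nl = ks.astype(float)
    nr = n - nl
    sl = csum[ks - 1]
    sr = csum[-1] - sl
    ml = sl / nl
    mr = sr / nr
    # unbiased variances, guarded against tiny negative round-off
    vl = np.maximum(csq[ks - 1] - nl * ml * ml, 0.0) / (nl - 1)
    vr = np.maximum((csq[-1] - csq[ks - 1]) - nr * mr * mr, 0.0) / (nr - 1)
    se2 = vl / nl + vr / nr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(ml - mr) / np.sqrt(se2)
    # zero-variance flanks: a genuine step is infinitely significant, but
    # means must differ beyond cumulative-sum round-off
    same_mean = np.isclose(ml, mr, rtol=1e-9, atol=1e-12)
    t = np.where((se2 == 0) & ~same_mean, np.inf, t)
    t = np.where((se2 == 0) & same_mean, 0.0, t)
    j = int(np.argmax(t))
    tbest = float(t[j])
    k = int(ks[j])
    if not np.isfinite(tbest):
        return k, tbest, 0.0
    if tbest == 0.0:
        return k, 0.0, 1.0
    # Welch-Satterthwaite degrees of freedom at the chosen split
    v_l, v_r, n_l, n_r = vl[j], vr[j], nl[j], nr[j]
    num = (v_l / n_l + v_r / n_r) ** 2
    den = (v_l / n_l) ** 2 / (n_l - 1) + (v_r / n_r) ** 2 / (n_r - 1)
    df = num / den if den > 0 else n - 2
    p = 2.0 * stats.t.sf(tbest, df)
    return k, tbest, float(p)


def segment_track(cn: np.ndarray, params: SegmentationParams) -> list[tuple[int, int]]:
    """Partition one chromosome's CN vector into [start, end) marker-index runs.

    Recursive binary splitting on log2(CN); deterministic for fixed input.
    """
    cn = np.asarray(cn, dtype=float)
    if cn.size == 0:
        return []
    if not np.all(np.isfinite(cn)) or np.any(cn <= 0):
        i = int(np.argmax(~(np.isfinite(cn) & (cn > 0))))
        raise ValueError(f"non-finite or non-positive CN at marker index {i}")
    x = np.log2(cn)

    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        found = _welch_scan(x[lo:hi], params.min_markers)
        if found is not None:
            k, _, p = found
            if p < params.p_threshold:
                recurse(lo, lo + k)
                recurse(lo + k, hi)
                return
        out.append((lo, hi))

    recurse(0, cn.size)
    out.sort()
    return out


def call_state(geo_cn: float, params: SegmentationParams) -> SegState:
    """State of a segment from its geometric-mean CN.

    The intervals (del_cn, neutral_lo) and (neutral_hi, amp_cn) are left
    INDETERMINATE: the conservative copy-neutral band is 1.9-2.1 even though
    amplification/deletion only start at 2.5/1.5.
    """
    if geo_cn >= params.amp_cn:
        return SegState.AMPLIFIED
    if geo_cn <= params.del_cn:
        return SegState.DELETED
    if params.neutral_lo <= geo_cn <= params.neutral_hi:
        return SegState.NEUTRAL
    return SegState.INDETERMINATE


def filter_segments(segments: list[Segment], params: SegmentationParams) -> list[Segment]:
    """Keep segments spanning at least ``min_length_bp`` (order-preserving)."""
    return [s for s in segments if s.length >= params.min_length_bp]
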