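"""Recurrent amplification/deletion/cnLOH regions across a cohort.

Per-sample segments are stacked into a coverage function over their
breakpoints; a recurrent region is a maximal interval where the number of
samples carrying the event at every base is at least ceil(min_fraction * N)
(the published rule: common to >= 9 of 86 samples, ~10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from .bands import SplitMagnitude
from .segmentation import Segment, SegState

__all__ = ["Region", "recurrent_regions", "cnloh_regions", "support_threshold"]

EVENT_STATE = {"AMP": SegState.AMPLIFIED, "DEL": SegState.DELETED}


@dataclass(frozen=True)
class Region:
    """Maximal genomic interval recurrently affected across the cohort.

    Interval is 0-based half-open (BED convention). ``samples`` is the set of
    samples whose qualifying segments overlap the region; ``support`` is the
    minimum pointwise coverage, which every base of the region attains.
    """

    chrom: int
    start: int
    end: int
    event: str                  # AMP | DEL | CNLOH
    samples: tuple[str, ...]
    support: int
    cohort_size: int

    @property
    def length(self) -> int:
        return self.end - self.start


def support_threshold(cohort_size: int, min_fraction: float) -> int:
    return max(1, ceil(min_fraction * cohort_size))


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals (0-based half-open), so each sample counts once per base."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _stack(per_sample: dict[str, list[tuple[int, int]]], threshold: int) -> list[tuple[int, int, int, tuple[str, ...]]]:
    """Maximal intervals with pointwise coverage >= threshold on one chromosome.

    Returns (start, end, min_support, samples) tuples; boundary sweep over all
    segment endpoints, exact (no discretisation).
    """
    events: list[tuple[int, int]] = []  # (pos, delta)
    for ivs in per_sample.values():
        for s, e in _merge(ivs):
            events.append((s, +1))
            events.append((e, -1))
    if not events:
        return []
    events.sort()
    out: list[tuple[int, int, int, tuple[str, ...]]] = []
    cov = 0
    run_start: int | None = None
    run_min = 0
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            cov += events[i][1]
            i += 1
        if cov >= threshold and run_start is None:
            run_start, run_min = pos, cov
        elif cov >= threshold:
            run_min = min(run_min, cov)
        elif run_start is not None:
            out.append(_finish(run_start, pos, run_min, per_sample))
            run_start = None
    return out


def _finish(start: int, end: int, run_min: int, per_sample) -> tuple[int, int, int, tuple[str, ...]]:
    samples = tuple(sorted(
        s for s, ivs in per_sample.items()
        if any(a < end and b > start for a, b in ivs)
    ))
    return (start, end, run_min, samples)


def _regions_from_intervals(
    intervals_by_sample_chrom: dict[int, dict[str, list[tuple[int, int]]]],
    event: str,
    cohort_size: int,
    min_fraction: float,
) -> list[Region]:
    threshold = support_threshold(cohort_size, min_fraction)
    regions: list[Region] = []
    for chrom in sorted(intervals_by_sample_chrom):
        for start, end, run_min, samples in _stack(intervals_by_sample_chrom[chrom], threshold):
            regions.append(Region(chrom, start, end, event, samples, run_min, cohort_size))
    return regions


def _collect(segments_by_sample: dict[str, list[Segment]], keep) -> dict[int, dict[str, list[tuple[int, int]]]]:
    by_chrom: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for sample, segs in segments_by_sample.items():
        for seg in segs:
            if keep(seg):
                # 1-based inclusive marker span -> 0-based half-open
                by_chrom.setdefault(seg.chrom, {}).setdefault(sample, []).append(
                    (seg.start - 1, seg.end)
                )
    return by_chrom


def recurrent_regions(
    segments_by_sample: dict[str, list[Segment]],
    event: str,
    min_fraction: float = 0.10,
    cohort_size: int | None = None,
) -> list[Region]:
    """Recurrent regions of one event type (AMP or DEL) across the cohort.

    Input segments are expected to already pass the minimum-length filter.
    ``cohort_size`` defaults to the number of samples in the mapping (pass the
    full cohort size when some samples contributed no qualifying segments).
    """
    if event not in EVENT_STATE:
        raise ValueError(f"event must be AMP or DEL, got {event!r}")
    n = cohort_size if cohort_size is not None else len(segments_by_sample)
    state = EVENT_STATE[event]
    by_chrom = _collect(segments_by_sample, lambda s: s.state == state)
    return _regions_from_intervals(by_chrom, event, n, min_fraction)


def cnloh_regions(
    segments_by_sample: dict[str, list[Segment]],
    min_fraction: float = 0.10,
    cohort_size: int | None = None,
) -> list[Region]:
    """Recurrent copy-neutral LOH regions.

    A segment qualifies when it is copy-neutral by the conservative band
    (state NEUTRAL, geometric-mean CN in 1.9-2.1) and its heterozygote pane
    shows at least a moderate split.
    """
    n = cohort_size if cohort_size is not None else len(segments_by_sample)

    def keep(seg: Segment) -> bool:
        return (
            seg.state == SegState.NEUTRAL
            and seg.band_profile is not None
            and not seg.band_profile.indeterminate
            and seg.band_profile.split_class >= SplitMagnitude.MODERATE
        )

    by_chrom = _collect(segments_by_sample, keep)
    return _regions_from_intervals(by_chrom, "CNLOH", n, min_fraction)
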