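"""End-to-end orchestration: paired CN -> segmentation -> bands -> mechanism.

``analyze_pair`` turns one tumor/normal pair into fully annotated segments;
``run_cohort`` stacks a whole cohort into recurrent regions and association
results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allelic import enumerate_mosaicism
from .bands import detect_baf_bands
from .recurrence import Region, cnloh_regions, recurrent_regions
from .association import region_state_matrix, run_association
from .segmentation import (
    MarkerTrack, Segment, SegmentationParams,
    call_state, filter_segments, geometric_mean_cn, paired_cn, segment_track,
)

__all__ = ["estimate_baf_noise", "analyze_pair", "run_cohort"]

HET_BAF_RANGE = (0.4, 0.6)  # markers heterozygous in the matched normal


def estimate_baf_noise(normal: MarkerTrack, floor: float = 0.01) -> float:
    """Per-marker BAF noise from the normal's heterozygous markers."""
    het = _het_mask(normal)
    if het.sum() < 10:
        return 0.03
    return max(float(np.std(normal.baf[het] - 0.5)), floor)


def _het_mask(normal: MarkerTrack) -> np.ndarray:
    if normal.is_het is not None:
        return normal.is_het
    lo, hi = HET_BAF_RANGE
    return (normal.baf >= lo) & (normal.baf <= hi)


def analyze_pair(
    tumor: MarkerTrack,
    normal: MarkerTrack,
    params: SegmentationParams | None = None,
    noise_sd: float | None = None,
    max_copies: int = 4,
    grid_step: float = 0.01,
) -> list[Segment]:
    """Segment one pair and annotate every segment with band profile and mechanism."""
    params = params or SegmentationParams()
    cn = paired_cn(tumor, normal)
    het = _het_mask(normal)
    if noise_sd is None:
        noise_sd = estimate_baf_noise(normal)

    segments: list[Segment] = []
    for chrom in tumor.chromosomes():
        mask = tumor.chrom == chrom
        idx = np.flatnonzero(mask)
        cn_c = cn[idx]
        pos_c = tumor.pos[idx]
        baf_c = tumor.baf[idx]
        het_c = het[idx]
        for lo, hi in segment_track(cn_c, params):
            geo = geometric_mean_cn(cn_c[lo:hi])
            seg = Segment(
                sample=tumor.sample, chrom=chrom,
                start=int(pos_c[lo]), end=int(pos_c[hi - 1]),
                n_markers=hi - lo, geo_mean_cn=geo,
                state=call_state(geo, params), start_idx=lo, end_idx=hi,
            )
            het_bafs = baf_c[lo:hi][het_c[lo:hi]]
            if het_bafs.size:
                seg.band_profile = detect_baf_bands(het_bafs, noise_sd)
                if not seg.band_profile.indeterminate and 0.0 < geo <= max_copies:
                    seg.mechanism = enumerate_mosaicism(
                        seg.band_profile.band_centers, geo,
                        grid_step=grid_step, max_copies=max_copies,
                    )
            segments.append(seg)
    return segments


def run_cohort(
    tracks: dict[str, tuple[MarkerTrack, MarkerTrack]],
    phenotypes: pd.DataFrame | None = None,
    params: SegmentationParams | None = None,
    min_fraction: float = 0.10,
    stratify_by_msi: bool = True,
) -> dict:
    """Full cohort analysis.

    Returns a dict with per-sample segments (all and length-filtered),
    recurrent AMP/DEL/cnLOH regions, the region-state matrix and, when a
    phenotype table is given, the association results.
    """
    params = params or SegmentationParams()
    segments_all: dict[str, list[Segment]] = {}
    segments_flt: dict[str, list[Segment]] = {}
    for sample, (tumor, normal) in tracks.items():
        segs = analyze_pair(tumor, normal, params)
        segments_all[sample] = segs
        segments_flt[sample] = filter_segments(segs, params)

    n = len(tracks)
    regions: list[Region] = (
        recurrent_regions(segments_flt, "AMP", min_fraction, n)
        + recurrent_regions(segments_flt, "DEL", min_fraction, n)
        + cnloh_regions(segments_flt, min_fraction, n)
    )
    amp_del = [r for r in regions if r.event in ("AMP", "DEL")]
    matrix = region_state_matrix(amp_del, segments_flt)
    out = {
        "segments": segments_all,
        "segments_filtered": segments_flt,
        "regions": regions,
        "state_matrix": matrix,
    }
    if phenotypes is not None:
        out["association"] = run_association(
            amp_del, matrix, phenotypes, stratify_by_msi=stratify_by_msi
        )
    return out
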