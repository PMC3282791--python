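"""Synthetic paired tumor/normal SNP-array cohorts with known truth.

The generator runs the admixture model forwards: germline genotypes are drawn
from a population B-allele frequency, and within each planted aberration event
the tumor BAF is the expected mixture BAF conditioned on the germline genotype
while the tumor log-R ratio is shifted by log2(CN_exp / 2). BAF noise is
truncated normal (clipped to [0, 1]); LRR noise is normal.

Defaults model the band widths seen on Infinium-class arrays: BAF sd 0.03,
LRR sd 0.15, a heterozygosity-rich map (population B-allele frequency 0.5),
and a scaled two-chromosome genome (2,500 markers over 50 Mb each) so a full
cohort analysis runs in seconds. A denser "610k-like" map can be requested by
raising ``markers_per_chrom``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allelic import Admixture, CellPopulation, expected_baf, expected_cn
from .segmentation import MarkerTrack

__all__ = ["SimEvent", "SimConfig", "simulate_pair", "simulate_cohort", "plant_association"]


@dataclass(frozen=True)
class SimEvent:
    """One planted aberration: an aberrant clone over an interval of a sample.

    ``b_count``/``n_copies`` describe the aberrant clone at markers
    heterozygous in the germline; at homozygous markers the clone carries only
    the germline allele. Intervals are 1-based inclusive in bp.
    """

    sample: str
    chrom: int
    start: int
    end: int
    b_count: int
    n_copies: int
    p_aberrant: float

    def __post_init__(self) -> None:
        CellPopulation(self.b_count, self.n_copies)  # validates counts
        if not (0.0 < self.p_aberrant <= 1.0):
            raise ValueError(f"p_aberrant must be in (0, 1], got {self.p_aberrant}")
        if self.end < self.start:
            raise ValueError("event end before start")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort."""

    n_samples: int = 20
    chrom_lengths: dict[int, int] = field(default_factory=lambda: {1: 50_000_000, 2: 50_000_000})
    markers_per_chrom: int = 2500
    pop_b_freq: float = 0.5
    baf_sd: float = 0.03
    lrr_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baf_sd <= 0 or self.lrr_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if not set(self.chrom_lengths) <= set(range(1, 23)):
            raise ValueError("chromosomes must be autosomes 1-22")


def _marker_map(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms, poss, names = [], [], []
    for c in sorted(config.chrom_lengths):
        length = config.chrom_lengths[c]
        m = config.markers_per_chrom
        pos = np.round(np.linspace(1, length, m)).astype(np.int64)
        pos = np.maximum.accumulate(pos)  # guard equal rounded positions
        pos = pos + np.arange(m) * (np.diff(pos, prepend=0) == 0)
        chroms.append(np.full(m, c, dtype=np.int64))
        poss.append(pos)
        names.extend(f"snp_{c}_{i}" for i in range(m))
    return np.concatenate(chroms), np.concatenate(poss), np.asarray(names)


def simulate_pair(
    config: SimConfig,
    sample: str,
    events: list[SimEvent],
    rng: np.random.Generator,
) -> tuple[MarkerTrack, MarkerTrack, pd.DataFrame]:
    """One tumor/normal pair plus its per-event truth table.

    Outside events the tumor signal is drawn from the same distribution as the
    normal; within an event the tumor follows the admixture model conditioned
    on the germline genotype.
    """
    chrom, pos, names = _marker_map(config)
    n = len(pos)
    b_germ = rng.binomial(2, config.pop_b_freq, size=n)  # germline B-allele count
    is_het = b_germ == 1

    def noisy_baf(truth: np.ndarray) -> np.ndarray:
        return np.clip(truth + rng.normal(0.0, config.baf_sd, size=len(truth)), 0.0, 1.0)

    normal_baf = noisy_baf(b_germ / 2.0)
    normal_lrr = rng.normal(0.0, config.lrr_sd, size=n)

    tumor_truth_baf = b_germ / 2.0
    tumor_lrr_shift = np.zeros(n)
    for ev in events:
        if ev.sample != sample:
            continue
        if ev.chrom not in config.chrom_lengths or ev.end > config.chrom_lengths[ev.chrom]:
            raise ValueError(f"event outside marker map: chr{ev.chrom}:{ev.start}-{ev.end}")
        mask = (chrom == ev.chrom) & (pos >= ev.start) & (pos <= ev.end)
        if not mask.any():
            raise ValueError(f"event covers no markers: chr{ev.chrom}:{ev.start}-{ev.end}")
        for g, b1 in ((0, 0), (1, ev.b_count), (2, ev.n_copies)):
            sel = mask & (b_germ == g)
            if not sel.any():
                continue
            adm = Admixture(CellPopulation(b1, ev.n_copies),
                            CellPopulation(g, 2), ev.p_aberrant)
            tumor_truth_baf[sel] = expected_baf(adm)
            tumor_lrr_shift[sel] = np.log2(expected_cn(adm) / 2.0)

    tumor_baf = noisy_baf(tumor_truth_baf)
    tumor_lrr = tumor_lrr_shift + rng.normal(0.0, config.lrr_sd, size=n)

    normal = MarkerTrack(sample, chrom, pos, normal_baf, normal_lrr, names, is_het)
    tumor = MarkerTrack(sample, chrom, pos, tumor_baf, tumor_lrr, names, is_het)
    truth = pd.DataFrame(
        [{
            "sample": ev.sample, "chrom": ev.chrom, "start": ev.start, "end": ev.end,
            "b_count": ev.b_count, "n_copies": ev.n_copies, "p_aberrant": ev.p_aberrant,
            "expected_cn": expected_cn(Admixture(CellPopulation(ev.b_count, ev.n_copies),
                                                 CellPopulation(1, 2), ev.p_aberrant)),
        } for ev in events if ev.sample == sample]
    )
    return tumor, normal, truth


def plant_association(
    n_samples: int,
    chrom: int,
    start: int,
    end: int,
    clone: tuple[int, int] = (2, 3),
    p_aberrant: float = 0.8,
    group_col: str = "location",
    group_levels: tuple[str, str] = ("left", "right"),
    group_fractions: tuple[float, float] = (0.75, 0.25),
    carrier_prob: tuple[float, float] = (0.6, 0.05),
    rng: np.random.Generator | None = None,
) -> tuple[list[SimEvent], pd.DataFrame]:
    """Plant a region-phenotype association of known effect size.

    Assigns each sample to one of two phenotype levels and gives it the
    aberration with level-specific probability; returns the event roster and a
    phenotype table carrying the planted column plus an msi column (all MSS,
    so unstratified and MSS-stratified analyses coincide).
    """
    rng = rng or np.random.default_rng(0)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    levels = rng.choice(group_levels, size=n_samples, p=group_fractions)
    carrier = rng.random(n_samples) < np.where(levels == group_levels[0],
                                               carrier_prob[0], carrier_prob[1])
    b, nc = clone
    events = [SimEvent(s, chrom, start, end, b, nc, p_aberrant)
              for s, c in zip(samples, carrier) if c]
    pheno = pd.DataFrame({
        "sample_id": samples,
        group_col: levels,
        "msi": "MSS",
        "carrier_truth": carrier,
    })
    return events, pheno


def simulate_cohort(
    config: SimConfig,
    events: list[SimEvent],
    phenotypes: pd.DataFrame | None = None,
) -> tuple[dict[str, tuple[MarkerTrack, MarkerTrack]], pd.DataFrame, pd.DataFrame]:
    """Simulate every pair of the cohort; fully reproducible from config.seed.

    Returns (tracks by sample, phenotype table, truth table of all events).
    Samples are named S000..S{n-1}; events referring to other samples are an
    error.
    """
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    known = set(samples)
    stray = {ev.sample for ev in events} - known
    if stray:
        raise ValueError(f"events reference unknown samples: {sorted(stray)}")
    rng = np.random.default_rng(config.seed)
    tracks: dict[str, tuple[MarkerTrack, MarkerTrack]] = {}
    truths = []
    for sample in samples:
        tumor, normal, truth = simulate_pair(config, sample, events, rng)
        tracks[sample] = (tumor, normal)
        truths.append(truth)
    truth_all = pd.concat([t for t in truths if not t.empty], ignore_index=True) \
        if any(not t.empty for t in truths) else pd.DataFrame()
    if phenotypes is None:
        phenotypes = pd.DataFrame({"sample_id": samples, "msi": "MSS"})
    return tracks, phenotypes, truth_all
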