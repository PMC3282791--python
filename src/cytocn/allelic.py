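"""Two-population admixture model for SNP-array BAF/CN and mosaicism back-calculation.

A tumor sample is modelled as a mixture of an aberrant clone (population 1)
and normal cells (population 2). At a marker where the normal genotype carries
``b2`` B alleles on ``n2`` total copies and the aberrant clone carries ``b1``
on ``n1``, the expected B-allele frequency of the mixture is

    B_exp = (b1*P1 + b2*P2) / (n1*P1 + n2*P2)

with P1 the aberrant-cell proportion and P2 = 1 - P1, while the expected total
copy number is the denominator n1*P1 + n2*P2. Inverting these two observables
over an exhaustive grid of integer clones (b1, n1) and P1 recovers both the
cytogenetic mechanism (mono-/bi-allelic amplification, deletion, copy-neutral
LOH, amplification on cnLOH) and the mosaic fraction.

Only markers heterozygous in the matched normal are informative for band
splitting, so band modelling fixes the normal population at (b2, n2) = (1, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CellPopulation",
    "Admixture",
    "Mechanism",
    "Candidate",
    "MechanismCall",
    "UndefinedBafError",
    "expected_baf",
    "expected_cn",
    "enumerate_mosaicism",
    "table2_label",
]

DIPLOID_HET = None  # assigned after CellPopulation is defined


class UndefinedBafError(ValueError):
    """Raised when both populations are nullisomic at a locus (BAF undefined)."""


class Mechanism(str, Enum):
    NORMAL = "NORMAL"
    MONOALLELIC_AMP = "MONOALLELIC_AMP"
    BIALLELIC_AMP = "BIALLELIC_AMP"
    MONOALLELIC_DEL = "MONOALLELIC_DEL"
    CNLOH = "CNLOH"
    AMP_ON_CNLOH = "AMP_ON_CNLOH"
    MOSAIC_MONOSOMY = "MOSAIC_MONOSOMY"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class CellPopulation:
    """Integer allele content of one cell population at a locus.

    ``b_count`` is the *number* of B alleles (a count, not a frequency) and
    ``n_copies`` the total copy number of the locus in that population.
    """

    b_count: int
    n_copies: int

    def __post_init__(self) -> None:
        if not (0 <= self.b_count <= self.n_copies):
            raise ValueError(
                f"need 0 <= b_count <= n_copies, got b={self.b_count}, n={self.n_copies}"
            )


DIPLOID_HET = CellPopulation(1, 2)


@dataclass(frozen=True)
class Admixture:
    """Mixture of an aberrant clone and normal cells.

    ``p_aberrant`` is P1; the normal proportion P2 = 1 - P1 is derived, never
    stored.
    """

    aberrant: CellPopulation
    normal: CellPopulation = DIPLOID_HET
    p_aberrant: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_aberrant <= 1.0):
            raise ValueError(f"p_aberrant must be in [0, 1], got {self.p_aberrant}")

    @property
    def p_normal(self) -> float:
        return 1.0 - self.p_aberrant


def expected_cn(adm: Admixture) -> float:
    """Expected total copy number of the admixture (diploid reference = 2)."""
    return adm.aberrant.n_copies * adm.p_aberrant + adm.normal.n_copies * adm.p_normal


def expected_baf(adm: Admixture) -> float:
    """Expected BAF of the admixture; undefined when both populations are nullisomic."""
    den = expected_cn(adm)
    if den <= 0.0:
        raise UndefinedBafError("both populations nullisomic at locus: BAF undefined")
    num = adm.aberrant.b_count * adm.p_aberrant + adm.normal.b_count * adm.p_normal
    return num / den


# Mechanism implied by the aberrant clone (b1, n1), normal fixed at het (1,2).
# Keys are canonical: b1 folded so that b1 >= n1 - b1.
_CLONE_MECHANISM: dict[tuple[int, int], Mechanism] = {
    (1, 1): Mechanism.MONOALLELIC_DEL,  # covers (0,1) by mirror symmetry
    (2, 2): Mechanism.CNLOH,            # covers (0,2)
    (1, 2): Mechanism.NORMAL,
    (2, 3): Mechanism.MONOALLELIC_AMP,  # covers (1,3)
    (3, 3): Mechanism.AMP_ON_CNLOH,     # covers (0,3)
    (2, 4): Mechanism.BIALLELIC_AMP,
}


def _clone_mechanism(b1: int, n1: int) -> Mechanism:
    key = (max(b1, n1 - b1), n1)
    return _CLONE_MECHANISM.get(key, Mechanism.INDETERMINATE)


@dataclass(frozen=True)
class Candidate:
    """One grid point of the back-calculation, with its fit residual."""

    b_count: int
    n_copies: int
    p_aberrant: float
    residual: float
    mechanism: Mechanism

    def predicted_baf_bands(self) -> tuple[float, ...]:
        adm = Admixture(CellPopulation(self.b_count, self.n_copies), DIPLOID_HET, self.p_aberrant)
        baf = expected_baf(adm)
        lo, hi = min(baf, 1.0 - baf), max(baf, 1.0 - baf)
        return (0.5,) if abs(hi - lo) < 1e-12 else (lo, hi)


@dataclass
class MechanismCall:
    """Best mechanism explanation for an observed (BAF bands, CN) pair."""

    mechanism: Mechanism
    p_aberrant_est: float | None
    fit_residual: float
    candidates: list[Candidate] = field(default_factory=list)


def enumerate_mosaicism(
    observed_bands,
    observed_cn: float,
    grid_step: float = 0.01,
    max_copies: int = 4,
    baf_weight: float = 2.0,
    n_candidates: int = 10,
    min_fraction: float = 0.05,
    monosomy_min_fraction: float = 0.95,
) -> MechanismCall:
    """Back-calculate the aberrant clone and mosaic fraction from observed data.

    Exhaustively evaluates every aberrant clone (b1, n1) with
    0 <= b1 <= n1 <= ``max_copies`` against a normal heterozygote (1, 2), with
    the aberrant proportion P1 swept over a grid of step ``grid_step``. Each
    grid point is scored by

        residual = baf_weight * |upper(B_exp) - upper observed band|
                   + |CN_exp - observed_cn|

    where upper(x) = max(x, 1-x) folds the A/B label symmetry (b1 and n1-b1
    produce mirrored bands and are equivalent). Ties are broken by parsimony
    (smaller |n1 - 2|), then smaller P1.

    Parameters
    ----------
    observed_bands
        Sorted heterozygote band centers in [0, 1] (e.g. {0.34, 0.66}, or
        {0.5} for an unsplit pane). An empty list yields INDETERMINATE.
    observed_cn
        Segment mean copy number; must lie in (0, max_copies].
    min_fraction
        Detection floor: a best fit with aberrant fraction below this value is
        indistinguishable from a normal diploid at realistic noise and is
        reported as NORMAL.
    monosomy_min_fraction
        A best clone with n1 = 1 and estimated fraction above this value
        (observed CN near 1) is labelled MOSAIC_MONOSOMY rather than
        MONOALLELIC_DEL.
    """
    bands = sorted(float(b) for b in observed_bands)
    if len(bands) == 0:
        return MechanismCall(Mechanism.INDETERMINATE, None, float("inf"), [])
    if not (0.0 < observed_cn <= max_copies):
        raise ValueError(f"observed_cn must be in (0, {max_copies}], got {observed_cn}")
    if any(not (0.0 <= b <= 1.0) for b in bands):
        raise ValueError(f"band centers must lie in [0, 1], got {bands}")

    upper_band = max(bands[-1], 1.0 - bands[0])
    n_steps = int(round(1.0 / grid_step))
    p_grid = np.linspace(0.0, 1.0, n_steps + 1)

    rows: list[Candidate] = []
    for n1 in range(0, max_copies + 1):
        # canonical clones only: b1 >= n1 - b1 (mirror handled by folding)
        for b1 in range((n1 + 1) // 2, n1 + 1):
            den = n1 * p_grid + 2.0 * (1.0 - p_grid)
            valid = den > 0.0
            baf = np.full_like(p_grid, 0.5)
            baf[valid] = (b1 * p_grid[valid] + (1.0 - p_grid[valid])) / den[valid]
            upper = np.maximum(baf, 1.0 - baf)
            resid = baf_weight * np.abs(upper - upper_band) + np.abs(den - observed_cn)
            resid[~valid] = np.inf
            k = int(np.argmin(resid))
            rows.append(
                Candidate(b1, n1, float(p_grid[k]), float(resid[k]), _clone_mechanism(b1, n1))
            )

    # residuals are quantised before tie-breaking so that mirror-family clones
    # with identical predictions (e.g. (3,4) at P/2 vs (2,3) at P) tie exactly
    # and parsimony (|n1-2|, then smaller P) decides
    rows.sort(key=lambda c: (round(c.residual, 9), abs(c.n_copies - 2),
                             c.p_aberrant, c.n_copies))
    best = rows[0]

    mechanism = best.mechanism
    p_est: float | None = best.p_aberrant
    # sub-floor admixture or a diploid-het clone is indistinguishable from normal
    if best.p_aberrant < min_fraction or (best.b_count, best.n_copies) == (1, 2):
        mechanism, p_est = Mechanism.NORMAL, None
    elif best.n_copies == 1 and best.p_aberrant > monosomy_min_fraction:
        mechanism = Mechanism.MOSAIC_MONOSOMY
    return MechanismCall(mechanism, p_est, best.residual, rows[:n_candidates])


# Qualitative (CN state, heterozygote-pane split) -> interpretation, as used
# when summarising segment calls. Keys: (state, split) with state in
# {AMPLIFIED, DELETED, UNCHANGED} and split in {NO_SPLIT, MODERATE, LARGE}.
_TABLE2: dict[tuple[str, str], str] = {
    ("UNCHANGED", "NO_SPLIT"): "Normal",
    ("AMPLIFIED", "MODERATE"): "Mono-allelic Amplification",
    ("AMPLIFIED", "LARGE"): "Mono-allelic amplification superimposed on cnLOH",
    ("AMPLIFIED", "NO_SPLIT"): "Bi-allelic amplification",
    ("DELETED", "LARGE"): "Mono-allelic deletion",
    ("DELETED", "MODERATE"): "Mono-allelic deletion in small proportion of cells",
    ("UNCHANGED", "MODERATE"): "cnLOH",
}


def table2_label(cn_state: str, split) -> str:
    """Textual interpretation of a (CN state, split magnitude) combination.

    Unmapped combinations (e.g. DELETED with no split) return
    ``"Indeterminate"`` rather than raising.
    """
    state = getattr(cn_state, "name", str(cn_state)).upper()
    split_name = getattr(split, "name", str(split)).upper()
    return _TABLE2.get((state, split_name), "Indeterminate")
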