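"""Gene annotation of recurrent regions and therapeutic drug-target matching.

Genes are mapped into regions by overlap fraction of the *gene* (100% for the
headline gene lists, 90% for the grade analyses). Genes in amplified regions
are matched to drugs that down-modulate their products (antagonists,
antibodies, inhibitors); genes in deleted regions to drugs that up-modulate
them (agonists, activators, inducers). Drugs with discontinued or unknown
approval status are excluded from the "available" report but kept in the full
report.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .recurrence import Region

__all__ = [
    "GeneInterval",
    "DrugRecord",
    "AMP_DRUG_TYPES",
    "DEL_DRUG_TYPES",
    "overlap_fraction",
    "genes_in_regions",
    "match_drugs",
    "bundled_drug_table",
]

DRUG_TYPES = frozenset({"antibody", "antagonist", "inhibitor", "agonist", "activator", "inducer"})
DRUG_STATUSES = frozenset({"approved", "trial_phase", "discontinued", "unknown"})
AMP_DRUG_TYPES = frozenset({"antagonist", "antibody", "inhibitor"})
DEL_DRUG_TYPES = frozenset({"agonist", "activator", "inducer"})
AVAILABLE_STATUSES = frozenset({"approved", "trial_phase"})


@dataclass(frozen=True)
class GeneInterval:
    """One gene of the gene model (0-based half-open, symbol is the unique key)."""

    symbol: str
    chrom: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.symbol}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DrugRecord:
    gene: str
    drug: str
    drug_type: str
    status: str
    indication: str = ""

    def __post_init__(self) -> None:
        if self.drug_type not in DRUG_TYPES:
            raise ValueError(f"unknown drug type {self.drug_type!r}")
        if self.status not in DRUG_STATUSES:
            raise ValueError(f"unknown drug status {self.status!r}")


def overlap_fraction(gene: GeneInterval, region: Region) -> float:
    """Fraction of the gene contained in the region (0 on other chromosomes)."""
    if gene.chrom != region.chrom:
        return 0.0
    ov = min(gene.end, region.end) - max(gene.start, region.start)
    return max(ov, 0) / gene.length


def genes_in_regions(
    genes: list[GeneInterval],
    regions: list[Region],
    min_frac: float = 1.0,
) -> dict[Region, list[GeneInterval]]:
    """Genes overlapping each region by at least ``min_frac`` of their length."""
    if not (0.0 < min_frac <= 1.0):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    out: dict[Region, list[GeneInterval]] = {}
    for region in regions:
        seen: set[str] = set()
        hits: list[GeneInterval] = []
        for gene in genes:
            if gene.symbol not in seen and overlap_fraction(gene, region) >= min_frac:
                hits.append(gene)
                seen.add(gene.symbol)
        out[region] = hits
    return out


def match_drugs(
    genes_by_region: dict[Region, list[GeneInterval]],
    drugs: list[DrugRecord] | pd.DataFrame,
    available_only: bool = True,
) -> pd.DataFrame:
    """Match each region's genes to drugs of the therapeutically relevant mode.

    Amplified regions match {antagonist, antibody, inhibitor}; deleted regions
    match {agonist, activator, inducer}. With ``available_only`` (default) the
    report drops records whose approval status is discontinued or unknown; the
    full report keeps them with ``available=False``.
    """
    if isinstance(drugs, pd.DataFrame):
        drugs = [DrugRecord(r.gene, r.drug, r.type, r.status, getattr(r, "indication", ""))
                 for r in drugs.itertuples(index=False)]
    by_gene: dict[str, list[DrugRecord]] = {}
    for rec in drugs:
        by_gene.setdefault(rec.gene, []).append(rec)

    rows = []
    for region, genes in genes_by_region.items():
        if region.event == "AMP":
            modes = AMP_DRUG_TYPES
        elif region.event == "DEL":
            modes = DEL_DRUG_TYPES
        else:
            continue  # cnLOH regions have no drug-mode rule
        for gene in genes:
            for rec in by_gene.get(gene.symbol, []):
                if rec.drug_type not in modes:
                    continue
                rows.append({
                    "region": f"chr{region.chrom}:{region.start}-{region.end}",
                    "event": region.event, "gene": gene.symbol,
                    "drug": rec.drug, "drug_type": rec.drug_type,
                    "status": rec.status, "indication": rec.indication,
                    "available": rec.status in AVAILABLE_STATUSES,
                })
    cols = ["region", "event", "gene", "drug", "drug_type", "status", "indication", "available"]
    report = pd.DataFrame(rows, columns=cols)
    if available_only:
        report = report[report["available"]].reset_index(drop=True)
    return report


def bundled_drug_table() -> pd.DataFrame:
    """The approved-drug fixture shipped with the package (gene, cytoband,
    drug, type, status, indication)."""
    with resources.files("cytocn").joinpath("data/approved_drugs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
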