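"""Association of per-region copy-number state with tumor phenotypes.

Each recurrent region is scored per sample as Amplification / Deletion /
Unchanged (a state requires a qualifying segment of that state covering at
least half the region). Categorical phenotypes are tested against the state
with Pearson's chi-square after dropping all-zero rows/columns; continuous
phenotypes with one-way ANOVA. Analyses are stratified by MSI status, since
chromosomal instability differs sharply between MSI and MSS tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .recurrence import Region
from .segmentation import Segment, SegState

__all__ = [
    "ContingencyResult",
    "chi_square",
    "anova_oneway",
    "region_state_matrix",
    "run_association",
    "PHENOTYPE_COLUMNS",
]

PHENOTYPE_COLUMNS = [
    "sample_id", "sex", "age", "bmi", "family_history", "location",
    "diagnosis", "tumor_cell_pct", "lymph_node", "stage", "grade", "msi",
]

STATES = ("Amplification", "Deletion", "Unchanged")


@dataclass
class ContingencyResult:
    """Chi-square test on a reduced (all-zero rows/columns dropped) count table."""

    observed: np.ndarray
    correction: str           # "none" | "yates"
    statistic: float | None
    df: int | None
    p_value: float | None
    testable: bool = True
    note: str = ""


def _reduce(table: np.ndarray) -> np.ndarray:
    table = table[table.sum(axis=1) > 0, :]
    return table[:, table.sum(axis=0) > 0]


def chi_square(table, correction: str = "none") -> ContingencyResult:
    """Pearson chi-square on a count table, dropping all-zero rows/columns first.

    ``correction="yates"`` applies the continuity correction and is only valid
    for a 2x2 (after reduction). Degenerate reduced tables (fewer than 2 rows
    or columns) are flagged untestable and carry no p-value.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    if correction not in ("none", "yates"):
        raise ValueError(f"correction must be 'none' or 'yates', got {correction!r}")
    red = _reduce(obs)
    if red.shape[0] < 2 or red.shape[1] < 2:
        return ContingencyResult(red, correction, None, None, None, False,
                                 "degenerate table after dropping all-zero rows/columns")
    if correction == "yates" and red.shape != (2, 2):
        raise ValueError("Yates continuity correction applies to 2x2 tables only")
    res = stats.chi2_contingency(red, correction=(correction == "yates"))
    return ContingencyResult(red, correction, float(res.statistic), int(res.dof),
                             float(res.pvalue))


def anova_oneway(values, groups) -> tuple[float, float]:
    """One-way ANOVA of ``values`` across the levels of ``groups``.

    For two groups the F statistic equals the squared pooled-variance t.
    All-constant groups with differing means are degenerate (F infinite,
    p reported as 0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(s) == 0 for s in samples):
        means = [s.mean() for s in samples]
        if len(set(means)) > 1:
            return float("inf"), 0.0
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def region_state_matrix(
    regions: list[Region],
    segments_by_sample: dict[str, list[Segment] | None],
    min_cover: float = 0.5,
) -> pd.DataFrame:
    """Per-sample CN state for each region.

    A sample is Amplification (Deletion) for a region iff an AMPLIFIED
    (DELETED) segment covers at least ``min_cover`` of the region; otherwise
    Unchanged. Samples whose segment list is None are unanalyzable for every
    region and marked missing (NaN). Segments are expected to be pre-filtered
    to the minimum length.
    """
    region_ids = [_region_id(r) for r in regions]
    data: dict[str, list] = {}
    for sample, segs in segments_by_sample.items():
        if segs is None:
            data[sample] = [np.nan] * len(regions)
            continue
        states = []
        for region in regions:
            cov = {SegState.AMPLIFIED: 0, SegState.DELETED: 0}
            for seg in segs:
                if seg.chrom != region.chrom or seg.state not in cov:
                    continue
                ov = min(seg.end, region.end) - max(seg.start - 1, region.start)
                if ov > 0:
                    cov[seg.state] += ov
            need = min_cover * region.length
            amp, dele = cov[SegState.AMPLIFIED], cov[SegState.DELETED]
            if amp >= need and amp >= dele:
                states.append("Amplification")
            elif dele >= need:
                states.append("Deletion")
            else:
                states.append("Unchanged")
        data[sample] = states
    return pd.DataFrame.from_dict(data, orient="index", columns=region_ids)


def _region_id(region: Region) -> str:
    return f"chr{region.chrom}:{region.start}-{region.end}:{region.event}"


def run_association(
    regions: list[Region],
    state_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    phenotype_cols: list[str] | None = None,
    stratify_by_msi: bool = True,
    min_abnormal_fraction: float = 0.10,
) -> pd.DataFrame:
    """Chi-square association of region state with each categorical phenotype.

    Returns one row per (stratum, region, phenotype) with the reduced-table
    statistic, df, raw p-value and a Benjamini-Hochberg adjusted column
    (reported for convenience; raw p-values are the primary output). Samples
    missing for a region are excluded per-region. ``frequent`` flags regions
    whose CN abnormality occurs in at least ``min_abnormal_fraction`` of the
    stratum's samples.
    """
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    if phenotype_cols is None:
        phenotype_cols = [c for c in ("diagnosis", "location", "grade", "stage", "lymph_node", "sex")
                          if c in pheno.columns]
    strata = {}
    if stratify_by_msi and "msi" in pheno.columns:
        for level in pheno["msi"].unique():
            strata[str(level)] = pheno.index[pheno["msi"] == level]
    else:
        strata["all"] = pheno.index

    rows = []
    for stratum, samples in strata.items():
        samples = [s for s in samples if s in state_matrix.index]
        sub = state_matrix.loc[samples]
        for region in regions:
            rid = _region_id(region)
            if rid not in sub.columns:
                continue
            col = sub[rid].dropna()
            n_abn = int((col != "Unchanged").sum())
            frequent = len(col) > 0 and n_abn >= min_abnormal_fraction * len(col)
            for phen in phenotype_cols:
                lab = pheno.loc[col.index, phen].dropna()
                if lab.empty:
                    continue
                tab = pd.crosstab(lab, col.loc[lab.index])
                tab = tab.reindex(columns=[s for s in STATES if s in tab.columns], fill_value=0)
                res = chi_square(tab.to_numpy(), correction="none")
                rows.append({
                    "stratum": stratum, "region": rid, "event": region.event,
                    "phenotype": phen, "n": int(len(lab)),
                    "n_abnormal": n_abn, "frequent": frequent,
                    "statistic": res.statistic, "df": res.df, "p": res.p_value,
                    "testable": res.testable,
                })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = np.nan
        mask = out["p"].notna()
        if mask.any():
            out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
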