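"""Readers and writers for the pipeline's file formats.

Marker tables are tab-delimited BeadStudio-final-report-like files with a
header ``Sample ID, SNP Name, Chr, Position, B Allele Freq, Log R Ratio``;
positions are 1-based as in array manifests. All interval outputs are written
as BED (0-based half-open). Chromosome labels are accepted as "1".."22" with
or without a "chr" prefix and normalised internally; non-autosomal rows are
dropped with a logged count. Readers reject rather than silently coerce
malformed input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import DrugRecord, GeneInterval
from .association import PHENOTYPE_COLUMNS
from .recurrence import Region
from .segmentation import MarkerTrack, Segment

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "read_phenotypes",
    "read_gene_bed",
    "read_drug_table",
    "write_segments",
    "write_regions",
    "write_run_metadata",
]

log = logging.getLogger("cytocn")

MARKER_COLUMNS = ["Sample ID", "SNP Name", "Chr", "Position", "B Allele Freq", "Log R Ratio"]


def _normalize_chrom(raw: pd.Series) -> pd.Series:
    s = raw.astype(str).str.strip().str.removeprefix("chr")
    return pd.to_numeric(s, errors="coerce")  # X/Y/MT -> NaN (non-autosomal)


def read_marker_table(path) -> dict[str, MarkerTrack]:
    """Read a marker table into one validated, chromosome-sorted track per sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    chrom = _normalize_chrom(df["Chr"])
    non_auto = chrom.isna() | ~chrom.isin(range(1, 23))
    if non_auto.any():
        log.info("%s: dropped %d non-autosomal marker rows", path, int(non_auto.sum()))
        df, chrom = df[~non_auto], chrom[~non_auto]

    def numeric(col: str, lo=None, hi=None) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2  # header + 1-based
        elif lo is not None and ((vals < lo) | (vals > hi)).any():
            line = int(df.index[(vals < lo) | (vals > hi)][0]) + 2
        else:
            return vals.to_numpy(dtype=float)
        raise ValueError(f"{path}: malformed {col!r} at line {line}")

    pos = numeric("Position").astype(np.int64)
    baf = numeric("B Allele Freq", 0.0, 1.0)
    lrr = numeric("Log R Ratio")

    tracks: dict[str, MarkerTrack] = {}
    for sample, idx in df.groupby("Sample ID", sort=True).groups.items():
        loc = df.index.get_indexer(idx)
        order = np.lexsort((pos[loc], chrom.to_numpy()[loc]))
        loc = loc[order]
        c = chrom.to_numpy()[loc].astype(np.int64)
        p = pos[loc]
        for cc in np.unique(c):
            if np.any(np.diff(p[c == cc]) == 0):
                raise ValueError(f"{path}: duplicated position on chr{cc} for sample {sample}")
        tracks[str(sample)] = MarkerTrack(
            str(sample), c, p, baf[loc], lrr[loc],
            names=df["SNP Name"].to_numpy()[loc],
        )
    return tracks


def write_marker_table(tracks: dict[str, MarkerTrack] | MarkerTrack, path) -> None:
    if isinstance(tracks, MarkerTrack):
        tracks = {tracks.sample: tracks}
    frames = []
    for sample, t in tracks.items():
        frames.append(pd.DataFrame({
            "Sample ID": sample,
            "SNP Name": t.names if t.names is not None else [f"m{i}" for i in range(len(t))],
            "Chr": t.chrom, "Position": t.pos,
            "B Allele Freq": t.baf, "Log R Ratio": t.lrr,
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample_id")
    return df


def read_gene_bed(path) -> list[GeneInterval]:
    """Gene model as BED (chrom, start, end, name, score, strand)."""
    genes = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: BED line {ln} has fewer than 4 fields")
            chrom = f[0].removeprefix("chr")
            if not chrom.isdigit() or not 1 <= int(chrom) <= 22:
                continue
            symbol = f[3]
            if symbol in seen:
                raise ValueError(f"{path}: duplicate gene symbol {symbol!r} at line {ln}")
            seen.add(symbol)
            strand = f[5] if len(f) > 5 else "+"
            genes.append(GeneInterval(symbol, int(chrom), int(f[1]), int(f[2]), strand))
    return genes


def read_drug_table(path) -> list[DrugRecord]:
    """Drug table TSV with columns gene, drug, type, status[, indication]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "drug", "type", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing drug-table column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            records.append(DrugRecord(row.gene, row.drug, str(row.type).lower(),
                                      str(row.status).lower(), getattr(row, "indication", "")))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return records


def segments_frame(segments_by_sample: dict[str, list[Segment]]) -> pd.DataFrame:
    rows = []
    for sample, segs in segments_by_sample.items():
        for s in segs:
            prof, mech = s.band_profile, s.mechanism
            rows.append({
                "sample": sample, "chrom": s.chrom, "start": s.start, "end": s.end,
                "n_markers": s.n_markers, "geo_mean_cn": round(s.geo_mean_cn, 4),
                "state": s.state.value,
                "band_d": round(prof.split_deviation, 4) if prof else np.nan,
                "split_class": prof.split_class.name if prof else "",
                "mechanism": mech.mechanism.value if mech else "",
                "p_aberrant": (round(mech.p_aberrant_est, 4)
                               if mech and mech.p_aberrant_est is not None else np.nan),
            })
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_markers",
                                       "geo_mean_cn", "state", "band_d", "split_class",
                                       "mechanism", "p_aberrant"])


def write_segments(segments_by_sample: dict[str, list[Segment]], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = segments_frame(segments_by_sample)
    df.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    with open(outdir / "segments.bed", "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(f"chr{r.chrom}\t{r.start - 1}\t{r.end}\t{r.sample}:{r.state}\t0\t.\n")


def regions_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end, "event": r.event,
        "support": r.support, "cohort_size": r.cohort_size,
        "samples": ",".join(r.samples),
    } for r in regions], columns=["chrom", "start", "end", "event",
                                  "support", "cohort_size", "samples"])


def write_regions(regions: list[Region], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = regions_frame(regions)
    df.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    with open(outdir / "regions.bed", "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(f"chr{r.chrom}\t{r.start}\t{r.end}\t{r.event}\t{r.support}\t.\n")


def write_run_metadata(outdir, **params) -> None:
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"cytocn_version": __version__,
            "numpy": np.__version__, "pandas": pd.__version__}
    meta.update(params)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
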