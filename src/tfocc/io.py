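"""Readers and writers for the on-disk formats.

JASPAR PFM flat files (both the 4-row ``A [ ... ]`` dialect and the
transposed position-per-row dialect, auto-detected), FASTA (multi-record,
index-backed through pyfaidx when reading from disk), BED6 site lists with
a sidecar TSV carrying exact real-valued scores, 4-column tag-track TSVs,
and bedGraph numeric tracks.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import BASES, PositionFrequencyMatrix, SiteList
from .tracks import NumericTrack, TagTrack


def read_jaspar_pfm(path) -> PositionFrequencyMatrix:
    """Read a JASPAR-style PFM; detects 4-row vs transposed layouts."""
    text = Path(path).read_text()
    name = "motif"
    rows = []
    base_rows = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] or name
            continue
        match = re.match(r"^([ACGT])\s*[\[|]?\s*([-\d.eE+\s]+)\]?\s*$", line)
        if match:
            base_rows[match.group(1)] = [float(x)
                                         for x in match.group(2).split()]
        else:
            values = [float(x) for x in line.replace("[", " ")
                      .replace("]", " ").split()]
            if values:
                rows.append(values)
    if len(base_rows) == 4:
        length = {len(v) for v in base_rows.values()}
        if len(length) != 1:
            raise ValueError("base rows have unequal lengths")
        values = np.array([base_rows[b] for b in BASES]).T
        return PositionFrequencyMatrix(values, name=name)
    if rows and all(len(r) == 4 for r in rows):
        return PositionFrequencyMatrix(np.array(rows), name=name)
    raise ValueError(f"unrecognized PFM format in {path}")


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path):
    lines = [f">{pfm.name}"]
    for i, base in enumerate(BASES):
        values = " ".join(f"{v:g}" for v in pfm.values[:, i])
        lines.append(f"{base} [ {values} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict:
    """All records of a FASTA file as ``{name: sequence}`` (index-backed)."""
    import pyfaidx
    with pyfaidx.Fasta(str(path)) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(seq_by_chrom: dict, path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in seq_by_chrom.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sites_bed(sites: SiteList, path, sidecar: bool = True):
    """BED6 (one-base interval at the center, integer-scaled score) plus a
    sidecar ``<path>.scores.tsv`` with exact real-valued scores."""
    path = Path(path)
    with open(path, "w") as fh:
        for site in sites:
            bed_score = int(np.clip(round(site.score * 100), 0, 1000))
            fh.write(f"{site.chrom}\t{site.center}\t{site.center + 1}\t"
                     f"{site.id}\t{bed_score}\t{site.strand}\n")
    if sidecar:
        sites.frame[["id", "score"]].to_csv(
            path.with_suffix(path.suffix + ".scores.tsv"), sep="\t",
            index=False)


def read_sites_bed(path) -> SiteList:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "id", "score",
                               "strand"],
                        dtype={"chrom": str, "id": str})
    frame["center"] = frame["start"].astype(int)
    frame["score"] = frame["score"].astype(float) / 100.0
    sidecar = path.with_suffix(path.suffix + ".scores.tsv")
    if sidecar.exists():
        exact = pd.read_csv(sidecar, sep="\t").set_index("id")["score"]
        frame["score"] = frame["id"].map(exact).fillna(frame["score"])
    return SiteList(frame[["chrom", "center", "strand", "score", "id"]])


def read_peaks(path, dialect: str = "narrowPeak") -> SiteList:
    """ENCODE peak files reduced to single-base centers.

    narrowPeak uses the summit offset (column 10) when nonnegative, else
    the interval midpoint; broadPeak always the midpoint.
    """
    frame = pd.read_csv(path, sep="\t", header=None)
    chrom = frame[0].astype(str)
    start = frame[1].astype(int)
    end = frame[2].astype(int)
    mid = start + (end - start) // 2
    if dialect == "narrowPeak" and frame.shape[1] >= 10:
        summit = frame[9].astype(int)
        center = np.where(summit >= 0, start + summit, mid)
    elif dialect in ("narrowPeak", "broadPeak"):
        center = mid
    else:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    score = frame[6].astype(float) if frame.shape[1] > 6 else \
        frame[4].astype(float) if frame.shape[1] > 4 else 0.0
    ids = (frame[3].astype(str) if frame.shape[1] > 3
           else pd.Series([f"peak_{i}" for i in range(len(frame))]))
    if ids.duplicated().any():
        ids = pd.Series([f"{n}_{i}" for i, n in enumerate(ids)])
    out = pd.DataFrame({"chrom": chrom, "center": center, "strand": ".",
                        "score": score, "id": ids})
    return SiteList(out)


def write_tag_track(track: TagTrack, path):
    """Sorted 4-column TSV: chrom, pos, strand, count."""
    track.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_tag_track(path, name: str | None = None) -> TagTrack:
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "pos", "strand", "count"],
                        dtype={"chrom": str})
    return TagTrack._from_frame(frame, name or Path(path).stem)


def tag_track_from_bam(path, name: str | None = None,
                       min_mapq: int = 0) -> TagTrack:
    """Extract read 5' positions from a BAM file (requires pysam)."""
    import pysam
    records = []
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam:
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if read.is_reverse:
                records.append((read.reference_name,
                                read.reference_end - 1, "-"))
            else:
                records.append((read.reference_name,
                                read.reference_start, "+"))
    return TagTrack.from_positions(records, name or Path(path).stem)


def write_bedgraph(track: NumericTrack, path):
    track.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path, name: str | None = None) -> NumericTrack:
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "value"],
                        dtype={"chrom": str})
    frame = frame[~frame["chrom"].str.startswith(("track", "#"))].dropna()
    records = list(frame.itertuples(index=False, name=None))
    return NumericTrack.from_intervals(records, name or Path(path).stem)


def read_snp_bed(path) -> SiteList:
    frame = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    out = pd.DataFrame({"chrom": frame[0].astype(str),
                        "center": frame[1].astype(int),
                        "strand": ".", "score": 0.0,
                        "id": [f"snp_{i}" for i in range(len(frame))]})
    return SiteList(out)


def write_snp_bed(snps: SiteList, path):
    with open(path, "w") as fh:
        for site in snps:
            fh.write(f"{site.chrom}\t{site.center}\t{site.center + 1}\n")
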