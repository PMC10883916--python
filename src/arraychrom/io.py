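"""On-disk formats and coordinate-convention conversions.

Internal coordinates are 0-based half-open, matching BED and bedGraph on
disk; GFF3 is 1-based inclusive, so the conversion at that boundary is
``internal (start, end)`` <-> ``GFF3 (start + 1, end)``. FASTA goes through
Biopython, GFF3 reading through gffutils; BED/bedGraph writers are plain
line formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Feature
from .tracks import StrandedCoverage


class ParseError(ValueError):
    """A malformed input line, reported with its file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


# --- coordinate conversions -------------------------------------------------

def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if end <= start:
        raise ValueError("empty interval")
    return start + 1, end


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise ValueError("invalid 1-based inclusive interval")
    return start1 - 1, end1


# --- FASTA ------------------------------------------------------------------

def write_fasta(path, sequence: str, name: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")],
                str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- bedGraph ---------------------------------------------------------------

def write_bedgraph(path, values: np.ndarray, replicon: str) -> None:
    """Run-length encode a per-base track as 0-based half-open bedGraph."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{replicon}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, length: int) -> np.ndarray:
    """Expand a bedGraph file to a per-base array of the given length."""
    out = np.zeros(length)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, "expected 4 bedGraph columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if not 0 <= s < e <= length:
                raise ParseError(path, lineno, f"interval [{s},{e}) outside "
                                 f"replicon of length {length}")
            out[s:e] = v
    return out


def write_stranded_bedgraph(prefix, cov: StrandedCoverage) -> tuple[Path, Path]:
    """Write one bedGraph per strand (``<prefix>.plus/.minus.bedgraph``)."""
    plus = Path(f"{prefix}.plus.bedgraph")
    minus = Path(f"{prefix}.minus.bedgraph")
    write_bedgraph(plus, cov.fwd, cov.replicon)
    write_bedgraph(minus, cov.rev, cov.replicon)
    return plus, minus


def read_stranded_bedgraph(prefix, length: int, replicon: str = "synchrom",
                           circular: bool = True) -> StrandedCoverage:
    return StrandedCoverage(
        replicon,
        read_bedgraph(f"{prefix}.plus.bedgraph", length),
        read_bedgraph(f"{prefix}.minus.bedgraph", length),
        circular)


# --- BED6 -------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(path, intervals: list[tuple]) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, lineno, "expected 6 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3],
                             float(parts[4]), parts[5]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if rows[-1][2] <= rows[-1][1]:
                raise ParseError(path, lineno, "end must exceed start")
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


# --- GFF3 -------------------------------------------------------------------

def write_gff3(path, features: list[Feature], replicon: str,
               length: int) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {replicon} 1 {length}\n")
        for f in features:
            start1, end1 = internal_to_gff(f.start, f.end)
            attrs = f"ID={f.id}" if f.id else "."
            if f.parent:
                attrs += f";Parent={f.parent}"
            fh.write(f"{replicon}\tarraychrom\t{f.kind}\t{start1}\t{end1}\t."
                     f"\t{f.strand}\t.\t{attrs}\n")


def read_gff3(path) -> list[Feature]:
    """Read GFF3 features back into internal 0-based half-open intervals."""
    feats = []
    for rec in gffutils.iterators.DataIterator(str(path)):
        start, end = gff_to_internal(rec.start, rec.end)
        fid = rec.attributes.get("ID", [""])[0]
        parent = rec.attributes.get("Parent", [None])[0]
        feats.append(Feature(rec.featuretype, start, end, rec.strand, fid,
                             parent))
    return feats


# --- TSS cluster tables -----------------------------------------------------

def clusters_to_frame(clusters) -> pd.DataFrame:
    """Flatten TSS clusters to a table (centre reported 1-based)."""
    rows = []
    for cl in clusters:
        row = {"replicon": cl.replicon, "centre_1based": cl.centre + 1,
               "strand": cl.strand, "n_members": len(cl.members),
               "class": cl.tss_class, "leaderless": cl.leaderless,
               "utr_length": cl.utr_length, "operon": cl.operon}
        for sample, count in cl.counts.items():
            row[f"count_{sample}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def write_clusters(path, clusters) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
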