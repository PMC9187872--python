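"""Readers and writers for the standard text formats the pipeline touches.

bedGraph (4-col), narrowPeak (BED6+4), BED6 repeats (class in the name
column), FASTA, GTF gene/exon features and TSV matrices. Internal
coordinates are uniformly 0-based half-open; GTF's 1-based inclusive
coordinates are converted here, at the boundary.
"""

from __future__ import annotations

import os

import pandas as pd

from .core import (
    UNKNOWN_SUMMIT,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    Peak,
    RepeatElement,
    REPEAT_CLASSES,
)
from .coverage import CoverageTrack

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gtf_genes",
    "read_repeats_bed",
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class ParseError(ValueError):
    """Malformed record, with file and line context."""


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bedgraph(path: str | os.PathLike, assembly: GenomeAssembly) -> CoverageTrack:
    """Parse a 4-column bedGraph into a coverage track.

    Records may arrive unsorted; overlaps between records are a
    validation error, as is any interval beyond assembly bounds.
    """
    records = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if chrom not in assembly:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        records.append((chrom, start, end, value))
    track = CoverageTrack(assembly)
    per_chrom: dict[str, list] = {}
    for rec in records:
        per_chrom.setdefault(rec[0], []).append(rec[1:])
    for chrom, recs in per_chrom.items():
        s, e, v = zip(*recs)
        track.set_segments(chrom, s, e, v)  # validates overlap/bounds
    return track


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_narrowpeak(path: str | os.PathLike) -> list[Peak]:
    """Parse ENCODE narrowPeak (BED6+4).

    Column 10 is the summit offset from ``start``; −1 means unknown and
    is carried through as the unknown-summit sentinel so the summit can
    be recomputed from coverage downstream.
    """
    peaks = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 10:
            raise ParseError(
                f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}"
            )
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5] if fields[5] in ("+", "-") else "."
        score = float(fields[4])
        offset = int(fields[9])
        if offset >= end - start:
            raise ParseError(
                f"{path}:{lineno}: summit offset {offset} >= peak length {end - start}"
            )
        summit = start + offset if offset >= 0 else UNKNOWN_SUMMIT
        peaks.append(
            Peak(GenomicInterval(chrom, start, end, strand), summit=summit, score=score)
        )
    return peaks


def write_narrowpeak(peaks, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            offset = p.summit - p.interval.start if p.summit != UNKNOWN_SUMMIT else -1
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak_{i + 1}\t{p.score:g}\t{p.interval.strand}\t"
                f"{p.score:g}\t-1\t-1\t{offset}\n"
            )


def read_gtf_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Collect gene models from GTF gene/exon features.

    Exons of all transcripts of one gene id are unioned into a single
    model. A gene without an explicit ``gene`` feature line gets the
    span of its exons.
    """
    spans: dict[str, list] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    names: dict[str, str] = {}
    order: list[str] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
        chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
        if feature not in ("gene", "exon", "transcript"):
            continue
        attr = _parse_gtf_attrs(attrs)
        gene_id = attr.get("gene_id")
        if not gene_id:
            raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
        start, end = int(start1) - 1, int(end1)  # to 0-based half-open
        if gene_id not in spans:
            order.append(gene_id)
            spans[gene_id] = [chrom, start, end, strand]
            exons[gene_id] = []
        else:
            spans[gene_id][1] = min(spans[gene_id][1], start)
            spans[gene_id][2] = max(spans[gene_id][2], end)
        if "gene_name" in attr:
            names[gene_id] = attr["gene_name"]
        if feature == "exon":
            exons[gene_id].append((start, end))
    genes = []
    for gid in order:
        chrom, start, end, strand = spans[gid]
        merged = _union_intervals(exons[gid])
        genes.append(
            GeneModel(
                gene_id=gid,
                name=names.get(gid, gid),
                interval=GenomicInterval(chrom, start, end, strand),
                exons=[GenomicInterval(chrom, s, e, strand) for s, e in merged],
            )
        )
    return genes


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def _union_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_repeats_bed(path: str | os.PathLike) -> list[RepeatElement]:
    """BED6 with the repeat class in the name column."""
    repeats = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: repeat BED needs >= 4 columns")
        chrom, start, end, cls = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        if cls not in REPEAT_CLASSES:
            cls = "other"
        repeats.append(RepeatElement(GenomicInterval(chrom, start, end, strand), cls))
    return repeats


def read_fasta(path: str | os.PathLike) -> GenomeAssembly:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    if not sequences:
        raise ParseError(f"{path}: no FASTA records")
    return GenomeAssembly.from_sequences(sequences)


def write_fasta(assembly: GenomeAssembly, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in assembly.chroms():
            seq = assembly.sequences[chrom]
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_matrix_tsv(path: str | os.PathLike, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)
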