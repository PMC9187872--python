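"""Shared genomic value types.

All coordinates are 0-based half-open (BED convention). GTF input is
converted at the parsing boundary; nothing downstream ever sees 1-based
coordinates. Chromosome names are taken verbatim — no ``chr`` prefix
normalization — and a name mismatch between files is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GenomeAssembly",
    "GeneModel",
    "RepeatElement",
    "Peak",
    "ConsensusSite",
    "SiteAnnotation",
]

#: sentinel for a summit not yet localized from coverage
UNKNOWN_SUMMIT = -1

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "simple_repeat", "other")

ANNOTATION_CATEGORIES = (
    "promoter",
    "TTS",
    "exon",
    "SINE",
    "LINE",
    "LTR",
    "simple_repeat",
    "intron",
    "intergenic",
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeAssembly:
    """Chromosome sizes plus (optionally) their sequence.

    Parameters
    ----------
    sizes
        Mapping chromosome name -> length in bp.
    sequences
        Optional mapping chromosome name -> DNA string over {A,C,G,T,N}.
        When given for a chromosome, its length must equal the declared
        size.
    """

    def __init__(self, sizes: dict[str, int], sequences: dict[str, str] | None = None):
        if not sizes:
            raise ValueError("assembly needs at least one chromosome")
        for name, size in sizes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive size {size}")
        self.sizes = dict(sizes)
        self.sequences: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                if name not in self.sizes:
                    raise ValueError(f"sequence for unknown chromosome {name}")
                if len(seq) != self.sizes[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared size "
                        f"{self.sizes[name]} for {name}"
                    )
                self.sequences[name] = seq.upper()

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "GenomeAssembly":
        return cls({c: len(s) for c, s in sequences.items()}, sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def chroms(self) -> list[str]:
        return list(self.sizes)

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval (forward strand)."""
        if interval.chrom not in self.sequences:
            raise KeyError(f"no sequence for chromosome {interval.chrom}")
        if interval.end > self.sizes[interval.chrom]:
            raise ValueError(f"interval {interval} beyond chromosome end")
        return self.sequences[interval.chrom][interval.start : interval.end]

    def same_chroms(self, other: "GenomeAssembly") -> bool:
        return self.sizes == other.sizes


@dataclass
class GeneModel:
    """A gene with the union of its transcripts' exons.

    TSS is the first transcribed base: ``start`` on '+', ``end - 1``
    on '-'.  TES mirrors it.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def tes(self) -> int:
        if self.strand == "-":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat class {self.repeat_class!r} not in {REPEAT_CLASSES}"
            )


@dataclass
class Peak:
    """A called enrichment interval with a summit.

    ``summit`` is an absolute position; ``UNKNOWN_SUMMIT`` marks a peak
    whose summit must be recomputed from coverage later. ``score`` is an
    opaque enrichment score (narrowPeak column 5 style) kept for output
    only; the pipeline never ranks on it.
    """

    interval: GenomicInterval
    summit: int = UNKNOWN_SUMMIT
    score: float = 0.0
    probe_set: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.summit != UNKNOWN_SUMMIT and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside peak {self.interval}"
            )


@dataclass
class ConsensusSite:
    """Binding site supported by both probe sets in all replicates."""

    interval: GenomicInterval
    summit: int
    summit_pairs: list[tuple[int, int]]  # per replicate (even, odd) summits
    support: int = 3


@dataclass
class SiteAnnotation:
    site: ConsensusSite
    category: str
    nearest_gene: str
    tss_distance: float  # signed; inf when no gene on the chromosome

    def __post_init__(self) -> None:
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
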