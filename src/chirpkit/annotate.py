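"""Genomic-context classification and nearest-gene assignment of sites.

Classification is by summit position with the fixed priority
promoter > TTS > exon > repeat class > intron > intergenic. The
promoter window is strand-aware around the TSS (default -1000..+100);
the TTS window mirrors it around the TES.
"""

from __future__ import annotations

from collections import Counter

from .core import (
    ANNOTATION_CATEGORIES,
    ConsensusSite,
    GeneModel,
    RepeatElement,
    SiteAnnotation,
)

__all__ = ["classify_site", "nearest_gene", "annotate_sites", "annotation_summary"]

DEFAULT_PROMOTER_WINDOW = (-1000, 100)


def _window_around(anchor: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    """Strand-aware half-open window [anchor+lo, anchor+hi] inclusive of hi."""
    lo, hi = window
    if strand == "-":
        return anchor - hi, anchor - lo + 1
    return anchor + lo, anchor + hi + 1


def classify_site(
    site: ConsensusSite,
    genes: list[GeneModel],
    repeats: list[RepeatElement],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> str:
    pos = site.summit
    chrom = site.interval.chrom
    chrom_genes = [g for g in genes if g.interval.chrom == chrom]
    for g in chrom_genes:
        lo, hi = _window_around(g.tss, g.strand, promoter_window)
        if lo <= pos < hi:
            return "promoter"
    for g in chrom_genes:
        lo, hi = _window_around(g.tes, g.strand, promoter_window)
        if lo <= pos < hi:
            return "TTS"
    in_gene = False
    for g in chrom_genes:
        if g.interval.start <= pos < g.interval.end:
            in_gene = True
            for ex in g.exons:
                if ex.start <= pos < ex.end:
                    return "exon"
    for rep in repeats:
        iv = rep.interval
        if iv.chrom == chrom and iv.start <= pos < iv.end:
            if rep.repeat_class in ANNOTATION_CATEGORIES:
                return rep.repeat_class
    if in_gene:
        return "intron"
    return "intergenic"


def nearest_gene(site: ConsensusSite, genes: list[GeneModel]) -> tuple[str, float]:
    """Gene minimizing |summit - TSS|; signed distance respects gene strand.

    Negative distance = summit upstream of the TSS. Ties go to the
    lexicographically first gene id. No gene on the chromosome ->
    ("", inf).
    """
    pos = site.summit
    best: tuple[int, str, float] | None = None
    for g in genes:
        if g.interval.chrom != site.interval.chrom:
            continue
        dist = abs(pos - g.tss)
        if best is None or dist < best[0] or (dist == best[0] and g.gene_id < best[1]):
            signed = pos - g.tss if g.strand != "-" else g.tss - pos
            best = (dist, g.gene_id, float(signed))
    if best is None:
        return "", float("inf")
    return best[1], best[2]


def annotate_sites(
    sites: list[ConsensusSite],
    genes: list[GeneModel],
    repeats: list[RepeatElement],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> list[SiteAnnotation]:
    out = []
    for site in sites:
        category = classify_site(site, genes, repeats, promoter_window)
        gene_id, dist = nearest_gene(site, genes)
        out.append(SiteAnnotation(site, category, gene_id, dist))
    return out


def annotation_summary(
    annotations: list[SiteAnnotation],
) -> dict[str, tuple[int, float]]:
    """Per-category (count, fraction); fractions sum to 1."""
    if not annotations:
        raise ValueError("empty annotation set")
    counts = Counter(a.category for a in annotations)
    total = len(annotations)
    return {cat: (counts.get(cat, 0), counts.get(cat, 0) / total)
            for cat in ANNOTATION_CATEGORIES}
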