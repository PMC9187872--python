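"""Candidate peak calling and dual-probe / triplicate consensus rules.

``call_peaks`` is a deliberately simple Poisson scan-statistic caller
(a stand-in for a full peak caller, whose parameters are all exposed);
externally called narrowPeak files can be supplied instead. The
consensus layer then demands that a site be supported by an even/odd
peak pair (overlapping intervals, summits within a maximum distance)
in every replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import UNKNOWN_SUMMIT, ConsensusSite, GenomicInterval, Peak
from .coverage import CoverageTrack, region_max

__all__ = ["CallerParams", "call_peaks", "pair_even_odd", "replicate_consensus"]


@dataclass
class CallerParams:
    window: int = 300
    p_threshold: float = 1e-5
    min_length: int = 100
    flank_small: int = 5000
    flank_large: int = 10000


def call_peaks(
    track: CoverageTrack,
    params: CallerParams | None = None,
    *,
    probe_set: str = "",
    replicate: int = 0,
) -> list[Peak]:
    """Scan a coverage track for windows exceeding a Poisson background.

    The background rate per base is the maximum of the genome-wide mean
    and the local means over 5-kb and 10-kb windows centred on the
    candidate (the local-lambda idea of count-based callers).
    Significant overlapping windows are merged; each merged region
    shorter than ``min_length`` is dropped; the summit is the leftmost
    maximum of the region.
    """
    params = params or CallerParams()
    genome_bp = sum(track.assembly.sizes.values())
    genome_mean = track.total() / genome_bp if genome_bp else 0.0
    peaks: list[Peak] = []
    if genome_mean == 0.0:
        return peaks
    w = params.window
    for chrom in sorted(track.chroms()):
        size = track.assembly.sizes[chrom]
        if size < w:
            continue
        cov = track.to_array(chrom)
        csum = np.concatenate([[0.0], np.cumsum(cov)])
        starts = np.arange(0, size - w + 1)
        win_sum = csum[starts + w] - csum[starts]
        lam = np.maximum(
            _local_mean(csum, starts + w // 2, params.flank_small, size),
            _local_mean(csum, starts + w // 2, params.flank_large, size),
        )
        lam = np.maximum(lam, genome_mean) * w
        k = np.round(win_sum).astype(np.int64)
        # only test windows that could possibly be enriched
        candidate = win_sum > lam
        pvals = np.ones(len(starts))
        if candidate.any():
            pvals[candidate] = stats.poisson.sf(k[candidate] - 1, lam[candidate])
        hit = pvals < params.p_threshold
        for region_start, region_end, best_p in _merge_hit_windows(starts[hit], w, pvals[hit]):
            if region_end - region_start < params.min_length:
                continue
            interval = GenomicInterval(chrom, int(region_start), int(region_end))
            summit, _ = region_max(track, interval)
            score = min(10000.0, -10.0 * math.log10(max(best_p, 1e-300)))
            peaks.append(
                Peak(interval, summit=summit, score=score,
                     probe_set=probe_set, replicate=replicate)
            )
    return peaks


def _local_mean(csum: np.ndarray, centers: np.ndarray, width: int, size: int) -> np.ndarray:
    lo = np.clip(centers - width // 2, 0, size)
    hi = np.clip(centers + width // 2, 0, size)
    span = np.maximum(hi - lo, 1)
    return (csum[hi] - csum[lo]) / span


def _merge_hit_windows(hit_starts: np.ndarray, w: int, hit_pvals: np.ndarray):
    """Union overlapping significant windows into (start, end, min p)."""
    if len(hit_starts) == 0:
        return
    region_start = int(hit_starts[0])
    region_end = region_start + w
    best_p = float(hit_pvals[0])
    for s, p in zip(hit_starts[1:], hit_pvals[1:]):
        if s <= region_end:
            region_end = int(s) + w
            best_p = min(best_p, float(p))
        else:
            yield region_start, region_end, best_p
            region_start, region_end, best_p = int(s), int(s) + w, float(p)
    yield region_start, region_end, best_p


def pair_even_odd(
    peaks_even: list[Peak],
    peaks_odd: list[Peak],
    max_summit_distance: int = 200,
    *,
    sense: str = "maximum",
) -> list[tuple[Peak, Peak]]:
    """Match even- and odd-probe-set peaks of one replicate.

    A pair requires interval overlap of at least 1 bp and an even/odd
    summit separation of at most ``max_summit_distance`` (the published
    wording "minimal distance of 200 bp" is read as a maximum allowed
    separation; ``sense='minimum'`` gives the literal reading).
    Matching is greedy by smallest summit distance, each peak used at
    most once.
    """
    if sense not in ("maximum", "minimum"):
        raise ValueError("sense must be 'maximum' or 'minimum'")
    candidates = []
    for i, pe in enumerate(peaks_even):
        if pe.summit == UNKNOWN_SUMMIT:
            raise ValueError("even peak without summit; recompute from coverage first")
        for j, po in enumerate(peaks_odd):
            if po.summit == UNKNOWN_SUMMIT:
                raise ValueError("odd peak without summit; recompute from coverage first")
            if not pe.interval.overlaps(po.interval):
                continue
            dist = abs(pe.summit - po.summit)
            ok = dist <= max_summit_distance if sense == "maximum" else dist >= max_summit_distance
            if ok:
                candidates.append((dist, pe.summit, po.summit, i, j))
    candidates.sort()
    used_even: set[int] = set()
    used_odd: set[int] = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_even or j in used_odd:
            continue
        used_even.add(i)
        used_odd.add(j)
        pairs.append((peaks_even[i], peaks_odd[j]))
    pairs.sort(key=lambda pr: (pr[0].interval.chrom, min(pr[0].interval.start, pr[1].interval.start)))
    return pairs


def _footprint(pair: tuple[Peak, Peak]) -> tuple[str, int, int]:
    pe, po = pair
    return (
        pe.interval.chrom,
        min(pe.interval.start, po.interval.start),
        max(pe.interval.end, po.interval.end),
    )


def replicate_consensus(*replicate_pairs: list[tuple[Peak, Peak]]) -> list[ConsensusSite]:
    """Sites whose even∪odd footprints mutually overlap in all replicates.

    In one dimension, pairwise overlap of a set of intervals is
    equivalent to a non-empty common intersection, so support is checked
    by intersecting footprints across replicates. The site interval is
    the union span of the supporting footprints; the representative
    summit is the median of all supporting summits (lower of the middle
    two for an even count). Each footprint supports at most one site.
    """
    if len(replicate_pairs) < 3:
        raise ValueError("need pair lists from at least three replicates")
    return consensus_over(list(replicate_pairs))


def consensus_over(replicate_pairs: list[list[tuple[Peak, Peak]]]) -> list[ConsensusSite]:
    """Consensus requiring support from every supplied replicate list."""
    n = len(replicate_pairs)
    anchor = sorted(
        range(len(replicate_pairs[0])),
        key=lambda i: _footprint(replicate_pairs[0][i]),
    )
    used: list[set[int]] = [set() for _ in range(n)]
    sites: list[ConsensusSite] = []
    for i0 in anchor:
        chrom, lo, hi = _footprint(replicate_pairs[0][i0])
        chosen = [i0]
        ix_lo, ix_hi = lo, hi  # running common intersection
        un_lo, un_hi = lo, hi  # running union span
        ok = True
        for r in range(1, n):
            best = None
            for j, pair in enumerate(replicate_pairs[r]):
                if j in used[r]:
                    continue
                c, s, e = _footprint(pair)
                if c != chrom or s >= ix_hi or e <= ix_lo:
                    continue
                overlap = min(e, ix_hi) - max(s, ix_lo)
                if best is None or overlap > best[0] or (overlap == best[0] and s < best[2]):
                    best = (overlap, j, s, e)
            if best is None:
                ok = False
                break
            _, j, s, e = best
            chosen.append(j)
            ix_lo, ix_hi = max(ix_lo, s), min(ix_hi, e)
            un_lo, un_hi = min(un_lo, s), max(un_hi, e)
        if not ok:
            continue
        for r, j in enumerate(chosen):
            used[r].add(j)
        summit_pairs = []
        summits = []
        for r, j in enumerate(chosen):
            pe, po = replicate_pairs[r][j]
            summit_pairs.append((pe.summit, po.summit))
            summits.extend([pe.summit, po.summit])
        summits.sort()
        summit = summits[(len(summits) - 1) // 2]  # lower median
        sites.append(
            ConsensusSite(
                interval=GenomicInterval(chrom, un_lo, un_hi),
                summit=summit,
                summit_pairs=summit_pairs,
                support=n,
            )
        )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return sites
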