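"""Interval-resolution arithmetic on piecewise-constant coverage tracks.

The central operation is :func:`take_lower_merge`, the per-base minimum
of an even- and an odd-probe-set track. Positions without an explicit
segment have value 0, so the merge of a covered and an uncovered region
is 0.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .core import GenomeAssembly, GenomicInterval

__all__ = ["CoverageTrack", "take_lower_merge", "region_max"]


class CoverageTrack:
    """Sorted, disjoint (start, end, value) segments per chromosome.

    Segments are stored as three parallel numpy arrays per chromosome.
    Zero-valued gaps are implicit. Adjacent equal-valued segments are
    coalesced on construction so the representation is canonical.
    """

    def __init__(self, assembly: GenomeAssembly):
        self.assembly = assembly
        self._segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction -------------------------------------------------

    def set_segments(
        self, chrom: str, starts, ends, values, *, validate: bool = True
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if chrom not in self.assembly:
            raise ValueError(f"chromosome {chrom} not in assembly")
        if len(starts) == 0:
            self._segments.pop(chrom, None)
            return
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if validate:
            if np.any(starts < 0) or np.any(ends > self.assembly.sizes[chrom]):
                raise ValueError(f"segment beyond bounds of {chrom}")
            if np.any(starts >= ends):
                raise ValueError("empty or inverted segment")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping segments on {chrom} near position {starts[i + 1]}"
                )
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError("values must be finite and non-negative")
        # drop zero segments (implicit) and coalesce equal neighbours
        keep = values != 0
        starts, ends, values = starts[keep], ends[keep], values[keep]
        if len(starts) == 0:
            self._segments.pop(chrom, None)
            return
        cs, ce, cv = [starts[0]], [ends[0]], [values[0]]
        for s, e, v in zip(starts[1:], ends[1:], values[1:]):
            if s == ce[-1] and v == cv[-1]:
                ce[-1] = e
            else:
                cs.append(s)
                ce.append(e)
                cv.append(v)
        self._segments[chrom] = (
            np.asarray(cs, dtype=np.int64),
            np.asarray(ce, dtype=np.int64),
            np.asarray(cv, dtype=np.float64),
        )

    @classmethod
    def from_records(
        cls, assembly: GenomeAssembly, records
    ) -> "CoverageTrack":
        """Build from an iterable of (chrom, start, end, value)."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls(assembly)
        for chrom, recs in per_chrom.items():
            s, e, v = zip(*recs)
            track.set_segments(chrom, s, e, v)
        return track

    # -- queries -------------------------------------------------------

    def chroms(self) -> list[str]:
        return list(self._segments)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom in self._segments:
            s, e, v = self._segments[chrom]
            return s.copy(), e.copy(), v.copy()
        empty_i = np.empty(0, dtype=np.int64)
        return empty_i, empty_i.copy(), np.empty(0, dtype=np.float64)

    def iter_records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._segments):
            s, e, v = self._segments[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._segments:
            return 0.0
        s, e, v = self._segments[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return 0.0

    def to_array(self, chrom: str, start: int = 0, end: int | None = None) -> np.ndarray:
        """Per-base expansion over [start, end); implicit zeros filled in."""
        if end is None:
            end = self.assembly.sizes[chrom]
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._segments:
            return out
        s, e, v = self._segments[chrom]
        lo = np.maximum(s, start)
        hi = np.minimum(e, end)
        for a, b, val in zip(lo, hi, v):
            if a < b:
                out[a - start : b - start] = val
        return out

    def total(self) -> float:
        tot = 0.0
        for s, e, v in self._segments.values():
            tot += float(np.sum((e - s) * v))
        return tot

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        out = CoverageTrack(self.assembly)
        for chrom, (s, e, v) in self._segments.items():
            out.set_segments(chrom, s, e, v * factor, validate=False)
        return out


def take_lower_merge(
    track_even: CoverageTrack,
    track_odd: CoverageTrack,
    *,
    scale_even: float = 1.0,
    scale_odd: float = 1.0,
) -> CoverageTrack:
    """Per-base minimum of two tracks on the same assembly.

    Implemented as a sweep over the union of segment boundaries, so the
    cost is linear in the number of segments, never in genome size.
    Optional scale factors are applied to each input first (whether the
    source libraries were depth-normalized is not specified upstream;
    default 1 leaves the tracks untouched).
    """
    if not track_even.assembly.same_chroms(track_odd.assembly):
        raise ValueError("tracks are on different assemblies")
    if scale_even != 1.0:
        track_even = track_even.scaled(scale_even)
    if scale_odd != 1.0:
        track_odd = track_odd.scaled(scale_odd)
    merged = CoverageTrack(track_even.assembly)
    for chrom in sorted(set(track_even.chroms()) & set(track_odd.chroms())):
        s1, e1, v1 = track_even.segments(chrom)
        s2, e2, v2 = track_odd.segments(chrom)
        bounds = np.unique(np.concatenate([s1, e1, s2, e2]))
        if len(bounds) < 2:
            continue
        mids = bounds[:-1]  # left edge identifies each elementary interval
        val1 = _values_at(s1, e1, v1, mids)
        val2 = _values_at(s2, e2, v2, mids)
        merged.set_segments(
            chrom, bounds[:-1], bounds[1:], np.minimum(val1, val2), validate=False
        )
    return merged


def _values_at(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    out = np.zeros(len(pos), dtype=np.float64)
    if len(starts) == 0:
        return out
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    out[valid] = values[idx[valid]]
    return out


def region_max(track: CoverageTrack, interval: GenomicInterval) -> tuple[int, float]:
    """Leftmost position attaining the maximum value inside ``interval``."""
    if interval.chrom not in track.assembly:
        raise ValueError(f"chromosome {interval.chrom} not in assembly")
    if interval.end > track.assembly.sizes[interval.chrom]:
        raise ValueError("interval beyond assembly bounds")
    s, e, v = track.segments(interval.chrom)
    best_pos, best_val = interval.start, 0.0
    # candidate positions: interval start plus every segment start inside
    overlapping = (s < interval.end) & (e > interval.start)
    for seg_s, seg_v in zip(s[overlapping], v[overlapping]):
        pos = max(int(seg_s), interval.start)
        if seg_v > best_val:
            best_pos, best_val = pos, float(seg_v)
    if best_val == 0.0:
        # all-zero region (or leading gap is the max): leftmost base
        # unless a gap before the first overlapping segment exists —
        # value 0 there too, so interval.start is correct either way.
        return interval.start, 0.0
    # a zero gap can precede the best segment; max is still the segment
    return best_pos, best_val
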