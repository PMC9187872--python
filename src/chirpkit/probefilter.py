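"""Probe-sequence decontamination of consensus sites.

Each hybridization probe oligo is turned into a log-odds scoring matrix
(literal probe plus pseudo-frequency smoothing, FIMO-style) with an
exact score-to-p-value mapping computed by dynamic programming over the
discretized per-column score distribution under a 0-order background.
Sites containing a match below the p cutoff on either strand are
removed as direct DNA:probe capture artifacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ConsensusSite, GenomeAssembly

__all__ = [
    "ProbeMatrix",
    "MatchResult",
    "PValueTable",
    "build_probe_matrix",
    "exact_pvalue_table",
    "scan_and_filter",
    "genome_background",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDO = 0.01
DEFAULT_GRANULARITY = 1e-3  # bits per integer score unit
MAX_TABLE_SIZE = 10_000_000


@dataclass
class ProbeMatrix:
    """Log-odds matrix (bits) for one literal probe oligo.

    ``int_scores`` are the bit scores discretized to units of
    ``granularity``; the p-value DP and all sequence scoring use the
    same integer units so table lookups are exact.
    """

    name: str
    length: int
    freqs: np.ndarray  # (4, L), columns sum to 1
    background: np.ndarray  # (4,), sums to 1
    granularity: float = DEFAULT_GRANULARITY
    scores: np.ndarray = field(init=False)  # bits
    int_scores: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("probe length must be >= 4")
        if not np.allclose(self.freqs.sum(axis=0), 1.0):
            raise ValueError("matrix columns must sum to 1")
        self.scores = np.log2(self.freqs / self.background[:, None])
        self.int_scores = np.round(self.scores / self.granularity).astype(np.int64)


@dataclass
class MatchResult:
    site_index: int
    probe: str
    offset: int
    strand: str
    score: float  # bits
    p_value: float


def build_probe_matrix(
    probe: str,
    background=None,
    pseudo: float = DEFAULT_PSEUDO,
    *,
    name: str = "probe",
    granularity: float = DEFAULT_GRANULARITY,
) -> ProbeMatrix:
    """Column frequencies ``(1 - pseudo)·indicator + pseudo·background``."""
    probe = probe.upper()
    if any(b not in _CODE for b in probe):
        raise ValueError(f"probe contains non-ACGT characters: {probe!r}")
    if not (0 < pseudo < 0.5):
        raise ValueError("pseudo must be in (0, 0.5)")
    bg = _as_background(background)
    L = len(probe)
    freqs = np.tile(pseudo * bg[:, None], (1, L))
    for i, b in enumerate(probe):
        freqs[_CODE[b], i] += 1.0 - pseudo
    return ProbeMatrix(name=name, length=L, freqs=freqs, background=bg,
                       granularity=granularity)


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=np.float64)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    return bg / bg.sum()


def genome_background(assembly: GenomeAssembly) -> np.ndarray:
    """0-order base composition of the supplied genome (N ignored)."""
    counts = np.zeros(4, dtype=np.int64)
    for seq in assembly.sequences.values():
        for i, b in enumerate(_BASES):
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


class PValueTable:
    """Exact tail probabilities of the background score distribution.

    ``tail[k]`` = Pr(total integer score >= min_score + k) for a random
    L-mer drawn column-independently from the background.
    """

    def __init__(self, min_score: int, tail: np.ndarray, granularity: float):
        self.min_score = min_score
        self.tail = tail
        self.granularity = granularity

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.tail) - 1

    def pvalue(self, int_score: int) -> float:
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            return 0.0
        return float(self.tail[int_score - self.min_score])

    def pvalue_bits(self, score_bits: float) -> float:
        return self.pvalue(int(round(score_bits / self.granularity)))


def exact_pvalue_table(
    matrix: ProbeMatrix, *, max_table_size: int = MAX_TABLE_SIZE
) -> PValueTable:
    """Column-wise convolution of the discretized score distribution."""
    col_min = matrix.int_scores.min(axis=0)
    col_max = matrix.int_scores.max(axis=0)
    total_range = int((col_max - col_min).sum()) + 1
    if total_range > max_table_size:
        raise ValueError(
            f"p-value table would need {total_range} entries "
            f"(> {max_table_size}); use a coarser granularity"
        )
    dist = np.zeros(total_range, dtype=np.float64)
    dist[0] = 1.0
    width = 1  # occupied prefix of dist, scores offset by sum(col_min) so far
    for j in range(matrix.length):
        shifts = matrix.int_scores[:, j] - col_min[j]
        new_width = width + int(col_max[j] - col_min[j])
        new = np.zeros(total_range, dtype=np.float64)
        for b in range(4):
            new[shifts[b] : shifts[b] + width] += matrix.background[b] * dist[:width]
        dist = new
        width = new_width
    tail = np.cumsum(dist[:width][::-1])[::-1]
    # clamp accumulated float error; tail must start at exactly 1
    tail = np.minimum(tail, 1.0)
    tail[0] = 1.0
    return PValueTable(int(col_min.sum()), tail, matrix.granularity)


def encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(codes), -1, dtype=np.int64)
    for b, i in _CODE.items():
        out[codes == ord(b)] = i
    return out


def scan_sequence(
    seq: str, matrix: ProbeMatrix, table: PValueTable
) -> list[tuple[int, str, float, float]]:
    """Score every offset of both strands; return (offset, strand, bits, p)."""
    results = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = encode(s)
        L = matrix.length
        if len(codes) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = np.all(windows >= 0, axis=1)
        if not valid.any():
            continue
        cols = np.arange(L)
        scores = matrix.int_scores[np.clip(windows, 0, 3), cols].sum(axis=1)
        for off in np.nonzero(valid)[0]:
            int_score = int(scores[off])
            results.append(
                (int(off), strand, int_score * matrix.granularity, table.pvalue(int_score))
            )
    return results


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_and_filter(
    sites: list[ConsensusSite],
    genome: GenomeAssembly,
    probes: dict[str, ProbeMatrix] | list[ProbeMatrix],
    p_cutoff: float = 1e-8,
    *,
    flank: int = 0,
) -> tuple[list[ConsensusSite], list[tuple[ConsensusSite, list[MatchResult]]]]:
    """Partition sites into (retained, removed-with-match-evidence).

    A site is removed when any offset on either strand of its sequence
    matches any probe matrix with p below ``p_cutoff``. The best
    per-match p-value is used as-is (no correction across offsets).
    Sites whose sequence is more than 50% N are skipped with a warning
    and retained.
    """
    if isinstance(probes, dict):
        probe_items = list(probes.items())
    else:
        probe_items = [(m.name, m) for m in probes]
    tables = {name: exact_pvalue_table(m) for name, m in probe_items}
    retained, removed = [], []
    for idx, site in enumerate(sites):
        chrom = site.interval.chrom
        start = max(0, site.interval.start - flank)
        end = min(genome.sizes[chrom], site.interval.end + flank)
        seq = genome.sequences[chrom][start:end]
        if seq.count("N") > 0.5 * len(seq):
            warnings.warn(
                f"site {idx} at {chrom}:{start}-{end} is >50% N; skipped, retained"
            )
            retained.append(site)
            continue
        hits = []
        for name, m in probe_items:
            for off, strand, bits, p in scan_sequence(seq, m, tables[name]):
                if p < p_cutoff:
                    hits.append(MatchResult(idx, name, off, strand, bits, p))
        if hits:
            removed.append((site, hits))
        else:
            retained.append(site)
    return retained, removed


def enumerate_pvalues(matrix: ProbeMatrix) -> dict[int, float]:
    """Brute-force tail probabilities by enumerating all 4^L L-mers.

    Exponential; intended for validating the DP on probes of length <= 8.
    """
    if matrix.length > 10:
        raise ValueError("enumeration oracle limited to length <= 10")
    from itertools import product

    scores = []
    probs = []
    for word in product(range(4), repeat=matrix.length):
        s = int(matrix.int_scores[list(word), range(matrix.length)].sum())
        p = float(np.prod(matrix.background[list(word)]))
        scores.append(s)
        probs.append(p)
    scores = np.asarray(scores)
    probs = np.asarray(probs)
    out = {}
    for s in np.unique(scores):
        out[int(s)] = float(probs[scores >= s].sum())
    return out
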