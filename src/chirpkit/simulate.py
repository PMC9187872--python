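"""Seeded generators for every input the pipeline consumes.

Genome + gene models + repeats, dual-probe-set replicate coverage
tracks with planted binding sites and probe-contaminant loci,
expression matrices with planted regulation and lncRNA-coupled targets,
and LFQ intensity matrices with planted enrichment and
intensity-dependent missingness. Every generator is a pure function of
(config, seed): identical inputs give identical outputs, and the
returned truth tables are sufficient to score recall/precision for
every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeAssembly, GenomicInterval, RepeatElement
from .coverage import CoverageTrack
from .lfq import LFQMatrix

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_chirp",
    "simulate_expression",
    "simulate_lfq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    chrom_count: int = 2
    chrom_size: int = 100_000
    n_genes: int = 16
    gene_length: tuple[int, int] = (2_000, 6_000)
    exons_per_gene: tuple[int, int] = (2, 4)
    repeats_per_class: int = 6
    repeat_length: tuple[int, int] = (150, 400)
    # ChIRP
    n_sites: int = 10
    n_contaminants: int = 3
    site_width: int = 400
    site_fold: float = 15.0
    background_mean: float = 2.0  # expected coverage per base
    replicate_noise_sd: float = 0.1  # lognormal sd of per-replicate site factor
    coverage_bin: int = 50
    probe_length: int = 20
    probes_per_set: int = 5
    contaminant_single_set: bool = False  # see design note in simulate_chirp
    # expression
    n_expr_genes: int = 300
    n_up: int = 30
    n_down: int = 30
    n_coupled: int = 40
    expr_effect_log2fc: float = 2.0
    expr_noise_cv: float = 0.1
    lnc_gene: str = "lncG0000"
    # LFQ
    n_proteins: int = 500
    n_enriched: int = 10
    lfq_shift_sd: float = 4.0  # planted shift in units of replicate noise sd
    lfq_noise_sd: float = 0.3
    lfq_mean: float = 25.0
    lfq_spread: float = 2.0
    flag_rate: float = 0.02
    n_exclusive: int = 3

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------- genome


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[GeneModel], list[RepeatElement]]:
    """Uniform-base genome with non-overlapping genes and repeats."""
    if config.chrom_size < 10_000:
        raise ValueError("chromosome size must be >= 10 kb")
    rng = config.rng(1)
    sequences = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=config.chrom_size))
        for i in range(config.chrom_count)
    }
    assembly = GenomeAssembly.from_sequences(sequences)
    genes = _place_genes(config, assembly, rng)
    repeats = _place_repeats(config, assembly, genes, rng)
    return assembly, genes, repeats


def _place_genes(config, assembly, rng) -> list[GeneModel]:
    chroms = assembly.chroms()
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    genes: list[GeneModel] = []
    gi = 0
    for chrom in chroms:
        size = assembly.sizes[chrom]
        cursor = int(rng.integers(1_000, 3_000))
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length))
            if cursor + length + 2_000 > size:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            end = cursor + length
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * n_ex - 2, replace=False))
            edges = np.concatenate([[0], cuts, [length]])
            exons = [
                GenomicInterval(chrom, start + int(edges[2 * k]), start + int(edges[2 * k + 1]), strand)
                for k in range(n_ex)
            ]
            gid = f"gene{gi:04d}"
            genes.append(
                GeneModel(gid, gid.capitalize(), GenomicInterval(chrom, start, end, strand), exons)
            )
            gi += 1
            cursor = end + int(rng.integers(2_000, 6_000))
    if gi < config.n_genes:
        raise ValueError("requested genes exceed genome capacity")
    return genes


def _place_repeats(config, assembly, genes, rng) -> list[RepeatElement]:
    from .core import REPEAT_CLASSES

    exon_spans = {
        chrom: [(e.start, e.end) for g in genes if g.interval.chrom == chrom for e in g.exons]
        for chrom in assembly.chroms()
    }
    repeats: list[RepeatElement] = []
    for cls in REPEAT_CLASSES[:4]:  # SINE, LINE, LTR, simple_repeat
        placed = 0
        attempts = 0
        while placed < config.repeats_per_class and attempts < 10_000:
            attempts += 1
            chrom = assembly.chroms()[int(rng.integers(len(assembly.chroms())))]
            length = int(rng.integers(*config.repeat_length))
            start = int(rng.integers(0, assembly.sizes[chrom] - length))
            if any(start < e and s < start + length for s, e in exon_spans[chrom]):
                continue
            if any(
                r.interval.chrom == chrom
                and r.interval.start < start + length
                and start < r.interval.end
                for r in repeats
            ):
                continue
            repeats.append(RepeatElement(GenomicInterval(chrom, start, start + length), cls))
            placed += 1
        if placed < config.repeats_per_class:
            raise ValueError("could not place requested repeats")
    return repeats


# ---------------------------------------------------------------- ChIRP


@dataclass
class ChirpTruth:
    sites: list[GenomicInterval] = field(default_factory=list)
    contaminants: list[GenomicInterval] = field(default_factory=list)


def simulate_chirp(
    config: SimulationConfig, genome: GenomeAssembly
) -> tuple[dict[tuple[int, str], CoverageTrack], ChirpTruth, dict[str, str], GenomeAssembly]:
    """Replicate even/odd coverage tracks with planted sites.

    Planted binding sites receive fold-elevated coverage in both probe
    sets with independent replicate noise. Contaminant loci carry a
    verbatim copy of one probe oligo in the genome sequence and — since
    such direct DNA:probe capture products survived the dual-probe
    consensus in the experiment this emulates — are by default also
    elevated in both probe-set tracks, so only the sequence-based probe
    filter can remove them (``contaminant_single_set=True`` restricts
    the elevation to the probe's own set, in which case pairing already
    excludes them).

    Returns (tracks keyed by (replicate, probe_set), truth, probes,
    genome-with-planted-probe-sequences).
    """
    rng = config.rng(2)
    probes = _make_probes(config, rng)
    truth = ChirpTruth()
    positions = _spread_positions(
        config, genome, rng, config.n_sites + config.n_contaminants
    )
    sequences = dict(genome.sequences)
    for k, (chrom, start) in enumerate(positions):
        iv = GenomicInterval(chrom, start, start + config.site_width)
        if k < config.n_sites:
            truth.sites.append(iv)
        else:
            truth.contaminants.append(iv)
            probe_name = list(probes)[(k - config.n_sites) % len(probes)]
            seq = sequences[chrom]
            mid = start + config.site_width // 2
            ins = probes[probe_name]
            sequences[chrom] = seq[:mid] + ins + seq[mid + len(ins) :]
    genome_out = GenomeAssembly.from_sequences(sequences)
    tracks: dict[tuple[int, str], CoverageTrack] = {}
    nbins = {c: genome.sizes[c] // config.coverage_bin for c in genome.chroms()}
    for rep in (1, 2, 3):
        for probe_set in ("even", "odd"):
            track = CoverageTrack(genome_out)
            for chrom in genome.chroms():
                b = config.coverage_bin
                vals = rng.poisson(config.background_mean * b, size=nbins[chrom]) / b
                vals = vals.astype(np.float64)
                for kind, ivs in (("site", truth.sites), ("cont", truth.contaminants)):
                    for iv in ivs:
                        if iv.chrom != chrom:
                            continue
                        if (
                            kind == "cont"
                            and config.contaminant_single_set
                            and probe_set != "even"
                        ):
                            continue
                        factor = rng.lognormal(0.0, config.replicate_noise_sd)
                        lo, hi = iv.start // b, -(-iv.end // b)
                        # triangular profile: summit pinned near the centre
                        centers = (np.arange(lo, hi) + 0.5) * b
                        mid = (iv.start + iv.end) / 2
                        shape = 1.0 - 0.8 * np.abs(centers - mid) / (len(iv) / 2)
                        vals[lo:hi] += (
                            config.site_fold * config.background_mean * factor * shape
                        )
                starts = np.arange(nbins[chrom]) * b
                ends = starts + b
                track.set_segments(chrom, starts, ends, vals, validate=False)
            tracks[(rep, probe_set)] = track
    return tracks, truth, probes, genome_out


def _make_probes(config, rng) -> dict[str, str]:
    """Tile 20-nt oligos across a synthetic transcript, alternating sets."""
    L = config.probe_length
    n_total = 2 * config.probes_per_set
    transcript = "".join(rng.choice(_BASES, size=L * n_total))
    probes = {}
    for i in range(n_total):
        name = f"{'even' if i % 2 == 0 else 'odd'}_{i // 2 + 1}"
        probes[name] = transcript[i * L : (i + 1) * L]
    return probes


def _spread_positions(config, genome, rng, n) -> list[tuple[str, int]]:
    min_gap = 4 * config.site_width + 1_000
    chroms = genome.chroms()
    positions: list[tuple[str, int]] = []
    attempts = 0
    while len(positions) < n and attempts < 100_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(2_000, genome.sizes[chrom] - config.site_width - 2_000))
        if any(c == chrom and abs(s - start) < min_gap for c, s in positions):
            continue
        positions.append((chrom, start))
    if len(positions) < n:
        raise ValueError("could not place requested sites; genome too small")
    return positions


# ------------------------------------------------------------ expression


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, pd.DataFrame], pd.DataFrame]:
    """TPM matrix for 2 conditions x 2 days x 4 replicates, plus DE stats.

    DE statistics are emitted from generator truth: null genes get a
    standard-normal 'stat', planted genes an offset of +-8, and 'fdr' is
    the Benjamini-Hochberg adjustment of the implied normal p-values —
    DESeq2-shaped columns without running a DE package. One designated
    lncRNA gene is reduced ~50% under KD and drives coupled targets
    with sign +1 on day 5 and -1 on day 7.
    """
    rng = config.rng(3)
    n = config.n_expr_genes
    gene_ids = [config.lnc_gene] + [f"gene{i:04d}" for i in range(1, n)]
    meta = []
    for cond in ("CON", "KD"):
        for day in (5, 7):
            for rep in (1, 2, 3, 4):
                meta.append((f"{cond}_d{day}_r{rep}", cond, day, rep))
    metadata = pd.DataFrame(
        meta, columns=["sample", "condition", "day", "replicate"]
    ).set_index("sample")

    base = rng.lognormal(3.0, 1.0, size=n)  # baseline TPM per gene
    base[0] = 50.0  # the lncRNA
    is_up = np.zeros(n, dtype=bool)
    is_down = np.zeros(n, dtype=bool)
    coupled = np.zeros(n, dtype=int)  # coupling sign on day 5; flips on day 7
    free = rng.permutation(np.arange(1, n))
    is_up[free[: config.n_up]] = True
    is_down[free[config.n_up : config.n_up + config.n_down]] = True
    c0 = config.n_up + config.n_down
    coupled_idx = free[c0 : c0 + config.n_coupled]
    coupled[coupled_idx] = np.where(rng.random(len(coupled_idx)) < 0.5, 1, -1)

    lnc_level = {}  # (cond, day) -> mean level of the lncRNA
    for day, growth in ((5, 1.0), (7, 2.0)):
        for cond, kd in (("CON", 1.0), ("KD", 0.5)):
            lnc_level[(cond, day)] = base[0] * growth * kd

    cols = {}
    effect = config.expr_effect_log2fc
    for sample, row in metadata.iterrows():
        cond, day = row["condition"], row["day"]
        mean = base.copy()
        mean[0] = lnc_level[(cond, day)]
        if cond == "KD":
            mean[is_up] *= 2.0**effect
            mean[is_down] *= 2.0**-effect
        lnc_dev = np.log2(lnc_level[(cond, day)] / base[0])
        sign = 1 if day == 5 else -1
        coupling = coupled * sign * lnc_dev * 0.8
        mean = mean * 2.0**coupling
        noise = rng.normal(1.0, config.expr_noise_cv, size=n).clip(min=0.05)
        cols[sample] = mean * noise
    expr = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    de: dict[int, pd.DataFrame] = {}
    from scipy.stats import norm

    for day in (5, 7):
        stat = rng.normal(0.0, 1.0, size=n)
        stat[is_up] += 8.0
        stat[is_down] -= 8.0
        stat[coupled_idx] += 6.0 * (1 if day == 5 else -1) * coupled[coupled_idx] * -1
        pv = 2.0 * norm.sf(np.abs(stat))
        order = np.argsort(pv)
        ranked = pv[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr = np.empty(n)
        fdr[order] = np.minimum(adj, 1.0)
        de[day] = pd.DataFrame(
            {"stat": stat, "fdr": fdr}, index=pd.Index(gene_ids, name="gene_id")
        )

    truth = pd.DataFrame(
        {
            "planted_up": is_up,
            "planted_down": is_down,
            "coupling_day5": coupled,
            "coupling_day7": -coupled,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return expr, metadata, de, truth


# ------------------------------------------------------------------ LFQ


def simulate_lfq(config: SimulationConfig) -> tuple[LFQMatrix, pd.DataFrame]:
    """5 vs 5 log-normal LFQ design with planted enrichment.

    Planted proteins are shifted up in the 'fl' condition by
    ``lfq_shift_sd`` replicate-noise SDs; missingness follows a logistic
    curve in log2 intensity so low-abundance proteins lose values; a
    few proteins are forced below detection in 'mut' to create
    exclusive-detection cases; reverse/contaminant/identified-by-site
    flags are sprinkled at ``flag_rate``.
    """
    rng = config.rng(4)
    n = config.n_proteins
    samples = [f"fl_{i + 1}" for i in range(5)] + [f"mut_{i + 1}" for i in range(5)]
    conditions = pd.Series(["fl"] * 5 + ["mut"] * 5, index=samples)
    base = rng.normal(config.lfq_mean, config.lfq_spread, size=n)
    enriched = np.zeros(n, dtype=bool)
    exclusive = np.zeros(n, dtype=bool)
    idx = rng.permutation(n)
    enriched[idx[: config.n_enriched]] = True
    exclusive[idx[config.n_enriched : config.n_enriched + config.n_exclusive]] = True
    # exclusive cases must be safely detectable in 'fl': pin their baseline
    base[exclusive] = np.maximum(base[exclusive], config.lfq_mean)

    log2 = np.empty((n, 10))
    for j in range(10):
        shift = np.zeros(n)
        if conditions.iloc[j] == "fl":
            shift[enriched] = config.lfq_shift_sd * config.lfq_noise_sd
            shift[exclusive] = 3.0
        else:
            shift[exclusive] = -15.0  # push far below detection
        log2[:, j] = base + shift + rng.normal(0, config.lfq_noise_sd, size=n)

    # logistic missingness: centred near the low quantile of intensity
    x0 = np.quantile(base, 0.08)
    p_miss = 1.0 / (1.0 + np.exp((log2 - x0) / 0.8))
    missing = rng.random((n, 10)) < p_miss
    intens = np.power(2.0, log2)
    intens[missing] = np.nan

    flags = pd.DataFrame(
        {
            "reverse": rng.random(n) < config.flag_rate,
            "contaminant": rng.random(n) < config.flag_rate,
            "identified_by_site": rng.random(n) < config.flag_rate,
        },
        index=pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id"),
    )
    intensities = pd.DataFrame(intens, index=flags.index, columns=samples)
    truth = pd.DataFrame(
        {"planted_enriched": enriched, "planted_exclusive": exclusive},
        index=flags.index,
    )
    matrix = LFQMatrix(
        intensities=intensities,
        conditions=conditions,
        flags=flags,
        gene_names=pd.Series(flags.index, index=flags.index),
    )
    return matrix, truth
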