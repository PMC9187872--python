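"""End-to-end orchestration of the binding-site inference chain.

merge -> call/ingest peaks -> even/odd pairing -> triplicate consensus
-> probe decontamination -> annotation, with every stage parameter
collected in one config object whose defaults are the published values.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

from .annotate import annotate_sites
from .coverage import CoverageTrack, take_lower_merge
from .core import ConsensusSite, GeneModel, GenomeAssembly, RepeatElement
from .peaks import CallerParams, call_peaks, pair_even_odd, replicate_consensus
from .probefilter import (
    MatchResult,
    build_probe_matrix,
    genome_background,
    scan_and_filter,
)

__all__ = ["PipelineConfig", "ChirpResult", "run_chirp", "write_manifest"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published values."""

    max_summit_distance: int = 200
    summit_sense: str = "maximum"
    probe_p_cutoff: float = 1e-8
    probe_pseudo: float = 0.01
    fdr_cut: float = 0.05
    stat_cut: float = 2.0
    fc_threshold: float = 2.0
    p_threshold: float = 0.002
    s0: float = 0.1
    alpha: float = 0.05
    impute_downshift: float = 2.0
    impute_width: float = 0.2
    seed: int = 0
    call_on: str = "probe_sets"  # or "merged": re-call on take-lower tracks
    caller: CallerParams = field(default_factory=CallerParams)


@dataclass
class ChirpResult:
    merged: dict[int, CoverageTrack]
    peaks: dict[tuple[int, str], list]
    pairs: dict[int, list]
    sites: list[ConsensusSite]
    retained: list[ConsensusSite]
    removed: list[tuple[ConsensusSite, list[MatchResult]]]


def run_chirp(
    tracks: dict[tuple[int, str], CoverageTrack],
    genome: GenomeAssembly,
    probes: dict[str, str],
    config: PipelineConfig | None = None,
) -> ChirpResult:
    """Run the consensus chain on even/odd tracks of three replicates.

    ``tracks`` is keyed by (replicate, probe_set) with probe_set in
    {'even', 'odd'}. With ``call_on='probe_sets'`` peaks are called per
    probe-set track and then paired; with ``call_on='merged'`` they are
    called on the take-lower merged track of each replicate, where the
    dual-probe requirement is already implicit.
    """
    config = config or PipelineConfig()
    replicates = sorted({rep for rep, _ in tracks})
    merged = {
        rep: take_lower_merge(tracks[(rep, "even")], tracks[(rep, "odd")])
        for rep in replicates
    }
    peaks: dict[tuple[int, str], list] = {}
    pairs: dict[int, list] = {}
    for rep in replicates:
        if config.call_on == "merged":
            called = call_peaks(merged[rep], config.caller, probe_set="merged", replicate=rep)
            peaks[(rep, "merged")] = called
            pairs[rep] = [(p, p) for p in called]
        else:
            pe = call_peaks(tracks[(rep, "even")], config.caller, probe_set="even", replicate=rep)
            po = call_peaks(tracks[(rep, "odd")], config.caller, probe_set="odd", replicate=rep)
            peaks[(rep, "even")] = pe
            peaks[(rep, "odd")] = po
            pairs[rep] = pair_even_odd(
                pe, po, config.max_summit_distance, sense=config.summit_sense
            )
    sites = replicate_consensus(*(pairs[rep] for rep in replicates))
    background = genome_background(genome)
    matrices = {
        name: build_probe_matrix(
            seq, background, config.probe_pseudo, name=name
        )
        for name, seq in probes.items()
    }
    retained, removed = scan_and_filter(
        sites, genome, matrices, config.probe_p_cutoff
    )
    return ChirpResult(merged, peaks, pairs, sites, retained, removed)


def annotate_result(
    result: ChirpResult,
    genes: list[GeneModel],
    repeats: list[RepeatElement],
):
    return annotate_sites(result.retained, genes, repeats)


def write_manifest(path: str | os.PathLike, config: PipelineConfig, inputs: dict[str, str]) -> None:
    """Record every parameter actually used plus input digests."""
    digests = {}
    for name, p in inputs.items():
        if p and os.path.exists(p):
            with open(p, "rb") as fh:
                digests[name] = hashlib.sha256(fh.read()).hexdigest()[:16]
    payload = {"parameters": _jsonable(asdict(config)), "inputs": digests}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
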