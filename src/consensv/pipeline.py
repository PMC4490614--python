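"""Library-level orchestration of the consensus pipeline.

The CLI subcommands are thin wrappers over these functions; chaining the
subcommands on files is equivalent to calling :func:`run_end_to_end` on
the same inputs in memory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .clustering import cluster_and_merge
from .config import PipelineConfig
from .model import Locus, SVCall
from .simulate import (
    SimConfig,
    TruthSV,
    match_loci_to_truth,
    simulate_callsets,
    simulate_evidence,
    simulate_snvs,
    simulate_truth,
)
from .support import EvidenceRecord, SupportResult, apply_support, score_loci


def merge_callsets(
    callsets: Sequence[Sequence[SVCall]], config: PipelineConfig | None = None
) -> list[Locus]:
    """Standardized calls from any number of call sets -> merged loci."""
    config = config or PipelineConfig()
    calls = [c for cs in callsets for c in cs]
    return cluster_and_merge(
        calls,
        thresholds=config.thresholds,
        bandwidths=config.bandwidths,
        size_min=config.size_min,
        size_max=config.size_max,
    )


def support_loci(
    loci: Sequence[Locus],
    contig_evidence: Sequence[EvidenceRecord],
    read_evidence: Sequence[EvidenceRecord],
    config: PipelineConfig | None = None,
) -> tuple[list[Locus], list[SupportResult]]:
    config = config or PipelineConfig()
    results = score_loci(loci, contig_evidence, read_evidence, config.support)
    return apply_support(loci, results), results


@dataclass
class SimulationBundle:
    """Everything one simulated study produces, in memory."""

    truth: list[TruthSV]
    callsets: dict[str, list[SVCall]]
    loci: list[Locus]
    truth_match: dict[str, str]
    contig_evidence: list[EvidenceRecord]
    read_evidence: list[EvidenceRecord]
    snvs: list
    coverage: dict[str, float]
    scored_loci: list[Locus] = field(default_factory=list)
    support: list[SupportResult] = field(default_factory=list)


def run_simulation(
    sim_config: SimConfig, pipeline_config: PipelineConfig | None = None
) -> SimulationBundle:
    """Simulate truth + call sets, merge them, and derive SNVs/evidence.

    Evidence and SNVs are keyed to the merged locus ids, so re-merging the
    emitted call sets with the same pipeline configuration reproduces the
    ids the evidence refers to.
    """
    pipeline_config = pipeline_config or PipelineConfig()
    truth = simulate_truth(sim_config)
    callsets = simulate_callsets(truth, sim_config)
    loci = merge_callsets(list(callsets.values()), pipeline_config)
    truth_match = match_loci_to_truth(loci, truth)
    contigs, reads = simulate_evidence(loci, truth, sim_config, truth_match)
    deletion_loci = [l for l in loci if l.svtype.value == "DEL"]
    snvs, coverage = simulate_snvs(deletion_loci, truth_match, sim_config)
    bundle = SimulationBundle(
        truth=truth,
        callsets=callsets,
        loci=loci,
        truth_match=truth_match,
        contig_evidence=contigs,
        read_evidence=reads,
        snvs=snvs,
        coverage=coverage,
    )
    scored, support = support_loci(loci, contigs, reads, pipeline_config)
    bundle.scored_loci = scored
    bundle.support = support
    return bundle


def run_end_to_end(
    sim_config: SimConfig, pipeline_config: PipelineConfig | None = None
) -> SimulationBundle:
    """Alias of :func:`run_simulation`: simulate -> merge -> support."""
    return run_simulation(sim_config, pipeline_config)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: PipelineConfig | Mapping | None,
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Record command, effective config, input digests, seed and version.

    Inputs plus this manifest fully determine the run's outputs (the
    timestamp is informational only).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot = (
        config.to_dict() if isinstance(config, PipelineConfig) else dict(config or {})
    )
    manifest = {
        "command": command,
        "config": snapshot,
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
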