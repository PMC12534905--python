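"""Per-cluster representative selection, merge + reassembly, redundancy
removal, and the end-to-end pipeline driver.

Pipeline stages, in order: length filter → purity filter → ANI graph →
components → cliques → orphan assignment → per-cluster selection (with
optional merge+reassembly) → redundancy removal → final completeness
filter. Stage input/output counts are recorded on the result.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from . import quality as Q
from .ani_engine import (
    DEFAULT_K,
    DEFAULT_SCALED,
    build_ani_graph,
    canonical_kmer_codes,
    estimate_ani,
    sketch_bin,
)
from .clustering import BinCluster, cluster_graph
from .errors import EmptySketchError, InputError, ReassemblyError
from .model_io import (
    AniEdge,
    Contig,
    DereplicationResult,
    QualityRecord,
    RetainedBin,
    SequenceBin,
    read_quality_table,
    write_fasta,
)

logger = logging.getLogger(__name__)

MODE_REPRESENTATIVE = "representative"
MODE_MERGED_REASSEMBLED = "merged_reassembled"
MODE_MERGED_REJECTED = "merged_rejected"

# a merged bin's quality provider, (bin) -> (completeness, contamination)
QualityProvider = Callable[[SequenceBin], tuple[float, float]]


@dataclass(frozen=True)
class ClusterDecision:
    """What happened in one cluster and why."""

    cluster_id: str
    mode: str
    chosen_bin: str
    candidate_scores: dict[str, float]
    quality_provider: str = "table"


@dataclass
class PipelineConfig:
    """Knobs for :func:`run_pipeline`; defaults mirror the CLI defaults."""

    ani_cutoff: float = 99.0
    purity_threshold: float = 95.0
    min_completeness: float = 50.0
    min_length: int = 200_000
    k: int = DEFAULT_K
    scaled: int = DEFAULT_SCALED
    min_aligned_fraction: float = 0.0
    no_reassembly: bool = False
    max_exact_component: int = 5_000
    containment_threshold: float = 0.95
    min_contig_length: int = 500
    assembler_cmd: str | None = None
    quality_cmd: str | None = None
    quality_provider: QualityProvider | None = None
    edges: list[AniEdge] | None = None
    threads: int = 1  # accepted for CLI parity; computation is deterministic regardless
    seed: int = 0


def select_representative(
    cluster: BinCluster, qualities: Mapping[str, QualityRecord]
) -> str | None:
    """Highest-scoring member passing the strict high-quality gate, or None."""
    candidates = [
        q for m in cluster.members if Q.is_high_quality(q := Q.require_quality(m, qualities))
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda q: (-q.quality_score, q.bin_id)).bin_id


def merge_bins(cluster: BinCluster, bins: Mapping[str, SequenceBin]) -> list[Contig]:
    """Union of member contigs; ids prefixed by source bin to stay unique."""
    merged: list[Contig] = []
    for member in cluster.members:  # members are sorted
        for contig in bins[member].contigs:
            merged.append(Contig(f"{member}|{contig.id}", contig.sequence))
    return merged


def containment_merge(
    contigs: list[Contig], k: int = DEFAULT_K, threshold: float = 0.95
) -> list[Contig]:
    """Greedy dedup: drop a contig whose canonical k-mer set is >= threshold
    contained in a longer retained contig's set; longest first."""
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    kmer_sets = {c.id: canonical_kmer_codes(c.sequence, k) for c in order}
    retained: list[Contig] = []
    for contig in order:
        mine = kmer_sets[contig.id]
        if mine.size == 0:
            retained.append(contig)
            continue
        contained = False
        for keeper in retained:
            other = kmer_sets[keeper.id]
            if other.size == 0:
                continue
            shared = np.intersect1d(mine, other, assume_unique=True).size
            if shared >= threshold * mine.size:
                contained = True
                break
        if not contained:
            retained.append(contig)
    retained.sort(key=lambda c: c.id)
    return retained


def _run_external_assembler(
    contigs: list[Contig], cmd_template: str, min_contig_length: int
) -> list[Contig]:
    from .model_io import read_fasta

    with tempfile.TemporaryDirectory(prefix="binderep_asm_") as tmp:
        in_path = Path(tmp) / "merged_input.fa"
        out_path = Path(tmp) / "assembled.fa"
        write_fasta(contigs, in_path)
        cmd = cmd_template.format(input=in_path, output=out_path)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise ReassemblyError(f"assembler failed (exit {proc.returncode}): {proc.stderr[-500:]}")
        if not out_path.exists():
            raise ReassemblyError("assembler produced no output file")
        assembled = [c for c in read_fasta(out_path) if len(c.sequence) >= min_contig_length]
        if not assembled:
            raise ReassemblyError("assembler produced no contigs above the minimum length")
        return assembled


def reassemble(
    contigs: list[Contig],
    bin_id: str,
    assembler_cmd: str | None = None,
    k: int = DEFAULT_K,
    containment_threshold: float = 0.95,
    min_contig_length: int = 500,
) -> SequenceBin:
    """Turn a merged contig set into a candidate bin.

    With ``assembler_cmd`` set, the external command template (placeholders
    ``{input}``/``{output}``) is run and its contigs are taken; otherwise
    the built-in containment merge deduplicates near-redundant contigs.
    Raises :class:`ReassemblyError` on external failure.
    """
    if not contigs:
        raise InputError("reassemble requires a non-empty contig set")
    if assembler_cmd:
        new_contigs = _run_external_assembler(contigs, assembler_cmd, min_contig_length)
    else:
        new_contigs = containment_merge(contigs, k=k, threshold=containment_threshold)
    return SequenceBin(bin_id=bin_id, sample_id="merged", contigs=tuple(new_contigs))


def _run_external_quality(seq_bin: SequenceBin, cmd_template: str) -> tuple[float, float]:
    with tempfile.TemporaryDirectory(prefix="binderep_qc_") as tmp:
        in_path = Path(tmp) / f"{seq_bin.bin_id}.fa"
        out_path = Path(tmp) / "quality_report.tsv"
        write_fasta(seq_bin.contigs, in_path)
        cmd = cmd_template.format(input=in_path, output=out_path)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise ReassemblyError(f"quality tool failed (exit {proc.returncode}): {proc.stderr[-500:]}")
        if not out_path.exists():
            raise ReassemblyError("quality tool produced no report")
        table = read_quality_table(out_path)
        if not table:
            raise ReassemblyError("quality tool report is empty")
        record = next(iter(table.values()))
        return record.completeness, record.contamination


def score_merged(
    merged: SequenceBin,
    quality_provider: QualityProvider | None = None,
    quality_cmd: str | None = None,
) -> tuple[QualityRecord, str] | None:
    """Quality of a merged bin via the external tool or the pluggable provider.

    Returns (record, provider name), or None when no provider is configured
    or the external tool fails (caller falls back to the best input bin).
    """
    if quality_cmd:
        try:
            completeness, contamination = _run_external_quality(merged, quality_cmd)
            return QualityRecord(merged.bin_id, completeness, contamination), "external"
        except ReassemblyError as exc:
            logger.warning("external quality tool failed for %s: %s", merged.bin_id, exc)
            return None
    if quality_provider is not None:
        completeness, contamination = quality_provider(merged)
        return QualityRecord(merged.bin_id, completeness, contamination), "internal"
    return None


def choose_best(
    cluster: BinCluster,
    member_qualities: Mapping[str, QualityRecord],
    merged_quality: QualityRecord | None,
) -> tuple[str, str, dict[str, float]]:
    """Argmax of quality score over members (+ the merged candidate).

    The merged candidate loses exact ties to an original bin. Returns
    (chosen bin id, mode, candidate score map).
    """
    scores = {m: member_qualities[m].quality_score for m in cluster.members}
    best_member = min(scores, key=lambda m: (-scores[m], m))
    if merged_quality is None:
        return best_member, MODE_MERGED_REJECTED, scores
    scores = dict(scores)
    scores[merged_quality.bin_id] = merged_quality.quality_score
    if merged_quality.quality_score > scores[best_member]:
        return merged_quality.bin_id, MODE_MERGED_REASSEMBLED, scores
    return best_member, MODE_MERGED_REJECTED, scores


def remove_redundancy(
    candidates: list[RetainedBin],
    cutoff: float,
    k: int = DEFAULT_K,
    scaled: int = DEFAULT_SCALED,
) -> tuple[list[RetainedBin], list[tuple[str, str, float]]]:
    """Greedy redundancy removal by descending ANI.

    Pairwise ANI is recomputed from sequence (merged bins included); while
    any surviving pair is at or above the cutoff the lower-quality member
    of the highest-ANI offending pair is dropped.
    """
    by_id = {c.bin.bin_id: c for c in candidates}
    sketches = {}
    for bin_id in sorted(by_id):
        try:
            sketches[bin_id] = sketch_bin(by_id[bin_id].bin, k=k, scaled=scaled)
        except EmptySketchError as exc:
            logger.warning("redundancy pass: %s", exc)
    ids = sorted(sketches)
    offending: list[tuple[float, str, str]] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            edge = estimate_ani(sketches[ids[i]], sketches[ids[j]])
            if edge.ani >= cutoff:
                offending.append((edge.ani, edge.bin_a, edge.bin_b))
    offending.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = set(by_id)
    dropped: list[tuple[str, str, float]] = []
    for ani, a, b in offending:
        if a not in alive or b not in alive:
            continue
        qa, qb = by_id[a].quality.quality_score, by_id[b].quality.quality_score
        if (qa, b) > (qb, a):  # drop lower score; tie -> drop lexicographically larger id
            loser, winner = b, a
        else:
            loser, winner = a, b
        alive.discard(loser)
        dropped.append((loser, winner, ani))
        logger.info("redundancy: dropped %s (ANI %.3f with %s)", loser, ani, winner)
    retained = [by_id[bin_id] for bin_id in sorted(alive)]
    return retained, dropped


def _decide_cluster(
    cluster: BinCluster,
    bins_by_id: Mapping[str, SequenceBin],
    qualities: Mapping[str, QualityRecord],
    config: PipelineConfig,
) -> tuple[ClusterDecision, RetainedBin]:
    member_qualities = {m: Q.require_quality(m, qualities) for m in cluster.members}

    if config.no_reassembly:
        # best-scoring member regardless of the high-quality gate
        scores = {m: q.quality_score for m, q in member_qualities.items()}
        chosen = min(scores, key=lambda m: (-scores[m], m))
        decision = ClusterDecision(cluster.cluster_id, MODE_REPRESENTATIVE, chosen, scores)
        retained = RetainedBin(
            bins_by_id[chosen], member_qualities[chosen], "input", cluster.cluster_id, cluster.members
        )
        return decision, retained

    representative = select_representative(cluster, qualities)
    if representative is not None:
        scores = {m: q.quality_score for m, q in member_qualities.items()}
        decision = ClusterDecision(cluster.cluster_id, MODE_REPRESENTATIVE, representative, scores)
        retained = RetainedBin(
            bins_by_id[representative],
            member_qualities[representative],
            "input",
            cluster.cluster_id,
            cluster.members,
        )
        return decision, retained

    # no high-quality member: merge + reassemble and compare
    merged_id = f"merged_{cluster.cluster_id}"
    merged_quality: QualityRecord | None = None
    merged_bin: SequenceBin | None = None
    provider_name = "none"
    try:
        merged_bin = reassemble(
            merge_bins(cluster, bins_by_id),
            bin_id=merged_id,
            assembler_cmd=config.assembler_cmd,
            k=config.k,
            containment_threshold=config.containment_threshold,
            min_contig_length=config.min_contig_length,
        )
        scored = score_merged(merged_bin, config.quality_provider, config.quality_cmd)
        if scored is not None:
            merged_quality, provider_name = scored
    except ReassemblyError as exc:
        logger.warning("cluster %s: reassembly failed, falling back: %s", cluster.cluster_id, exc)

    chosen, mode, scores = choose_best(cluster, member_qualities, merged_quality)
    decision = ClusterDecision(cluster.cluster_id, mode, chosen, scores, provider_name)
    if mode == MODE_MERGED_REASSEMBLED:
        assert merged_bin is not None and merged_quality is not None
        retained = RetainedBin(merged_bin, merged_quality, "merged", cluster.cluster_id, cluster.members)
    else:
        retained = RetainedBin(
            bins_by_id[chosen], member_qualities[chosen], "input", cluster.cluster_id, cluster.members
        )
    return decision, retained


def run_pipeline(
    bins: list[SequenceBin],
    qualities: Mapping[str, QualityRecord],
    config: PipelineConfig | None = None,
) -> DereplicationResult:
    """End-to-end dereplication; see module docstring for the stage order."""
    config = config or PipelineConfig()
    counts: dict[str, int] = {"input_bins": len(bins)}

    for b in bins:
        Q.require_quality(b.bin_id, qualities)

    bins = Q.filter_by_length(bins, config.min_length)
    counts["after_length_filter"] = len(bins)
    bins, rejections = Q.filter_by_purity(bins, qualities, config.purity_threshold)
    counts["after_purity_filter"] = len(bins)
    logger.info(
        "filters: %d in, %d after length, %d after purity",
        counts["input_bins"],
        counts["after_length_filter"],
        counts["after_purity_filter"],
    )
    if not bins:
        logger.warning("no bins survived the input filters; emitting an empty result")
        return DereplicationResult(stage_counts=counts)

    graph = build_ani_graph(
        bins,
        edges=config.edges,
        cutoff=config.ani_cutoff,
        min_aligned_fraction=config.min_aligned_fraction,
        k=config.k,
        scaled=config.scaled,
    )
    counts["ani_edges"] = len(graph.edges)
    clusters = cluster_graph(graph, config.max_exact_component)
    counts["clusters"] = len(clusters)
    logger.info("%d ANI edges, %d clusters", len(graph.edges), len(clusters))

    bins_by_id = {b.bin_id: b for b in bins}
    decisions: list[ClusterDecision] = []
    chosen: dict[str, RetainedBin] = {}
    for cluster in clusters:
        decision, retained = _decide_cluster(cluster, bins_by_id, qualities, config)
        decisions.append(decision)
        # a bin chosen by several clusters is kept once (first cluster wins)
        chosen.setdefault(retained.bin.bin_id, retained)
    counts["merged_reassembled"] = sum(1 for d in decisions if d.mode == MODE_MERGED_REASSEMBLED)

    retained, dropped = remove_redundancy(
        list(chosen.values()), config.ani_cutoff, k=config.k, scaled=config.scaled
    )
    counts["after_redundancy_removal"] = len(retained)

    final = [r for r in retained if r.quality.completeness >= config.min_completeness]
    counts["after_completeness_filter"] = len(final)
    logger.info(
        "%d merged, %d after redundancy removal, %d final",
        counts["merged_reassembled"],
        counts["after_redundancy_removal"],
        counts["after_completeness_filter"],
    )
    final.sort(key=lambda r: r.bin.bin_id)
    return DereplicationResult(
        retained=final,
        decisions=decisions,
        dropped_redundant=dropped,
        stage_counts=counts,
    )
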