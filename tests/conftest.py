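from __future__ import annotations

import itertools

import numpy as np
import pytest

from binderep.ani_engine import AniGraph
from binderep.model_io import AniEdge, Contig, QualityRecord, SequenceBin


def build_bin(bin_id: str, *sequences: str, sample_id: str | None = None) -> SequenceBin:
    contigs = tuple(Contig(f"{bin_id}_c{i}", s) for i, s in enumerate(sequences))
    return SequenceBin(bin_id=bin_id, sample_id=sample_id or bin_id, contigs=contigs)


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()


def graph_from_pairs(nodes: set[str], pairs: set[tuple[str, str]], cutoff: float = 99.0) -> AniGraph:
    edges = [AniEdge(a, b, ani=99.5) for a, b in pairs]
    return AniGraph(nodes=set(nodes), edges=edges, cutoff=cutoff)


def random_graph(n: int, p: float, seed: int) -> AniGraph:
    rng = np.random.default_rng(seed)
    nodes = {f"n{i:02d}" for i in range(n)}
    pairs = {
        (a, b)
        for a, b in itertools.combinations(sorted(nodes), 2)
        if rng.random() < p
    }
    return graph_from_pairs(nodes, pairs)


@pytest.fixture
def quality_of():
    def make(bin_id: str, completeness: float, contamination: float) -> QualityRecord:
        return QualityRecord(bin_id, completeness, contamination)

    return make
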