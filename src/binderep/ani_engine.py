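"""Internal ANI estimation via FracMinHash k-mer sketches and the ANI graph.

The estimator is containment-based: for two sketches sharing (k, scaled),
C = |A ∩ B| / min(|A|, |B|) and ANI = 100 · C^(1/k). Containment rather
than Jaccard is used so that very incomplete bins of the same genome still
score high. An external ANI tool can be substituted upstream by feeding
precomputed edges to :func:`build_ani_graph`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptySketchError
from .model_io import AniEdge, SequenceBin

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_SCALED = 200

_HASH_SPACE = 1 << 64

# base encoding: A,C,G,T -> 0..3, anything else -> 4 (treated as N)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to the 2-bit alphabet (4 marks N/ambiguous)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mer codes of a sequence as uint64.

    A k-mer's code is its 2-bit packing; the canonical code is the minimum
    of the forward and reverse-complement packings. Windows containing N
    are skipped. Requires 2k <= 64.
    """
    if not 1 <= k <= 32:
        raise ConfigError(f"k must be in [1, 32], got {k}")
    enc = encode_sequence(seq)
    n = enc.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    e64 = enc.astype(np.uint64)
    comp = ((3 - enc.astype(np.int64)) % 4).astype(np.uint64)  # garbage at N, masked below
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd |= e64[j : j + m] << np.uint64(2 * (k - 1 - j))
        rev |= comp[j : j + m] << np.uint64(2 * j)
    # windows containing any N are invalid
    is_n = np.concatenate(([0], np.cumsum(enc == 4)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    canon = np.minimum(fwd[valid], rev[valid])
    return np.unique(canon)


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer — the fixed 64-bit k-mer hash."""
    x = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


@dataclass(frozen=True)
class KmerSketch:
    """FracMinHash sketch of one bin.

    ``hashes`` holds the retained canonical k-mer hashes (those below
    2^64 / scaled); ``genome_kmer_count`` is the distinct canonical k-mer
    count before subsampling.
    """

    bin_id: str
    k: int
    scaled: int
    hashes: frozenset[int]
    genome_kmer_count: int


def sketch_bin(bin: SequenceBin, k: int = DEFAULT_K, scaled: int = DEFAULT_SCALED) -> KmerSketch:
    """Sketch a bin's canonical k-mers with the FracMinHash retention rule."""
    if scaled < 1:
        raise ConfigError(f"scaled must be >= 1, got {scaled}")
    codes = [canonical_kmer_codes(c.sequence, k) for c in bin.contigs]
    all_codes = np.unique(np.concatenate(codes)) if codes else np.empty(0, dtype=np.uint64)
    if all_codes.size == 0:
        raise EmptySketchError(f"bin {bin.bin_id!r}: no k-mers at k={k} (all contigs too short?)")
    hashes = splitmix64(all_codes)
    if scaled == 1:
        retained = hashes
    else:
        retained = hashes[hashes < np.uint64(_HASH_SPACE // scaled)]
    return KmerSketch(
        bin_id=bin.bin_id,
        k=k,
        scaled=scaled,
        hashes=frozenset(int(h) for h in retained),
        genome_kmer_count=int(all_codes.size),
    )


def estimate_ani(a: KmerSketch, b: KmerSketch) -> AniEdge:
    """Containment ANI between two sketches (symmetric)."""
    if a.k != b.k or a.scaled != b.scaled:
        raise ConfigError(
            f"sketch parameter mismatch: ({a.k},{a.scaled}) vs ({b.k},{b.scaled})"
        )
    if not a.hashes or not b.hashes:
        raise EmptySketchError("cannot estimate ANI from an empty sketch")
    shared = len(a.hashes & b.hashes)
    containment = shared / min(len(a.hashes), len(b.hashes))
    ani = 100.0 * containment ** (1.0 / a.k) if containment > 0 else 0.0
    return AniEdge(a.bin_id, b.bin_id, ani=ani, aligned_fraction=containment)


@dataclass
class AniGraph:
    """Thresholded, undirected, simple ANI graph over bin ids."""

    nodes: set[str]
    edges: list[AniEdge] = field(default_factory=list)
    cutoff: float = 99.0

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.bin_a].add(e.bin_b)
            adj[e.bin_b].add(e.bin_a)
        return adj

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}


def build_ani_graph(
    bins: list[SequenceBin],
    *,
    edges: list[AniEdge] | None = None,
    cutoff: float = 99.0,
    min_aligned_fraction: float = 0.0,
    k: int = DEFAULT_K,
    scaled: int = DEFAULT_SCALED,
) -> AniGraph:
    """Build the thresholded ANI graph over ``bins``.

    With ``edges`` given (external-tool adapter path) they are filtered by
    the cutoff and aligned-fraction gate; otherwise all-vs-all internal
    sketch ANI is computed. Every input bin appears as a node even when
    isolated; bins with no k-mers are excluded with a warning.
    """
    if not 0.0 < cutoff <= 100.0:
        raise ConfigError(f"ANI cutoff must be in (0, 100], got {cutoff}")
    nodes = {b.bin_id for b in bins}
    if edges is not None:
        kept = [
            e
            for e in sorted(edges, key=lambda e: e.pair)
            if e.ani >= cutoff
            and e.aligned_fraction >= min_aligned_fraction
            and e.bin_a in nodes
            and e.bin_b in nodes
        ]
        return AniGraph(nodes=nodes, edges=kept, cutoff=cutoff)

    sketches: list[KmerSketch] = []
    for b in sorted(bins, key=lambda b: b.bin_id):
        try:
            sketches.append(sketch_bin(b, k=k, scaled=scaled))
        except EmptySketchError as exc:
            logger.warning("excluding bin from ANI graph: %s", exc)
            nodes.discard(b.bin_id)
    kept = []
    for i in range(len(sketches)):
        for j in range(i + 1, len(sketches)):
            edge = estimate_ani(sketches[i], sketches[j])
            if edge.ani >= cutoff and edge.aligned_fraction >= min_aligned_fraction:
                kept.append(edge)
    kept.sort(key=lambda e: e.pair)
    return AniGraph(nodes=nodes, edges=kept, cutoff=cutoff)
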