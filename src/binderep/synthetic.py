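"""Fully-labelled synthetic inputs: genomes, strains at controlled ANI,
sample-wise bins with controlled completeness/contamination.

Strains are derived from a species ancestor by point substitutions only, so
the true ANI of any pair of strain genomes is exactly their position-wise
identity — a closed-form oracle for the sketch estimator. All randomness
derives from one master seed through ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .ani_engine import canonical_kmer_codes
from .errors import InputError
from .model_io import Contig, QualityRecord, SequenceBin, write_fasta

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BinTruth:
    """Ground truth for one synthetic bin."""

    bin_id: str
    source_genome: str
    completeness: float  # realized, %
    contamination: float  # realized, % of native length
    contaminant_genome: str | None
    intervals: tuple[tuple[int, int], ...]  # native coverage on the source genome


@dataclass
class SyntheticTruth:
    """Everything the generator knows: genomes, bin provenance, true ANI."""

    genomes: dict[str, str] = field(default_factory=dict)  # genome_id -> sequence
    species_of: dict[str, str] = field(default_factory=dict)  # genome_id -> species_id
    bins: dict[str, BinTruth] = field(default_factory=dict)
    genome_ani: dict[tuple[str, str], float] = field(default_factory=dict)

    def pair_ani(self, genome_a: str, genome_b: str) -> float | None:
        if genome_a == genome_b:
            return 100.0
        key = tuple(sorted((genome_a, genome_b)))
        return self.genome_ani.get(key)


def simulate_genome(length: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """i.i.d. random genome at the stated GC content, deterministic per seed."""
    if length < 10_000:
        raise InputError(f"genome length must be >= 10000, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise InputError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    draws = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return draws.tobytes().decode("ascii")


def mutate_to_ani(genome: str, target_ani: float, seed: int = 0) -> tuple[str, float]:
    """Point-substitute at per-base rate (100 − target_ani)/100.

    Every selected position changes to a uniformly chosen different base, so
    the realized per-base identity (returned alongside the sequence) is
    exact and substitution-count-derived.
    """
    if not 80.0 <= target_ani <= 100.0:
        raise InputError(f"target_ani must be in [80, 100], got {target_ani}")
    rng = np.random.default_rng(seed)
    rate = (100.0 - target_ani) / 100.0
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    if rate > 0.0:
        mask = rng.random(arr.size) < rate
        idx = np.nonzero(mask)[0]
        # map base to 0..3, add 1..3 mod 4: always a different base
        code = np.searchsorted(np.sort(_BASES), arr[idx])
        order = np.argsort(_BASES)  # identity here, but keep it explicit
        new_code = (code + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = _BASES[order[new_code]]
        n_changed = idx.size
    else:
        n_changed = 0
    identity = 100.0 * (arr.size - n_changed) / arr.size
    return arr.tobytes().decode("ascii"), identity


def pairwise_identity(a: str, b: str) -> float:
    """Position-wise percent identity of two equal-length sequences."""
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    if xa.size != xb.size:
        raise InputError("pairwise_identity requires equal-length sequences")
    return 100.0 * float(np.mean(xa == xb))


def _random_fragments(
    length: int, contig_length_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Partition [0, length) into consecutive fragments with random sizes."""
    lo, hi = contig_length_range
    fragments: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        size = int(rng.integers(lo, hi + 1))
        fragments.append((pos, min(pos + size, length)))
        pos += size
    return fragments


def make_bin(
    bin_id: str,
    sample_id: str,
    strain: str,
    source_genome: str,
    completeness: float,
    contamination: float = 0.0,
    contaminant: str | None = None,
    contaminant_genome: str | None = None,
    contig_length_range: tuple[int, int] = (5_000, 50_000),
    seed: int = 0,
) -> tuple[SequenceBin, BinTruth]:
    """Cut a strain into contigs covering ~completeness% of its genome and
    admix ~contamination% (of native length) of foreign contigs.

    Realized values (recomputable from the emitted fragments) go into the
    returned :class:`BinTruth`.
    """
    if not 0.0 < completeness <= 100.0:
        raise InputError(f"completeness must be in (0, 100], got {completeness}")
    if contamination < 0.0:
        raise InputError(f"contamination must be >= 0, got {contamination}")
    if contamination > 0.0 and contaminant is None:
        raise InputError(f"bin {bin_id!r}: contamination requested but no contaminant genome given")
    rng = np.random.default_rng(seed)
    genome_length = len(strain)
    fragments = _random_fragments(genome_length, contig_length_range, rng)
    order = rng.permutation(len(fragments))
    target_native = completeness / 100.0 * genome_length
    chosen: list[tuple[int, int]] = []
    native_total = 0
    for i in order:
        if native_total >= target_native:
            break
        start, end = fragments[i]
        chosen.append((start, end))
        native_total += end - start
    chosen.sort()
    contigs = [
        Contig(f"{bin_id}_n{idx:04d}", strain[start:end]) for idx, (start, end) in enumerate(chosen)
    ]

    foreign_total = 0
    if contamination > 0.0:
        target_foreign = contamination / 100.0 * native_total
        lo, hi = contig_length_range
        idx = 0
        while foreign_total < target_foreign:
            size = int(rng.integers(lo, hi + 1))
            # cap at the remaining budget so realized contamination ~= requested
            size = min(size, len(contaminant), max(int(np.ceil(target_foreign - foreign_total)), 1))
            start = int(rng.integers(0, len(contaminant) - size + 1))
            contigs.append(Contig(f"{bin_id}_x{idx:04d}", contaminant[start : start + size]))
            foreign_total += size
            idx += 1

    truth = BinTruth(
        bin_id=bin_id,
        source_genome=source_genome,
        completeness=100.0 * native_total / genome_length,
        contamination=100.0 * foreign_total / native_total,
        contaminant_genome=contaminant_genome if foreign_total else None,
        intervals=tuple(chosen),
    )
    return SequenceBin(bin_id=bin_id, sample_id=sample_id, contigs=tuple(contigs)), truth


def simulate_dataset(
    n_species: int = 3,
    strains_per_species: int = 2,
    samples: int = 4,
    within_ani: float = 99.5,
    between_ani_max: float = 90.0,
    completeness_range: tuple[float, float] = (92.0, 100.0),
    contamination_range: tuple[float, float] = (0.0, 2.0),
    genome_length: int = 300_000,
    gc_content: float = 0.5,
    contig_length_range: tuple[int, int] = (5_000, 50_000),
    seed: int = 0,
) -> tuple[list[SequenceBin], dict[str, QualityRecord], SyntheticTruth]:
    """Full labelled dataset: one bin per (sample, species).

    ``within_ani`` is the minimum target pairwise ANI between strains of one
    species (each strain diverges from the ancestor by half the distance);
    species ancestors are independent random genomes, so between-species
    identity is far below any sensible cutoff.
    """
    if within_ani <= between_ani_max:
        raise InputError(
            f"within_ani ({within_ani}) must exceed between_ani_max ({between_ani_max})"
        )
    seeds = np.random.SeedSequence(seed).spawn(4)
    genome_seeds = seeds[0].generate_state(n_species)
    strain_seeds = seeds[1].spawn(n_species)
    bin_seeds = seeds[2].spawn(samples * n_species)
    value_rng = np.random.default_rng(seeds[3])

    truth = SyntheticTruth()
    strains_by_species: dict[str, list[str]] = {}
    # divergence from ancestor: half the pairwise target distance
    strain_target = 100.0 - (100.0 - within_ani) / 2.0
    for sp in range(n_species):
        species_id = f"sp{sp}"
        ancestor = simulate_genome(genome_length, gc_content, seed=int(genome_seeds[sp]))
        strain_ids: list[str] = []
        sub_seeds = strain_seeds[sp].generate_state(max(strains_per_species, 1))
        for st in range(max(strains_per_species, 1)):
            genome_id = f"{species_id}_st{st}"
            if strains_per_species <= 1:
                sequence = ancestor
            else:
                sequence, _ = mutate_to_ani(ancestor, strain_target, seed=int(sub_seeds[st]))
            truth.genomes[genome_id] = sequence
            truth.species_of[genome_id] = species_id
            strain_ids.append(genome_id)
        strains_by_species[species_id] = strain_ids

    # realized pairwise identity within each species (exact, substitutions only)
    for species_id, strain_ids in strains_by_species.items():
        for i in range(len(strain_ids)):
            for j in range(i + 1, len(strain_ids)):
                key = tuple(sorted((strain_ids[i], strain_ids[j])))
                truth.genome_ani[key] = pairwise_identity(
                    truth.genomes[strain_ids[i]], truth.genomes[strain_ids[j]]
                )

    bins: list[SequenceBin] = []
    qualities: dict[str, QualityRecord] = {}
    species_ids = sorted(strains_by_species)
    k = 0
    for s in range(samples):
        for sp_idx, species_id in enumerate(species_ids):
            strain_ids = strains_by_species[species_id]
            genome_id = strain_ids[s % len(strain_ids)]
            completeness = float(value_rng.uniform(*completeness_range))
            contamination = float(value_rng.uniform(*contamination_range))
            contaminant_species = species_ids[(sp_idx + 1) % len(species_ids)]
            contaminant_id = strains_by_species[contaminant_species][0]
            bin_id = f"s{s}__{species_id}"
            seq_bin, bin_truth = make_bin(
                bin_id=bin_id,
                sample_id=f"s{s}",
                strain=truth.genomes[genome_id],
                source_genome=genome_id,
                completeness=completeness,
                contamination=contamination,
                contaminant=truth.genomes[contaminant_id] if contamination > 0 else None,
                contaminant_genome=contaminant_id if contamination > 0 else None,
                contig_length_range=contig_length_range,
                seed=int(bin_seeds[k].generate_state(1)[0]),
            )
            k += 1
            bins.append(seq_bin)
            truth.bins[bin_id] = bin_truth
            qualities[bin_id] = QualityRecord(
                bin_id, bin_truth.completeness, bin_truth.contamination
            )
    return bins, qualities, truth


def truth_ani_edges(truth: SyntheticTruth) -> list:
    """Ground-truth ANI edges between bins of the same species.

    Emulates an external aligner: the ANI of two bins is the true genome
    identity of their source strains (100 for the same strain), independent
    of how complete either bin is. Cross-species pairs are omitted (their
    identity is background noise, far below any cutoff).
    """
    from .model_io import AniEdge

    edges = []
    ids = sorted(truth.bins)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ta, tb = truth.bins[ids[i]], truth.bins[ids[j]]
            if truth.species_of[ta.source_genome] != truth.species_of[tb.source_genome]:
                continue
            ani = truth.pair_ani(ta.source_genome, tb.source_genome)
            edges.append(AniEdge(ids[i], ids[j], ani=float(ani)))
    return edges


def truth_quality_provider(
    truth: SyntheticTruth, k: int = 21
) -> Callable[[SequenceBin], tuple[float, float]]:
    """Ground-truth quality for merged bins via k-mer set arithmetic.

    completeness proxy: fraction of the best-matching species' k-mers
    present in the bin; contamination proxy: fraction (of that species'
    k-mer count) of bin k-mers matching any other species.
    """
    species_kmers: dict[str, np.ndarray] = {}
    for species_id in sorted(set(truth.species_of.values())):
        members = [g for g, sp in truth.species_of.items() if sp == species_id]
        sets = [canonical_kmer_codes(truth.genomes[g], k) for g in sorted(members)]
        species_kmers[species_id] = np.unique(np.concatenate(sets))

    def provider(seq_bin: SequenceBin) -> tuple[float, float]:
        parts = [canonical_kmer_codes(c.sequence, k) for c in seq_bin.contigs]
        bin_kmers = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
        overlaps = {
            sp: np.intersect1d(bin_kmers, kmers, assume_unique=True).size
            for sp, kmers in species_kmers.items()
        }
        source = max(sorted(overlaps), key=lambda sp: overlaps[sp])
        source_size = species_kmers[source].size
        completeness = 100.0 * overlaps[source] / source_size
        foreign = sum(n for sp, n in overlaps.items() if sp != source)
        contamination = 100.0 * foreign / source_size
        return min(completeness, 100.0), contamination

    return provider


def write_dataset(
    bins: list[SequenceBin],
    qualities: dict[str, QualityRecord],
    truth: SyntheticTruth,
    directory: Path | str,
) -> None:
    """Write bins as FASTA plus the quality and truth tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for b in bins:
        write_fasta(b.contigs, directory / f"{b.bin_id}.fa")
    with open(directory / "quality_report.tsv", "w") as out:
        out.write("Name\tCompleteness\tContamination\n")
        for bin_id in sorted(qualities):
            q = qualities[bin_id]
            out.write(f"{bin_id}\t{q.completeness!r}\t{q.contamination!r}\n")
    with open(directory / "truth.tsv", "w") as out:
        out.write("bin_id\tsource_genome\tcompleteness\tcontamination\tcontaminant_genome\n")
        for bin_id in sorted(truth.bins):
            t = truth.bins[bin_id]
            out.write(
                f"{bin_id}\t{t.source_genome}\t{t.completeness!r}\t{t.contamination!r}"
                f"\t{t.contaminant_genome or '-'}\n"
            )
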