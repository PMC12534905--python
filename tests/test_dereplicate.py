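from __future__ import annotations

import itertools

import numpy as np
import pytest

from binderep.ani_engine import canonical_kmer_codes, estimate_ani, sketch_bin
from binderep.clustering import BinCluster
from binderep.dereplicate import (
    MODE_MERGED_REASSEMBLED,
    MODE_MERGED_REJECTED,
    MODE_REPRESENTATIVE,
    PipelineConfig,
    choose_best,
    containment_merge,
    merge_bins,
    reassemble,
    remove_redundancy,
    run_pipeline,
    score_merged,
    select_representative,
)
from binderep.model_io import Contig, QualityRecord, RetainedBin, SequenceBin
from binderep.synthetic import (
    SyntheticTruth,
    make_bin,
    simulate_dataset,
    simulate_genome,
    truth_ani_edges,
    truth_quality_provider,
)

from conftest import build_bin, random_dna


def _cluster(*members, cluster_id="c0000.000"):
    return BinCluster(cluster_id=cluster_id, members=tuple(members), component_id="c0000")


def _q(bin_id, comp, cont):
    return QualityRecord(bin_id, comp, cont)


class TestSelectRepresentative:
    def test_max_of_two(self):
        q = {"a": _q("a", 95, 2), "b": _q("b", 98, 1)}
        assert select_representative(_cluster("a", "b"), q) == "b"

    def test_none_when_no_high_quality(self):
        q = {"a": _q("a", 80, 1), "b": _q("b", 89, 0)}
        assert select_representative(_cluster("a", "b"), q) is None

    def test_lexicographic_tie_break(self):
        q = {"x": _q("x", 95, 2), "m": _q("m", 95, 2)}
        assert select_representative(_cluster("x", "m"), q) == "m"


class TestMergeBins:
    def test_counts_and_uniqueness(self):
        bins = {
            "b1": build_bin("b1", "ACGTA", "GGGTT", "TTTTA"),
            "b2": build_bin("b2", "CCCCA", "AAAAC"),
        }
        merged = merge_bins(_cluster("b1", "b2"), bins)
        assert len(merged) == 5
        assert len({c.id for c in merged}) == 5

    def test_singleton_identity(self):
        bins = {"b1": build_bin("b1", "ACGTA")}
        merged = merge_bins(_cluster("b1"), bins)
        assert [c.sequence for c in merged] == ["ACGTA"]

    def test_shared_contig_ids_disambiguated(self):
        bins = {
            "b1": SequenceBin("b1", "s1", (Contig("c1", "ACGTA"),)),
            "b2": SequenceBin("b2", "s2", (Contig("c1", "TTTTT"),)),
        }
        merged = merge_bins(_cluster("b1", "b2"), bins)
        assert {c.id for c in merged} == {"b1|c1", "b2|c1"}


class TestContainmentMerge:
    def test_identical_contigs_collapse(self):
        seq = random_dna(5_000, seed=1)
        contigs = [Contig("a", seq), Contig("b", seq)]
        assert len(containment_merge(contigs)) == 1

    def test_disjoint_contigs_kept(self):
        contigs = [Contig("a", random_dna(5_000, seed=1)), Contig("b", random_dna(5_000, seed=2))]
        assert len(containment_merge(contigs)) == 2

    def test_subcontig_dropped(self):
        seq = random_dna(10_000, seed=3)
        contigs = [Contig("whole", seq), Contig("part", seq[2_000:6_000])]
        kept = containment_merge(contigs)
        assert [c.id for c in kept] == ["whole"]

    def test_complementary_halves_plus_duplicate(self):
        # oracle: merged k-mer set equals exact union; the duplicate adds nothing
        genome = random_dna(40_000, seed=4)
        half1, half2 = genome[:22_000], genome[18_000:]
        contigs = [Contig("h1", half1), Contig("h2", half2), Contig("dup", half1)]
        kept = containment_merge(contigs)
        # "dup" == "h1" by content; at equal length the lexicographically
        # smaller id is processed first and survives
        assert {c.id for c in kept} == {"dup", "h2"}
        union = np.union1d(canonical_kmer_codes(half1, 21), canonical_kmer_codes(half2, 21))
        merged_set = np.unique(
            np.concatenate([canonical_kmer_codes(c.sequence, 21) for c in kept])
        )
        assert np.array_equal(merged_set, np.unique(union))


class TestReassemble:
    def test_internal_backend(self):
        seq = random_dna(5_000, seed=5)
        merged = reassemble([Contig("a", seq), Contig("b", seq)], bin_id="m")
        assert merged.bin_id == "m"
        assert len(merged.contigs) == 1

    def test_external_backend_failure_raises(self):
        from binderep.errors import ReassemblyError

        with pytest.raises(ReassemblyError):
            reassemble([Contig("a", "ACGT" * 100)], bin_id="m", assembler_cmd="false {input} {output}")

    def test_external_backend_via_cp(self):
        seq = random_dna(2_000, seed=6)
        merged = reassemble([Contig("a", seq)], bin_id="m", assembler_cmd="cp {input} {output}")
        assert merged.contigs[0].sequence == seq


class TestScoreMerged:
    def test_ground_truth_provider_full_recovery(self):
        genome = simulate_genome(50_000, seed=7)
        truth = SyntheticTruth(genomes={"g_st0": genome}, species_of={"g_st0": "g"})
        provider = truth_quality_provider(truth)
        merged = build_bin("m", genome)
        scored = score_merged(merged, quality_provider=provider)
        assert scored is not None
        record, name = scored
        assert record.completeness == pytest.approx(100.0, abs=0.01)
        assert record.contamination == 0.0
        assert name == "internal"

    def test_no_provider_returns_none(self):
        assert score_merged(build_bin("m", "ACGT" * 100)) is None

    def test_failing_external_tool_returns_none(self):
        scored = score_merged(build_bin("m", "ACGT" * 100), quality_cmd="false {input} {output}")
        assert scored is None


class TestChooseBest:
    def test_merged_wins(self):
        cluster = _cluster("a", "b")
        q = {"a": _q("a", 40, 0), "b": _q("b", 35, 0)}
        chosen, mode, scores = choose_best(cluster, q, _q("merged_x", 60, 0))
        assert (chosen, mode) == ("merged_x", MODE_MERGED_REASSEMBLED)
        assert scores["merged_x"] == 60

    def test_input_wins(self):
        cluster = _cluster("a", "b")
        q = {"a": _q("a", 60, 0), "b": _q("b", 35, 0)}
        chosen, mode, _ = choose_best(cluster, q, _q("merged_x", 40, 0))
        assert (chosen, mode) == ("a", MODE_MERGED_REJECTED)

    def test_exact_tie_goes_to_input(self):
        cluster = _cluster("a")
        q = {"a": _q("a", 60, 0)}
        chosen, mode, _ = choose_best(cluster, q, _q("merged_x", 60, 0))
        assert (chosen, mode) == ("a", MODE_MERGED_REJECTED)


def _retained(seq_bin, comp, cont):
    return RetainedBin(seq_bin, _q(seq_bin.bin_id, comp, cont), "input", "c0000.000", (seq_bin.bin_id,))


class TestRemoveRedundancy:
    def test_pair_drops_lower_quality(self):
        seq = random_dna(50_000, seed=8)
        a, b = build_bin("a", seq), build_bin("b", seq)
        retained, dropped = remove_redundancy([_retained(a, 80, 0), _retained(b, 70, 0)], 99.0, scaled=20)
        assert [r.bin.bin_id for r in retained] == ["a"]
        assert dropped[0][0] == "b"
        assert dropped[0][1] == "a"

    def test_all_below_cutoff_identity(self):
        a = build_bin("a", random_dna(50_000, seed=9))
        b = build_bin("b", random_dna(50_000, seed=10))
        retained, dropped = remove_redundancy([_retained(a, 80, 0), _retained(b, 70, 0)], 99.0, scaled=20)
        assert len(retained) == 2
        assert dropped == []

    def test_chain_greedy_matches_optimal(self):
        # x and z are disjoint halves of y's genome: x~y and y~z at ANI 100,
        # x~z far below cutoff. Scores 90, 50, 80 -> y dropped once.
        genome = random_dna(120_000, seed=11)
        x = build_bin("x", genome[:60_000])
        z = build_bin("z", genome[60_000:])
        y = build_bin("y", genome)
        candidates = [_retained(x, 90, 0), _retained(y, 50, 0), _retained(z, 80, 0)]
        retained, dropped = remove_redundancy(candidates, 99.0, scaled=20)
        assert [r.bin.bin_id for r in retained] == ["x", "z"]
        assert [d[0] for d in dropped] == ["y"]
        # oracle: exhaustive search over drop orders — {x,z} is the unique
        # maximal surviving set with no pair at/above the cutoff
        sketches = {n: sketch_bin(b, scaled=20) for n, b in (("x", x), ("y", y), ("z", z))}
        ok_sets = []
        for r in range(1, 4):
            for keep in itertools.combinations(sorted(sketches), r):
                if all(
                    estimate_ani(sketches[p], sketches[q]).ani < 99.0
                    for p, q in itertools.combinations(keep, 2)
                ):
                    ok_sets.append(set(keep))
        assert max(map(len, ok_sets)) == 2
        assert {"x", "z"} in ok_sets


class TestRunPipeline:
    def test_single_bin_identity(self):
        seq = random_dna(250_000, seed=12)
        b = build_bin("solo", seq)
        q = {"solo": _q("solo", 95, 1)}
        result = run_pipeline([b], q, PipelineConfig())
        assert [r.bin.bin_id for r in result.retained] == ["solo"]
        assert result.retained[0].bin.contigs == b.contigs
        assert result.decisions[0].mode == MODE_REPRESENTATIVE

    def test_empty_after_filters(self):
        b = build_bin("tiny", "ACGT" * 100)
        q = {"tiny": _q("tiny", 95, 1)}
        result = run_pipeline([b], q, PipelineConfig(min_length=200_000))
        assert result.retained == []
        assert result.stage_counts["after_length_filter"] == 0

    def test_missing_quality_record_is_error(self):
        from binderep.errors import InputError

        with pytest.raises(InputError, match="nameless"):
            run_pipeline([build_bin("nameless", "ACGT")], {}, PipelineConfig())

    def test_three_species_recovery(self):
        bins, qualities, truth = simulate_dataset(seed=3)
        result = run_pipeline(bins, qualities, PipelineConfig())
        assert len(result.retained) == 3
        species = {
            truth.species_of[truth.bins[r.bin.bin_id].source_genome] for r in result.retained
        }
        assert len(species) == 3

    def test_no_reassembly_same_clusters(self):
        bins, qualities, _ = simulate_dataset(seed=4)
        with_merge = run_pipeline(bins, qualities, PipelineConfig())
        without = run_pipeline(bins, qualities, PipelineConfig(no_reassembly=True))
        clusters_a = sorted(d.cluster_id for d in with_merge.decisions)
        clusters_b = sorted(d.cluster_id for d in without.decisions)
        assert clusters_a == clusters_b
        assert all(d.mode != MODE_MERGED_REASSEMBLED for d in without.decisions)

    def test_quality_dominance_invariant(self):
        bins, qualities, _ = simulate_dataset(seed=5)
        result = run_pipeline(bins, qualities, PipelineConfig())
        for decision in result.decisions:
            best_member = max(
                v for k, v in decision.candidate_scores.items() if not k.startswith("merged_")
            )
            if decision.mode == MODE_MERGED_REASSEMBLED:
                assert decision.candidate_scores[decision.chosen_bin] > best_member
            else:
                assert decision.candidate_scores[decision.chosen_bin] >= best_member


class TestMergeScenario:
    """Two complementary 60%-complete bins of one strain."""

    def _setup(self, seed=6):
        genome = simulate_genome(400_000, seed=seed)
        truth = SyntheticTruth(genomes={"sp0_st0": genome}, species_of={"sp0_st0": "sp0"})
        bins, qualities = [], {}
        for i, bin_seed in enumerate((seed + 10, seed + 20)):
            b, t = make_bin(
                f"s{i}__sp0",
                f"s{i}",
                genome,
                "sp0_st0",
                completeness=60.0,
                seed=bin_seed,
            )
            bins.append(b)
            truth.bins[b.bin_id] = t
            qualities[b.bin_id] = _q(b.bin_id, t.completeness, t.contamination)
        return genome, truth, bins, qualities

    def test_union_coverage_exceeds_either(self):
        genome, truth, bins, _ = self._setup()
        covered = np.zeros(len(genome), dtype=bool)
        singles = []
        for b in bins:
            mask = np.zeros(len(genome), dtype=bool)
            for start, end in truth.bins[b.bin_id].intervals:
                mask[start:end] = True
            singles.append(mask.mean())
            covered |= mask
        assert covered.mean() > max(singles)

    def test_pipeline_prefers_merged(self):
        genome, truth, bins, qualities = self._setup()
        config = PipelineConfig(
            edges=truth_ani_edges(truth),
            quality_provider=truth_quality_provider(truth),
        )
        result = run_pipeline(bins, qualities, config)
        assert len(result.retained) == 1
        entry = result.retained[0]
        assert entry.source == "merged"
        assert entry.quality.completeness > max(q.completeness for q in qualities.values())
        assert result.decisions[0].mode == MODE_MERGED_REASSEMBLED

    def test_merge_yield_dominates_no_reassembly(self):
        _, truth, bins, qualities = self._setup()
        base = dict(edges=truth_ani_edges(truth), quality_provider=truth_quality_provider(truth))
        merged = run_pipeline(bins, qualities, PipelineConfig(**base))
        plain = run_pipeline(bins, qualities, PipelineConfig(no_reassembly=True, **base))

        def passing(result):
            return sum(
                1
                for r in result.retained
                if r.quality.completeness >= 50 and r.quality.contamination < 5
            )

        assert passing(merged) >= passing(plain)
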