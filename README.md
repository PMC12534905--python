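# binderep

Cross-sample dereplication of metagenome-assembled bins.

Sample-wise metagenome assembly recovers the same genomes in many samples.
`binderep` removes that redundancy while maximizing quality: it clusters
near-identical bins by average nucleotide identity (ANI), and for each
genome cluster either keeps the best high-quality bin or — when no member
is good enough on its own — merges the members' contigs and deduplicates
them into a higher-coverage candidate bin.

Pipeline stages:

1. **Input filters** — minimum total length (default 200 kb, inclusive) and
   a strict purity gate (default: purity > 95 %, i.e. contamination < 5 %).
2. **ANI graph** — all-vs-all pairwise ANI at a cutoff (default 99 %),
   either from the built-in FracMinHash containment estimator
   (`ANI = 100 · C^(1/k)`, k = 21, scaled = 200) or from a precomputed
   skani-style edge list (`--edges`).
3. **Clustering** — single-linkage connected components (depth-first
   search), then *all* maximal cliques per component (Bron–Kerbosch with
   pivoting; a bin can belong to several clusters), then attachment of
   unclustered bins to cliques containing a neighbor. Every edge is
   guaranteed to have both endpoints co-clustered somewhere.
4. **Per-cluster selection** — the member with the highest quality score
   (`completeness − 5 × contamination`) among those with completeness > 90 %
   and contamination < 5 %; if none qualifies, the cluster is merged and
   reassembled (external assembler command template, or the built-in
   containment merge) and the best of {members, merged candidate} wins
   (ties go to original data). `--no-reassembly` skips merging and keeps the
   best-scoring member unconditionally.
5. **Redundancy removal** — pairwise ANI among the chosen bins is recomputed
   from sequence; the lower-quality member of each offending pair (highest
   ANI first) is dropped until no pair is at/above the cutoff.
6. **Final completeness gate** — keep bins with completeness ≥ `-c`
   (default 50 %).

Quality values are consumed from a CheckM2-style `quality_report.tsv`
(`Name`/`Completeness`/`Contamination`); they are never estimated from
sequence. Merged-bin quality comes from an external tool command template
(`--quality-cmd`) or, in synthetic runs, from the generator's ground truth.

## CLI

```sh
# generate a labelled synthetic dataset (3 species x 4 samples by default)
binderep simulate -o data/ --seed 1

# dereplicate it
binderep dereplicate -b data/ -q data/quality_report.tsv -o out/ \
    --ani 99 -p 95 -c 50

# inspect intermediates
binderep ani -b data/ -o ani.tsv          # all-vs-all internal ANI table
binderep cluster -b data/ -o clusters.tsv # clusters without selection
```

Key `dereplicate` flags: `--ani` (cutoff, default 99), `-p` (purity
threshold, default 95), `-c` (final completeness gate, default 50),
`--min-length`, `--edges` (precomputed skani-dist TSV), `--no-reassembly`,
`--assembler-cmd` / `--quality-cmd` (external command templates with
`{input}`/`{output}` placeholders), `-k`, `--scaled`, `--min-af`,
`--threads` (outputs are byte-identical for any value), `--seed`, and
`--config FILE` (flat `key: value` file; explicit flags win).

Outputs: one FASTA per retained bin, `derep_report.tsv`
(bin_id, source, cluster_id, completeness, contamination, quality_score,
member_bins), `run_summary.txt` (per-stage counts) and `binderep.log`.

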