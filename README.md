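# spaq

Alignment-free phylogeny reconstruction from **spa**ced-word **q**uartet
micro-alignments.

Given four or more genomes in FASTA format, `spaq`:

1. generates a binary match/don't-care pattern (default length 110, weight
   10) with low *overlap complexity* via a seeded hill-climb of random 1↔0
   swaps (the overlap-complexity objective accumulates `2^k` over all nonzero
   shifts, where `k` counts coinciding match positions);
2. enumerates all spaced-word occurrences on both strands and buckets them by
   word in lexicographic order;
3. randomly samples up to `M` gap-free four-taxon micro-alignments
   ("quartet blocks"), keeping only *homologous* blocks — those with an
   anchor row whose three pairwise match scores under a fixed nucleotide
   substitution matrix are all positive — and removing used occurrences so no
   occurrence enters two blocks;
4. selects each block's maximum-likelihood unrooted topology under GTR+Γ
   (Felsenstein pruning, empirical base frequencies, four discrete Γ
   categories, per-block branch-length and shape optimisation), flagging
   blocks whose top two topologies are within a tie tolerance as
   *inconclusive*;
5. amalgamates the conclusive quartet topologies into an unrooted,
   topology-only supertree by recursively bipartitioning the taxon set so as
   to minimise the ratio of good (within-pair) to bad (cross-pair) quartet
   edges cut.

A sequence-evolution simulator (random trees, JC/GTR substitutions, optional
indels) and Robinson–Foulds tree comparison utilities are included, so the
whole pipeline is verifiable end-to-end without external data.

## CLI

```sh
# infer a tree from one FASTA file per taxon
spaq run taxon1.fa taxon2.fa taxon3.fa taxon4.fa -o tree.nwk --report report.tsv

# the main knobs
spaq run *.fa -l 110 -w 10 -M 1000000 --seed 1 --columns all --tie-tol 1e-3

# simulate genomes along a random tree (one FASTA per taxon)
spaq simulate -n 8 -L 100000 --seed 1 --out-dir sim/ --tree-out truth.nwk

# Robinson-Foulds distance between two Newick trees (absolute, normalized)
spaq rf truth.nwk tree.nwk

# print a low-overlap-complexity pattern
spaq pattern -l 110 -w 10 --seed 1
```

`spaq run` writes the Newick topology (no branch lengths) to stdout or
`-o`, a TSV run report (block counts, conclusive/inconclusive tallies, seed,
pattern) with `--report`, and an optional TSV block dump (1-based positions)
with `--dump-blocks`. Runs are deterministic for a fixed `--seed`.

## Python API

```python
from spaq import (RunConfig, run_pipeline, random_tree, evolve,
                  SimulationConfig, rf_distance)

tree = random_tree(8, seed=1)
seqs = evolve(tree, SimulationConfig(n_taxa=8, sequence_length=100_000, seed=1))
inferred, report = run_pipeline(seqs, RunConfig(seed=1, max_blocks=1000))
print(rf_distance(tree, inferred))
```

## Tests and acceptance report

```sh
python -m pytest -q tests/            # full suite incl. acceptance criteria
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(exact constants, brute-force oracles for enumeration/likelihood/RF, seeded
recovery benchmarks). The end-to-end benchmark uses 8 taxa × 100 kb genomes
with a reduced block cap so it fits on one CPU.

## Notes

- Windows overlapping ambiguity codes are skipped entirely; characters
  outside the IUPAC alphabet additionally warn per record.
- Reverse-strand occurrences are stored with coordinates on the
  reverse-complemented record; block positions are provenance metadata only.
- By default exchangeabilities are fixed at 1 within the GTR form (a
  110-column block barely identifies five free rates); pass
  `params_policy="full_gtr"` to `best_topology` to optimise them.
- The supertree stage emits multifurcations when the quartets carry no
  usable signal for a subset instead of resolving it arbitrarily.
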