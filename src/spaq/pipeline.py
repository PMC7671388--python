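"""End-to-end orchestration: FASTA sequences in, Newick supertree out.

Stages: generate a low-overlap-complexity pattern, enumerate spaced-word
occurrences on both strands, sample homologous quartet blocks, pick each
block's maximum-likelihood topology, and amalgamate the conclusive quartets
into a supertree.  A single seed drives every stage, so identical inputs and
seeds give identical trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .patterns import Pattern, generate_pattern
from .pblocks import sample_pblocks
from .quartet_ml import best_topology
from .spaced_words import default_matrix, enumerate_occurrences
from .supertree import build_supertree
from .treeops import PhyloTree

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    pattern_length: int = 110
    weight: int = 10
    max_blocks: int = 1_000_000
    seed: int = 1
    columns: str = "all"  # "all" or "dontcare_only"
    tie_tol: float = 1e-3
    gtr_policy: str = "fixed_exchangeabilities"
    max_probes: int = 50
    pattern_iterations: int = 10_000
    pattern: Pattern | None = None  # overrides generation when given
    restarts: int = 50  # supertree cut restarts


@dataclass
class RunReport:
    pattern: str
    seed: int
    n_taxa: int
    n_occurrences: int
    n_blocks: int
    n_conclusive: int
    n_inconclusive: int
    excluded_taxa: list[str] = field(default_factory=list)
    newick: str = ""

    def as_tsv(self) -> str:
        rows = [
            ("pattern", self.pattern),
            ("seed", self.seed),
            ("n_taxa", self.n_taxa),
            ("n_occurrences", self.n_occurrences),
            ("n_blocks", self.n_blocks),
            ("n_conclusive", self.n_conclusive),
            ("n_inconclusive", self.n_inconclusive),
            ("excluded_taxa", ",".join(self.excluded_taxa)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def run_pipeline(sequences: dict, config: RunConfig | None = None) -> tuple[PhyloTree, RunReport]:
    """Run the whole pipeline on taxon-labelled sequences.

    ``sequences`` maps taxon id to a sequence string (or list of record
    strings / SeqRecords).  Returns the unrooted topology-only supertree and a
    run report with per-stage tallies.
    """
    if config is None:
        config = RunConfig()
    if len(sequences) < 4:
        raise PipelineError(f"need at least 4 taxa, got {len(sequences)}")
    if config.max_blocks <= 0:
        raise PipelineError("max_blocks must be positive: no quartets to amalgamate otherwise")

    ss = np.random.SeedSequence(config.seed)
    rng_pattern, rng_sample, rng_tree = (np.random.default_rng(s) for s in ss.spawn(3))

    pattern = config.pattern or generate_pattern(
        config.pattern_length, config.weight, seed=rng_pattern, iterations=config.pattern_iterations
    )
    logger.info("pattern: %s (seed %d)", pattern, config.seed)

    index = enumerate_occurrences(sequences, pattern, include_reverse=True)
    per_taxon = np.bincount(index.taxon_idx, minlength=index.n_taxa) if len(index) else np.zeros(index.n_taxa)
    excluded = [t for t, c in zip(index.taxa, per_taxon) if c == 0]
    for t in excluded:
        logger.warning("taxon %r has no spaced-word occurrences; excluded", t)
    if index.n_taxa - len(excluded) < 4:
        raise PipelineError("fewer than 4 taxa with occurrences")

    matrix = default_matrix()
    blocks = sample_pblocks(
        index, matrix, max_blocks=config.max_blocks, seed=rng_sample, max_probes=config.max_probes
    )
    logger.info("sampled %d quartet blocks", len(blocks))
    if not blocks:
        raise PipelineError("no homologous quartet blocks found")

    quartets = [
        best_topology(b, params_policy=config.gtr_policy, tie_tol=config.tie_tol, columns=config.columns)
        for b in blocks
    ]
    conclusive = [q for q in quartets if not q.inconclusive]
    logger.info("%d conclusive / %d inconclusive quartets", len(conclusive), len(quartets) - len(conclusive))
    if not conclusive:
        raise PipelineError("all quartet blocks were inconclusive")

    taxa = frozenset(t for t in index.taxa if t not in excluded)
    tree = build_supertree(conclusive, taxa=taxa, seed=rng_tree, restarts=config.restarts)
    from .treeops import write_newick

    report = RunReport(
        pattern=str(pattern),
        seed=config.seed,
        n_taxa=len(taxa),
        n_occurrences=len(index),
        n_blocks=len(blocks),
        n_conclusive=len(conclusive),
        n_inconclusive=len(quartets) - len(conclusive),
        excluded_taxa=excluded,
        newick=write_newick(tree),
    )
    return tree, report
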