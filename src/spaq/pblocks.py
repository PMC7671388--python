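"""Random sampling of homologous quartet blocks from an occurrence index.

A quartet block is a gap-free 4-row micro-alignment formed by four occurrences
of one spaced word in four distinct taxa.  A block is *homologous* if it has
an anchor occurrence whose three pairwise match scores with the other rows are
all positive.  The sampler draws anchors uniformly over all remaining
occurrences, probes same-word occurrences from other taxa at random until
three positively-scoring rows from three further taxa are found, and removes
accepted occurrences so no occurrence enters two blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .patterns import Pattern
from .spaced_words import (
    OccurrenceIndex,
    SpacedWordOccurrence,
    SubstitutionMatrix,
    default_matrix,
)

__all__ = ["PBlock", "sample_pblocks"]

logger = logging.getLogger(__name__)

_STALL_CAP = 100_000


@dataclass(frozen=True)
class PBlock:
    """Four same-word occurrences from four distinct taxa; rows sorted by taxon."""

    occurrences: tuple[SpacedWordOccurrence, ...]
    anchor: int  # index into occurrences of the certified anchor row
    pattern: Pattern

    def __post_init__(self):
        if len(self.occurrences) != 4:
            raise ValueError("a quartet block needs exactly four occurrences")
        taxa = [o.taxon_id for o in self.occurrences]
        if len(set(taxa)) != 4:
            raise ValueError("block occurrences must come from four distinct taxa")
        if len({o.key for o in self.occurrences}) != 1:
            raise ValueError("block occurrences must share one spaced word")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(o.taxon_id for o in self.occurrences)

    @property
    def rows(self) -> tuple[str, ...]:
        """The 4 x length alignment rows, in occurrence (sorted-taxon) order."""
        return tuple(o.window for o in self.occurrences)


def sample_pblocks(
    index: OccurrenceIndex,
    matrix: SubstitutionMatrix | None = None,
    max_blocks: int = 1_000_000,
    seed: int | np.random.Generator | None = 0,
    max_probes: int = 50,
) -> list[PBlock]:
    """Sample up to ``max_blocks`` disjoint homologous quartet blocks.

    Anchors are drawn uniformly over remaining occurrences.  For an anchor,
    other-taxon occurrences of the same word are probed in seeded random order;
    a probe whose score with the anchor is positive is accepted (one row per
    taxon), and the anchor is abandoned after ``max_probes`` failed probes or
    bucket exhaustion.  Sampling stops at the block cap or after as many
    consecutive abandoned anchors as there are remaining occurrences (capped).
    Deterministic for a fixed seed; with the seed fixed, the result for a
    smaller cap is a prefix of the result for a larger one.
    """
    if matrix is None:
        matrix = default_matrix()
    if max_blocks < 0:
        raise ValueError("max_blocks must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if index.n_taxa < 4:
        logger.warning("fewer than 4 taxa in the occurrence index; no blocks can be formed")
        return []
    n = len(index)
    if n == 0 or max_blocks == 0:
        return []

    scores = matrix.scores
    ell = index.pattern.length
    taxon_idx = index.taxon_idx

    # alive-list with swap-remove so uniform anchor draws stay O(1)
    alive = np.arange(n, dtype=np.int64)
    pos_in_alive = np.arange(n, dtype=np.int64)
    removed = np.zeros(n, dtype=bool)

    def remove(i: int) -> None:
        nonlocal n_alive
        p = pos_in_alive[i]
        last = alive[n_alive - 1]
        alive[p] = last
        pos_in_alive[last] = p
        n_alive -= 1
        removed[i] = True

    n_alive = n
    blocks: list[PBlock] = []
    stall = 0
    while len(blocks) < max_blocks and n_alive >= 4:
        if stall >= min(n_alive, _STALL_CAP):
            break
        anchor = int(alive[rng.integers(n_alive)])
        start, stop = index.bucket_slice(anchor)
        members = np.arange(start, stop)
        members = members[~removed[members]]
        a_taxon = int(taxon_idx[anchor])
        cand = members[(taxon_idx[members] != a_taxon)]
        # cheap pretest: the bucket must span four distinct taxa
        if len(np.unique(taxon_idx[cand])) < 3:
            stall += 1
            continue
        rng.shuffle(cand)
        a_win = index.window_codes(anchor)
        accepted: list[int] = []
        accepted_taxa = {a_taxon}
        fails = 0
        for j in cand:
            tj = int(taxon_idx[j])
            if tj in accepted_taxa:
                continue
            s = int(scores[a_win, index.window_codes(int(j))].sum())
            if s > 0:
                accepted.append(int(j))
                accepted_taxa.add(tj)
                if len(accepted) == 3:
                    break
            else:
                fails += 1
                if fails >= max_probes:
                    break
        if len(accepted) == 3:
            rows = [anchor] + accepted
            occs = sorted((index.occurrence(i) for i in rows), key=lambda o: o.taxon_id)
            anchor_occ = index.occurrence(anchor)
            blocks.append(
                PBlock(
                    occurrences=tuple(occs),
                    anchor=occs.index(anchor_occ),
                    pattern=index.pattern,
                )
            )
            for i in rows:
                remove(i)
            stall = 0
        else:
            stall += 1
    return blocks
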