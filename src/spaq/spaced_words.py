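"""Spaced-word occurrence enumeration, indexing and match scoring.

An occurrence of a spaced word is a window of pattern length on one strand of
one input record whose nucleotides at the pattern's match positions spell the
word.  Occurrences are enumerated on both strands (reverse-strand coordinates
live on the reverse-complemented record) and bucketed by word in lexicographic
order.  A pair of occurrences of the same word is scored by summing a 4x4
nucleotide substitution matrix over all aligned columns of the two windows —
match columns contribute diagonal entries by construction, don't-care columns
may pay mismatch penalties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .patterns import Pattern

__all__ = [
    "SubstitutionMatrix",
    "SpacedWordOccurrence",
    "OccurrenceIndex",
    "default_matrix",
    "enumerate_occurrences",
    "score_match",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

# Default scores for aligned nucleotide pairs (rows/cols in ACGT order).
_DEFAULT_SCORES = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int64,
)

# byte -> 2-bit code; 254 marks IUPAC ambiguity codes, 255 anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
for _c in "RYSWKMBDHVNU":
    _CODE[ord(_c)] = 254
    _CODE[ord(_c.lower())] = 254

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip("ACGTacgt", "TGCAtgca"):
    _COMPLEMENT[ord(_a)] = ord(_b)


class SpacedWordError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric nucleotide substitution scores over ACGT."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    def score(self, x: str, y: str) -> int:
        i, j = _CODE[ord(x)], _CODE[ord(y)]
        if i > 3 or j > 3:
            raise SpacedWordError(f"cannot score non-ACGT pair ({x!r}, {y!r})")
        return int(self.scores[i, j])


def default_matrix() -> SubstitutionMatrix:
    """The default nucleotide substitution matrix used for match filtering."""
    return SubstitutionMatrix(_DEFAULT_SCORES.copy())


@dataclass(frozen=True)
class SpacedWordOccurrence:
    """One placement of a spaced word: (taxon, record, strand, 0-based position)."""

    taxon_id: str
    strand: str  # "+" or "-"
    position: int  # window start on the stored strand
    key: str  # nucleotides at match positions
    window: str  # full pattern-length window
    record_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def reverse_complement(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[c] for c in codes)


SequencesLike = Mapping[str, Union[str, Sequence]]


def _records_of(taxon_value) -> list[tuple[str, str]]:
    """Normalize a taxon's value to a list of (record_id, sequence string)."""
    if isinstance(taxon_value, str):
        return [("", taxon_value)]
    records = []
    for k, rec in enumerate(taxon_value):
        if isinstance(rec, str):
            records.append((str(k), rec))
        elif isinstance(rec, tuple) and len(rec) == 2:
            records.append((str(rec[0]), str(rec[1])))
        else:  # Biopython SeqRecord or similar
            records.append((getattr(rec, "id", str(k)), str(getattr(rec, "seq", rec))))
    return records


class OccurrenceIndex:
    """All spaced-word occurrences of one pattern, bucketed by word.

    Columnar storage: parallel arrays of (taxon index, record index, strand,
    position, integer-packed key), stably sorted by key so every bucket is a
    contiguous slice.  The encoded source sequences are kept so windows can be
    materialised and scored on demand.
    """

    def __init__(self, pattern: Pattern, taxa: Sequence[str]):
        self.pattern = pattern
        self.taxa = list(taxa)
        self._seqs: dict[tuple[int, int, int], np.ndarray] = {}
        self._record_ids: dict[tuple[int, int], str] = {}
        self.taxon_idx = np.empty(0, dtype=np.int32)
        self.record_idx = np.empty(0, dtype=np.int32)
        self.strand = np.empty(0, dtype=np.uint8)  # 0 = "+", 1 = "-"
        self.position = np.empty(0, dtype=np.int64)
        self.key = np.empty(0, dtype=np.uint64)
        self.bucket_starts = np.empty(0, dtype=np.int64)
        self.bucket_keys = np.empty(0, dtype=np.uint64)

    def __len__(self) -> int:
        return len(self.key)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def _finalize(self, cols):
        taxon_idx, record_idx, strand, position, key = cols
        order = np.argsort(key, kind="stable")
        self.taxon_idx = taxon_idx[order]
        self.record_idx = record_idx[order]
        self.strand = strand[order]
        self.position = position[order]
        self.key = key[order]
        if len(self.key):
            self.bucket_keys, self.bucket_starts = np.unique(self.key, return_index=True)

    def bucket_slice(self, i: int) -> tuple[int, int]:
        """Contiguous [start, stop) range of the bucket containing occurrence i."""
        b = np.searchsorted(self.bucket_starts, i, side="right") - 1
        start = int(self.bucket_starts[b])
        stop = int(self.bucket_starts[b + 1]) if b + 1 < len(self.bucket_starts) else len(self.key)
        return start, stop

    def window_codes(self, i: int) -> np.ndarray:
        seq = self._seqs[(int(self.taxon_idx[i]), int(self.record_idx[i]), int(self.strand[i]))]
        p = int(self.position[i])
        return seq[p : p + self.pattern.length]

    def key_string(self, i: int) -> str:
        return _decode(self.window_codes(i)[self.pattern.match_positions])

    def occurrence(self, i: int) -> SpacedWordOccurrence:
        w = self.window_codes(i)
        return SpacedWordOccurrence(
            taxon_id=self.taxa[int(self.taxon_idx[i])],
            strand="+" if self.strand[i] == 0 else "-",
            position=int(self.position[i]),
            key=_decode(w[self.pattern.match_positions]),
            window=_decode(w),
            record_id=self._record_ids.get((int(self.taxon_idx[i]), int(self.record_idx[i])), ""),
        )

    def buckets(self):
        """Iterate (key string, list of occurrence row indices) in lexicographic order."""
        n = len(self.key)
        for b, start in enumerate(self.bucket_starts):
            stop = self.bucket_starts[b + 1] if b + 1 < len(self.bucket_starts) else n
            yield self.key_string(int(start)), list(range(int(start), int(stop)))


def enumerate_occurrences(
    sequences: SequencesLike,
    pattern: Pattern,
    include_reverse: bool = True,
) -> OccurrenceIndex:
    """Enumerate every valid spaced-word occurrence on the requested strands.

    A window is valid iff all of its pattern-length nucleotides are plain
    A/C/G/T; windows overlapping ambiguity codes are skipped, and characters
    outside the IUPAC alphabet additionally trigger a per-record warning.
    Packed keys require pattern weight <= 32.
    """
    ell = pattern.length
    w = pattern.weight
    if w > 32:
        raise SpacedWordError("pattern weight > 32 not supported by the packed index")
    match_pos = pattern.match_positions

    index = OccurrenceIndex(pattern, list(sequences.keys()))
    parts: list[tuple[np.ndarray, ...]] = []
    for t, (taxon, value) in enumerate(sequences.items()):
        for r, (rec_id, seq) in enumerate(_records_of(value)):
            index._record_ids[(t, r)] = rec_id
            strands = [(0, seq)]
            if include_reverse:
                strands.append((1, reverse_complement(seq)))
            warned = False
            for s, text in strands:
                codes = _encode(text)
                index._seqs[(t, r, s)] = codes
                if s == 0 and np.any(codes == 255) and not warned:
                    logger.warning(
                        "taxon %r record %r contains non-IUPAC characters; "
                        "overlapping windows skipped",
                        taxon,
                        rec_id,
                    )
                    warned = True
                n_win = len(codes) - ell + 1
                if n_win <= 0:
                    continue
                bad = (codes > 3).astype(np.int64)
                cs = np.concatenate([[0], np.cumsum(bad)])
                valid = (cs[ell:] - cs[:-ell]) == 0
                pos = np.flatnonzero(valid).astype(np.int64)
                if len(pos) == 0:
                    continue
                key = np.zeros(len(pos), dtype=np.uint64)
                for mp in match_pos:
                    key = (key << np.uint64(2)) | codes[pos + mp].astype(np.uint64)
                parts.append(
                    (
                        np.full(len(pos), t, dtype=np.int32),
                        np.full(len(pos), r, dtype=np.int32),
                        np.full(len(pos), s, dtype=np.uint8),
                        pos,
                        key,
                    )
                )
    if parts:
        cols = tuple(np.concatenate([p[i] for p in parts]) for i in range(5))
        index._finalize(cols)
    return index


def score_match(
    a: SpacedWordOccurrence,
    b: SpacedWordOccurrence,
    m: SubstitutionMatrix | None = None,
) -> int:
    """Score a spaced-word match: sum of matrix entries over all aligned columns."""
    if a.key != b.key:
        raise SpacedWordError(f"occurrences are not of the same spaced word: {a.key} != {b.key}")
    if len(a.window) != len(b.window):
        raise SpacedWordError("window length mismatch")
    if m is None:
        m = default_matrix()
    ca, cb = _encode(a.window), _encode(b.window)
    if ca.max() > 3 or cb.max() > 3:
        raise SpacedWordError("windows must contain only A,C,G,T")
    return int(m.scores[ca, cb].sum())
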