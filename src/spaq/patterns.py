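"""Binary spaced-seed patterns: match / don't-care masks and their optimisation.

A pattern is a fixed-length string of 1s (match positions) and 0s (don't-care
positions).  Pattern quality is measured by *overlap complexity* (OC): for
every nonzero relative shift of a pattern against another (or against itself)
count the coinciding 1s, and accumulate ``2 ** coincidences``.  Lower OC
correlates with better seed sensitivity.  ``generate_pattern`` performs a
seeded hill-climb (random 1<->0 swaps, accepted iff the self-OC does not
increase) starting from a random pattern of the requested length and weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "Pattern",
    "PatternError",
    "weight_of",
    "overlap_complexity",
    "generate_pattern",
]


class PatternError(ValueError):
    """Raised for malformed masks or impossible length/weight requests."""


MaskLike = Union[str, Iterable[int], "Pattern"]


def _mask_to_tuple(mask: MaskLike) -> tuple[int, ...]:
    if isinstance(mask, Pattern):
        return mask.mask
    if isinstance(mask, str):
        symbols = list(mask)
    else:
        symbols = list(mask)
    out = []
    for s in symbols:
        if s in (0, 1):
            out.append(int(s))
        elif s in ("0", "1"):
            out.append(int(s))
        else:
            raise PatternError(f"non-binary symbol in pattern mask: {s!r}")
    if not out:
        raise PatternError("empty pattern mask")
    return tuple(out)


@dataclass(frozen=True)
class Pattern:
    """A binary match/don't-care mask in canonical form (first symbol is 1)."""

    mask: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "mask", _mask_to_tuple(self.mask))
        if self.mask[0] != 1:
            raise PatternError("canonical patterns must start with a match position (1)")

    @classmethod
    def from_string(cls, text: str) -> "Pattern":
        return cls(_mask_to_tuple(text.strip()))

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        return sum(self.mask)

    @property
    def match_positions(self) -> np.ndarray:
        """0-based offsets of the match positions."""
        return np.flatnonzero(np.asarray(self.mask))

    @property
    def dontcare_positions(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask) == 0)

    def __str__(self) -> str:
        return "".join(map(str, self.mask))

    def __len__(self) -> int:
        return len(self.mask)


def weight_of(mask: MaskLike) -> int:
    """Number of match (1) positions in *mask*."""
    return sum(_mask_to_tuple(mask))


def _shift_overlaps(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # full cross-correlation: entry s gives the number of coinciding 1s when
    # b is shifted by (s - (len(b)-1)) relative to a
    return np.correlate(a, b, mode="full")


def overlap_complexity(p: MaskLike, q: MaskLike) -> int:
    """Overlap complexity between two patterns.

    Sum of ``2**sigma(s)`` over all nonzero relative shifts *s*, where
    ``sigma(s)`` is the number of aligned (1, 1) pairs at shift *s*.  For a
    pattern against itself only one shift direction is counted (the two
    directions are mirror images); for distinct patterns both directions
    contribute.  Exact integer arithmetic, so arbitrary weights are safe.
    """
    pm, qm = _mask_to_tuple(p), _mask_to_tuple(q)
    a = np.asarray(pm, dtype=np.int64)
    b = np.asarray(qm, dtype=np.int64)
    corr = _shift_overlaps(a, b)
    centre = len(qm) - 1  # index of shift 0
    if pm == qm:
        sigmas = corr[centre + 1 :]
    else:
        sigmas = np.concatenate([corr[:centre], corr[centre + 1 :]])
    return int(sum(1 << int(s) for s in sigmas))


def _self_oc(mask: np.ndarray) -> int:
    corr = np.correlate(mask, mask, mode="full")
    centre = len(mask) - 1
    return int(sum(1 << int(s) for s in corr[centre + 1 :]))


def generate_pattern(
    length: int,
    weight: int,
    seed: int | np.random.Generator | None = 0,
    iterations: int = 10_000,
) -> Pattern:
    """Hill-climb a pattern of the given length and weight towards low self-OC.

    Position 1 is pinned to a match position (canonical form).  Each step
    proposes swapping a random 1 with a random 0; the swap is kept iff the
    self-OC does not increase.  Deterministic for a fixed seed.
    """
    if length < 1 or weight < 1 or weight > length:
        raise PatternError(f"invalid pattern parameters: length={length}, weight={weight}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mask = np.zeros(length, dtype=np.int64)
    mask[0] = 1
    if weight > 1:
        extra = rng.choice(np.arange(1, length), size=weight - 1, replace=False)
        mask[extra] = 1

    if weight == length or weight == 1 or length == 1:
        return Pattern(tuple(int(x) for x in mask))

    oc = _self_oc(mask)
    ones = np.flatnonzero(mask)[1:]  # position 0 never moves
    zeros = np.flatnonzero(mask == 0)
    for _ in range(iterations):
        i = ones[rng.integers(len(ones))]
        j = zeros[rng.integers(len(zeros))]
        mask[i], mask[j] = 0, 1
        new_oc = _self_oc(mask)
        if new_oc <= oc:
            oc = new_oc
            ones = np.flatnonzero(mask)[1:]
            zeros = np.flatnonzero(mask == 0)
        else:
            mask[i], mask[j] = 1, 0
    return Pattern(tuple(int(x) for x in mask))
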