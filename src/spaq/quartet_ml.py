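"""Maximum-likelihood quartet topology selection under GTR(+Gamma).

For a 4-row gap-free block there are three unrooted topologies.  Each is
scored by Felsenstein pruning over the block's site-pattern counts with a
general time-reversible rate matrix and a discrete-Gamma mixture of site
rates; branch lengths (and the Gamma shape) are optimised per topology by
cyclic bounded scalar maximisation.  The block is *inconclusive* when the two
best topologies' log-likelihoods differ by no more than a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaincc
from scipy.stats import gamma as gamma_dist

from .pblocks import PBlock
from .spaced_words import _encode

__all__ = [
    "GTRParams",
    "SitePatternCounts",
    "QuartetResult",
    "site_pattern_counts",
    "quartet_loglik",
    "best_topology",
    "discrete_gamma_rates",
]

logger = logging.getLogger(__name__)

# the three unrooted splits on rows (0,1,2,3): (pair, pair)
SPLITS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

_BL_BOUNDS = (1e-8, 10.0)
_ALPHA_BOUNDS = (0.02, 100.0)
_STARTS = (0.05, 0.5)
_CONV_TOL = 1e-6
_MAX_CYCLES = 30


@dataclass(frozen=True)
class GTRParams:
    """General time-reversible model parameters with discrete-Gamma rates.

    Exchangeabilities are in (AC, AG, AT, CG, CT, GT) order with GT pinned to
    1 for identifiability; the rate matrix is normalised to one expected
    substitution per unit branch length.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0) or not np.all(np.isfinite(ex)):
            raise ValueError("need six positive, finite exchangeabilities")
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("base frequencies must be four nonnegative values summing to 1")
        if not (np.isfinite(self.gamma_shape) and self.gamma_shape > 0):
            raise ValueError("gamma shape must be positive and finite")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")
        object.__setattr__(self, "exchangeabilities", tuple(ex))
        object.__setattr__(self, "base_freqs", tuple(pi))

    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix Q (rows sum to 0, mean rate 1)."""
        return _gtr_q(np.asarray(self.exchangeabilities), np.asarray(self.base_freqs))


def _gtr_q(ex: np.ndarray, pi: np.ndarray) -> np.ndarray:
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(ex, pairs):
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(pi, np.diag(q))
    if mu > 0:
        q /= mu
    return q


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete-Gamma categories (mean 1)."""
    return _gamma_rates_cached(float(alpha), int(n_categories)).copy()


@lru_cache(maxsize=4096)
def _gamma_rates_cached(alpha: float, n_categories: int) -> np.ndarray:
    if n_categories == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_categories) / n_categories, a=alpha, scale=1.0 / alpha)
    # category mean via the upper incomplete gamma at shape alpha+1
    upper = gammaincc(alpha + 1.0, np.concatenate([[0.0], edges * alpha, [np.inf]]))
    rates = (upper[:-1] - upper[1:]) * n_categories
    return np.clip(rates, 1e-12, None)


@dataclass(frozen=True)
class SitePatternCounts:
    """Aggregated column patterns of a 4-row block (rows sorted by taxon id)."""

    taxa: tuple[str, str, str, str]
    patterns: np.ndarray  # (n_patterns, 4) int codes
    counts: np.ndarray  # (n_patterns,)

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def empirical_freqs(self, floor: float = 1e-6) -> np.ndarray:
        tot = np.zeros(4)
        for b in range(4):
            tot[b] = ((self.patterns == b) * self.counts[:, None]).sum()
        tot = np.maximum(tot / tot.sum(), floor)
        return tot / tot.sum()


def site_pattern_counts(
    block: PBlock | Sequence[str],
    columns: str = "all",
    taxa: Sequence[str] | None = None,
) -> SitePatternCounts:
    """Collapse a block's columns into counted site patterns.

    ``columns="dontcare_only"`` keeps only the pattern's 0-positions (match
    columns are constant by construction).  Rows are ordered by sorted taxon
    id.  Raw 4-row alignments are accepted in place of a block, in which case
    ``columns`` must be ``"all"`` unless a pattern is available.
    """
    if isinstance(block, PBlock):
        row_taxa = list(block.taxa)
        rows = list(block.rows)
        pat = block.pattern
    else:
        rows = [str(r) for r in block]
        row_taxa = list(taxa) if taxa is not None else [f"t{i}" for i in range(len(rows))]
        pat = None
    if len(rows) != 4:
        raise ValueError("site patterns are defined for exactly four rows")
    order = np.argsort(row_taxa, kind="stable")
    row_taxa = [row_taxa[i] for i in order]
    rows = [rows[i] for i in order]

    mat = np.stack([_encode(r) for r in rows])  # (4, L)
    if mat.max() > 3:
        raise ValueError("block rows must contain only A,C,G,T")
    if columns == "dontcare_only":
        if pat is None:
            raise ValueError("dontcare_only needs the block's pattern")
        mat = mat[:, pat.dontcare_positions]
    elif columns != "all":
        raise ValueError(f"unknown column mode {columns!r}")

    packed = (
        mat[0].astype(np.int64) * 64 + mat[1] * 16 + mat[2] * 4 + mat[3]
    )
    uniq, counts = np.unique(packed, return_counts=True)
    patterns = np.stack([(uniq // 64) % 4, (uniq // 16) % 4, (uniq // 4) % 4, uniq % 4], axis=1)
    return SitePatternCounts(
        taxa=tuple(row_taxa), patterns=patterns.astype(np.int64), counts=counts.astype(np.int64)
    )


@dataclass(frozen=True)
class QuartetResult:
    """Per-block outcome: the three topology log-likelihoods and the winner."""

    taxa: tuple[str, str, str, str]
    logliks: tuple[float, float, float]  # in SPLITS order over sorted taxa
    best_split: tuple[tuple[str, str], tuple[str, str]] | None
    inconclusive: bool

    def split_labels(self) -> tuple:
        return tuple(
            (tuple(self.taxa[i] for i in a), tuple(self.taxa[i] for i in b)) for a, b in SPLITS
        )


class _PrunedQuartet:
    """Pruning-algorithm likelihood for one 4-leaf tree family.

    The reversible Q is eigendecomposed once (via the pi-symmetrised form, so
    the spectrum is real); every likelihood evaluation is then a handful of
    4x4 products vectorised over site patterns and rate categories.
    """

    def __init__(self, counts: SitePatternCounts, params: GTRParams):
        self.counts = counts
        self.params = params
        self.pi = np.asarray(params.base_freqs)
        q = params.rate_matrix()
        sqrt_pi = np.sqrt(self.pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]  # D^{1/2} Q D^{-1/2}
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self.lam = lam
        self.right = u / sqrt_pi[:, None] * 1.0  # D^{-1/2} U
        self.left = (u * sqrt_pi[:, None]).T  # U^T D^{1/2}
        pats = counts.patterns
        self._idx = [
            (pats[:, a], pats[:, b], pats[:, c], pats[:, d]) for (a, b), (c, d) in SPLITS
        ]
        self._cnt = counts.counts.astype(float)

    def _tp(self, t: np.ndarray) -> np.ndarray:
        """Transition matrices for an array of scaled branch lengths."""
        e = np.exp(np.multiply.outer(t, self.lam))  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", self.right, e, self.left)
        return np.clip(p, 1e-300, None)

    def _loglik_fast(self, split_idx: int, bl: np.ndarray, alpha: float) -> float:
        ncat = self.params.n_categories
        rates = _gamma_rates_cached(alpha, ncat)
        tp = self._tp(np.multiply.outer(rates, bl))  # (ncat, 5, 4, 4)
        ia, ib, ic, id_ = self._idx[split_idx]
        pa, pb, pc, pd, p5 = tp[:, 0], tp[:, 1], tp[:, 2], tp[:, 3], tp[:, 4]
        fa = pa[:, :, ia] * pb[:, :, ib]  # (ncat, 4, npat)
        fb = pc[:, :, ic] * pd[:, :, id_]
        inner = p5 @ fb  # (ncat, 4, npat)
        site = np.einsum("x,cxp,cxp->p", self.pi, fa, inner)
        return float(self._cnt @ np.log(site / ncat))

    def loglik(self, split_idx: int, branch_lengths: Sequence[float], alpha: float | None = None) -> float:
        """Log-likelihood of one split with the five given branch lengths.

        ``branch_lengths`` order: the four leaf branches in row order
        (0, 1, 2, 3) followed by the internal branch.
        """
        bl = np.asarray(branch_lengths, dtype=float)
        if bl.shape != (5,) or np.any(bl < 0) or not np.all(np.isfinite(bl)):
            raise ValueError("need five finite nonnegative branch lengths")
        shape = self.params.gamma_shape if alpha is None else alpha
        if not (np.isfinite(shape) and shape > 0):
            raise ValueError("gamma shape must be positive and finite")
        return self._loglik_fast(split_idx, bl, float(shape))


def quartet_loglik(
    counts: SitePatternCounts,
    split: int | tuple,
    branch_lengths: Sequence[float],
    params: GTRParams,
) -> float:
    """Exact pruning log-likelihood for one quartet split.

    ``split`` is an index into the three canonical splits, or a pair of pairs
    of row indices / taxon ids.
    """
    idx = _resolve_split(split, counts.taxa)
    return _PrunedQuartet(counts, params).loglik(idx, branch_lengths)


def _resolve_split(split, taxa) -> int:
    if isinstance(split, (int, np.integer)):
        if not 0 <= int(split) <= 2:
            raise ValueError("split index must be 0, 1 or 2")
        return int(split)
    (a, b), (c, d) = split
    if isinstance(a, str):
        lookup = {t: i for i, t in enumerate(taxa)}
        a, b, c, d = lookup[a], lookup[b], lookup[c], lookup[d]
    want = frozenset((frozenset((a, b)), frozenset((c, d))))
    for i, ((x, y), (z, v)) in enumerate(SPLITS):
        if frozenset((frozenset((x, y)), frozenset((z, v)))) == want:
            return i
    raise ValueError(f"not a valid quartet split: {split!r}")


def _optimize_split(
    pq: _PrunedQuartet,
    split_idx: int,
    start: float,
    optimize_alpha: bool,
    optimize_exchangeabilities: bool,
) -> tuple[float, bool]:
    """Cyclic coordinate ascent over branch lengths (+alpha, +exchangeabilities)."""
    bl = np.full(5, start)
    alpha = pq.params.gamma_shape
    ex = np.asarray(pq.params.exchangeabilities)

    def rebuild() -> _PrunedQuartet:
        return _PrunedQuartet(
            pq.counts,
            GTRParams(
                exchangeabilities=tuple(ex),
                base_freqs=pq.params.base_freqs,
                gamma_shape=alpha,
                n_categories=pq.params.n_categories,
            ),
        )

    cur_pq = pq
    best = cur_pq._loglik_fast(split_idx, bl, alpha)
    for _ in range(_MAX_CYCLES):
        prev = best
        for k in range(5):
            def f(x, k=k):
                trial = bl.copy()
                trial[k] = x
                return -cur_pq._loglik_fast(split_idx, trial, alpha)

            res = minimize_scalar(f, bounds=_BL_BOUNDS, method="bounded", options={"xatol": 1e-6})
            if -res.fun > best:
                best = -res.fun
                bl[k] = res.x
        if optimize_alpha:
            def g(x):
                return -cur_pq._loglik_fast(split_idx, bl, float(np.exp(x)))

            res = minimize_scalar(
                g,
                bounds=(np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1])),
                method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > best:
                best = -res.fun
                alpha = float(np.exp(res.x))
        if optimize_exchangeabilities:
            for e in range(5):  # GT stays pinned at 1
                def h(x, e=e):
                    trial = ex.copy()
                    trial[e] = np.exp(x)
                    return -_PrunedQuartet(
                        pq.counts,
                        GTRParams(tuple(trial), pq.params.base_freqs, alpha, pq.params.n_categories),
                    ).loglik(split_idx, bl)

                res = minimize_scalar(
                    h, bounds=(np.log(1e-3), np.log(1e3)), method="bounded", options={"xatol": 1e-3}
                )
                if -res.fun > best:
                    best = -res.fun
                    ex[e] = np.exp(res.x)
                    cur_pq = rebuild()
        if best - prev < _CONV_TOL:
            return best, True
    return best, False


def best_topology(
    block: PBlock | SitePatternCounts,
    params_policy: str = "fixed_exchangeabilities",
    tie_tol: float = 1e-3,
    columns: str = "all",
    n_categories: int = 4,
    optimize_alpha: bool = True,
) -> QuartetResult:
    """Select the maximum-likelihood topology for one quartet block.

    ``params_policy`` is ``"fixed_exchangeabilities"`` (all exchangeabilities
    pinned to 1; the default — short blocks barely identify five free rates)
    or ``"full_gtr"`` (five free exchangeabilities optimised as well).  Base
    frequencies are always empirical from the used columns.  The result is
    inconclusive when the top two log-likelihoods differ by at most
    ``tie_tol``.
    """
    if params_policy not in ("fixed_exchangeabilities", "full_gtr"):
        raise ValueError(f"unknown params_policy {params_policy!r}")
    counts = block if isinstance(block, SitePatternCounts) else site_pattern_counts(block, columns)
    params = GTRParams(
        base_freqs=tuple(counts.empirical_freqs()),
        gamma_shape=1.0,
        n_categories=n_categories,
    )
    pq = _PrunedQuartet(counts, params)

    logliks = []
    failed = False
    for split_idx in range(3):
        ll, converged = _optimize_split(
            pq, split_idx, _STARTS[0], optimize_alpha, params_policy == "full_gtr"
        )
        if not converged:
            ll2, converged = _optimize_split(
                pq, split_idx, _STARTS[1], optimize_alpha, params_policy == "full_gtr"
            )
            ll = max(ll, ll2)
            if not converged:
                failed = True
        logliks.append(ll)
    order = np.argsort(logliks)[::-1]
    gap = logliks[order[0]] - logliks[order[1]]
    inconclusive = failed or gap <= tie_tol
    if failed:
        logger.warning("quartet optimiser did not converge for taxa %s", counts.taxa)
    best_split = None
    if not inconclusive:
        (a, b), (c, d) = SPLITS[int(order[0])]
        t = counts.taxa
        best_split = (tuple(sorted((t[a], t[b]))), tuple(sorted((t[c], t[d]))))
        best_split = tuple(sorted(best_split))
    return QuartetResult(
        taxa=counts.taxa,
        logliks=tuple(float(x) for x in logliks),
        best_split=best_split,
        inconclusive=inconclusive,
    )
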