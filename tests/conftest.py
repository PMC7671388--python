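import itertools

import numpy as np
import pytest

from spaq.patterns import Pattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pattern():
    return Pattern("1101001")


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(seq, n_changes, rng):
    """Return seq with exactly n_changes substituted positions."""
    s = list(seq)
    idx = rng.choice(len(s), size=n_changes, replace=False)
    for i in idx:
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    return "".join(s)


def brute_force_quartets(tree):
    """All quartet topologies induced by a tree, via 4-point condition on
    path lengths with unit branch lengths (independent of the supertree code)."""
    t = tree.dendropy_tree.clone(depth=1)
    for e in t.edges():
        e.length = 1.0
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace if x is not None}
    labels = sorted(taxa)

    def dist(a, b):
        return pdm.distance(taxa[a], taxa[b])

    out = []
    for a, b, c, d in itertools.combinations(labels, 4):
        s1 = dist(a, b) + dist(c, d)
        s2 = dist(a, c) + dist(b, d)
        s3 = dist(a, d) + dist(b, c)
        m = min(s1, s2, s3)
        if s1 == m and s2 > m and s3 > m:
            out.append(((a, b), (c, d)))
        elif s2 == m and s1 > m and s3 > m:
            out.append(((a, c), (b, d)))
        elif s3 == m and s1 > m and s2 > m:
            out.append(((a, d), (b, c)))
    return out
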