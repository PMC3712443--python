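"""Shared fixtures and independent oracles for the test suite.

The oracle functions deliberately re-derive results through a different route
than the package (brute-force enumeration, closed forms, direct loops) so
that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from floralsignals.bee_vision import HexagonVisionModel


@pytest.fixture(scope="session")
def vision_model():
    """Default-configuration hexagon vision model, fitted once."""
    return HexagonVisionModel().fit()


# ---------------------------------------------------------------------------
# parsimony oracles (exhaustive enumeration over internal labelings)

def _tree_edges_and_tips(tree):
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf()]
    tips = {i: n.taxon.label for i, n in enumerate(nodes) if n.is_leaf()}
    edges = [
        (index[id(n.parent_node)], index[id(n)]) for n in nodes if n.parent_node is not None
    ]
    root = index[id(tree.seed_node)]
    return nodes, internal, tips, edges, root


def brute_force_parsimony(tree, char):
    """Exhaustive minimum change count over all internal-state assignments.

    Returns (score, min_gains, max_gains) where a gain is a 0->1 edge change
    plus one origin when the root carries state 1; min/max are taken over the
    enumerated most-parsimonious assignments. Missing tip states ({0,1}) are
    enumerated too.
    """
    nodes, internal, tips, edges, root = _tree_edges_and_tips(tree)
    free = list(internal)
    fixed = {}
    for i, label in tips.items():
        s = char.get(label)
        if s is None:
            free.append(i)
        else:
            fixed[i] = s
    best = None
    results = []
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, combo))
        changes = sum(1 for p, c in edges if state[p] != state[c])
        gains = sum(1 for p, c in edges if state[p] == 0 and state[c] == 1)
        gains += 1 if state[root] == 1 else 0
        results.append((changes, gains))
        if best is None or changes < best:
            best = changes
    mpr_gains = [g for c, g in results if c == best]
    return best, min(mpr_gains), max(mpr_gains)


@pytest.fixture(scope="session")
def parsimony_oracle():
    return brute_force_parsimony


def random_small_tree(n_tips, rng):
    """A random binary tree with <= 10 tips, via the package's Yule grower."""
    from floralsignals.synthetic_data import _grow_yule_tree

    return _grow_yule_tree(n_tips, rng)


@pytest.fixture(scope="session")
def small_tree_factory():
    return random_small_tree


# ---------------------------------------------------------------------------
# bootstrap oracle: direct re-implementation of the null-resampling loop

def direct_focal_bootstrap(xy, species, focal, n_boot, seed):
    """Plain-loop re-implementation of the focal distinctness bootstrap.

    Computes distances directly from coordinates (no distance matrix) but
    follows the same RNG protocol, so it must agree bit-for-bit.
    """
    import statistics

    n = len(species)
    f0 = species.index(focal)

    def dist(i, j):
        return float(np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]))

    def stat(f, members):
        focal_d = [dist(f, j) for j in members]
        other_d = [
            dist(members[a], members[b])
            for a in range(len(members))
            for b in range(a + 1, len(members))
        ]
        return statistics.median(focal_d) - statistics.median(other_d)

    def stat_dedup(f, members):
        focal_d = [dist(f, j) for j in members]
        other_d = [
            dist(members[a], members[b])
            for a in range(len(members))
            for b in range(a + 1, len(members))
            if members[a] != members[b]
        ]
        return statistics.median(focal_d) - (statistics.median(other_d) if other_d else 0.0)

    T_obs = stat(f0, [i for i in range(n) if i != f0])
    rng = np.random.default_rng(seed)
    candidates = [i for i in range(n) if i != f0]
    focal_stars = rng.integers(0, n - 1, size=n_boot)
    count = 0
    for b in range(n_boot):
        f = candidates[int(focal_stars[b])]
        pool = np.delete(np.arange(n), f)
        drawn = [int(v) for v in rng.choice(pool, size=n - 1, replace=True)]
        if stat_dedup(f, drawn) >= T_obs:
            count += 1
    return T_obs, count / n_boot
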