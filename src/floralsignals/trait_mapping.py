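"""Parsimony mapping of a binary floral-colour state on a phylogeny.

The bee-UV-green ("yellow") colour state of each tip is mapped onto a rooted
tree by unweighted parsimony — Fitch's algorithm, generalised to polytomies
after Hartigan — and the number of independent origins of the state is
bracketed over all most-parsimonious reconstructions (MPRs) by dynamic
programming. An *origin* is a 0 -> 1 change along an edge, plus one origin
when the root itself is reconstructed in state 1 (the state arose on the stem
lineage); this is the convention under which "the trait evolved at least k
times" is read off the tree. Edge lengths are ignored; missing tip states are
treated as fully ambiguous {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

INF = float("inf")


class CharacterDataError(ValueError):
    """Tip states unusable (no scored tips, tips absent from tree...)."""


def read_newick(source, path: bool | None = None) -> dendropy.Tree:
    """Parse a rooted newick tree, preserving polytomies.

    ``source`` may be a file path or a newick string. Duplicate tip labels are
    rejected.
    """
    text = None
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise CharacterDataError(f"duplicate tip labels: {exc}") from exc
    return tree


def read_character_tsv(path) -> tuple[dict, dict]:
    """Read a tip-state table (tip_name, state[, genus]) -> (states, genus map)."""
    df = pd.read_csv(path, sep="\t")
    states = {}
    for _, row in df.iterrows():
        raw = row["state"]
        states[str(row["tip_name"])] = None if pd.isna(raw) else int(raw)
    genus = (
        {str(r["tip_name"]): str(r["genus"]) for _, r in df.iterrows()}
        if "genus" in df.columns
        else {}
    )
    return states, genus


@dataclass
class ReconstructionResult:
    """Parsimony score, origin-count bracket, and per-node optimal state sets."""

    parsimony_score: int
    min_gains: int
    max_gains: int
    root_states: tuple[int, ...]  # root states attaining the parsimony score
    state_sets: dict = field(repr=False, default_factory=dict)  # node -> frozenset
    gain_convention: str = (
        "0->1 edge changes, plus one origin when the root is reconstructed in state 1"
    )


def _tip_state_sets(tree: dendropy.Tree, char: dict) -> dict:
    """Allowed-state set per tip; missing or unscored tips are {0, 1}."""
    sets = {}
    scored = 0
    for leaf in tree.leaf_node_iter():
        s = char.get(leaf.taxon.label)
        if s is None:
            sets[leaf] = frozenset({0, 1})
        else:
            if s not in (0, 1):
                raise CharacterDataError(f"state {s!r} for tip {leaf.taxon.label!r}")
            sets[leaf] = frozenset({s})
            scored += 1
    if scored == 0:
        raise CharacterDataError("no scored tips")
    extra = set(char) - {l.taxon.label for l in tree.leaf_node_iter()}
    if extra:
        raise CharacterDataError(f"scored tips absent from tree: {sorted(extra)}")
    return sets


def fitch_parsimony(tree: dendropy.Tree, char: dict) -> ReconstructionResult:
    """Minimum number of state changes, with Hartigan downpass state sets.

    At each internal node the preliminary set collects the states occurring in
    the largest number of child sets; the score grows by (number of children
    minus that count). On binary trees this is exactly Fitch's
    intersection/union rule.
    """
    tip_sets = _tip_state_sets(tree, char)
    score = 0
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = tip_sets[node]
            continue
        children = node.child_nodes()
        count = {0: 0, 1: 0}
        for c in children:
            for s in sets[c]:
                count[s] += 1
        k = max(count.values())
        sets[node] = frozenset(s for s in (0, 1) if count[s] == k)
        score += len(children) - k
    result = count_origins(tree, char)
    result.state_sets = sets
    assert result.parsimony_score == score  # Hartigan and Sankoff must agree
    return result


def count_origins(tree: dendropy.Tree, char: dict) -> ReconstructionResult:
    """Bracket the number of origins of state 1 over all MPRs.

    Unit-cost Sankoff dynamic programming tracks, for every node and state,
    the minimum subtree cost together with the fewest and most 0 -> 1 changes
    achievable at that cost. Root states are chosen to minimise total changes;
    when both root states tie, both are explored and reported.
    """
    tip_sets = _tip_state_sets(tree, char)
    cost: dict = {}
    gmin: dict = {}
    gmax: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = tip_sets[node]
            cost[node] = {s: (0 if s in allowed else INF) for s in (0, 1)}
            gmin[node] = {s: 0 for s in (0, 1)}
            gmax[node] = {s: 0 for s in (0, 1)}
            continue
        c_n = {s: 0.0 for s in (0, 1)}
        g_lo = {s: 0 for s in (0, 1)}
        g_hi = {s: 0 for s in (0, 1)}
        for child in node.child_nodes():
            for s in (0, 1):
                options = []
                for sp in (0, 1):
                    cc = cost[child][sp] + (1 if sp != s else 0)
                    if cc < INF:
                        gain = 1 if (s == 0 and sp == 1) else 0
                        options.append((cc, gmin[child][sp] + gain, gmax[child][sp] + gain))
                best = min(o[0] for o in options)
                c_n[s] += best
                at_best = [o for o in options if o[0] == best]
                g_lo[s] += min(o[1] for o in at_best)
                g_hi[s] += max(o[2] for o in at_best)
        cost[node], gmin[node], gmax[node] = c_n, g_lo, g_hi
    root = tree.seed_node
    best = min(cost[root].values())
    root_states = tuple(s for s in (0, 1) if cost[root][s] == best)
    lo = min(gmin[root][s] + (1 if s == 1 else 0) for s in root_states)
    hi = max(gmax[root][s] + (1 if s == 1 else 0) for s in root_states)
    return ReconstructionResult(
        parsimony_score=int(best),
        min_gains=int(lo),
        max_gains=int(hi),
        root_states=root_states,
    )


def _backtrack_states(tree: dendropy.Tree, char: dict) -> dict:
    """One MPR (the one attaining min_gains), as node -> state."""
    tip_sets = _tip_state_sets(tree, char)
    cost: dict = {}
    gmin: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = tip_sets[node]
            cost[node] = {s: (0 if s in allowed else INF) for s in (0, 1)}
            gmin[node] = {s: 0 for s in (0, 1)}
            continue
        cost[node] = {s: 0.0 for s in (0, 1)}
        gmin[node] = {s: 0 for s in (0, 1)}
        for child in node.child_nodes():
            for s in (0, 1):
                opts = []
                for sp in (0, 1):
                    cc = cost[child][sp] + (1 if sp != s else 0)
                    if cc < INF:
                        opts.append((cc, gmin[child][sp] + (1 if (s == 0 and sp == 1) else 0)))
                b = min(o[0] for o in opts)
                cost[node][s] += b
                gmin[node][s] += min(o[1] for o in opts if o[0] == b)
    root = tree.seed_node
    best = min(cost[root].values())
    ties = [s for s in (0, 1) if cost[root][s] == best]
    root_state = min(ties, key=lambda s: gmin[root][s] + (1 if s == 1 else 0))
    assign = {root: root_state}
    for node in tree.preorder_node_iter():
        s = assign[node]
        for child in node.child_nodes():
            opts = []
            for sp in (0, 1):
                cc = cost[child][sp] + (1 if sp != s else 0)
                if cc < INF:
                    opts.append((cc, gmin[child][sp] + (1 if (s == 0 and sp == 1) else 0), sp))
            b = min(o[0] for o in opts)
            assign[child] = min((o for o in opts if o[0] == b), key=lambda o: o[1])[2]
    return assign


def annotate_tree(tree: dendropy.Tree, char: dict) -> str:
    """Newick string with per-node reconstructed states.

    Internal nodes are labelled ``state=S`` (with ``|ambiguous`` when the
    Hartigan downpass set contains both states); the assignment is one MPR,
    the one attaining the minimum number of origins.
    """
    result = fitch_parsimony(tree, char)
    assign = _backtrack_states(tree, char)

    def label(node) -> str:
        tag = f"state={assign[node]}"
        if len(result.state_sets[node]) > 1:
            tag += "|ambiguous"
        return tag

    def render(node) -> str:
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            return f"{name}[&{label(node)}]"
        inner = ",".join(render(c) for c in node.child_nodes())
        return f"({inner})[&{label(node)}]"

    return render(tree.seed_node) + ";"


def genus_origin_summary(char: dict, genus_map: dict) -> pd.DataFrame:
    """Genera containing the state-1 colour, the genus-level origin summary.

    Counting genera that contain the state is the coarser companion to the
    tree-based origin bracket; the two need not agree and both are reported.
    """
    rows = {}
    for tip, state in char.items():
        g = genus_map.get(tip, tip.split("_")[0].split(" ")[0])
        rec = rows.setdefault(g, {"genus": g, "n_tips": 0, "n_state1": 0})
        rec["n_tips"] += 1
        if state == 1:
            rec["n_state1"] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["genus"]))
    df["has_state"] = df["n_state1"] > 0
    return df
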