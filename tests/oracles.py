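"""Independent oracles shared by the emergence and acceptance tests.

Trees are nested tuples of leaf-name strings; every function here is a
deliberately naive reimplementation, kept separate from the package code
it checks.
"""

import numpy as np


def tuple_tree_newick(t):
    if isinstance(t, str):
        return t
    return f"({tuple_tree_newick(t[0])}:1,{tuple_tree_newick(t[1])}:1)"


def tuple_leaves(t):
    if isinstance(t, str):
        return [t]
    return tuple_leaves(t[0]) + tuple_leaves(t[1])


def fitch_changes(t, calls):
    """Binary Fitch small-parsimony change count (set-based)."""

    def rec(node):
        nonlocal changes
        if isinstance(node, str):
            return {calls[node]}
        a = rec(node[0])
        b = rec(node[1])
        inter = a & b
        if inter:
            return inter
        changes += 1
        return a | b

    changes = 0
    rec(t)
    return changes


def rules_oracle(t, calls):
    """Literal reimplementation of the emergence rules; returns
    (n_events, number_of_event_event_merges)."""

    def rec(node):
        nonlocal events, merges
        if isinstance(node, str):
            return calls[node]
        a = rec(node[0])
        b = rec(node[1])
        if a == "E" and b == "E":
            merges += 1
            return "E"
        if a == "E":
            return b
        if b == "E":
            return a
        if a == b:
            return a
        events += 1
        return "E"

    events = 0
    merges = 0
    rec(t)
    return events, merges


def insert_everywhere(t, leaf):
    yield (t, leaf)
    if not isinstance(t, str):
        for sub in insert_everywhere(t[0], leaf):
            yield (sub, t[1])
        for sub in insert_everywhere(t[1], leaf):
            yield (t[0], sub)


def all_rooted_trees(leaves):
    """All (2n-3)!! rooted binary topologies on labeled leaves."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        nxt = []
        for t in trees:
            nxt.extend(insert_everywhere(t, leaf))
        trees = nxt
    return trees


def tuple_to_arrays(t, leaf_ids):
    """Postorder child-pointer arrays for a tuple tree.

    Returns (left, right, leaf_of) where nodes are numbered in postorder,
    leaf nodes have left/right = -1 and ``leaf_of`` gives their leaf index
    (-1 for internal nodes).
    """
    left, right, leaf_of = [], [], []

    def rec(node):
        if isinstance(node, str):
            left.append(-1)
            right.append(-1)
            leaf_of.append(leaf_ids[node])
            return len(left) - 1
        a = rec(node[0])
        b = rec(node[1])
        left.append(a)
        right.append(b)
        leaf_of.append(-1)
        return len(left) - 1

    rec(t)
    return np.array(left), np.array(right), np.array(leaf_of)


def all_labelings_counts(t, leaves):
    """Vectorized (events, fitch, merges) over all 2^n leaf labelings.

    Both the emergence rules and the Fitch count are evaluated with the
    same postorder sweep across every labeling at once; states are coded
    0/1 genotype, 2 event; Fitch sets as bitmasks 1/2/3.
    """
    n = len(leaves)
    M = 1 << n
    leaf_ids = {s: i for i, s in enumerate(leaves)}
    left, right, leaf_of = tuple_to_arrays(t, leaf_ids)
    lab = ((np.arange(M)[None, :] >> np.arange(n)[:, None]) & 1).astype(np.int8)

    n_nodes = len(left)
    state = np.empty((n_nodes, M), dtype=np.int8)
    fset = np.empty((n_nodes, M), dtype=np.int8)
    events = np.zeros(M, dtype=np.int16)
    fitch = np.zeros(M, dtype=np.int16)
    merges = np.zeros(M, dtype=np.int16)
    for nd in range(n_nodes):
        if left[nd] < 0:
            s = lab[leaf_of[nd]]
            state[nd] = s
            fset[nd] = s + 1  # {0} -> 1, {1} -> 2
            continue
        a = state[left[nd]]
        b = state[right[nd]]
        both_gen = (a < 2) & (b < 2)
        new_event = both_gen & (a != b)
        events += new_event
        ee = (a == 2) & (b == 2)
        merges += ee
        out = np.where(
            new_event | ee,
            2,
            np.where(both_gen, a, np.where(a == 2, b, a)),
        ).astype(np.int8)
        state[nd] = out
        fa = fset[left[nd]]
        fb = fset[right[nd]]
        inter = fa & fb
        empty = inter == 0
        fitch += empty
        fset[nd] = np.where(empty, fa | fb, inter)
    return events, fitch, merges
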