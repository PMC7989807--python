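"""Independent oracles the test suite checks the implementation against.

Each oracle re-derives a quantity by a different algorithmic route than
the implementation: a memoised tuple-valued recursion for global
alignment, explicit splice construction for chimera detection, leaf-path
enumeration for tree bipartitions, and Monte-Carlo subsampling for
rarefied richness.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -1, -2, -1


def align_oracle(query: str, ref: str, free_ref_end_gaps: bool = False):
    """Optimal (score, matches, columns) under the lexicographic objective
    (score, matches, -columns), by memoised suffix recursion."""
    m, n = len(query), len(ref)
    NEG = (-(10 ** 9), 0, 0)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str):
        if i == m:
            if free_ref_end_gaps or j == n:
                stop = (0, 0, 0)
            else:
                stop = None
            if j == n:
                return stop
        options = []
        if i == m and free_ref_end_gaps:
            options.append((0, 0, 0))
        if i < m and j < n:
            hit = query[i] == ref[j]
            step = (MATCH if hit else MISMATCH, 1 if hit else 0, -1)
            tail = best(i + 1, j + 1, "M")
            if tail is not None:
                options.append(tuple(a + b for a, b in zip(step, tail)))
        if i < m and prev != "Y":
            cost = GAP_EXT if prev == "X" else GAP_OPEN
            tail = best(i + 1, j, "X")
            if tail is not None:
                options.append((cost + tail[0], tail[1], -1 + tail[2]))
        if j < n and i < m:  # paid gap consuming ref (not after X)
            if prev != "X":
                cost = GAP_EXT if prev == "Y" else GAP_OPEN
                tail = best(i, j + 1, "Y")
                if tail is not None:
                    options.append((cost + tail[0], tail[1], -1 + tail[2]))
        if j < n and i == m and not free_ref_end_gaps and prev != "X":
            cost = GAP_EXT if prev == "Y" else GAP_OPEN
            tail = best(i, j + 1, "Y")
            if tail is not None:
                options.append((cost + tail[0], tail[1], -1 + tail[2]))
        if not options:
            return None
        return max(options)

    if free_ref_end_gaps:
        candidates = [best(0, j0, "M") for j0 in range(n + 1)]
        result = max(c for c in candidates if c is not None)
    else:
        result = best(0, 0, "M")
    best.cache_clear()
    score, matches, negcols = result
    return score, matches, -negcols


def chimera_oracle(uniques, skew: float = 2.0, max_diffs: int = 0):
    """Exhaustive parent-pair x breakpoint chimera search.

    ``uniques``: sequence of objects with .seq and .size, sorted by size
    descending. Returns a boolean flag per unique.
    """
    flags = []
    for idx, cand in enumerate(uniques):
        L = len(cand.seq)
        single = False
        for i in range(idx):
            other = uniques[i]
            if len(other.seq) == L:
                diffs = sum(x != y for x, y in zip(other.seq, cand.seq))
                if diffs <= max_diffs:
                    single = True
        if single:
            flags.append(False)
            continue
        found = False
        for i in range(idx):
            for j in range(idx):
                if i == j:
                    continue
                A, B = uniques[i], uniques[j]
                if len(A.seq) != L or len(B.seq) != L:
                    continue
                if A.size < skew * cand.size or B.size < skew * cand.size:
                    continue
                for b in range(1, L):
                    model = A.seq[:b] + B.seq[b:]
                    diffs = sum(x != y for x, y in zip(model, cand.seq))
                    if diffs <= max_diffs:
                        found = True
                        break
                if found:
                    break
            if found:
                break
        flags.append(found)
    return flags


def branch_score_oracle(tree_a, tree_b) -> float:
    """Branch-score distance by leaf-path bipartition enumeration.

    For each tree, each edge is keyed by the set of leaves whose path to
    the root crosses it (canonicalised against a reference leaf); lengths
    of edges mapping to the same key add. The distance is the Euclidean
    distance of the two length vectors over the union of keys.
    """
    import dendropy

    def table(tree: dendropy.Tree, shared: frozenset):
        ref = min(shared)
        edge_leaves: dict[int, set] = {}
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in shared:
                continue
            node = leaf
            while node.parent_node is not None:
                edge_leaves.setdefault(id(node), set()).add(leaf.taxon.label)
                node = node.parent_node
        lengths: dict[frozenset, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(edge_leaves.get(id(node), set()))
            if not side or side == shared:
                continue
            key = side if ref not in side else shared - side
            lengths[key] = lengths.get(key, 0.0) + float(node.edge.length)
        return lengths

    leaves_a = frozenset(l.taxon.label for l in tree_a.leaf_node_iter())
    leaves_b = frozenset(l.taxon.label for l in tree_b.leaf_node_iter())
    shared = leaves_a & leaves_b
    ta, tb = table(tree_a, shared), table(tree_b, shared)
    total = 0.0
    for key in set(ta) | set(tb):
        d = ta.get(key, 0.0) - tb.get(key, 0.0)
        total += d * d
    return total ** 0.5


def rarefaction_oracle(counts, n: int, reps: int = 10_000,
                       seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo expected richness in subsamples of size n without
    replacement; returns (mean, standard error)."""
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty(reps)
    for k in range(reps):
        sub = rng.choice(pool, size=n, replace=False)
        richness[k] = len(np.unique(sub))
    return float(richness.mean()), float(richness.std(ddof=1) / reps ** 0.5)
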