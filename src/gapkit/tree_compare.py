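"""Tree distance and marker-gene cluster congruence.

The "Euclidean distance between two trees" is the Kuhner-Felsenstein
branch-score metric: index every branch by the leaf bipartition it induces
(trees compared unrooted, pendant branches included), treat each tree as a
vector of branch lengths over the union of bipartitions (0 where absent),
and take the Euclidean distance. Congruence between two marker-gene
classifications (amoA vs 16S rRNA lineages) is tabulated from the strain
affiliation table as per-lineage purity scores.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import dendropy
import pandas as pd

from .formats_io import StrainTable

logger = logging.getLogger("gapkit")


def load_tree(source: str | Path) -> dendropy.Tree:
    """Load a Newick tree from a path or a Newick string."""
    s = str(source)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def _bipartition_lengths(tree: dendropy.Tree,
                         shared: frozenset[str]) -> dict[frozenset[str], float]:
    """Branch length per canonical leaf bipartition, restricted to the
    shared leaf set. Restriction naturally merges edges that collapse onto
    the same bipartition after pruning (their lengths add), and drops
    edges leading only to pruned leaves."""
    ref = min(shared)
    table: dict[frozenset[str], float] = {}
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            ls = frozenset([label]) & shared
        else:
            ls = frozenset().union(*(leafsets[id(c)] for c in
                                     node.child_nodes()))
        leafsets[id(node)] = ls
        if node.parent_node is None:
            continue  # the root has no branch of its own
        side = ls
        if not side or side == shared:
            continue  # branch is trivial after restriction
        key = side if ref not in side else shared - side
        length = node.edge.length
        if length is None:
            raise ValueError(
                "branch length missing on an internal edge; all branches "
                "must carry lengths for the branch-score distance"
            )
        table[key] = table.get(key, 0.0) + float(length)
    return table


def branch_score_distance(tree_a: dendropy.Tree | str | Path,
                          tree_b: dendropy.Tree | str | Path) -> float:
    """Kuhner-Felsenstein branch-score distance between two trees.

    Trees are compared unrooted; leaf sets differing between the trees are
    pruned to their intersection with a warning. Raises on fewer than 4
    shared leaves.
    """
    ta = tree_a if isinstance(tree_a, dendropy.Tree) else load_tree(tree_a)
    tb = tree_b if isinstance(tree_b, dendropy.Tree) else load_tree(tree_b)
    leaves_a = frozenset(l.taxon.label for l in ta.leaf_node_iter())
    leaves_b = frozenset(l.taxon.label for l in tb.leaf_node_iter())
    shared = leaves_a & leaves_b
    if shared != leaves_a or shared != leaves_b:
        logger.warning("leaf sets differ; pruning to %d shared leaves",
                       len(shared))
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 4")
    la = _bipartition_lengths(ta, shared)
    lb = _bipartition_lengths(tb, shared)
    total = 0.0
    for key in set(la) | set(lb):
        d = la.get(key, 0.0) - lb.get(key, 0.0)
        total += d * d
    return total ** 0.5


def lineage_counts(table: StrainTable) -> tuple[int, int, int]:
    """(number of strains, distinct amoA lineages, distinct 16S lineages)."""
    return (
        len(table.rows),
        len({r.amoA_lineage for r in table.rows}),
        len({r.rrna_lineage for r in table.rows}),
    )


def congruence_table(table: StrainTable) -> pd.DataFrame:
    """Per-amoA-lineage 16S composition and purity.

    Purity is the fraction of a lineage's strains falling in its modal 16S
    cluster (modal ties broken alphabetically). Columns: n_strains,
    rrna_lineages (counted multiset as 'label x n' strings), modal_rrna,
    purity.
    """
    groups: dict[str, Counter] = {}
    for r in table.rows:
        groups.setdefault(r.amoA_lineage, Counter())[r.rrna_lineage] += 1
    rows = {}
    for lineage in sorted(groups):
        counts = groups[lineage]
        n = sum(counts.values())
        modal = min(
            counts, key=lambda k: (-counts[k], k)
        )
        rows[lineage] = {
            "n_strains": n,
            "rrna_lineages": ", ".join(
                f"{lab} x{cnt}" for lab, cnt in sorted(counts.items())
            ),
            "modal_rrna": modal,
            "purity": counts[modal] / n,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "amoA_lineage"
    return df


def overall_congruence(table: StrainTable) -> float:
    """Strain-weighted mean purity across amoA lineages."""
    df = congruence_table(table)
    if df.empty:
        return float("nan")
    return float((df["purity"] * df["n_strains"]).sum() / df["n_strains"].sum())
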