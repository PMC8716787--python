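"""Marker-level interaction mining from a boosted-tree ensemble dump.

Features that split on the same root-to-leaf path of a regression tree are
treated as interacting. For every internal parent -> internal child edge the
child's split gain is credited to the ordered (parent feature, child feature)
pair; summing over the ensemble yields the sumGain statistic, with the edge
count as the pair's frequency. Only direct parent/child edges are counted —
grandparent relations are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "ParsedTree",
    "TreeEnsembleDump",
    "PairStat",
    "parse_dump",
    "pair_stats",
    "snp_gain_totals",
    "gain_bins",
    "pair_stats_to_tsv",
]


@dataclass(frozen=True)
class TreeNode:
    node_id: int
    is_leaf: bool
    feature: int | None = None  # split feature index; None for leaves
    gain: float = 0.0
    left: int | None = None
    right: int | None = None


@dataclass
class ParsedTree:
    """One regression tree as an id -> node map plus its root id."""

    nodes: dict[int, TreeNode]
    root: int

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def children(self, node: TreeNode) -> list[TreeNode]:
        out = []
        for cid in (node.left, node.right):
            if cid is not None:
                out.append(self.nodes[cid])
        return out

    def paths(self) -> Iterator[list[int]]:
        """Split-feature sequences of every root-to-leaf path."""

        def walk(node: TreeNode, prefix: list[int]) -> Iterator[list[int]]:
            if node.is_leaf:
                yield prefix
                return
            for child in self.children(node):
                yield from walk(child, prefix + [node.feature])

        yield from walk(self.nodes[self.root], [])


@dataclass
class TreeEnsembleDump:
    trees: list[ParsedTree] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def total_internal_gain(self) -> float:
        return float(sum(n.gain for t in self.trees for n in t.internal_nodes))

    def total_root_gain(self) -> float:
        return float(
            sum(t.nodes[t.root].gain for t in self.trees if not t.nodes[t.root].is_leaf)
        )


@dataclass
class PairStat:
    """Accumulated interaction evidence for one ordered (parent, child) pair."""

    parent_snp: str
    child_snp: str
    sum_gain: float
    frequency: int


def _feature_index(split: str | int) -> int:
    if isinstance(split, int):
        return split
    if split.startswith("f") and split[1:].isdigit():
        return int(split[1:])
    raise ValueError(
        f"cannot resolve split feature {split!r}; dump the booster without "
        "feature names or pass integer indices"
    )


def _parse_tree(spec: dict) -> ParsedTree:
    nodes: dict[int, TreeNode] = {}

    def walk(d: dict) -> int:
        nid = int(d["nodeid"])
        if "leaf" in d:
            nodes[nid] = TreeNode(node_id=nid, is_leaf=True)
            return nid
        children = {int(c["nodeid"]): c for c in d.get("children", [])}
        left = d.get("yes")
        right = d.get("no")
        for c in children.values():
            walk(c)
        nodes[nid] = TreeNode(
            node_id=nid,
            is_leaf=False,
            feature=_feature_index(d["split"]),
            gain=float(d.get("gain", 0.0)),
            left=int(left) if left is not None else None,
            right=int(right) if right is not None else None,
        )
        return nid

    root = walk(spec)
    return ParsedTree(nodes=nodes, root=root)


def parse_dump(raw: Sequence[str] | Sequence[dict]) -> TreeEnsembleDump:
    """Parse a booster dump (JSON strings or parsed dicts, one per tree)."""
    trees = []
    for item in raw:
        spec = json.loads(item) if isinstance(item, str) else item
        trees.append(_parse_tree(spec))
    return TreeEnsembleDump(trees=trees)


def pair_stats(
    dump: TreeEnsembleDump,
    snp_names: Sequence[str],
    gene_ids: Sequence[str] | None = None,
    cross_gene_only: bool = False,
    unordered: bool = False,
) -> list[PairStat]:
    """Ranked sumGain statistics for parent/child split-feature pairs.

    For each edge from an internal node to an internal child, the child's
    gain is added to the (parent feature, child feature) pair and the pair's
    frequency is incremented. Pairs are ranked by sum_gain descending, ties
    broken by frequency then lexicographic names. ``cross_gene_only``
    restricts output to pairs whose SNPs map to different genes (requires
    ``gene_ids``); ``unordered`` folds (a, b) and (b, a) together.
    """
    if cross_gene_only and gene_ids is None:
        raise ValueError("cross_gene_only requires gene_ids")
    acc: dict[tuple[str, str], list] = {}
    for tree in dump.trees:
        for node in tree.internal_nodes:
            for child in tree.children(node):
                if child.is_leaf:
                    continue
                key = (snp_names[node.feature], snp_names[child.feature])
                if unordered:
                    key = tuple(sorted(key))  # type: ignore[assignment]
                entry = acc.setdefault(key, [0.0, 0])
                entry[0] += child.gain
                entry[1] += 1
    stats = [
        PairStat(parent_snp=a, child_snp=b, sum_gain=g, frequency=f)
        for (a, b), (g, f) in acc.items()
    ]
    if cross_gene_only:
        gene_of = dict(zip(snp_names, gene_ids))  # type: ignore[arg-type]
        stats = [s for s in stats if gene_of[s.parent_snp] != gene_of[s.child_snp]]
    stats.sort(key=lambda s: (-s.sum_gain, -s.frequency, s.parent_snp, s.child_snp))
    return stats


def snp_gain_totals(dump: TreeEnsembleDump, snp_names: Sequence[str]) -> dict[str, float]:
    """Per-SNP total split gain over all internal nodes of the ensemble."""
    totals: dict[str, float] = {name: 0.0 for name in snp_names}
    for tree in dump.trees:
        for node in tree.internal_nodes:
            totals[snp_names[node.feature]] += node.gain
    return totals


def gain_bins(stats: Sequence[PairStat], n_bins: int = 4) -> list[int]:
    """Equal-width intensity bins over [0, max sumGain]; 1 = weakest, n = strongest."""
    if len(stats) == 0:
        raise ValueError("gain_bins needs at least one pair")
    top = max(s.sum_gain for s in stats)
    if top <= 0:
        return [n_bins] * len(stats)
    labels = []
    for s in stats:
        b = int(np.ceil(s.sum_gain / top * n_bins))
        labels.append(min(max(b, 1), n_bins))
    return labels


def pair_stats_to_tsv(stats: Sequence[PairStat], path) -> None:
    rows = [
        {
            "index": i + 1,
            "parent_snp": s.parent_snp,
            "child_snp": s.child_snp,
            "sum_gain": s.sum_gain,
            "frequency": s.frequency,
        }
        for i, s in enumerate(stats)
    ]
    columns = ["index", "parent_snp", "child_snp", "sum_gain", "frequency"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
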