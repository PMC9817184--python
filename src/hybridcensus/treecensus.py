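"""Gene-tree sister-taxon census for a focal (hybrid) tip.

Each gene tree is rooted on a designated outgroup leaf, the sister group
of the focal tip is extracted, and trees whose sister is a single leaf
("singleton-sister" trees) are tallied per species.  Trees whose sister is
a multi-leaf clade, and trees lacking the outgroup (unrootable), are
counted separately and excluded from the proportion denominator.  Branch
lengths are ignored throughout: the census is topology-only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import dendropy


@dataclass
class SisterCensus:
    """Per-species singleton-sister counts over a gene-tree forest."""

    counts: dict[str, int]
    n_trees_total: int
    n_singleton: int
    n_multi_sister: int
    n_unrootable: int

    def __post_init__(self) -> None:
        assert (
            self.n_singleton + self.n_multi_sister + self.n_unrootable
            == self.n_trees_total
        )

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_singleton == 0:
            return {sp: 0.0 for sp in self.counts}
        return {sp: c / self.n_singleton for sp, c in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "proportions": self.proportions,
            "n_trees_total": self.n_trees_total,
            "n_singleton": self.n_singleton,
            "n_multi_sister": self.n_multi_sister,
            "n_unrootable": self.n_unrootable,
        }


def read_newick_forest(path: str | Path) -> list[dendropy.Tree]:
    """Read gene trees from a Newick file (one or more trees) or directory."""
    path = Path(path)
    files = sorted(path.glob("*")) if path.is_dir() else [path]
    trees: list[dendropy.Tree] = []
    for f in files:
        try:
            tl = dendropy.TreeList.get(
                path=str(f), schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise ValueError(f"malformed Newick in {f}: {exc}") from exc
        trees.extend(tl)
    return trees


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick string: {exc}") from exc


def root_at_outgroup(tree: dendropy.Tree, outgroup_name: str) -> dendropy.Tree | None:
    """Place the root on the edge subtending the outgroup leaf (in place).

    Returns the tree, or None when the outgroup leaf is absent (the tree
    is then unrootable and sisterhood of any tip is undefined).
    """
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == outgroup_name:
            node = leaf
            break
    if node is None:
        return None
    parent = node.parent_node
    if parent is not None and parent.parent_node is None and len(parent.child_nodes()) == 2:
        return tree  # already rooted on the outgroup edge
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def sister_of(tree: dendropy.Tree, focal_name: str) -> set[str]:
    """Leaf labels of the focal tip's sister group in a rooted tree.

    Under a multifurcating parent the union of all co-children's leaves is
    returned (hence non-singleton).
    """
    focal = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == focal_name:
            focal = leaf
            break
    if focal is None:
        raise ValueError(f"focal tip {focal_name!r} absent from tree")
    parent = focal.parent_node
    if parent is None:
        return set()
    labels: set[str] = set()
    for child in parent.child_nodes():
        if child is focal:
            continue
        for leaf in child.leaf_iter():
            if leaf.taxon is not None:
                labels.add(leaf.taxon.label)
    return labels


def sister_census(
    forest: list[dendropy.Tree] | list[str],
    focal_name: str,
    outgroup_name: str,
    species: list[str] | None = None,
) -> SisterCensus:
    """Root every tree on the outgroup and census singleton sisters.

    ``forest`` may hold parsed trees or Newick strings.  Proportions are
    reported over singleton-sister trees only; multi-leaf sisters and
    unrootable trees are tallied but excluded from the denominator.
    """
    counts: Counter[str] = Counter()
    n_single = n_multi = n_unroot = 0
    total = 0
    for t in forest:
        total += 1
        tree = parse_newick(t) if isinstance(t, str) else t
        rooted = root_at_outgroup(tree, outgroup_name)
        if rooted is None:
            n_unroot += 1
            continue
        sisters = sister_of(rooted, focal_name)
        if len(sisters) == 1:
            counts[next(iter(sisters))] += 1
            n_single += 1
        else:
            n_multi += 1
    rows = {sp: 0 for sp in (species or sorted(counts))}
    rows.update(counts)
    return SisterCensus(
        counts=rows,
        n_trees_total=total,
        n_singleton=n_single,
        n_multi_sister=n_multi,
        n_unrootable=n_unroot,
    )
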