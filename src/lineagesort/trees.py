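"""Tree data model and I/O.

Thin layer over :mod:`dendropy` providing validated parsing, writing,
pruning and bipartition extraction for the rooted gene trees and
ultrametric chronograms used throughout the pipeline.  Distances and
bipartitions are always computed on the *unrooted* topology; rooting is
retained only because the coalescent simulator needs node ages.

Taxon labels are matched exactly (no whitespace folding or fuzzy
matching): a silent label mismatch would corrupt every cross-gene
comparison downstream, so mismatches are hard errors.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable

import dendropy

__all__ = [
    "TreeSample",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "write_tree_sample",
    "prune_taxa",
    "bipartitions",
    "restrict_splits",
    "is_ultrametric",
    "tip_labels",
    "rf_from_splits",
]


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise ValueError("tree has an unlabeled tip")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string into a rooted :class:`dendropy.Tree`.

    Internal-node labels (support values) are tolerated and ignored for
    all downstream computations.  Malformed input raises ``ValueError``
    with the parser's position diagnostics; duplicate or empty tip
    labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises DataError subclasses
        raise ValueError(f"newick parse error: {exc}") from exc
    return _validate(tree)


def write_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Serialize ``tree`` as a newick string (no translate table).

    Round-trips through :func:`parse_newick` up to branch-length
    formatting at ``precision`` decimal places.
    """
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}f",
        unquoted_underscores=True,
    )
    return s.strip()


def _open_maybe_gzip(path: str):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_schema(text: str) -> str:
    head = text.lstrip()[:6].lower()
    return "nexus" if head.startswith("#nexus") else "newick"


@dataclass
class TreeSample:
    """An ordered collection of trees on one common taxon set.

    Mirrors a posterior tree sample for a single locus (or a batch of
    simulated gene trees).  Construction rejects mixed taxon sets.
    """

    trees: list[dendropy.Tree]
    source: str = "unknown"
    _taxa: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSample must contain at least one tree")
        taxa = tip_labels(self.trees[0])
        for i, t in enumerate(self.trees[1:], start=1):
            if tip_labels(t) != taxa:
                diff = tip_labels(t) ^ taxa
                raise ValueError(
                    f"tree {i} of sample '{self.source}' has a different "
                    f"taxon set (difference: {sorted(diff)})"
                )
        self._taxa = frozenset(taxa)

    @property
    def taxa(self) -> frozenset[str]:
        return self._taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> dendropy.Tree:
        return self.trees[i]

    def restrict_to(self, taxa: Iterable[str]) -> "TreeSample":
        """Prune every tree down to ``taxa`` (shared-taxon restriction)."""
        keep = set(taxa)
        drop = self._taxa - keep
        missing = keep - self._taxa
        if missing:
            raise ValueError(f"taxa not in sample '{self.source}': {sorted(missing)}")
        if not drop:
            return self
        return TreeSample(
            [prune_taxa(t, drop) for t in self.trees], source=self.source
        )

    def split_sets(self) -> list[frozenset]:
        """Canonical nontrivial bipartition set of every member tree."""
        return [bipartitions(t) for t in self.trees]


def read_tree_sample(path: str, source: str | None = None) -> TreeSample:
    """Read a multi-tree newick or NEXUS file (optionally gzipped).

    NEXUS translate tables are honored.  The schema is sniffed from the
    leading ``#NEXUS`` token.
    """
    with _open_maybe_gzip(path) as fh:
        text = fh.read()
    schema = _sniff_schema(text)
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse tree file {path!r}: {exc}") from exc
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path!r}")
    return TreeSample([_validate(t) for t in trees], source=source or path)


def write_tree_sample(sample: TreeSample, path: str, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for t in sample:
            fh.write(write_newick(t, precision=precision) + "\n")


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def prune_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` with ``taxa`` removed.

    Unifurcations created by the removal are suppressed with branch
    lengths summed, so all remaining pairwise path lengths are
    unchanged.  Requesting an absent taxon, or leaving fewer than three
    tips, is an error.
    """
    drop = set(taxa)
    if not drop:
        return tree
    present = tip_labels(tree)
    missing = drop - present
    if missing:
        raise ValueError(f"cannot prune absent taxa: {sorted(missing)}")
    if len(present) - len(drop) < 3:
        raise ValueError(
            f"pruning {len(drop)} of {len(present)} taxa leaves fewer than 3 tips"
        )
    out = tree.clone(depth=1)
    out.prune_taxa_with_labels(sorted(drop), suppress_unifurcations=True)
    # dendropy can leave the root edge; drop it so depths stay meaningful
    out.seed_node.edge.length = None
    return out


def _anchor(taxa: frozenset[str]) -> str:
    return min(taxa)


def bipartitions(tree: dendropy.Tree) -> frozenset:
    """Canonical nontrivial bipartitions of the unrooted topology.

    Each split is represented by the tip-label side *not* containing the
    lexicographically smallest taxon, making the set independent of
    rooting.  Trivial splits (one side < 2 tips) are excluded; a star
    tree therefore yields the empty set.
    """
    taxa = tip_labels(tree)
    n = len(taxa)
    anchor = _anchor(taxa)
    splits: set[frozenset] = set()
    # postorder accumulation of tip sets
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
        else:
            clade = frozenset().union(*(below[c] for c in node.child_nodes()))
            below[node] = clade
            k = len(clade)
            if 2 <= k <= n - 2:
                side = clade if anchor not in clade else taxa - clade
                splits.add(side)
    return frozenset(splits)


def restrict_splits(
    splits: Iterable[frozenset], full_taxa: frozenset[str], drop: Iterable[str]
) -> frozenset:
    """Bipartition set after removing ``drop`` taxa, without re-pruning.

    Equivalent to ``bipartitions(prune_taxa(tree, drop))`` for the tree
    that produced ``splits`` — the identity the test suite checks — but
    operates on the cached split set, which is what makes the deletion
    scan affordable.
    """
    drop = frozenset(drop)
    kept = full_taxa - drop
    n = len(kept)
    if n < 4:
        return frozenset()
    anchor = _anchor(kept)
    out: set[frozenset] = set()
    for side in splits:
        side2 = side - drop
        k = len(side2)
        if 2 <= k <= n - 2:
            out.add(side2 if anchor not in side2 else kept - side2)
    return frozenset(out)


def rf_from_splits(s1: frozenset, s2: frozenset) -> int:
    """Robinson-Foulds symmetric difference of two canonical split sets."""
    return len(s1) + len(s2) - 2 * len(s1 & s2)


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``."""
    depths = []
    for lf in tree.leaf_node_iter():
        d = 0.0
        node = lf
        while node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError("ultrametricity check requires branch lengths")
            d += node.edge.length
            node = node.parent_node
        depths.append(d)
    return max(depths) - min(depths) <= tol
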