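"""Relative evolutionary divergence (RED) on rooted branch-length trees.

RED normalizes the position of a node between the root (RED = 0) and the
leaves (RED = 1). For a node n with parent RED p, branch length d to its
parent, and mean distance u from the parent to all leaves descending
through n, the recursion is

    red(n) = p + (d / u) * (1 - p)

evaluated in preorder. At a leaf d = u, so every leaf lands exactly at 1;
RED is non-decreasing along any root-to-leaf path. The degenerate case
u = 0 (an all-zero-length subtree) takes the limit red(n) = p, with a
warning.

The tree is used exactly as supplied: no rerooting. Trees here are
dendropy trees under the hood; leaf labels are strain IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd

from .align import IdentityMatrix
from .records import RANK_ORDER, ParseError, TaxonomyRecord

__all__ = [
    "RedTree",
    "TaxonRedMinima",
    "compute_reds",
    "find_mrca",
    "taxonomy_concordance_filter",
    "min_red_within_taxon",
    "identity_red_pairs",
    "filter_metadata_table",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class RedTree:
    """A rooted tree with branch lengths, RED values, and MRCA queries.

    Wraps a :class:`dendropy.Tree`. RED values live in ``node.red`` after
    :func:`compute_reds`; leaf labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate()
        self._index()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick_file(cls, path: PathLike) -> "RedTree":
        try:
            tree = dendropy.Tree.get(
                path=str(path),
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ParseError(f"{path}: could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "RedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise ParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon]
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ParseError(f"duplicate leaf labels: {dups}")
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise ParseError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}"
                )
            if node.edge.length < 0:
                raise ValueError("negative branch length")

    def _index(self) -> None:
        self._leaf: dict[str, dendropy.Node] = {}
        self._depth_steps: dict[int, int] = {}  # edge count from root
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            self._depth_steps[id(node)] = (
                0 if parent is None else self._depth_steps[id(parent)] + 1
            )
            if node.is_leaf():
                if node.taxon is None:
                    raise ParseError("leaf without a label")
                self._leaf[node.taxon.label] = node

    # -- basic queries ---------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_labels(self) -> list[str]:
        return sorted(self._leaf)

    def n_leaves(self) -> int:
        return len(self._leaf)

    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if not n.is_leaf())

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self._leaf[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    def depth_of(self, node: dendropy.Node) -> float:
        """Sum of branch lengths from the root to ``node``."""
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        return d

    def red_of(self, node_or_label) -> float:
        node = (
            self.leaf(node_or_label) if isinstance(node_or_label, str) else node_or_label
        )
        try:
            return node.red
        except AttributeError:
            raise RuntimeError("RED not computed yet; call compute_reds first") from None

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
            ).strip()
        )


def compute_reds(t: RedTree) -> RedTree:
    """Compute RED for every node of ``t`` (stored as ``node.red``).

    Postorder pass: mean distance from each node to its descendant leaves.
    Preorder pass: the interpolation recursion. Leaves come out exactly 1,
    the root exactly 0.
    """
    # mean node->descendant-leaf distance
    for node in t.tree.postorder_node_iter():
        if node.is_leaf():
            node._n_leaves = 1
            node._sum_leaf_dist = 0.0
        else:
            node._n_leaves = sum(c._n_leaves for c in node.child_nodes())
            node._sum_leaf_dist = sum(
                c._sum_leaf_dist + c._n_leaves * c.edge.length
                for c in node.child_nodes()
            )
    for node in t.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.red = 0.0
            continue
        if node.is_leaf():
            node.red = 1.0
            continue
        p = parent.red
        d = node.edge.length
        u = d + node._sum_leaf_dist / node._n_leaves
        if u == 0.0:
            log.warning("zero-length subtree below a node; red set to parent's value")
            node.red = p
        else:
            node.red = p + (d / u) * (1.0 - p)
    return t


def find_mrca(t: RedTree, a: str, b: str) -> dendropy.Node:
    """Most recent common ancestor of two distinct leaves.

    Walks parent pointers, equalizing depths first; O(depth) per query.
    """
    if a == b:
        raise ValueError("MRCA of a leaf with itself is not defined here")
    na, nb = t.leaf(a), t.leaf(b)
    da, db = t._depth_steps[id(na)], t._depth_steps[id(nb)]
    while da > db:
        na = na.parent_node
        da -= 1
    while db > da:
        nb = nb.parent_node
        db -= 1
    while na is not nb:
        na = na.parent_node
        nb = nb.parent_node
    return na


def taxonomy_concordance_filter(
    lpsn_like: Iterable[TaxonomyRecord], gtdb_like: Iterable[TaxonomyRecord]
) -> list[str]:
    """Strain IDs whose lineage agrees between two taxonomies.

    Agreement means exact string equality (after whitespace trimming) of
    phylum, class, order, family, genus and species; IDs present in only
    one collection are dropped.
    """
    def key(rec: TaxonomyRecord) -> tuple[str, ...]:
        return tuple(
            rec.rank_value(r).strip()
            for r in ("phylum", "class", "order", "family", "genus", "species")
        )

    a = {r.strain_id: key(r) for r in lpsn_like}
    b = {r.strain_id: key(r) for r in gtdb_like}
    return sorted(sid for sid in set(a) & set(b) if a[sid] == b[sid])


@dataclass(frozen=True)
class TaxonRedMinima:
    """Minimum MRCA-RED over within-taxon leaf pairs, for one taxon."""

    rank: str
    taxon_name: str
    n_members: int
    min_red: float
    argmin_pair: tuple[str, str]


def min_red_within_taxon(
    t: RedTree, taxa: Iterable[TaxonomyRecord], rank: str
) -> list[TaxonRedMinima]:
    """Per-taxon minimum of red(MRCA(pair)) over within-taxon pairs.

    Because RED is non-decreasing toward the leaves, the minimum over
    pairs is attained at the MRCA of the whole taxon, by a pair of members
    descending through two different children of that node; that pair is
    reported as the argmin. Taxa with fewer than two members are omitted;
    members missing from the tree raise ``KeyError``.
    """
    if rank not in RANK_ORDER:
        raise KeyError(f"unknown rank {rank!r}")
    groups: dict[str, list[str]] = {}
    missing: list[str] = []
    for rec in taxa:
        if rec.strain_id not in t._leaf:
            missing.append(rec.strain_id)
            continue
        groups.setdefault(rec.rank_value(rank), []).append(rec.strain_id)
    if missing:
        raise KeyError(f"taxon members not in tree: {sorted(missing)[:10]}")

    out: list[TaxonRedMinima] = []
    for name in sorted(groups):
        members = sorted(groups[name])
        if len(members) < 2:
            continue
        # MRCA of the whole set by iterated pairwise MRCA
        anc = t.leaf(members[0])
        for sid in members[1:]:
            anc = _mrca_nodes(t, anc, t.leaf(sid))
        # a pair split across two children of the set MRCA attains the min
        child_of: dict[str, int] = {}
        for k, sid in enumerate(members):
            node = t.leaf(sid)
            prev = node
            while node is not anc:
                prev = node
                node = node.parent_node
            child_of[sid] = id(prev)
        first = members[0]
        partner = next(s for s in members[1:] if child_of[s] != child_of[first])
        out.append(
            TaxonRedMinima(
                rank=rank,
                taxon_name=name,
                n_members=len(members),
                min_red=t.red_of(anc),
                argmin_pair=(first, partner),
            )
        )
    return out


def _mrca_nodes(t: RedTree, na: dendropy.Node, nb: dendropy.Node) -> dendropy.Node:
    da, db = t._depth_steps[id(na)], t._depth_steps[id(nb)]
    while da > db:
        na = na.parent_node
        da -= 1
    while db > da:
        nb = nb.parent_node
        db -= 1
    while na is not nb:
        na = na.parent_node
        nb = nb.parent_node
    return na


def identity_red_pairs(
    m: IdentityMatrix, t: RedTree, ids: Iterable[str]
) -> pd.DataFrame:
    """Pair (identity, MRCA-RED) for every unordered pair of ``ids``.

    ``ids`` are typically taxonomy-concordant strains present both in the
    identity matrix and as tree leaves. Returns a DataFrame with columns
    id_a, id_b, identity_pct, mrca_red.
    """
    ids = sorted(ids)
    unknown = [s for s in ids if s not in t._leaf or s not in m._index]
    if unknown:
        raise KeyError(f"ids missing from matrix or tree: {unknown[:10]}")
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            node = find_mrca(t, a, b)
            rows.append((a, b, m.get(a, b), t.red_of(node)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "identity_pct", "mrca_red"])


def filter_metadata_table(
    df: pd.DataFrame,
    criteria: Optional[dict[str, object]] = None,
) -> pd.DataFrame:
    """Keep metadata rows matching all column == value criteria.

    The documented default keeps rows whose type designation comes from
    the nomenclature registry and that are cluster representatives — the
    selection used when pairing registry strains with reference-tree
    leaves.
    """
    if criteria is None:
        criteria = {"lpsn_type_designation": True, "gtdb_representative": True}
    mask = pd.Series(True, index=df.index)
    for col, val in criteria.items():
        if col not in df.columns:
            raise KeyError(f"metadata table lacks column {col!r}")
        mask &= df[col] == val
    return df[mask]
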