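"""Taxonomy tree queries, LCA placement and lineage-bin assignment.

The tree follows the NCBI Taxonomy data model: every node carries a
numeric taxid, a parent taxid, a rank label and a scientific name, and
the root is the unique node that is its own parent (conventionally
taxid 1). Marker sequences are placed on the tree by lowest-common-
ancestor (LCA) inference over alignment hits, keeping only hits whose
bitscore lies within a fractional band of the best hit, and LCA results
are rolled up into a fixed, ordered set of lineage bins for
contamination reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxNode",
    "TaxonomyTree",
    "BinSet",
    "OTHER_BIN",
    "UNKNOWN_BIN",
    "DEFAULT_BIN_NAMES",
    "lca_from_hits",
    "assign_bin",
]

#: Reserved report categories; never usable as taxon-bin names.
OTHER_BIN = "Other"
UNKNOWN_BIN = "Unknown"

#: The 19 named lineage bins of the contamination report, in report
#: column order. Together with Other and Unknown they form the 21
#: report categories.
DEFAULT_BIN_NAMES: tuple[str, ...] = (
    "Amoebozoa",
    "Ciliophora",
    "Colpodellida",
    "Cryptophyceae",
    "Dinophyceae",
    "Euglenozoa",
    "Glaucocystophyceae",
    "Haptophyta",
    "Heterolobosea",
    "Opisthokonta",
    "Palpitomonas",
    "Perkinsozoa",
    "Rhizaria",
    "Rhodophyta",
    "Stramenopiles",
    "Viridiplantae",
    "Bacteria",
    "Archaea",
    "Viruses",
)


@dataclass(frozen=True)
class TaxNode:
    """One taxonomy node: taxid, parent taxid, rank label, name."""

    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted taxonomy indexed by taxid.

    Parameters
    ----------
    nodes:
        Iterable of :class:`TaxNode`. Exactly one node must be its own
        parent (the root) and every other parent must be present.
    merged:
        Optional mapping of retired taxids to their current
        replacements (the ``merged.dmp`` convention); lookups through
        :meth:`resolve` follow this mapping.
    """

    def __init__(
        self,
        nodes: Iterable[TaxNode],
        merged: Mapping[int, int] | None = None,
    ) -> None:
        self._nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        if not self._nodes:
            raise ValueError("taxonomy tree has no nodes")
        roots = [n.taxid for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root node, found {roots}")
        self.root: int = roots[0]
        orphans = sorted(
            n.taxid
            for n in self._nodes.values()
            if n.parent not in self._nodes
        )
        if orphans:
            raise ValueError(
                "orphan taxid"
                + ("s " if len(orphans) > 1 else " ")
                + ", ".join(str(t) for t in orphans)
            )
        self.merged: dict[int, int] = dict(merged or {})
        # cycles other than the root self-loop would make lineage() spin
        for taxid in self._nodes:
            self.lineage(taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxid: int) -> TaxNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def resolve(self, taxid: int) -> int:
        """Map a possibly retired taxid onto the current tree.

        Raises ``KeyError`` if the taxid is neither present nor in the
        merged-taxid map.
        """
        if taxid in self._nodes:
            return taxid
        if taxid in self.merged:
            new = self.merged[taxid]
            if new in self._nodes:
                return new
        raise KeyError(f"unknown taxid {taxid}")

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node taxid path, inclusive at both ends."""
        node = self.node(taxid)
        path = [node.taxid]
        seen = {node.taxid}
        while node.taxid != self.root:
            node = self._nodes[node.parent]
            if node.taxid in seen:
                raise ValueError(f"cycle in taxonomy at taxid {node.taxid}")
            seen.add(node.taxid)
            path.append(node.taxid)
        path.reverse()
        return path

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor: the deepest node present on every
        member's root path."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty taxid set is undefined")
        paths = [self.lineage(self.resolve(t)) for t in taxids]
        shortest = min(len(p) for p in paths)
        lca = self.root
        for depth in range(shortest):
            level = {p[depth] for p in paths}
            if len(level) != 1:
                break
            lca = level.pop()
        return lca

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor-or-self with the given rank, or ``None``."""
        for t in reversed(self.lineage(taxid)):
            if self._nodes[t].rank == rank:
                return t
        return None

    def descendants(self, taxid: int) -> set[int]:
        """All taxids whose lineage passes through ``taxid`` (inclusive)."""
        self.node(taxid)
        return {t for t in self._nodes if taxid in set(self.lineage(t))}


@dataclass(frozen=True)
class BinSet:
    """Ordered lineage bins for contamination reporting.

    ``bins`` maps bin name to bin taxid, in report column order. The
    reserved categories ``Other`` and ``Unknown`` are implicit and may
    not be used as taxon-bin names.
    """

    bins: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.bins]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bin names")
        for reserved in (OTHER_BIN, UNKNOWN_BIN):
            if reserved in names:
                raise ValueError(f"bin name {reserved!r} is reserved")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.bins)

    @property
    def column_names(self) -> tuple[str, ...]:
        """All report categories: taxon bins plus Other and Unknown."""
        return self.names + (OTHER_BIN, UNKNOWN_BIN)

    def taxid(self, name: str) -> int:
        for bin_name, taxid in self.bins:
            if bin_name == name:
                return taxid
        raise KeyError(f"unknown bin {name!r}")

    def validate(self, tree: TaxonomyTree) -> None:
        missing = [t for _, t in self.bins if t not in tree]
        if missing:
            raise ValueError(f"bin taxids absent from tree: {missing}")

    @classmethod
    def from_config(cls, path: str | Path) -> "BinSet":
        """Load bins from a plain-text config: one ``name<whitespace>taxid``
        pair per line; '#' starts a comment."""
        pairs: list[tuple[str, int]] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"malformed bin config line: {raw!r}")
            pairs.append((fields[0], int(fields[1])))
        return cls(tuple(pairs))

    def to_config(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{taxid}\n" for name, taxid in self.bins)
        )


def lca_from_hits(
    tree: TaxonomyTree,
    hits: Sequence,
    evalue_max: float = 1e-5,
    top_frac: float = 0.10,
) -> int | None:
    """Place one query on the tree from its alignment hits.

    Hits with E-value above ``evalue_max`` are discarded; of the rest,
    only hits whose bitscore is within ``top_frac`` of the best
    surviving bitscore are retained (the aligner's ``--top`` semantics).
    Returns the LCA taxid of the retained subjects, or ``None`` when no
    hit survives.
    """
    if not 0.0 <= top_frac <= 1.0:
        raise ValueError("top_frac must lie in [0, 1]")
    passing = [h for h in hits if h.evalue <= evalue_max]
    if not passing:
        return None
    best = max(h.bitscore for h in passing)
    floor = (1.0 - top_frac) * best
    retained = [h.subject_taxid for h in passing if h.bitscore >= floor]
    return tree.lca(retained)


def assign_bin(tree: TaxonomyTree, taxid: int | None, bins: BinSet) -> str:
    """Roll a placement up into a lineage-bin name.

    ``None`` (unplaced) maps to ``Unknown``; otherwise the deepest bin
    whose taxid lies on the query's root path wins, and queries on
    branches holding no bin map to ``Other``.
    """
    if taxid is None:
        return UNKNOWN_BIN
    path = tree.lineage(tree.resolve(taxid))
    depth = {t: i for i, t in enumerate(path)}
    best_name = OTHER_BIN
    best_depth = -1
    for name, bin_taxid in bins.bins:
        d = depth.get(bin_taxid, -1)
        if d > best_depth:
            best_depth = d
            best_name = name
    return best_name if best_depth >= 0 else OTHER_BIN
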