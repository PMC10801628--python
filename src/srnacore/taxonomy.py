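"""Taxonomy tree and the taxon group set used for species identification.

The group set mirrors the screened taxa of a biofluid small-RNA study:
the host genus plus the taxonomic trees of potential host parasites and
microbiome members (bacteria, fungi, viruses, archaea and the protist
supergroups).  Each BLAST hit is mapped to the first listed group whose
subtree contains its taxid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import TaxonomyNode, read_taxonomy_table

DEFAULT_TAXON_GROUPS: list[tuple[str, int]] = [
    ("Homo", 9606),
    ("Bacteria", 2),
    ("Fungi", 4751),
    ("Viruses", 10239),
    ("Archaea", 2157),
    ("Amoebozoa", 554915),
    ("Discoba", 2611352),
    ("CRuMs", 2608240),
    ("Metamonada", 2611341),
    ("Sar", 2698737),
    ("Eukaryota incertae sedis", 2683617),
    ("Aphelida", 2316435),
    ("Ichthyosporea", 127916),
    ("Rotosphaerida", 2686024),
    ("other sequences", 28384),
]


class Taxonomy:
    """Rooted taxonomy tree over TaxonomyNode records (root is its own parent)."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {n.taxon_id: n for n in nodes}
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_id not in self.nodes:
                raise ValueError(f"node {n.taxon_id} has unknown parent {n.parent_id}")

    @classmethod
    def from_table(cls, path: str | Path) -> "Taxonomy":
        return cls(read_taxonomy_table(path))

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from root down to (and including) taxid."""
        path = []
        cur = taxid
        while True:
            path.append(cur)
            node = self.nodes[cur]
            if node.parent_id == cur:
                break
            cur = node.parent_id
        return path[::-1]

    def is_descendant(self, taxid: int, ancestor: int) -> bool:
        """True when ancestor lies on taxid's root path (inclusive)."""
        cur = taxid
        while True:
            if cur == ancestor:
                return True
            node = self.nodes[cur]
            if node.parent_id == cur:
                return False
            cur = node.parent_id

    def species_of(self, taxid: int) -> tuple[int, bool]:
        """Lift a taxid to its nearest ancestor of rank 'species'.

        Returns ``(species_taxid, is_species_level)``; taxa with no species
        ancestor (ranks above species) are returned unchanged and flagged
        False.
        """
        cur = taxid
        while True:
            node = self.nodes[cur]
            if node.rank == "species":
                return cur, True
            if node.parent_id == cur:
                return taxid, False
            cur = node.parent_id


@dataclass
class TaxonGroupSet:
    """Ordered (name, root taxid) groups; a hit joins the first containing group."""

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_TAXON_GROUPS)
    )

    def __post_init__(self) -> None:
        ids = [taxid for _, taxid in self.groups]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon group ids must be unique")

    def group_of(self, taxid: int, taxonomy: Taxonomy) -> str | None:
        """Name of the first group whose subtree contains taxid, else None."""
        if taxid not in taxonomy:
            return None
        for name, root in self.groups:
            if root in taxonomy and taxonomy.is_descendant(taxid, root):
                return name
        return None
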