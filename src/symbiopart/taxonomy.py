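"""Taxonomy table loading and lineage queries.

A :class:`TaxonomyTable` is a rooted tree of taxa keyed by integer taxid.
It answers the two questions the transcript source classifier needs:

* clade membership — is the subject of a similarity hit inside the host
  clade (e.g. the insect order Blattodea) or the symbiont clade (the
  protist clade Metamonada)?
* rank resolution — which order / genus does a subject taxon belong to?

Two input dialects are supported: a simple four-column TSV
(``taxid<TAB>parent<TAB>rank<TAB>name``) and the pipe-delimited NCBI dump
pair (``nodes.dmp`` + ``names.dmp``, scientific names only).  Merged or
deleted taxids are not resolved; inputs must be pre-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomy tables or unknown taxids."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyTable:
    """Rooted taxonomy tree with O(depth) lineage queries.

    Invariants (checked at construction): exactly one root (its parent is
    itself), every parent taxid present, no cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        self._validate()
        self._name_index = {n.name: n.taxid for n in self.nodes.values()}

    def _validate(self) -> None:
        if not self.nodes:
            raise TaxonomyError("empty taxonomy")
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise TaxonomyError(
                    f"missing parent {node.parent} of taxid {taxid}"
                )
        # cycle check: walk each node to the root, marking visited
        ok: set[int] = {self.root}
        for taxid in self.nodes:
            path = []
            cur = taxid
            while cur not in ok:
                path.append(cur)
                cur = self.nodes[cur].parent
                if cur in path:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
            ok.update(path)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self._node(taxid).name

    def taxid_of(self, name: str) -> int:
        """Look up a taxid by exact scientific name (convenience for tests)."""
        try:
            return self._name_index[name]
        except KeyError:
            raise TaxonomyError(f"unknown taxon name {name!r}") from None

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-taxon taxid path, inclusive at both ends."""
        self._node(taxid)
        path = [taxid]
        cur = taxid
        while cur != self.root:
            cur = self.nodes[cur].parent
            path.append(cur)
        path.reverse()
        return path

    def in_clade(self, taxid: int, clade_taxid: int) -> bool:
        """True iff *clade_taxid* lies on the lineage of *taxid* (reflexive)."""
        return clade_taxid in self.lineage(taxid)

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The unique lineage node with the given rank label, or None."""
        for anc in self.lineage(taxid):
            if self.nodes[anc].rank == rank:
                return anc
        return None


def _parse_simple_tsv(path: Path) -> list[TaxonNode]:
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxonomyError(
                    f"{path}:{lineno}: non-integer taxid field"
                ) from None
            nodes.append(TaxonNode(taxid, parent, fields[2], fields[3]))
    return nodes


def _parse_ncbi_dump(nodes_path: Path, names_path: Path) -> list[TaxonNode]:
    """Read NCBI-style nodes.dmp / names.dmp (scientific name class only)."""

    def dmp_fields(line: str) -> list[str]:
        return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]

    names: dict[int, str] = {}
    with open(names_path) as fh:
        for line in fh:
            fields = dmp_fields(line)
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[int(fields[0])] = fields[1]
    nodes = []
    with open(nodes_path) as fh:
        for line in fh:
            fields = dmp_fields(line)
            taxid = int(fields[0])
            nodes.append(
                TaxonNode(taxid, int(fields[1]), fields[2],
                          names.get(taxid, f"taxid-{taxid}"))
            )
    return nodes


def load_taxonomy(path: str | Path, dialect: str = "simple-tsv",
                  names_path: str | Path | None = None) -> TaxonomyTable:
    """Load and validate a taxonomy table.

    Parameters
    ----------
    path:
        The taxonomy TSV (simple-tsv dialect) or nodes.dmp (ncbi-dump).
    dialect:
        ``"simple-tsv"`` or ``"ncbi-dump"``.
    names_path:
        names.dmp, required for the ncbi-dump dialect.
    """
    path = Path(path)
    if dialect == "simple-tsv":
        return TaxonomyTable(_parse_simple_tsv(path))
    if dialect == "ncbi-dump":
        if names_path is None:
            raise TaxonomyError("ncbi-dump dialect requires names_path")
        return TaxonomyTable(_parse_ncbi_dump(path, Path(names_path)))
    raise TaxonomyError(f"unknown dialect {dialect!r}")
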