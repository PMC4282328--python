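"""Ranked taxonomies and training-file input/output.

The classifier's reference database is described by two plain-text files in
the style used by k-mer classifier training sets:

* a FASTA file whose description lines carry a semicolon-delimited lineage
  from the root rank down to the leaf, e.g.
  ``>AB123 Metazoa;Arthropoda;Insecta;Diptera;Culicidae;Aedes``;
* a taxonomy file with one node per line in the form
  ``taxid*name*parentTaxid*depth*rank``, root first, root parent ``-1``.

Lineage ranks are assigned positionally from an ordered rank list
(kingdom → species by default).  Ranks missing from a source classification
are represented by explicit placeholder names ``undef_<parentName>`` so that
every lineage is a complete path through the tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical rank order, most inclusive first.  "species" is carried in
#: lineages but is never a trained assignment rank.
DEFAULT_RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Prefix marking a placeholder taxon standing in for a missing rank.
UNDEF_PREFIX = "undef_"

ROOT_PARENT = -1


class TaxonomyError(ValueError):
    """Malformed lineage, taxonomy file, or inconsistent tree."""


def is_placeholder(name: str) -> bool:
    """True for placeholder taxa such as ``undef_Insecta``."""
    return name.startswith(UNDEF_PREFIX)


def placeholder_for(parent_name: str) -> str:
    return UNDEF_PREFIX + parent_name


@dataclass(frozen=True)
class Lineage:
    """Ordered (rank, name) path from the root rank to a leaf.

    Ranks strictly descend in inclusiveness and never repeat; names may be
    placeholders for ranks absent from the source classification.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise TaxonomyError("lineage must have at least one entry")
        ranks = [r for r, _ in self.entries]
        if len(set(ranks)) != len(ranks):
            raise TaxonomyError(f"repeated rank in lineage: {ranks}")

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    @property
    def leaf(self) -> str:
        return self.entries[-1][1]

    def name_at(self, rank: str) -> str | None:
        for r, n in self.entries:
            if r == rank:
                return n
        return None

    def has_named(self, rank: str) -> bool:
        """True iff `rank` carries a real (non-placeholder) name."""
        name = self.name_at(rank)
        return name is not None and not is_placeholder(name)

    def truncate(self, rank: str) -> "Lineage":
        """Lineage cut at `rank` (inclusive)."""
        out = []
        for r, n in self.entries:
            out.append((r, n))
            if r == rank:
                return Lineage(tuple(out))
        raise TaxonomyError(f"rank {rank!r} not present in lineage")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReferenceRecord:
    """One identified barcode sequence with its lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    name: str
    parent: int
    depth: int
    rank: str


class TaxonomyTree:
    """Rooted tree of taxa with integer ids.

    Taxids are deterministic: the root is 0 and the remaining nodes are
    numbered depth-first with children visited in lexicographic name order,
    so identical record sets always yield identical taxonomies.
    """

    def __init__(self, nodes: Sequence[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.taxid: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise TaxonomyError("duplicate taxid in taxonomy")
        roots = [n for n in nodes if n.parent == ROOT_PARENT or n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {n.taxid: [] for n in nodes}
        for n in nodes:
            if n is not self.root:
                if n.parent not in self.nodes:
                    raise TaxonomyError(f"node {n.name!r} has unknown parent {n.parent}")
                self._children[n.parent].append(n.taxid)
        # reachability + depth consistency
        seen: set[int] = set()
        stack = [self.root.taxid]
        while stack:
            tid = stack.pop()
            seen.add(tid)
            node = self.nodes[tid]
            expected = 0 if node is self.root else self.nodes[node.parent].depth + 1
            if node.depth != expected:
                raise TaxonomyError(
                    f"node {node.name!r} has depth {node.depth}, expected {expected}"
                )
            stack.extend(self._children[tid])
        if seen != set(self.nodes):
            raise TaxonomyError("taxonomy contains nodes unreachable from the root")

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, taxid: int) -> list[TaxNode]:
        return [self.nodes[t] for t in self._children[taxid]]

    def find(self, name: str, parent: int) -> TaxNode | None:
        for t in self._children[parent]:
            if self.nodes[t].name == name:
                return self.nodes[t]
        return None

    def path_exists(self, lineage: Lineage) -> bool:
        node = self.root
        if lineage.entries[0][1] != node.name:
            return False
        for rank, name in lineage.entries[1:]:
            nxt = self.find(name, node.taxid)
            if nxt is None or nxt.rank != rank:
                return False
            node = nxt
        return True

    def lineage_of(self, taxid: int) -> Lineage:
        """Reconstruct a lineage by walking parents up to the root."""
        path = []
        node = self.nodes[taxid]
        while True:
            path.append((node.rank, node.name))
            if node is self.root:
                break
            node = self.nodes[node.parent]
        return Lineage(tuple(reversed(path)))

    def iter_preorder(self) -> Iterable[TaxNode]:
        stack = [self.root.taxid]
        while stack:
            tid = stack.pop()
            yield self.nodes[tid]
            stack.extend(reversed(self._children[tid]))


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to T (inputs vary; COI is DNA)."""
    return seq.upper().replace("U", "T")


def parse_lineage_header(
    header: str, ranks: Sequence[str] = DEFAULT_RANKS
) -> tuple[str, Lineage]:
    """Split a FASTA description line into (id, Lineage).

    The line is ``identifier whitespace name;name;...`` with names mapped
    positionally onto `ranks`, root first.  Placeholder names pass through
    unchanged.
    """
    text = header[1:] if header.startswith(">") else header
    parts = text.strip().split(None, 1)
    if len(parts) < 2 or not parts[1].strip():
        raise TaxonomyError(f"no lineage in header {header!r}")
    ident, lineage_text = parts[0], parts[1].strip()
    names = [n.strip() for n in lineage_text.split(";") if n.strip()]
    if not names:
        raise TaxonomyError(f"no lineage in header {header!r}")
    if len(names) > len(ranks):
        raise TaxonomyError(
            f"{len(names)} lineage names exceed {len(ranks)} configured ranks "
            f"in header {header!r}"
        )
    return ident, Lineage(tuple(zip(ranks, names)))


def format_lineage(lineage: Lineage) -> str:
    return ";".join(lineage.names)


def build_tree(records: Sequence[ReferenceRecord]) -> TaxonomyTree:
    """Assemble the taxonomy implied by the records' lineages.

    Taxid assignment is deterministic (preorder, children in lexicographic
    name order), so shuffled inputs produce identical trees.
    """
    if not records:
        raise TaxonomyError("empty training set")
    root_names = {r.lineage.entries[0][1] for r in records}
    if len(root_names) != 1:
        raise TaxonomyError(f"lineages disagree on the root: {sorted(root_names)}")
    root_rank = records[0].lineage.entries[0][0]

    # nested dict keyed by name holding (rank, children)
    def new_node(rank: str) -> dict:
        return {"rank": rank, "children": {}}

    root_name = root_names.pop()
    root = new_node(root_rank)
    for rec in records:
        node = root
        for rank, name in rec.lineage.entries[1:]:
            child = node["children"].get(name)
            if child is None:
                child = new_node(rank)
                node["children"][name] = child
            elif child["rank"] != rank:
                raise TaxonomyError(
                    f"taxon {name!r} appears with conflicting ranks "
                    f"{child['rank']!r} and {rank!r} under the same parent"
                )
            node = child

    nodes: list[TaxNode] = []
    counter = iter(range(10**9))

    def emit(name: str, node: dict, parent: int, depth: int) -> None:
        taxid = next(counter)
        nodes.append(TaxNode(taxid, name, parent, depth, node["rank"]))
        for child_name in sorted(node["children"]):
            emit(child_name, node["children"][child_name], taxid, depth + 1)

    emit(root_name, root, ROOT_PARENT, 0)
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# Training-file IO


def write_training_files(
    records: Sequence[ReferenceRecord],
    tree: TaxonomyTree,
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    """Write the FASTA + taxonomy pair; ``read_training_files`` inverts it."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=format_lineage(rec.lineage))
        for rec in records
    ]
    with open(fasta_path, "w", newline="\n") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    with open(taxonomy_path, "w", newline="\n") as handle:
        for node in tree.iter_preorder():
            handle.write(
                f"{node.taxid}*{node.name}*{node.parent}*{node.depth}*{node.rank}\n"
            )


def read_taxonomy_file(taxonomy_path: str | Path) -> TaxonomyTree:
    nodes: list[TaxNode] = []
    with open(taxonomy_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("*")
            if len(fields) != 5:
                raise TaxonomyError(
                    f"{taxonomy_path}:{lineno}: expected 5 '*'-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                taxid, parent, depth = int(fields[0]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise TaxonomyError(f"{taxonomy_path}:{lineno}: {exc}") from exc
            nodes.append(TaxNode(taxid, fields[1], parent, depth, fields[4]))
    if not nodes:
        raise TaxonomyError(f"{taxonomy_path}: empty taxonomy file")
    return TaxonomyTree(nodes)


def read_training_files(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> tuple[list[ReferenceRecord], TaxonomyTree]:
    tree = read_taxonomy_file(taxonomy_path)
    records: list[ReferenceRecord] = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        ident, lineage = parse_lineage_header(seq_rec.description, ranks)
        if not tree.path_exists(lineage):
            raise TaxonomyError(
                f"{fasta_path}: lineage of {ident!r} names a taxon absent "
                f"from {taxonomy_path}"
            )
        records.append(
            ReferenceRecord(ident, normalize_sequence(str(seq_rec.seq)), lineage)
        )
    return records, tree


def read_query_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Plain query FASTA → list of (id, normalized sequence)."""
    return [
        (rec.id, normalize_sequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]


def format_fasta(records: Sequence[ReferenceRecord]) -> str:
    buf = io.StringIO()
    SeqIO.write(
        [
            SeqRecord(Seq(r.sequence), id=r.id, description=format_lineage(r.lineage))
            for r in records
        ],
        buf,
        "fasta",
    )
    return buf.getvalue()
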