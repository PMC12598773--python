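"""Reference packages: tree + amino-acid alignment + taxonomy for one marker gene.

A reference package is the fixed scaffold that metagenomic reads are placed
onto: a rooted phylogeny with branch lengths in substitutions/site, the
alignment its leaves were inferred from, and a taxonomy path (e.g.
``SAR11;Ia;Ia.1``) for every leaf.  Edges get stable integer identifiers in
post-order of the rooted tree, and every edge is labeled with the longest
common taxonomic prefix of the leaves distal to it — the label a read
placed on that edge inherits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

from .substitution import AMINO_ACIDS, encode_aa

#: characters accepted in reference alignments besides the 20 amino acids
_GAP_CHARS = set("-.Xx*")


class ReferencePackageError(ValueError):
    """Raised when a reference package fails validation."""


@dataclass
class ReferenceTree:
    """Rooted reference phylogeny with post-order edge indexing.

    Nodes are stored in post-order; the root is the last node.  Every
    non-root node ``i`` defines edge ``i`` to its parent, so edge ids are
    0..n_nodes-2 and are stable under serialize/parse round trips (child
    order is preserved in newick).
    """

    parent: np.ndarray            # parent node index per node (-1 for root)
    branch_length: np.ndarray     # substitutions/site, edge above each node
    children: list[list[int]]     # child node indices per node
    leaf_labels: dict[int, str]   # node index -> leaf label
    _dendropy: dendropy.Tree = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def distal_leaves(self, edge_id: int) -> list[str]:
        """Labels of all leaves on the far (non-root) side of an edge."""
        out: list[str] = []
        stack = [edge_id]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(self.leaf_labels[n])
            stack.extend(self.children[n])
        return out

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "ReferenceTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        leaf_labels: dict[int, str] = {}
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                length = node.edge.length
                if length is None:
                    raise ReferencePackageError(
                        "branch length missing on an edge; branch lengths are required")
                if not np.isfinite(length) or length < 0:
                    raise ReferencePackageError(
                        f"invalid branch length {length!r}: must be finite and >= 0")
                blen[i] = float(length)
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ReferencePackageError("unlabeled leaf in reference tree")
                leaf_labels[i] = node.taxon.label
        for i, p in enumerate(parent):
            if p >= 0:
                children[p].append(i)
        labels = list(leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise ReferencePackageError("duplicate leaf labels in reference tree")
        return cls(parent=parent, branch_length=blen, children=children,
                   leaf_labels=leaf_labels, _dendropy=tree)

    def newick(self, edge_numbers: bool = False) -> str:
        """Serialize to newick; with ``edge_numbers`` emit jplace {N} tags."""
        out = io.StringIO()
        labels = {v: k for k, v in self.leaf_labels.items()}

        def write(node: int) -> None:
            if self.children[node]:
                out.write("(")
                for k, ch in enumerate(self.children[node]):
                    if k:
                        out.write(",")
                    write(ch)
                out.write(")")
            else:
                out.write(self.leaf_labels[node])
            if node != self.root:
                out.write(f":{self.branch_length[node]:.12g}")
                if edge_numbers:
                    out.write(f"{{{node}}}")

        write(self.root)
        out.write(";")
        return out.getvalue()


@dataclass
class ReferenceAlignment:
    """Gapped amino-acid alignment over the reference leaves."""

    sequences: dict[str, str]
    n_columns: int

    @classmethod
    def from_fasta(cls, text: str) -> "ReferenceAlignment":
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise ReferencePackageError("empty reference alignment")
        seqs: dict[str, str] = {}
        for rec in records:
            s = str(rec.seq).upper()
            bad = set(s) - set(AMINO_ACIDS) - _GAP_CHARS
            if bad:
                raise ReferencePackageError(
                    f"invalid characters {sorted(bad)} in alignment of {rec.id}")
            seqs[rec.id] = s
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ReferencePackageError(
                f"alignment rows have unequal lengths: {sorted(lengths)}")
        return cls(sequences=seqs, n_columns=lengths.pop())

    def to_fasta(self) -> str:
        return "".join(f">{name}\n{seq}\n" for name, seq in self.sequences.items())

    def encoded(self, label: str) -> np.ndarray:
        """Integer state codes for one row; gaps/ambiguity -> -1."""
        return encode_aa(self.sequences[label])


@dataclass
class TaxonomyMap:
    """Leaf label -> ordered clade path (tuple of rank names)."""

    paths: dict[str, tuple[str, ...]]

    @classmethod
    def from_tsv(cls, text: str) -> "TaxonomyMap":
        paths: dict[str, tuple[str, ...]] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReferencePackageError(
                    f"taxonomy line {lineno}: expected 2 tab-separated columns")
            label, path = parts
            ranks = tuple(r.strip() for r in path.split(";") if r.strip())
            if not ranks:
                raise ReferencePackageError(f"taxonomy line {lineno}: empty path")
            paths[label] = ranks
        if not paths:
            raise ReferencePackageError("empty taxonomy table")
        first_ranks = {p[0] for p in paths.values()}
        if len(first_ranks) != 1:
            raise ReferencePackageError(
                f"taxonomy paths disagree on the first rank: {sorted(first_ranks)}")
        return cls(paths=paths)

    def to_tsv(self) -> str:
        return "".join(f"{label}\t{';'.join(path)}\n"
                       for label, path in self.paths.items())


#: EdgeLabeling: edge_id -> clade path (tuple), possibly truncated
EdgeLabeling = dict[int, tuple[str, ...]]


def _common_prefix(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
    out = []
    for x, y in zip(a, b):
        if x != y:
            break
        out.append(x)
    return tuple(out)


def label_edges(tree: ReferenceTree, tax: TaxonomyMap) -> EdgeLabeling:
    """Label every edge with the longest common taxonomic prefix of its
    distal leaves (terminal edges get the leaf's full path)."""
    prefix: dict[int, tuple[str, ...]] = {}
    for node in range(tree.n_nodes):  # nodes already in post-order
        if tree.is_leaf(node):
            label = tree.leaf_labels[node]
            if label not in tax.paths:
                raise ReferencePackageError(f"leaf {label} missing from taxonomy")
            prefix[node] = tax.paths[label]
        else:
            acc = prefix[tree.children[node][0]]
            for ch in tree.children[node][1:]:
                acc = _common_prefix(acc, prefix[ch])
            prefix[node] = acc
    return {e: prefix[e] for e in range(tree.n_edges)}


@dataclass
class ReferencePackage:
    """Validated bundle of tree, alignment, taxonomy and edge labels."""

    gene: str
    tree: ReferenceTree
    alignment: ReferenceAlignment
    taxonomy: TaxonomyMap
    labeling: EdgeLabeling

    @property
    def gene_length(self) -> int:
        """Marker gene length in alignment columns (used as L_g)."""
        return self.alignment.n_columns

    def encoded_leaf_matrix(self) -> tuple[np.ndarray, dict[int, int]]:
        """(n_leaves x n_columns) int matrix of leaf states plus a map
        node index -> row."""
        leaves = self.tree.leaves
        rows = {node: i for i, node in enumerate(leaves)}
        mat = np.stack([self.alignment.encoded(self.tree.leaf_labels[n])
                        for n in leaves])
        return mat, rows


def _root_on_outgroup(tree: dendropy.Tree, outgroup_leaves: list[str]) -> dendropy.Tree:
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(l) for l in outgroup_leaves]
    if any(t is None for t in taxa):
        missing = [l for l, t in zip(outgroup_leaves, taxa) if t is None]
        raise ReferencePackageError(f"outgroup leaves not in tree: {missing}")
    mrca = tree.mrca(taxa=taxa)
    seed = tree.seed_node
    if mrca is seed:
        raise ReferencePackageError(
            "outgroup is not monophyletic away from the root; cannot root")
    if mrca.parent_node is seed and len(seed.child_nodes()) == 2:
        return tree  # already rooted on the outgroup edge
    edge = mrca.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=False)
    return tree


def parse_reference_package(tree_text: str, alignment_text: str,
                            taxonomy_text: str, gene: str = "marker",
                            outgroup: str | None = None) -> ReferencePackage:
    """Parse and cross-validate the three reference-package files.

    Parameters
    ----------
    outgroup:
        Name of the taxonomy clade to root on: the tree is rerooted on the
        edge above the MRCA of all leaves whose path contains this rank.
        If omitted, the newick must already be rooted (binary root).
    """
    try:
        dtree = dendropy.Tree.get(data=tree_text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ReferencePackageError(f"unparseable newick: {exc}") from exc
    alignment = ReferenceAlignment.from_fasta(alignment_text)
    taxonomy = TaxonomyMap.from_tsv(taxonomy_text)

    if outgroup is not None:
        og = [l for l, path in taxonomy.paths.items() if outgroup in path]
        if not og:
            raise ReferencePackageError(f"no taxonomy path contains clade {outgroup!r}")
        dtree = _root_on_outgroup(dtree, og)
    elif len(dtree.seed_node.child_nodes()) > 2:
        raise ReferencePackageError(
            "tree is unrooted (multifurcating root) and no outgroup was designated")

    tree = ReferenceTree.from_dendropy(dtree)
    leaf_set = set(tree.leaf_labels.values())
    for label in sorted(leaf_set - set(alignment.sequences)):
        raise ReferencePackageError(f"leaf {label} lacks sequence in alignment")
    for label in sorted(leaf_set - set(taxonomy.paths)):
        raise ReferencePackageError(f"leaf {label} lacks taxonomy path")
    extra = set(alignment.sequences) - leaf_set
    if extra:
        raise ReferencePackageError(
            f"alignment rows not on the tree: {sorted(extra)[:5]}")

    labeling = label_edges(tree, taxonomy)
    return ReferencePackage(gene=gene, tree=tree, alignment=alignment,
                            taxonomy=taxonomy, labeling=labeling)
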