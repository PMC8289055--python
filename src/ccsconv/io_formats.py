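"""Readers, writers and core containers for alignments, trees and study designs.

The pipeline works with three kinds of inputs: per-gene multiple alignments
(FASTA or PHYLIP), a rooted species tree with branch lengths (Newick), and a
tab-separated design file assigning each taxon to one of five groups —
``outgroup``, two foreground clusters (``fg1``, ``fg2``) and two background
control clusters (``bg1``, ``bg2``).  Taxon names are matched
case-sensitively across the three inputs: silent case-folding hides data
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: characters treated as missing data downstream (gap and unknown)
MISSING = "-X"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + MISSING)
#: IUPAC nucleotide codes, for codon alignments fed to the rates module
NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVN" + "-")

DESIGN_GROUPS = ("outgroup", "fg1", "fg2", "bg1", "bg2")


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, bad characters, duplicate taxa."""


class DesignError(ValueError):
    """Malformed species design: overlapping groups, missing outgroup."""


class TreeError(ValueError):
    """Malformed Newick tree."""


@dataclass
class OrthologAlignment:
    """One gene's aligned sequences, keyed by taxon.

    Sequences are upper-case strings over the amino-acid alphabet
    (ACDEFGHIKLMNPQRSTVWY plus gap ``-`` and unknown ``X``) or, with
    ``alphabet="nucleotide"``, IUPAC nucleotides.  All rows have identical
    length and taxon names are unique.
    """

    gene_id: str
    taxa: list[str]
    sequences: dict[str, str]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequences[self.taxa[0]]) if self.taxa else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError(f"{self.gene_id}: duplicate taxon names")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET
        ref_len = None
        for taxon in self.taxa:
            seq = self.sequences[taxon]
            if ref_len is None:
                ref_len = len(seq)
            elif len(seq) != ref_len:
                raise AlignmentError(
                    f"{self.gene_id}: sequence for '{taxon}' has length "
                    f"{len(seq)}, expected {ref_len}"
                )
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise AlignmentError(
                        f"{self.gene_id}: illegal character {ch!r} for taxon "
                        f"'{taxon}' at column {pos + 1}"
                    )

    def column(self, i: int) -> dict[str, str]:
        """Residues of 1-based column *i* keyed by taxon."""
        return {t: self.sequences[t][i - 1] for t in self.taxa}

    def subset(self, taxa: list[str]) -> "OrthologAlignment":
        missing = [t for t in taxa if t not in self.sequences]
        if missing:
            raise AlignmentError(f"{self.gene_id}: taxa not in alignment: {missing}")
        return OrthologAlignment(
            self.gene_id, list(taxa), {t: self.sequences[t] for t in taxa}, self.alphabet
        )


@dataclass
class SpeciesDesign:
    """Symmetric experimental layout: outgroup O, foreground clusters P1/P2
    (e.g. placental mammals and syngnathids), background control clusters
    A1/A2 (their aplacental relatives).  Groups are pairwise disjoint and
    clusters hold at least two taxa each."""

    outgroup: str
    foreground_clusters: tuple[list[str], list[str]]
    background_clusters: tuple[list[str], list[str]]

    def __post_init__(self) -> None:
        groups = [
            [self.outgroup],
            *self.foreground_clusters,
            *self.background_clusters,
        ]
        seen: set[str] = set()
        for g in groups:
            for t in g:
                if t in seen:
                    raise DesignError(f"taxon '{t}' assigned to more than one group")
                seen.add(t)
        for cluster in (*self.foreground_clusters, *self.background_clusters):
            if len(cluster) < 2:
                raise DesignError("each cluster needs at least 2 taxa")

    @property
    def foreground_taxa(self) -> list[str]:
        return [*self.foreground_clusters[0], *self.foreground_clusters[1]]

    @property
    def background_taxa(self) -> list[str]:
        return [*self.background_clusters[0], *self.background_clusters[1]]

    @property
    def all_taxa(self) -> list[str]:
        return [self.outgroup, *self.foreground_taxa, *self.background_taxa]

    def swapped(self) -> "SpeciesDesign":
        """Design with foreground and background roles exchanged."""
        return SpeciesDesign(
            self.outgroup, self.background_clusters, self.foreground_clusters
        )


class PhyloTree:
    """Rooted phylogeny with branch lengths in expected substitutions/site.

    Thin array-backed structure built from (and written back to) Newick via
    dendropy.  Nodes are indexed in preorder with the root at index 0;
    internal nodes get stable identifiers ``N0, N1, ...`` in preorder unless
    the Newick string labels them.
    """

    def __init__(
        self,
        parent: list[int],
        lengths: list[float],
        names: list[str | None],
        labels: list[str],
    ):
        self.parent = list(parent)
        self.lengths = [float(x) for x in lengths]
        self.names = list(names)  # leaf name or None for internal nodes
        self.labels = list(labels)  # unique id for every node
        self.children: list[list[int]] = [[] for _ in parent]
        for i, p in enumerate(parent):
            if p >= 0:
                self.children[p].append(i)
        self._leaf_index = {
            n: i for i, n in enumerate(self.names) if n is not None
        }
        if len(self._leaf_index) != sum(1 for n in self.names if n is not None):
            raise TreeError("duplicate leaf names in tree")
        if any(x < 0 for x in self.lengths[1:]):
            raise TreeError("negative branch length")

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        parent: list[int] = []
        lengths: list[float] = []
        names: list[str | None] = []
        labels: list[str] = []
        index: dict[int, int] = {}
        n_internal = 0
        missing_lengths = False
        for node in dtree.preorder_node_iter():
            i = len(parent)
            index[id(node)] = i
            parent.append(index[id(node.parent_node)] if node.parent_node else -1)
            if node.edge.length is None:
                lengths.append(0.0)
                if node.parent_node is not None:
                    missing_lengths = True
            else:
                lengths.append(float(node.edge.length))
            if node.is_leaf():
                if node.taxon is None:
                    raise TreeError("leaf without a name")
                names.append(node.taxon.label.replace(" ", "_"))
                labels.append(names[-1])
            else:
                names.append(None)
                labels.append(node.label if node.label else f"N{n_internal}")
                n_internal += 1
        if missing_lengths:
            logger.warning("tree has branches without lengths; set to 0")
        return cls(parent, lengths, names, labels)

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_names(self) -> list[str]:
        return [n for n in self.names if n is not None]

    def leaf(self, name: str) -> int:
        try:
            return self._leaf_index[name]
        except KeyError:
            raise TreeError(f"taxon '{name}' is not a leaf of the tree") from None

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes))

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def mrca(self, names: list[str]) -> int:
        """Index of the most recent common ancestor of the named leaves."""
        paths = []
        for name in names:
            i = self.leaf(name)
            path = []
            while i >= 0:
                path.append(i)
                i = self.parent[i]
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor = largest preorder index on root path
        i = self.leaf(names[0])
        while i not in common:
            i = self.parent[i]
        return i

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent, self.lengths, self.names, self.labels)

    # -- output ----------------------------------------------------------

    def _newick_node(self, i: int, with_lengths: bool) -> str:
        if self.is_leaf(i):
            s = self.names[i]
        else:
            s = "(" + ",".join(
                self._newick_node(c, with_lengths) for c in self.children[i]
            ) + ")"
        if with_lengths and self.parent[i] >= 0:
            s += f":{self.lengths[i]:g}"
        return s

    def to_newick(self, with_lengths: bool = True) -> str:
        return self._newick_node(self.root, with_lengths) + ";"


# -- file-level operations ------------------------------------------------


def read_alignment(
    path: str | Path, format: str = "fasta", alphabet: str = "protein"
) -> OrthologAlignment:
    """Read one gene alignment (``fasta`` or ``phylip``; PHYLIP may be
    sequential or interleaved).  Residues are upper-cased; the gene id
    defaults to the file stem."""
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no FASTA records")
        taxa = [r.id for r in records]
        seqs = {r.id: str(r.seq).upper() for r in records}
    elif format == "phylip":
        msa = None
        for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                msa = AlignIO.read(str(path), dialect)
                break
            except ValueError:
                continue
        if msa is None:
            raise AlignmentError(f"{path}: could not parse as PHYLIP")
        taxa = [r.id for r in msa]
        seqs = {r.id: str(r.seq).upper() for r in msa}
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    return OrthologAlignment(path.stem, taxa, seqs, alphabet)


def write_alignment(
    aln: OrthologAlignment, path: str | Path, format: str = "fasta"
) -> None:
    path = Path(path)
    records = [
        SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa
    ]
    if format == "fasta":
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.seq}\n")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format: {format!r}")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; branches without lengths become 0 with a
    logged warning."""
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_design(path: str | Path) -> SpeciesDesign:
    """Read a two-column TSV ``taxon<TAB>group`` with groups in
    {outgroup, fg1, fg2, bg1, bg2}."""
    groups: dict[str, list[str]] = {g: [] for g in DESIGN_GROUPS}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DesignError(f"{path}:{lineno}: expected 'taxon<TAB>group'")
        taxon, group = parts[0].strip(), parts[1].strip()
        if group not in groups:
            raise DesignError(
                f"{path}:{lineno}: unknown group {group!r}; "
                f"expected one of {DESIGN_GROUPS}"
            )
        groups[group].append(taxon)
    if len(groups["outgroup"]) != 1:
        raise DesignError(
            f"{path}: need exactly one outgroup row, found {len(groups['outgroup'])}"
        )
    return SpeciesDesign(
        groups["outgroup"][0],
        (groups["fg1"], groups["fg2"]),
        (groups["bg1"], groups["bg2"]),
    )


def write_design(design: SpeciesDesign, path: str | Path) -> None:
    lines = [f"{design.outgroup}\toutgroup"]
    for name, cluster in zip(
        ("fg1", "fg2", "bg1", "bg2"),
        (*design.foreground_clusters, *design.background_clusters),
    ):
        lines += [f"{t}\t{name}" for t in cluster]
    Path(path).write_text("\n".join(lines) + "\n")
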