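"""Readers, writers and core containers shared by every pipeline stage.

Coordinate convention: everything in memory is 0-based half-open; GFF3 is
1-based inclusive and is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import gffutils

log = logging.getLogger("genefam")

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent records."""


# ---------------------------------------------------------------------------
# sequence containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence (protein or nucleotide)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A located, stranded, exon-structured gene.

    ``span`` and ``exons`` are 0-based half-open genomic intervals; ``exons``
    are sorted by start and disjoint.  ``rank`` is the 0-based position of the
    gene among all annotated genes on its chromosome ordered by start.
    ``cds`` is the spliced coding sequence in transcription order.
    """

    gene_id: str
    chromosome: str
    span: tuple[int, int]
    strand: str
    exons: list[tuple[int, int]]
    cds: str = ""
    rank: int = -1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        s, e = self.span
        if not 0 <= s < e:
            raise FormatError(f"{self.gene_id}: bad span {self.span}")
        prev_end = None
        for (a, b) in self.exons:
            if not (s <= a < b <= e):
                raise FormatError(f"{self.gene_id}: exon [{a},{b}) outside span {self.span}")
            if prev_end is not None and a < prev_end:
                raise FormatError(f"{self.gene_id}: overlapping or unsorted exons")
            prev_end = b
        if self.cds and len(self.cds) != sum(b - a for a, b in self.exons):
            raise FormatError(f"{self.gene_id}: cds length != sum of exon lengths")

    @property
    def exon_lengths_tx_order(self) -> list[int]:
        lens = [b - a for a, b in self.exons]
        return lens if self.strand == "+" else lens[::-1]


@dataclass
class GenomeBundle:
    """A genome with its annotation and proteome."""

    genome_id: str
    chromosomes: dict[str, int]
    genes: list[GeneModel]
    proteins: dict[str, SequenceRecord]
    chromosome_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise FormatError(f"{g.gene_id}: unknown chromosome {g.chromosome}")
        known = {g.gene_id for g in self.genes}
        for pid in self.proteins:
            if pid not in known:
                raise FormatError(f"protein {pid} has no gene model")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate_cds(self) -> None:
        """Assert translate(cds) == stored protein for every gene with both."""
        for g in self.genes:
            if g.gene_id in self.proteins and g.cds:
                prot = translate(g.cds)
                if prot != self.proteins[g.gene_id].residues:
                    raise FormatError(f"{g.gene_id}: CDS translation disagrees with stored protein")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file; ids are the first whitespace token of the header."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, wrap: int = 60) -> None:
    bio = []
    for r in records:
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def compute_ranks(genes: list[GeneModel]) -> None:
    """Assign per-chromosome 0-based ranks ordered by start coordinate."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.span[0], g.gene_id))
        for i, g in enumerate(members):
            g.rank = i


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon features of a GFF3 file into GeneModels.

    GFF3 1-based inclusive coordinates become 0-based half-open.  When a gene
    carries several mRNAs the one with the longest summed exon length is kept
    (with a warning).  Ranks are computed per chromosome.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            raise FormatError(f"gene {gene.id} has no mRNA child")
        best, best_len = None, -1
        for m in mrnas:
            exlen = sum(e.end - e.start + 1 for e in db.children(m, featuretype="exon"))
            if exlen > best_len:
                best, best_len = m, exlen
        if len(mrnas) > 1:
            log.warning("gene %s has %d mRNAs; keeping longest CDS model %s",
                        gene.id, len(mrnas), best.id)
        exons = []
        for e in db.children(best, featuretype="exon", order_by="start"):
            exons.append((e.start - 1, e.end))
        span = (gene.start - 1, gene.end)
        for a, b in exons:
            if not (span[0] <= a < b <= span[1]):
                raise FormatError(f"gene {gene.id}: exon [{a},{b}) outside gene span")
        gm = GeneModel(gene_id=gene.id, chromosome=gene.seqid, span=span,
                       strand=gene.strand, exons=exons)
        genes.append(gm)
    compute_ranks(genes)
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike,
               chromosomes: dict[str, int] | None = None) -> None:
    """Emit gene/mRNA/exon/CDS rows, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chromosomes:
            for name, length in chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.span[0], g.gene_id)):
            s, e = g.span[0] + 1, g.span[1]
            fh.write(f"{g.chromosome}\tgenefam\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.chromosome}\tgenefam\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(f"{g.chromosome}\tgenefam\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.exon{i};Parent={mid}\n")
                fh.write(f"{g.chromosome}\tgenefam\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                         f"ID={mid}.cds{i};Parent={mid}\n")


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(gene: GeneModel, chrom_seq: str | SequenceRecord) -> str:
    """Splice exons in genomic order; reverse-complement on the minus strand."""
    seq = chrom_seq.residues if isinstance(chrom_seq, SequenceRecord) else chrom_seq
    for a, b in gene.exons:
        if b > len(seq):
            raise FormatError(f"{gene.gene_id}: exon [{a},{b}) beyond chromosome end {len(seq)}")
    spliced = "".join(seq[a:b] for a, b in gene.exons)
    return reverse_complement(spliced) if gene.strand == "-" else spliced


def translate(cds: str) -> str:
    """Standard-code translation; a single terminal stop is stripped."""
    if len(cds) % 3:
        raise FormatError(f"CDS length {len(cds)} not a multiple of 3")
    if not cds:
        return ""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise FormatError(f"internal stop codon at protein position {prot.index('*')}")
    return prot


# ---------------------------------------------------------------------------
# trees and newick
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an (un)rooted phylogeny; ``support`` is a bootstrap percent."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree held as an arbitrarily rooted TreeNode.

    The root is a formal device: a trifurcation for trees of >=3 leaves.
    Bipartition supports live on internal nodes (the edge above each node).
    """

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    # -- bipartitions -------------------------------------------------------
    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map canonical bipartition -> internal node whose edge induces it.

        A bipartition is canonicalized as the frozenset of leaf names on the
        side *not* containing the lexicographically smallest leaf.
        """
        all_leaves = sorted(self.leaf_names())
        anchor = all_leaves[0]
        full = set(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(full) - 1:
                side = below if anchor not in below else full - below
                out[frozenset(side)] = node
            return below

        walk(self.root)
        return out

    # -- patristic distances ------------------------------------------------
    def patristic(self, a: str, b: str) -> float:
        parent: dict[int, tuple[TreeNode | None, float]] = {}
        nodes: dict[str, TreeNode] = {}

        def walk(node: TreeNode, par: TreeNode | None) -> None:
            parent[id(node)] = (par, node.length)
            if node.is_leaf:
                nodes[node.name] = node
            for c in node.children:
                walk(c, node)

        walk(self.root, None)
        if a not in nodes or b not in nodes:
            raise KeyError(f"leaf not in tree: {a if a not in nodes else b}")

        def path_to_root(n: TreeNode) -> list[tuple[int, float]]:
            out = []
            cur: TreeNode | None = n
            while cur is not None:
                par, ln = parent[id(cur)]
                out.append((id(cur), ln))
                cur = par
            return out

        pa = path_to_root(nodes[a])
        pb = path_to_root(nodes[b])
        ids_a = {i for i, _ in pa}
        common = None
        for i, _ in pb:
            if i in ids_a:
                common = i
                break
        dist = 0.0
        for i, ln in pa:
            if i == common:
                break
            dist += ln
        for i, ln in pb:
            if i == common:
                break
            dist += ln
        return dist


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}:{node.length:.6g}"


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    """Serialize with >=6 significant digits and supports as node labels."""
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    with open(path, "w") as fh:
        fh.write(f"({inner});\n")


def newick_string(tree: PhyloTree) -> str:
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    return f"({inner});"


def read_newick(path_or_string: str | os.PathLike) -> PhyloTree:
    """Parse newick (via Bio.Phylo); internal node labels become supports."""
    text = None
    p = str(path_or_string)
    if "(" in p and ";" in p:
        text = p
    else:
        with open(p) as fh:
            text = fh.read()
    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as tf:
        tf.write(text)
        tmp = tf.name
    try:
        try:
            btree = Phylo.read(tmp, "newick")
        except Exception as exc:  # Bio raises various parser errors
            raise FormatError(f"malformed newick: {exc}") from exc
    finally:
        os.unlink(tmp)

    def convert(clade) -> TreeNode:
        node = TreeNode(name=clade.name, length=clade.branch_length or 0.0)
        if clade.clades:
            node.children = [convert(c) for c in clade.clades]
            if clade.confidence is not None:
                node.support = float(clade.confidence)
            elif clade.name is not None:
                try:
                    node.support = float(clade.name)
                    node.name = None
                except ValueError:
                    pass
        return node

    return PhyloTree(root=convert(btree.root))
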