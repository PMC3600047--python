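"""Readers, writers and in-memory containers for every external artifact.

Formats handled: FASTA (alignments, via Biopython), Newick (trees, via
DendroPy), and TSV tables (gene partitions, species richness, sister-pair
definitions, via pandas).  All site coordinates are 0-based half-open.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from claderates.substitution_models import CodonStateSpace

logger = logging.getLogger(__name__)

#: smallest representable branch length; zero-length branches are stored at
#: this floor so downstream rate ratios stay finite.
BRANCH_LENGTH_FLOOR = 1e-9

#: IUPAC nucleotide codes mapped to the sets of bases they may represent.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT",
}

MISSING_CODON = -1


@dataclass
class Alignment:
    """A nucleotide multiple-sequence alignment.

    ``sites`` is an (n_taxa, length) array of single uppercase IUPAC
    symbols; gaps are ``-`` and missing data ``?`` or ``N``.
    """

    taxa: list[str]
    sites: np.ndarray

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype="<U1")
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise ValueError("sites must be a (n_taxa, length) matrix")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        bad = set(np.unique(self.sites)) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid alignment symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.sites.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        return self.sites[self.taxa.index(taxon)]

    def subset_sites(self, columns: np.ndarray) -> "Alignment":
        return Alignment(list(self.taxa), self.sites[:, columns])


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    kind: str  # "coding" | "noncoding"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PartitionMap:
    """Ordered, disjoint half-open site intervals labelled coding/noncoding."""

    partitions: list[Partition]

    def __post_init__(self):
        prev_end = None
        for p in sorted(self.partitions, key=lambda q: q.start):
            if p.start < 0 or p.end <= p.start:
                raise ValueError(f"partition {p.name}: bad interval [{p.start}, {p.end})")
            if p.kind not in ("coding", "noncoding"):
                raise ValueError(f"partition {p.name}: kind must be coding or noncoding")
            if prev_end is not None and p.start < prev_end:
                raise ValueError(f"partition {p.name} overlaps a previous interval")
            if p.kind == "coding" and p.length % 3 != 0:
                raise ValueError(f"coding partition {p.name} length {p.length} not divisible by 3")
            prev_end = p.end

    def coding(self) -> list[Partition]:
        return [p for p in self.partitions if p.kind == "coding"]

    def validate_against(self, aln: Alignment) -> None:
        for p in self.partitions:
            if p.end > aln.length:
                raise ValueError(f"partition {p.name} extends past alignment length {aln.length}")


@dataclass
class CodonAlignment:
    """In-frame codon matrix over the sense codons of a genetic code.

    ``codon_sites`` holds state indices into ``space.codons``; codons with
    any ambiguity, and stop codons (which are masked with a warning), are
    stored as ``MISSING_CODON``.
    """

    taxa: list[str]
    codon_sites: np.ndarray
    genetic_code: int = 1
    n_stops_masked: int = 0

    def __post_init__(self):
        self.codon_sites = np.asarray(self.codon_sites, dtype=int)
        if self.codon_sites.ndim != 2 or self.codon_sites.shape[0] != len(self.taxa):
            raise ValueError("codon_sites must be a (n_taxa, n_codons) matrix")
        n = self.space.n_states
        if self.codon_sites.size and (
            self.codon_sites.max() >= n or self.codon_sites.min() < MISSING_CODON
        ):
            raise ValueError("codon state indices out of range")

    @property
    def space(self) -> CodonStateSpace:
        return CodonStateSpace.get(self.genetic_code)

    @property
    def length(self) -> int:
        return self.codon_sites.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def position_base_counts(self) -> np.ndarray:
        """3x4 counts of nucleotides by codon position over non-missing codons."""
        counts = np.zeros((3, 4), dtype=float)
        codons = self.space.codons
        base_idx = {b: i for i, b in enumerate("ACGT")}
        flat = self.codon_sites[self.codon_sites != MISSING_CODON]
        states, mult = np.unique(flat, return_counts=True)
        for s, m in zip(states, mult):
            for pos, b in enumerate(codons[s]):
                counts[pos, base_idx[b]] += m
        return counts


class TreeNode:
    __slots__ = ("index", "label", "length", "parent", "children")

    def __init__(self, label=None, length=None):
        self.index: int = -1
        self.label: str | None = label
        self.length: float | None = length
        self.parent: "TreeNode | None" = None
        self.children: list["TreeNode"] = []

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with branch lengths, indexed in postorder.

    Branch ids are the postorder indices of the child-end nodes; the root
    carries no branch.  Branch lengths are floored at
    ``BRANCH_LENGTH_FLOOR`` on read.
    """

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._reindex()
        labels = [n.label for n in self.postorder if n.is_tip]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if any(lb is None for lb in labels):
            raise ValueError("every tip must be labelled")

    # -- structure ---------------------------------------------------------
    def _reindex(self) -> None:
        order: list[TreeNode] = []

        def walk(node: TreeNode):
            for c in node.children:
                walk(c)
            order.append(node)

        walk(self.root)
        for i, n in enumerate(order):
            n.index = i
        self.postorder = order
        self.tip_index = {n.label: n.index for n in order if n.is_tip}

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.postorder if n.is_tip]

    def node(self, index: int) -> TreeNode:
        return self.postorder[index]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; each represents the branch above it."""
        return [n for n in self.postorder if n is not self.root]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.postorder if not n.is_tip)

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v.is_tip:
                out.append(v.label)
            else:
                stack.extend(v.children)
        return frozenset(out)

    def mrca(self, labels) -> TreeNode:
        labels = set(labels)
        missing = labels - set(self.tip_index)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        counts: dict[int, int] = {}
        node = None
        # deepest postorder node whose clade covers all labels
        cover = {}
        for n in self.postorder:
            if n.is_tip:
                cover[n.index] = 1 if n.label in labels else 0
            else:
                cover[n.index] = sum(cover[c.index] for c in n.children)
            if cover[n.index] == len(labels):
                node = n
                break
        del counts
        assert node is not None
        return node

    def path_to_ancestor(self, tip_label: str, ancestor: TreeNode) -> float:
        """Sum of branch lengths from a tip up to (not including) ``ancestor``."""
        node = self.postorder[self.tip_index[tip_label]]
        total = 0.0
        while node is not ancestor:
            if node.parent is None:
                raise ValueError(f"{ancestor} is not an ancestor of {tip_label}")
            total += node.length or 0.0
            node = node.parent
        return total

    def depths(self) -> np.ndarray:
        """Distance from the root to every node, by postorder index."""
        d = np.zeros(len(self.postorder))
        for n in reversed(self.postorder):  # preorder
            if n.parent is not None:
                d[n.index] = d[n.parent.index] + (n.length or 0.0)
        return d

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.label, node.length)
            for ch in node.children:
                cc = clone(ch)
                cc.parent = c
                c.children.append(cc)
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def resolve_polytomies(self) -> int:
        """Arbitrarily resolve multifurcations with zero-length branches.

        Returns the number of new nodes introduced; postorder indices are
        rebuilt.  Resolution keeps child order: the first two children are
        grouped first.
        """
        added = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            while len(node.children) > 2:
                a, b = node.children[0], node.children[1]
                joint = TreeNode(length=BRANCH_LENGTH_FLOOR)
                joint.children = [a, b]
                a.parent = b.parent = joint
                joint.parent = node
                node.children = [joint] + node.children[2:]
                added += 1
            stack.extend(node.children)
        if added:
            logger.info("resolved polytomies by adding %d zero-length branches", added)
            self._reindex()
        return added

    def branch_lengths(self) -> dict[int, float]:
        return {n.index: n.length for n in self.branches()}

    def set_branch_lengths(self, lengths: dict[int, float]) -> None:
        for idx, t in lengths.items():
            node = self.postorder[idx]
            if node is self.root:
                continue
            node.length = max(float(t), BRANCH_LENGTH_FLOOR)

    # -- newick ------------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.parent is not None and node.length is not None:
                core += f":{node.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"


def read_tree(newick: str, floor: float = BRANCH_LENGTH_FLOOR) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Polytomies are accepted and resolved arbitrarily with floor-length
    branches (logged).  Branch lengths below the floor are raised to it.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        if length is not None:
            length = max(float(length), floor)
        node = TreeNode(label, length)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    root.length = None
    tree = PhyloTree(root, rooted=True)
    tree.resolve_polytomies()
    return tree


def load_tree(path) -> PhyloTree:
    return read_tree(Path(path).read_text())


def write_tree(tree: PhyloTree, path=None, branch_lengths: dict[int, float] | None = None) -> str:
    """Serialize a tree to Newick, optionally substituting branch values.

    ``branch_lengths`` maps branch ids (postorder node indices) to the
    values to write, e.g. a dN or dS annotation; the tree itself is not
    modified.
    """
    if branch_lengths is not None:
        tree = tree.copy()
        for node in tree.branches():
            if node.index in branch_lengths:
                node.length = float(branch_lengths[node.index])
    text = tree.to_newick() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA (or other SeqIO-supported) alignment file."""
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no sequence records found in {path}")
    return _alignment_from_records([(r.id, str(r.seq)) for r in records])


def read_alignment_text(text: str, format: str = "fasta") -> Alignment:
    records = list(SeqIO.parse(io.StringIO(text), format))
    if not records:
        raise ValueError("no sequence records found")
    return _alignment_from_records([(r.id, str(r.seq)) for r in records])


def _alignment_from_records(records: list[tuple[str, str]]) -> Alignment:
    taxa = [name for name, _ in records]
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        detail = ", ".join(f"{n}:{len(s)}" for n, s in records)
        raise ValueError(f"ragged alignment rows ({detail})")
    sites = np.array([list(seq.upper()) for _, seq in records], dtype="<U1")
    return Alignment(taxa, sites)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, taxon in enumerate(aln.taxa):
            fh.write(f">{taxon}\n{''.join(aln.sites[i])}\n")


def extract_codons(aln: Alignment, pmap: PartitionMap, code: int = 1) -> CodonAlignment:
    """Concatenate coding partitions and fold into codon columns.

    Any triplet containing a gap or ambiguity is masked to missing; stop
    triplets are masked too, with the count recorded on the result and a
    logged warning.
    """
    coding = pmap.coding()
    if not coding:
        raise ValueError("partition map has no coding partitions")
    pmap.validate_against(aln)
    cols = np.concatenate([np.arange(p.start, p.end) for p in coding])
    sub = aln.sites[:, cols]
    n_codons = sub.shape[1] // 3
    space = CodonStateSpace.get(code)
    out = np.full((aln.n_taxa, n_codons), MISSING_CODON, dtype=int)
    n_stops = 0
    for i in range(aln.n_taxa):
        row = sub[i]
        for j in range(n_codons):
            triplet = "".join(row[3 * j: 3 * j + 3])
            if any(ch not in "ACGT" for ch in triplet):
                continue
            if triplet in space.stop_codons:
                n_stops += 1
                continue
            out[i, j] = space.index[triplet]
    if n_stops:
        logger.warning("masked %d stop codons to missing during codon extraction", n_stops)
    return CodonAlignment(list(aln.taxa), out, genetic_code=code, n_stops_masked=n_stops)


# ---------------------------------------------------------------------------
# tables


def read_partition_table(path) -> PartitionMap:
    """TSV with columns name/start/end/kind; start/end are 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "start", "end", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"partition table missing columns: {sorted(missing)}")
    return PartitionMap(
        [Partition(str(r["name"]), int(r["start"]), int(r["end"]), str(r["kind"]))
         for _, r in df.iterrows()]
    )


def write_partition_table(pmap: PartitionMap, path) -> None:
    pd.DataFrame(
        [(p.name, p.start, p.end, p.kind) for p in pmap.partitions],
        columns=["name", "start", "end", "kind"],
    ).to_csv(path, sep="\t", index=False)


def read_richness_table(path) -> dict[str, int]:
    """TSV with columns lineage_id/species_count."""
    df = pd.read_csv(path, sep="\t")
    missing = {"lineage_id", "species_count"} - set(df.columns)
    if missing:
        raise ValueError(f"richness table missing columns: {sorted(missing)}")
    table = {}
    for _, r in df.iterrows():
        count = int(r["species_count"])
        if count < 1:
            raise ValueError(f"lineage {r['lineage_id']}: species count must be >= 1")
        table[str(r["lineage_id"])] = count
    return table


def write_richness_table(table: dict[str, int], path) -> None:
    pd.DataFrame(
        sorted(table.items()), columns=["lineage_id", "species_count"]
    ).to_csv(path, sep="\t", index=False)


def check_labels_match(tree: PhyloTree, aln: Alignment | CodonAlignment) -> None:
    """Raise if tree tips and alignment taxa are not the same label set."""
    tree_labels = set(tree.tip_index)
    aln_labels = set(aln.taxa)
    if tree_labels != aln_labels:
        only_tree = sorted(tree_labels - aln_labels)
        only_aln = sorted(aln_labels - tree_labels)
        raise ValueError(
            f"tree/alignment label mismatch: only in tree {only_tree}, only in alignment {only_aln}"
        )
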