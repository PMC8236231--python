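"""Phylogeny and subgroup classification.

Distance phylogeny as practiced for plant transcription-factor families:
protein MSA, Poisson-corrected distances under pairwise deletion,
neighbor-joining, nonparametric bootstrap, and assignment of unlabeled
family members to the A1-A6 subgroups of a labeled reference panel.

The aligner is a deterministic center-star progressive method ("once a gap,
always a gap"); a precomputed MSA may be supplied instead wherever an MSA is
consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import PhyloTree, SequenceRecord, TreeNode

log = logging.getLogger("genefam")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass
class MSA:
    """An ordered multiple sequence alignment; gap character '-'."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValueError("an MSA needs at least 3 sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def encoded(self) -> np.ndarray:
        """(n, L) int8 matrix: residue index 0..19, gap/other = -1."""
        out = np.full((len(self.records), self.n_columns), -1, dtype=np.int8)
        for i, r in enumerate(self.records):
            for j, a in enumerate(r.residues):
                out[i, j] = _AA_INDEX.get(a, -1)
        return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        self.d = d


# ---------------------------------------------------------------------------
# center-star alignment
# ---------------------------------------------------------------------------

def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_family(proteins: list[SequenceRecord]) -> MSA:
    """Center-star progressive alignment.

    The center is the sequence maximizing total pairwise global-alignment
    score (ties broken by lexicographic id); the others are merged against it
    under "once a gap, always a gap".
    """
    if len(proteins) < 3:
        raise ValueError("need at least 3 sequences to align")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    aligner = _global_aligner()
    n = len(proteins)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(proteins[i].residues, proteins[j].residues)
            scores[i, j] = scores[j, i] = s
    totals = scores.sum(axis=1)
    center_idx = min(range(n), key=lambda i: (-totals[i], proteins[i].id))
    center = proteins[center_idx]

    # master state: per-column center character; rows already merged
    master_center: list[str] = list(center.residues)
    rows: dict[str, list[str]] = {center.id: list(center.residues)}

    others = sorted((p for k, p in enumerate(proteins) if k != center_idx),
                    key=lambda p: p.id)
    for p in others:
        aln = aligner.align(center.residues, p.residues)[0]
        c_aln, p_aln = str(aln[0]), str(aln[1])
        new_master: list[str] = []
        new_rows: dict[str, list[str]] = {rid: [] for rid in rows}
        new_row: list[str] = []
        mi = pi = 0
        while mi < len(master_center) or pi < len(c_aln):
            if mi < len(master_center) and master_center[mi] == "-":
                # column inserted by an earlier merge; absent from the center
                new_master.append("-")
                for rid in rows:
                    new_rows[rid].append(rows[rid][mi])
                new_row.append("-")
                mi += 1
            elif pi < len(c_aln) and c_aln[pi] == "-":
                # insertion relative to the center introduced by this sequence
                new_master.append("-")
                for rid in rows:
                    new_rows[rid].append("-")
                new_row.append(p_aln[pi])
                pi += 1
            else:
                new_master.append(master_center[mi])
                for rid in rows:
                    new_rows[rid].append(rows[rid][mi])
                new_row.append(p_aln[pi])
                mi += 1
                pi += 1
        master_center = new_master
        rows = new_rows
        rows[p.id] = new_row

    order = [center.id] + [p.id for p in others]
    # report rows in the input order for stability
    input_order = [p.id for p in proteins]
    recs = [SequenceRecord(rid, "".join(rows[rid])) for rid in input_order]
    del order
    return MSA(records=recs)


# ---------------------------------------------------------------------------
# Poisson distances under pairwise deletion
# ---------------------------------------------------------------------------

def _pairwise_p(encoded: np.ndarray):
    """Shared-column counts and mismatch fractions for all pairs (vectorized)."""
    nongap = (encoded >= 0).astype(np.float64)
    shared = nongap @ nongap.T
    matches = np.zeros_like(shared)
    for a in range(20):
        ind = (encoded == a).astype(np.float64)
        matches += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (shared - matches) / shared
    return shared, p


def poisson_distance(msa: MSA) -> DistanceMatrix:
    """d = -ln(1-p) per pair, using only columns ungapped in both sequences."""
    enc = msa.encoded()
    labels = [r.id for r in msa.records]
    shared, p = _pairwise_p(enc)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] == 0:
                raise ValueError(f"no shared ungapped columns for pair "
                                 f"({labels[i]}, {labels[j]})")
            if p[i, j] >= 1.0:
                raise ValueError(f"saturated pair ({labels[i]}, {labels[j]}): "
                                 "all shared columns differ")
    d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=(d + d.T) / 2.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with negative-length clamping.

    A negative pendant length is clamped to zero and the deficit moved to the
    sibling edge (the pair sum is preserved).  Ties in the Q criterion break
    deterministically toward the smallest index pair in the current node
    ordering.
    """
    labels = dm.labels
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        dnew = (D[i] + D[j] - D[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    a.length, b.length, c.length = (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))
    return PhyloTree(root=TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _distances_from_encoded(enc: np.ndarray, labels: list[str]) -> DistanceMatrix | None:
    shared, p = _pairwise_p(enc)
    n = len(labels)
    iu = np.triu_indices(n, 1)
    if np.any(shared[iu] == 0) or np.any(p[iu] >= 1.0):
        return None
    d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=(d + d.T) / 2.0)


def bootstrap_supports(msa: MSA, n_replicates: int = 1000,
                       seed: int = 0) -> dict[frozenset, float]:
    """Column-resampling bootstrap; support as percent of valid replicates.

    Replicates whose resampled columns leave some pair with no shared
    ungapped column (or fully mismatched) are discarded; more than 10%
    discarded is an error.
    """
    enc = msa.encoded()
    labels = [r.id for r in msa.records]
    L = msa.n_columns
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    discarded = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        dm = _distances_from_encoded(enc[:, cols], labels)
        if dm is None:
            discarded += 1
            continue
        tree = nj_tree(dm)
        for bip in tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    if discarded > 0.1 * n_replicates:
        raise ValueError(f"{discarded}/{n_replicates} bootstrap replicates had "
                         "undefined distances")
    if discarded:
        log.warning("discarded %d/%d bootstrap replicates", discarded, n_replicates)
    valid = n_replicates - discarded
    return {bip: 100.0 * c / valid for bip, c in counts.items()}


def attach_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> None:
    """Write bootstrap percents onto the matching internal edges of a tree."""
    for bip, node in tree.bipartitions().items():
        node.support = round(supports.get(bip, 0.0), 1)


# ---------------------------------------------------------------------------
# subgroup assignment
# ---------------------------------------------------------------------------

@dataclass
class SubgroupAssignment:
    labels: dict[str, str]
    method: dict[str, str] = field(default_factory=dict)


def assign_subgroups(tree: PhyloTree,
                     reference_labels: dict[str, str]) -> SubgroupAssignment:
    """Label each query leaf from the smallest surrounding reference clade.

    For every edge-induced split side containing the query and at least one
    reference, take the smallest; if its references are unanimous, use that
    label (method "clade"), otherwise the label of the patristically nearest
    reference in that side (method "nearest", ties by reference id).
    """
    leaf_names = set(tree.leaf_names())
    refs_in_tree = {r for r in reference_labels if r in leaf_names}
    present_labels = {reference_labels[r] for r in refs_in_tree}
    missing = sorted(set(reference_labels.values()) - present_labels)
    if missing:
        raise ValueError(f"no reference present in tree for labels {missing}")
    queries = sorted(leaf_names - set(reference_labels))

    # every edge induces two sides; collect all sides once
    full = leaf_names
    sides: list[set[str]] = []

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            below = {node.name}
        else:
            below = set()
            for c in node.children:
                below |= walk(c)
        if node is not tree.root and 0 < len(below) < len(full):
            sides.append(below)
            sides.append(full - below)
        return below

    walk(tree.root)

    out = SubgroupAssignment(labels={}, method={})
    for q in queries:
        candidates = [s for s in sides if q in s and s & refs_in_tree]
        best = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        labels_here = {reference_labels[r] for r in best & refs_in_tree}
        if len(labels_here) == 1:
            out.labels[q] = labels_here.pop()
            out.method[q] = "clade"
        else:
            nearest = min(sorted(best & refs_in_tree),
                          key=lambda r: (tree.patristic(q, r), r))
            out.labels[q] = reference_labels[nearest]
            out.method[q] = "nearest"
    return out
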