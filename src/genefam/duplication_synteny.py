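"""Duplication classification, collinearity, Ka/Ks and divergence dating.

Tandem duplicates are family pairs on one chromosome separated by at most
five intervening gene loci.  Segmental duplicates are family pairs anchored
in a within-genome collinear block (chains of homologous gene-rank anchors,
found by dynamic programming under monotonicity and gap constraints, in the
spirit of MCScanX).  Substitution rates use the Nei-Gojobori (1986) counting
method with Jukes-Cantor correction, and divergence times the molecular
clock T = Ks / (2 * 6.56e-9) years.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

from .family_identify import KA_K, KA_LAMBDA, _make_aligner, evalue
from .io_formats import GenomeBundle, SequenceRecord, translate

log = logging.getLogger("genefam")

CLOCK_RATE = 6.56e-9        # synonymous substitutions / site / year
TANDEM_MAX_INTERVENING = 5
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NT = "ACGT"


class SaturationError(ValueError):
    """Raised when p >= 3/4 makes the Jukes-Cantor correction undefined."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologPair:
    id_a: str
    id_b: str
    bitscore: float
    genome_a: str
    genome_b: str


@dataclass
class CollinearBlock:
    block_id: str
    genomes: tuple[str, str]
    chromosomes: tuple[str, str]
    anchors: list[HomologPair]
    orientation: str                     # "same" | "inverted"
    ranks: list[tuple[int, int]] = field(default_factory=list)

    def validate(self, min_anchors: int, max_gap: int) -> None:
        assert len(self.anchors) >= min_anchors
        ra = [r for r, _ in self.ranks]
        rb = [r for _, r in self.ranks]
        assert all(x < y for x, y in zip(ra, ra[1:])), "ranks not monotone in A"
        if self.orientation == "same":
            assert all(x < y for x, y in zip(rb, rb[1:])), "ranks not monotone in B"
        else:
            assert all(x > y for x, y in zip(rb, rb[1:])), "ranks not anti-monotone in B"
        for (x1, y1), (x2, y2) in zip(self.ranks, self.ranks[1:]):
            assert abs(x2 - x1) <= max_gap and abs(y2 - y1) <= max_gap, "gap exceeded"


@dataclass
class DuplicatePair:
    id_a: str
    id_b: str
    dup_type: str                        # "tandem" | "segmental"
    intervening_loci: int | None = None
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    t_mya: float | None = None


@dataclass
class CodonAlignment:
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment rows have unequal lengths")


# ---------------------------------------------------------------------------
# tandem rule
# ---------------------------------------------------------------------------

def detect_tandem(family: list[str] | set[str], genome: GenomeBundle,
                  max_intervening: int = TANDEM_MAX_INTERVENING,
                  family_loci_only: bool = False) -> list[DuplicatePair]:
    """Family pairs on one chromosome separated by <= ``max_intervening`` loci.

    Intervening loci are counted among ALL annotated genes between the pair
    (rank difference minus one); with ``family_loci_only`` only family genes
    are counted.
    """
    info = {g.gene_id: (g.chromosome, g.rank) for g in genome.genes}
    members = sorted(set(family))
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for m in members:
        if m not in info:
            raise KeyError(f"family gene {m} absent from genome annotation")
        chrom, rank = info[m]
        by_chrom.setdefault(chrom, []).append((rank, m))
    out: list[DuplicatePair] = []
    for chrom in sorted(by_chrom):
        ranked = sorted(by_chrom[chrom])
        for (ra, ga), (rb, gb) in itertools.combinations(ranked, 2):
            if family_loci_only:
                intervening = sum(1 for r, _ in ranked if ra < r < rb)
            else:
                intervening = rb - ra - 1
            if intervening <= max_intervening:
                a, b = sorted((ga, gb))
                out.append(DuplicatePair(id_a=a, id_b=b, dup_type="tandem",
                                         intervening_loci=intervening))
    return out


# ---------------------------------------------------------------------------
# homolog pairs (plumbing for collinearity)
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def homolog_pairs(proteins_a: list[SequenceRecord],
                  proteins_b: list[SequenceRecord] | None = None,
                  genome_a: str = "A", genome_b: str | None = None,
                  evalue_cutoff: float = 1e-5,
                  min_shared_kmers: int = 5,
                  reciprocal_best: bool = False) -> list[HomologPair]:
    """Significant protein pairs by local alignment, k-mer prefiltered.

    With ``proteins_b`` None the search is within one proteome (self-pairs
    excluded, canonical id order).  E-values use the ungapped
    Karlin-Altschul form on the Smith-Waterman score.  With
    ``reciprocal_best`` only mutual best-scoring pairs are kept (the
    standard way to isolate one-to-one duplicate/ortholog partners before
    collinearity chaining).
    """
    within = proteins_b is None
    if within:
        proteins_b = proteins_a
        genome_b = genome_a
    kmers_a = [_kmer_set(p.residues) for p in proteins_a]
    kmers_b = kmers_a if within else [_kmer_set(p.residues) for p in proteins_b]
    aligner = _make_aligner()
    out: list[HomologPair] = []
    for i, pa in enumerate(proteins_a):
        jstart = i + 1 if within else 0
        for j in range(jstart, len(proteins_b)):
            pb = proteins_b[j]
            if len(kmers_a[i] & kmers_b[j]) < min_shared_kmers:
                continue
            s = aligner.score(pa.residues, pb.residues)
            if s <= 0 or evalue(s, len(pa), len(pb)) > evalue_cutoff:
                continue
            bits = (KA_LAMBDA * s - math.log(KA_K)) / math.log(2)
            ida, idb = pa.id, pb.id
            if within and idb < ida:
                ida, idb = idb, ida
            out.append(HomologPair(id_a=ida, id_b=idb, bitscore=bits,
                                   genome_a=genome_a, genome_b=genome_b))
    if reciprocal_best:
        out = _reciprocal_best(out, within)
    return out


def _reciprocal_best(pairs: list[HomologPair], within: bool) -> list[HomologPair]:
    best: dict[tuple[str, str], tuple[float, str]] = {}   # (side, id) -> (score, partner)
    for hp in pairs:
        keys = [(("g", hp.id_a) if within else ("a", hp.id_a), hp.id_b),
                (("g", hp.id_b) if within else ("b", hp.id_b), hp.id_a)]
        for key, partner in keys:
            cur = best.get(key)
            if cur is None or (hp.bitscore, ) > (cur[0], ) or \
                    (hp.bitscore == cur[0] and partner < cur[1]):
                best[key] = (hp.bitscore, partner)
    out = []
    for hp in pairs:
        ka = ("g", hp.id_a) if within else ("a", hp.id_a)
        kb = ("g", hp.id_b) if within else ("b", hp.id_b)
        if best[ka][1] == hp.id_b and best[kb][1] == hp.id_a:
            out.append(hp)
    return out


# ---------------------------------------------------------------------------
# collinear block chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: list[tuple[int, int, float, int]], sign: int,
                max_gap: int) -> list[int]:
    """Max-score chain (indices into anchors) monotone in A, sign-monotone in B."""
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k][0], sign * anchors[k][1]))
    best_score = [anchors[k][2] for k in order]
    back: list[int | None] = [None] * len(order)
    for u in range(len(order)):
        ra_u, rb_u, s_u, _ = anchors[order[u]]
        for v in range(u):
            ra_v, rb_v, _, _ = anchors[order[v]]
            if ra_v >= ra_u or sign * rb_v >= sign * rb_u:
                continue
            if ra_u - ra_v > max_gap or abs(rb_u - rb_v) > max_gap:
                continue
            cand = best_score[v] + s_u
            if cand > best_score[u]:
                best_score[u] = cand
                back[u] = v
    if not order:
        return []
    end = max(range(len(order)), key=lambda u: best_score[u])
    chain = []
    cur: int | None = end
    while cur is not None:
        chain.append(order[cur])
        cur = back[cur]
    return chain[::-1]


def detect_collinear(genome_a: GenomeBundle, genome_b: GenomeBundle,
                     pairs: list[HomologPair],
                     min_anchors: int = DEFAULT_MIN_ANCHORS,
                     max_gap: int = DEFAULT_MAX_GAP) -> list[CollinearBlock]:
    """Chain gene-rank anchors into collinear blocks.

    Per chromosome pair and orientation the best-scoring chain satisfying
    strict monotonicity and rank-gap <= ``max_gap`` on both sides is taken,
    its anchors removed, and the search repeated; chains shorter than
    ``min_anchors`` are dropped.  Each anchor belongs to at most one block.
    """
    within = genome_a.genome_id == genome_b.genome_id
    info_a = {g.gene_id: (g.chromosome, g.rank) for g in genome_a.genes}
    info_b = {g.gene_id: (g.chromosome, g.rank) for g in genome_b.genes}

    groups: dict[tuple[str, str], list[tuple[int, int, float, HomologPair]]] = {}
    for hp in pairs:
        if within and hp.id_a == hp.id_b:
            continue
        if hp.id_a not in info_a or hp.id_b not in info_b:
            continue
        (ca, ra), (cb, rb) = info_a[hp.id_a], info_b[hp.id_b]
        if within and (cb, rb) < (ca, ra):
            ca, ra, cb, rb = cb, rb, ca, ra
        groups.setdefault((ca, cb), []).append((ra, rb, hp.bitscore, hp))

    blocks: list[CollinearBlock] = []
    n_blocks = 0
    for (ca, cb) in sorted(groups):
        pool = groups[(ca, cb)]
        while True:
            anchors = [(ra, rb, s, k) for k, (ra, rb, s, _) in enumerate(pool)]
            best = None
            for sign, orient in ((1, "same"), (-1, "inverted")):
                chain = _best_chain(anchors, sign, max_gap)
                if len(chain) >= min_anchors:
                    score = sum(pool[k][2] for k in chain)
                    if best is None or score > best[0]:
                        best = (score, orient, chain)
            if best is None:
                break
            _, orient, chain = best
            n_blocks += 1
            picked = [pool[k] for k in chain]
            block = CollinearBlock(
                block_id=f"block{n_blocks}",
                genomes=(genome_a.genome_id, genome_b.genome_id),
                chromosomes=(ca, cb),
                anchors=[hp for _, _, _, hp in picked],
                orientation=orient,
                ranks=[(ra, rb) for ra, rb, _, _ in picked])
            block.validate(min_anchors, max_gap)
            blocks.append(block)
            used = set(chain)
            pool = [p for k, p in enumerate(pool) if k not in used]
    return blocks


def classify_duplicates(family: list[str] | set[str],
                        tandem: list[DuplicatePair],
                        self_blocks: list[CollinearBlock]) -> list[DuplicatePair]:
    """Tandem pairs first; non-tandem family anchor pairs become segmental."""
    fam = set(family)
    tandem_keys = {(p.id_a, p.id_b) for p in tandem}
    out = list(tandem)
    seen = set(tandem_keys)
    for block in self_blocks:
        for hp in block.anchors:
            a, b = sorted((hp.id_a, hp.id_b))
            if a in fam and b in fam and (a, b) not in seen:
                seen.add((a, b))
                out.append(DuplicatePair(id_a=a, id_b=b, dup_type="segmental"))
    return out


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def codon_align(prot_aln: tuple[str, str], cds_a: str, cds_b: str) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its CDSs ('---' for gaps)."""
    def strip_stop(cds: str) -> str:
        if len(cds) % 3:
            raise ValueError("CDS length not a multiple of 3")
        if cds[-3:].upper() in _STOPS:
            return cds[:-3]
        return cds

    rows = []
    for name, aln_row, cds in (("first", prot_aln[0], cds_a),
                               ("second", prot_aln[1], cds_b)):
        cds = strip_stop(cds.upper())
        degapped = aln_row.replace("-", "")
        if translate(cds) != degapped:
            raise ValueError(f"{name} sequence: aligned protein does not match "
                             "CDS translation")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        row, k = [], 0
        for a in aln_row:
            if a == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        rows.append(row)
    return CodonAlignment(codons_a=rows[0], codons_b=rows[1])


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites: per position, synonymous one-step
    changes / 3.  Changes producing stop codons count as nonsynonymous,
    keeping S + N = 3 exactly."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                s += 1.0
    return s / 3.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over substitution
    pathways; pathways through stop codons are excluded (if every pathway is
    blocked, all pathways are used with stop steps counted nonsynonymous)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        sd = nd = 0.0
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
                nd += 1.0
            elif cur in _STOPS:
                nd += 1.0
            elif _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); undefined at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(ca: CodonAlignment) -> tuple[float, float, float | None]:
    """Nei-Gojobori Ka, Ks and omega for a pairwise codon alignment."""
    S = N = Sd = Nd = 0.0
    n_pairs = 0
    for c1, c2 in zip(ca.codons_a, ca.codons_b):
        if "-" in c1 or "-" in c2:
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(f"stop codon in alignment: {c1}/{c2}")
        n_pairs += 1
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    if n_pairs == 0:
        raise ValueError("no ungapped codon pairs in alignment")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    omega = ka / ks if ks > 0 else None
    return ka, ks, omega


def divergence_time(ks: float, rate: float = CLOCK_RATE) -> float:
    """T = Ks / (2 * rate) years, reported in millions of years (MYA)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * rate) / 1e6


# ---------------------------------------------------------------------------
# evolutionary annotation of classified pairs
# ---------------------------------------------------------------------------

def annotate_pairs(pairs: list[DuplicatePair], genome: GenomeBundle) -> None:
    """Fill Ka, Ks, omega and T for classified duplicate pairs, in place."""
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    cds = {g.gene_id: g.cds for g in genome.genes}
    for pair in pairs:
        pa = genome.proteins[pair.id_a].residues
        pb = genome.proteins[pair.id_b].residues
        aln = aligner.align(pa, pb)[0]
        ca = codon_align((str(aln[0]), str(aln[1])), cds[pair.id_a], cds[pair.id_b])
        try:
            ka, ks, omega = ng86(ca)
        except SaturationError as exc:
            log.warning("pair (%s, %s) saturated: %s", pair.id_a, pair.id_b, exc)
            continue
        pair.ka, pair.ks, pair.omega = ka, ks, omega
        pair.t_mya = divergence_time(ks)


def ortholog_counts(blocks: list[CollinearBlock],
                    family: list[str] | set[str]) -> int:
    """Family genes of genome A appearing in at least one cross-genome anchor."""
    fam = set(family)
    seen: set[str] = set()
    for b in blocks:
        if b.genomes[0] == b.genomes[1]:
            raise ValueError("ortholog_counts expects cross-genome blocks")
        for hp in b.anchors:
            if hp.id_a in fam:
                seen.add(hp.id_a)
    return len(seen)
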