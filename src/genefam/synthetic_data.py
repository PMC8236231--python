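"""Synthetic genomes with planted ground truth.

Emulates the input data of a genome-wide gene-family survey: a
multi-chromosome genome with ranked gene loci, a planted multi-subgroup
family whose proteins carry a single 54-column AP2-like domain (valine at
column 14; glutamic acid at column 19 in a configurable fraction), near-miss
decoys, tandem arrays and segmental collinear blocks evolved to target Ks
and omega, planted ungapped protein motifs, and intron structures with
known splicing phases.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .duplication_synteny import _syn_sites, _CODON_TABLE, _STOPS
from .family_identify import BACKGROUND_FREQS, build_profile, packaged_seed_alignment
from .io_formats import (GeneModel, GenomeBundle, SequenceRecord, compute_ranks,
                         reverse_complement, translate)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_AA_P = np.array([BACKGROUND_FREQS[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()

# 1-based diagnostic columns of the domain
_V_COL, _E_COL = 14, 19

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)

DEFAULT_SUBGROUP_SIZES = {"A1": 11, "A2": 8, "A3": 2, "A4": 18, "A5": 8, "A6": 19}
DEFAULT_MOTIF_SPECS = [
    (9, "WDDMSLWSY"),
    (12, "QHPKYEDFVRSN"),
    (21, "FSPTSVLDMHGAENKYQWRIC"),
]


@dataclass
class SimConfig:
    seed: int = 1
    n_chromosomes: int = 12
    genes_per_chromosome: int = 60
    family_size_per_subgroup: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES))
    n_tandem_arrays: int = 10
    n_segmental_blocks: int = 8
    block_anchor_count: int = 6
    target_ks_list: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.5])
    target_omega: float = 0.2
    motif_specs: list[tuple[int, str]] = field(
        default_factory=lambda: list(DEFAULT_MOTIF_SPECS))
    decoy_fraction: float = 0.05
    e19_fraction: float = 40.0 / 66.0
    refs_per_subgroup: int = 3

    def __post_init__(self) -> None:
        for name, count in self.family_size_per_subgroup.items():
            if count < 0:
                raise ValueError(f"negative family size for {name}")
        for n in (self.n_chromosomes, self.genes_per_chromosome,
                  self.n_tandem_arrays, self.n_segmental_blocks,
                  self.block_anchor_count):
            if n < 0:
                raise ValueError("counts must be non-negative")
        for w, cons in self.motif_specs:
            if not 6 <= w <= 50:
                raise ValueError(f"motif width {w} outside [6, 50]")
            if len(cons) != w:
                raise ValueError(f"motif consensus length {len(cons)} != width {w}")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction outside [0, 1]")
        if any(k <= 0 for k in self.target_ks_list):
            raise ValueError("target Ks values must be positive")
        if self.target_omega <= 0:
            raise ValueError("target omega must be positive")


@dataclass
class PlantedTruth:
    family_members: dict[str, str]                  # gene_id -> subgroup
    v14_negative_decoys: set[str]
    multi_domain_decoys: set[str]
    no_domain_decoys: set[str]
    tandem_pairs: dict[tuple[str, str], int]        # pair -> intervening loci
    segmental_pairs: dict[tuple[str, str], str]     # pair -> block id
    pair_targets: dict[tuple[str, str], tuple[float, float]]
    motif_sites: dict[str, list[tuple[str, int]]]   # consensus -> (gene, offset)
    e19_members: set[str]
    intron_phases: dict[str, list[int]]


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_P))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float,
                    frozen: set[int] = frozenset()) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str,
                    terminal_stop: bool = True) -> str:
    codons = []
    for a in protein:
        opts = _CODONS_FOR_AA[a]
        codons.append(opts[int(rng.integers(0, len(opts)))])
    if terminal_stop:
        codons.append("TAA")
    return "".join(codons)


def plant_motif(protein: str, motif_consensus: str, offset: int,
                noise: float = 0.0, seed: int = 0) -> str:
    """Overwrite a window with the consensus, corrupting columns w.p. noise."""
    w = len(motif_consensus)
    if offset < 0 or offset + w > len(protein):
        raise ValueError(f"motif window [{offset}, {offset + w}) outside protein "
                         f"of length {len(protein)}")
    if not 0 <= noise < 1:
        raise ValueError("noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    window = list(motif_consensus)
    for i in range(w):
        if noise > 0 and rng.random() < noise:
            choices = [a for a in _AA if a != window[i]]
            window[i] = choices[int(rng.integers(0, len(choices)))]
    return protein[:offset] + "".join(window) + protein[offset + w:]


# ---------------------------------------------------------------------------
# codon-pair evolution
# ---------------------------------------------------------------------------

def _codon_changes(codon: str):
    """(synonymous, nonsynonymous) one-step changes avoiding stop codons."""
    syn, nonsyn = [], []
    aa = _CODON_TABLE[codon]
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in _STOPS:
                continue
            (syn if _CODON_TABLE[alt] == aa else nonsyn).append(alt)
    return syn, nonsyn


def _evolve_lineage(rng: np.random.Generator, codons: list[str],
                    n_syn: int, n_nonsyn: int) -> list[str]:
    codons = list(codons)
    events = ["s"] * n_syn + ["n"] * n_nonsyn
    rng.shuffle(events)
    for kind in events:
        options_per_codon = []
        weights = []
        for c in codons:
            syn, nonsyn = _codon_changes(c)
            opts = syn if kind == "s" else nonsyn
            options_per_codon.append(opts)
            weights.append(len(opts))
        total = sum(weights)
        if total == 0:
            continue
        probs = np.array(weights, dtype=float) / total
        ci = int(rng.choice(len(codons), p=probs))
        opts = options_per_codon[ci]
        codons[ci] = opts[int(rng.integers(0, len(opts)))]
    return codons


def evolve_codon_pair(ancestor_cds: str, target_ks: float, omega: float,
                      seed: int) -> tuple[str, str]:
    """Evolve two descendants to an expected synonymous divergence.

    Each lineage receives Poisson-distributed synonymous and nonsynonymous
    substitution events (expected ds = target_ks/2 per synonymous site and
    dn = omega*ds per nonsynonymous site); events pick uniformly among
    currently possible stop-avoiding one-step codon changes of the requested
    kind.  No stop codons are ever introduced.
    """
    ancestor_cds = ancestor_cds.upper()
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor CDS length not a multiple of 3")
    codons = [ancestor_cds[i:i + 3] for i in range(0, len(ancestor_cds), 3)]
    if any(c in _STOPS for c in codons):
        raise ValueError("ancestor CDS contains stop codons")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if target_ks > 4.0:
        raise ValueError("target_ks too large: synonymous sites would be "
                         "saturated (expected p_s near 3/4); use a smaller Ks")
    if target_ks == 0:
        return ancestor_cds, ancestor_cds
    S = sum(_syn_sites(c) for c in codons)
    N = 3 * len(codons) - S
    ds = target_ks / 2.0
    dn = omega * ds
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        n_syn = int(rng.poisson(ds * S))
        n_nonsyn = int(rng.poisson(dn * N))
        out.append("".join(_evolve_lineage(rng, codons, n_syn, n_nonsyn)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass
class _GeneItem:
    gene_id: str
    protein: str | None = None      # built lazily for plain background
    cds: str | None = None          # set when the CDS is fixed (evolved pairs)
    category: str = "background"


def _domain_variant(rng: np.random.Generator, domain: str, rate: float,
                    keep_e19: bool = True) -> str:
    frozen = {_V_COL - 1}
    if keep_e19:
        frozen.add(_E_COL - 1)
    out = _mutate_protein(rng, domain, rate, frozen=frozen)
    if not keep_e19:
        choices = [a for a in _AA if a != "E"]
        out = out[:_E_COL - 1] + choices[int(rng.integers(0, len(choices)))] + out[_E_COL:]
    return out


def _assemble_family_protein(flank_n: str, domain: str, flank_c: str) -> str:
    return flank_n + domain + flank_c


def simulate_genome(cfg: SimConfig):
    """Generate (GenomeBundle, PlantedTruth, reference panel, seed alignment)."""
    rng = np.random.default_rng(cfg.seed)
    seed_aln = packaged_seed_alignment()
    profile = build_profile(seed_aln)
    domain_base = profile.consensus()

    sizes = {k: v for k, v in sorted(cfg.family_size_per_subgroup.items())}
    subgroups = [s for s in sizes for _ in range(sizes[s])]
    n_family = len(subgroups)
    total_slots = cfg.n_chromosomes * cfg.genes_per_chromosome

    # ---- subgroup ancestors -------------------------------------------
    flank_n_len, flank_c_len = 70, 70
    fam_flank_n = _random_protein(rng, flank_n_len)
    fam_flank_c = _random_protein(rng, flank_c_len)
    sg_ancestors: dict[str, tuple[str, str, str]] = {}
    for sg in sizes:
        fn = _mutate_protein(rng, fam_flank_n, 0.35)
        fc = _mutate_protein(rng, fam_flank_c, 0.35)
        dom = _domain_variant(rng, domain_base, 0.12)
        sg_ancestors[sg] = (fn, dom, fc)

    # ---- allocate family members to pairs and singletons ---------------
    n_pairs = cfg.n_tandem_arrays + cfg.n_segmental_blocks
    if 2 * n_pairs > n_family:
        raise ValueError("family too small for the requested duplicate pairs")
    capacity = dict(sizes)
    pair_subgroups: list[str] = []
    for _ in range(n_pairs):
        avail = sorted(sg for sg, c in capacity.items() if c >= 2)
        if not avail:
            raise ValueError("cannot place duplicate pairs within subgroups")
        weights = np.array([capacity[sg] for sg in avail], dtype=float)
        sg = avail[int(rng.choice(len(avail), p=weights / weights.sum()))]
        capacity[sg] -= 2
        pair_subgroups.append(sg)
    singleton_subgroups = sorted(sg for sg, c in capacity.items() for _ in range(c))

    fam_ids = [f"FAM{i + 1:03d}" for i in range(n_family)]
    fam_iter = iter(fam_ids)
    family_members: dict[str, str] = {}

    # choose which members carry E19
    n_e19 = int(round(cfg.e19_fraction * n_family))
    e19_flags = np.zeros(n_family, dtype=bool)
    e19_flags[rng.choice(n_family, size=n_e19, replace=False)] = True
    e19_of = dict(zip(fam_ids, e19_flags))

    # motif -> subgroup assignment (cycled) and site bookkeeping
    motif_sites: dict[str, list[tuple[str, int]]] = {c: [] for _, c in cfg.motif_specs}
    sg_list = sorted(sizes)
    motif_of_sg: dict[str, list[tuple[int, str]]] = {sg: [] for sg in sg_list}
    by_size = sorted(sg_list, key=lambda s: (-sizes[s], s))
    for mi, spec in enumerate(cfg.motif_specs):
        motif_of_sg[by_size[mi % len(by_size)]].append(spec)

    def build_member_protein(member_id: str, sg: str) -> tuple[str, list[tuple[str, int]]]:
        fn, dom, fc = sg_ancestors[sg]
        fn = _mutate_protein(rng, fn, 0.22)
        fc = _mutate_protein(rng, fc, 0.22)
        dom_m = _domain_variant(rng, dom, 0.02, keep_e19=bool(e19_of[member_id]))
        # per-member random tail: motifs planted there stand out against an
        # otherwise unconserved background, as in real variable C-termini
        tail = _random_protein(rng, 55)
        prot = _assemble_family_protein(fn, dom_m, fc) + tail
        sites = []
        for w, cons in motif_of_sg[sg]:
            lo = len(prot) - len(tail)
            hi = len(prot) - w
            if hi < lo:
                continue
            off = int(rng.integers(lo, hi + 1))
            prot = plant_motif(prot, cons, off, noise=0.05,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
            sites.append((cons, off))
        return prot, sites

    # ---- duplicate pairs (tandem + segmental) --------------------------
    ks_cycle = itertools.cycle(sorted(cfg.target_ks_list))
    pair_targets: dict[tuple[str, str], tuple[float, float]] = {}
    tandem_groups: list[list[_GeneItem]] = []   # contiguous runs
    seg_family_pairs: list[tuple[_GeneItem, _GeneItem]] = []
    pending_sites: dict[str, list[tuple[str, int]]] = {}

    def evolve_member_pair(sg: str, id_a: str, id_b: str):
        e19_of[id_b] = e19_of[id_a]     # duplicates share the ancestral state
        prot, sites = build_member_protein(id_a, sg)
        cds = _back_translate(rng, prot, terminal_stop=False)
        ks = next(ks_cycle)
        cds_a, cds_b = evolve_codon_pair(cds, ks, cfg.target_omega,
                                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        # re-pin the diagnostic codons so the planted rule stays exact
        vpos, epos = flank_n_len + _V_COL - 1, flank_n_len + _E_COL - 1
        anc_codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        fixed = []
        for d in (cds_a, cds_b):
            cod = [d[i:i + 3] for i in range(0, len(d), 3)]
            for pos in (vpos, epos):
                if _CODON_TABLE[cod[pos]] != _CODON_TABLE[anc_codons[pos]]:
                    cod[pos] = anc_codons[pos]
            fixed.append("".join(cod))
        cds_a, cds_b = fixed
        pair_targets[tuple(sorted((id_a, id_b)))] = (ks, cfg.target_omega)
        for gid, d in ((id_a, cds_a), (id_b, cds_b)):
            pending_sites[gid] = sites
        item_a = _GeneItem(id_a, protein=translate(cds_a + "TAA"),
                           cds=cds_a + "TAA", category="family")
        item_b = _GeneItem(id_b, protein=translate(cds_b + "TAA"),
                           cds=cds_b + "TAA", category="family")
        return item_a, item_b

    for ti in range(cfg.n_tandem_arrays):
        sg = pair_subgroups[ti]
        id_a, id_b = next(fam_iter), next(fam_iter)
        family_members[id_a] = family_members[id_b] = sg
        item_a, item_b = evolve_member_pair(sg, id_a, id_b)
        tandem_groups.append([item_a, item_b])

    for bi in range(cfg.n_segmental_blocks):
        sg = pair_subgroups[cfg.n_tandem_arrays + bi]
        id_a, id_b = next(fam_iter), next(fam_iter)
        family_members[id_a] = family_members[id_b] = sg
        item_a, item_b = evolve_member_pair(sg, id_a, id_b)
        seg_family_pairs.append((item_a, item_b))

    singles: list[_GeneItem] = []
    for sg in singleton_subgroups:
        gid = next(fam_iter)
        family_members[gid] = sg
        prot, sites = build_member_protein(gid, sg)
        pending_sites[gid] = sites
        singles.append(_GeneItem(gid, protein=prot, category="family"))

    # ---- decoys ---------------------------------------------------------
    n_anchor_genes = cfg.n_segmental_blocks * (cfg.block_anchor_count - 1) * 2
    n_background = total_slots - n_family - n_anchor_genes
    if n_background < 0:
        raise ValueError("family and anchors exceed available gene loci")
    n_decoys = int(round(cfg.decoy_fraction * n_background))
    per_type = n_decoys // 3
    v14_negative: set[str] = set()
    multi_domain: set[str] = set()
    no_domain: set[str] = set()
    decoy_items: list[_GeneItem] = []
    dn = 0
    for _ in range(per_type):
        dn += 1
        gid = f"DECV{dn:03d}"
        sg = sg_list[int(rng.integers(0, len(sg_list)))]
        fn, dom, fc = sg_ancestors[sg]
        dom_bad = _domain_variant(rng, dom, 0.02)
        non_v = [a for a in _AA if a != "V"]
        dom_bad = (dom_bad[:_V_COL - 1]
                   + non_v[int(rng.integers(0, len(non_v)))] + dom_bad[_V_COL:])
        prot = _assemble_family_protein(_mutate_protein(rng, fn, 0.22), dom_bad,
                                        _mutate_protein(rng, fc, 0.22))
        v14_negative.add(gid)
        decoy_items.append(_GeneItem(gid, protein=prot, category="decoy"))
    for _ in range(per_type):
        dn += 1
        gid = f"DECM{dn:03d}"
        sg = sg_list[int(rng.integers(0, len(sg_list)))]
        fn, dom, fc = sg_ancestors[sg]
        linker = _random_protein(rng, 25)
        prot = (_mutate_protein(rng, fn, 0.22) + _domain_variant(rng, dom, 0.02)
                + linker + _domain_variant(rng, dom, 0.02)
                + _mutate_protein(rng, fc, 0.22))
        multi_domain.add(gid)
        decoy_items.append(_GeneItem(gid, protein=prot, category="decoy"))
    for _ in range(n_decoys - 2 * per_type):
        dn += 1
        gid = f"DECN{dn:03d}"
        prot = _random_protein(rng, int(rng.integers(120, 320)))
        no_domain.add(gid)
        decoy_items.append(_GeneItem(gid, protein=prot, category="decoy"))

    # ---- background pool ------------------------------------------------
    n_plain = n_background - len(decoy_items)
    plain = [_GeneItem(f"BG{i + 1:04d}") for i in range(n_plain)]
    pool: list[_GeneItem] = decoy_items + plain
    rng.shuffle(pool)

    # ---- segmental blocks: anchors and contiguous segments --------------
    if cfg.n_segmental_blocks and cfg.n_chromosomes < 2:
        raise ValueError("segmental blocks need at least 2 chromosomes")
    chrom_names = [f"chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    seg_segments: list[tuple[str, list[_GeneItem]]] = []
    segmental_pairs: dict[tuple[str, str], str] = {}
    an = 0
    for bi, (fam_a, fam_b) in enumerate(seg_family_pairs):
        block_id = f"planted_block{bi + 1}"
        segmental_pairs[tuple(sorted((fam_a.gene_id, fam_b.gene_id)))] = block_id
        c1, c2 = rng.choice(cfg.n_chromosomes, size=2, replace=False)
        anchors_a: list[_GeneItem] = []
        anchors_b: list[_GeneItem] = []
        for _ in range(cfg.block_anchor_count - 1):
            an += 1
            prot = _random_protein(rng, int(rng.integers(150, 260)))
            cds = _back_translate(rng, prot, terminal_stop=False)
            ca, cb = evolve_codon_pair(cds, 0.3, cfg.target_omega,
                                       seed=int(rng.integers(0, 2 ** 31 - 1)))
            anchors_a.append(_GeneItem(f"ANC{an:03d}a", protein=translate(ca + "TAA"),
                                       cds=ca + "TAA", category="anchor"))
            anchors_b.append(_GeneItem(f"ANC{an:03d}b", protein=translate(cb + "TAA"),
                                       cds=cb + "TAA", category="anchor"))
        ins = int(rng.integers(0, cfg.block_anchor_count))
        anchors_a.insert(ins, fam_a)
        anchors_b.insert(ins, fam_b)
        inverted = bool(rng.random() < 0.3)
        if inverted:
            anchors_b = anchors_b[::-1]

        def with_gaps(items: list[_GeneItem]) -> list[_GeneItem]:
            run: list[_GeneItem] = []
            for k, it in enumerate(items):
                run.append(it)
                if k < len(items) - 1:
                    for _ in range(int(rng.integers(0, 3))):
                        if pool:
                            run.append(pool.pop())
            return run

        seg_segments.append((chrom_names[c1], with_gaps(anchors_a)))
        seg_segments.append((chrom_names[c2], with_gaps(anchors_b)))

    # ---- tandem groups with intervening loci -----------------------------
    tandem_runs: list[tuple[str, list[_GeneItem]]] = []
    for gi, group in enumerate(tandem_groups):
        k = int(rng.integers(0, 6))
        run = [group[0]]
        for _ in range(k):
            if pool:
                run.append(pool.pop())
        run.append(group[1])
        tandem_runs.append(("", run))   # chromosome chosen by load balancing

    # ---- distribute everything over chromosomes --------------------------
    # family-bearing units (tandem runs, block segments, singletons) are kept
    # >= 7 background loci apart so the only tandem-rule pairs are planted ones
    units: dict[str, list[list[_GeneItem]]] = {c: [] for c in chrom_names}
    load = {c: 0 for c in chrom_names}
    for chrom, run in seg_segments:
        units[chrom].append(run)
        load[chrom] += len(run) + 7
    for _, run in tandem_runs:
        chrom = min(chrom_names, key=lambda c: (load[c], c))
        units[chrom].append(run)
        load[chrom] += len(run) + 7
    for single in singles:
        chrom = min(chrom_names, key=lambda c: (load[c], c))
        units[chrom].append([single])
        load[chrom] += 1 + 7
    layout: dict[str, list[_GeneItem]] = {}
    min_sep = 7
    for chrom in chrom_names:
        runs = list(units[chrom])
        rng.shuffle(runs)
        placed = sum(len(r) for r in runs)
        need = cfg.genes_per_chromosome - placed
        if need < 0:
            raise ValueError(f"{chrom}: planted structures exceed its gene capacity")
        fillers = [pool.pop() for _ in range(min(need, len(pool)))]
        m, k = len(fillers), len(runs)
        sep = min(min_sep, m // max(k - 1, 1)) if k > 1 else 0
        if k:
            span = m - sep * (k - 1)
            base = sorted(int(rng.integers(0, span + 1)) for _ in range(k))
            positions = [b + sep * i for i, b in enumerate(base)]
        else:
            positions = []
        out_items: list[_GeneItem] = []
        prev = 0
        for pos_, run in zip(positions, runs):
            out_items.extend(fillers[prev:pos_])
            out_items.extend(run)
            prev = pos_
        out_items.extend(fillers[prev:])
        layout[chrom] = out_items
    if pool:
        layout[chrom_names[-1]].extend(pool)
        pool = []

    # ---- build sequences, coordinates and structures ----------------------
    genes: list[GeneModel] = []
    proteins: dict[str, SequenceRecord] = {}
    chrom_seqs: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    intron_phases: dict[str, list[int]] = {}

    for chrom in chrom_names:
        parts: list[str] = []
        pos = 0
        for item in layout[chrom]:
            if item.protein is None:
                item.protein = _random_protein(rng, int(rng.integers(100, 300)))
            if item.cds is None:
                item.cds = _back_translate(rng, item.protein)
            cds = item.cds
            gap = int(rng.integers(200, 801))
            parts.append("".join(rng.choice(list(_NT), size=gap)))
            pos += gap

            if item.category == "family":
                r = rng.random()
                n_introns = 0 if r < 0.85 else (3 if r > 0.98 else 1)
            else:
                n_introns = int(rng.integers(0, 3)) if rng.random() < 0.3 else 0
            n_introns = min(n_introns, len(cds) // 60 - 1 if len(cds) >= 120 else 0)
            n_introns = max(n_introns, 0)
            if n_introns:
                cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_introns,
                                         replace=False).tolist())
            else:
                cuts = []
            tx_lens = []
            prev = 0
            for c in cuts:
                tx_lens.append(c - prev)
                prev = c
            tx_lens.append(len(cds) - prev)
            phases = []
            cum = 0
            for ln in tx_lens[:-1]:
                cum += ln
                phases.append(cum % 3)
            strand = "+" if rng.random() < 0.5 else "-"
            pieces_tx = []
            prev = 0
            for ln in tx_lens:
                pieces_tx.append(cds[prev:prev + ln])
                prev += ln
            if strand == "+":
                genomic_pieces = pieces_tx
            else:
                genomic_pieces = [reverse_complement(p) for p in reversed(pieces_tx)]
            exons = []
            gpos = pos
            for k, piece in enumerate(genomic_pieces):
                exons.append((gpos, gpos + len(piece)))
                parts.append(piece)
                gpos += len(piece)
                if k < len(genomic_pieces) - 1:
                    ilen = int(rng.integers(80, 301))
                    parts.append("".join(rng.choice(list(_NT), size=ilen)))
                    gpos += ilen
            span = (pos, gpos)
            pos = gpos
            genes.append(GeneModel(gene_id=item.gene_id, chromosome=chrom,
                                   span=span, strand=strand, exons=exons, cds=cds))
            proteins[item.gene_id] = SequenceRecord(item.gene_id, translate(cds))
            intron_phases[item.gene_id] = phases
        tail = int(rng.integers(200, 801))
        parts.append("".join(rng.choice(list(_NT), size=tail)))
        pos += tail
        chrom_seqs[chrom] = "".join(parts)
        chrom_lengths[chrom] = pos

    compute_ranks(genes)
    bundle = GenomeBundle(genome_id="synthA", chromosomes=chrom_lengths,
                          genes=genes, proteins=proteins,
                          chromosome_seqs=chrom_seqs)

    # ---- truth: tandem pairs re-derived from the final layout -------------
    # (the planted runs are guaranteed members; any family pair that the
    # shuffle happened to leave within the locus threshold belongs in the
    # truth as well, since the tandem rule is purely positional)
    info = {g.gene_id: (g.chromosome, g.rank) for g in genes}
    tandem_pairs: dict[tuple[str, str], int] = {}
    fam_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid in sorted(family_members):
        ch, rk = info[gid]
        fam_by_chrom.setdefault(ch, []).append((rk, gid))
    for ch in sorted(fam_by_chrom):
        ranked = sorted(fam_by_chrom[ch])
        for (ra, ga), (rb, gb) in itertools.combinations(ranked, 2):
            if rb - ra - 1 <= 5:
                tandem_pairs[tuple(sorted((ga, gb)))] = rb - ra - 1
    for _, run in tandem_runs:
        a, b = run[0].gene_id, run[-1].gene_id
        assert tuple(sorted((a, b))) in tandem_pairs

    truth_sites: dict[str, list[tuple[str, int]]] = {c: [] for _, c in cfg.motif_specs}
    for gid, sites in sorted(pending_sites.items()):
        for cons, off in sites:
            truth_sites[cons].append((gid, off))

    truth = PlantedTruth(
        family_members=family_members,
        v14_negative_decoys=v14_negative,
        multi_domain_decoys=multi_domain,
        no_domain_decoys=no_domain,
        tandem_pairs=tandem_pairs,
        segmental_pairs=segmental_pairs,
        pair_targets=pair_targets,
        motif_sites=truth_sites,
        e19_members={g for g, f in e19_of.items() if f},
        intron_phases=intron_phases,
    )

    # ---- labeled reference panel ------------------------------------------
    refs: list[SequenceRecord] = []
    for sg in sg_list:
        fn, dom, fc = sg_ancestors[sg]
        for i in range(cfg.refs_per_subgroup):
            prot = _assemble_family_protein(
                _mutate_protein(rng, fn, 0.10),
                _domain_variant(rng, dom, 0.02),
                _mutate_protein(rng, fc, 0.10))
            refs.append(SequenceRecord(f"REF_{sg}_{i + 1}", prot, description=sg))

    return bundle, truth, refs, seed_aln


# ---------------------------------------------------------------------------
# a diverged second genome with shared collinear blocks
# ---------------------------------------------------------------------------

def simulate_ortholog_genome(bundle: GenomeBundle, truth: PlantedTruth,
                             seed: int, n_shared_blocks: int = 6,
                             anchors_per_block: int = 8,
                             target_ks: float = 0.5, omega: float = 0.2,
                             n_chromosomes: int = 8,
                             genes_per_chromosome: int = 40):
    """Derive genome B sharing collinear windows with ``bundle``.

    Windows of consecutive genome-A genes centered on family members are
    copied, each gene evolved once to roughly ``target_ks`` synonymous
    divergence, and laid out collinearly on genome-B chromosomes.  Returns
    (bundle_b, expected_family_ortholog_count, shared_window_gene_ids).
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in bundle.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.rank)

    fam = sorted(truth.family_members)
    anchors_windows: list[list[GeneModel]] = []
    used: set[str] = set()
    candidates = list(fam)
    rng.shuffle(candidates)
    for gid in candidates:
        if len(anchors_windows) >= n_shared_blocks:
            break
        g = bundle.gene(gid)
        row = by_chrom[g.chromosome]
        i = next(k for k, x in enumerate(row) if x.gene_id == gid)
        lo = max(0, i - anchors_per_block // 2)
        window = row[lo:lo + anchors_per_block]
        if len(window) < anchors_per_block:
            continue
        if any(x.gene_id in used for x in window):
            continue
        used.update(x.gene_id for x in window)
        anchors_windows.append(window)

    shared_ids = sorted(used)
    expected = len([gid for gid in shared_ids if gid in truth.family_members])

    # build B gene items: evolved copies of window genes + random background
    items_b: list[tuple[str, str]] = []     # (gene_id, cds without stop)
    window_runs: list[list[tuple[str, str]]] = []
    for wi, window in enumerate(anchors_windows):
        run = []
        for g in window:
            cds = g.cds[:-3] if g.cds[-3:] in _STOPS else g.cds
            _, cb = evolve_codon_pair(cds, target_ks, omega,
                                      seed=int(rng.integers(0, 2 ** 31 - 1)))
            run.append((f"B_{g.gene_id}", cb))
        window_runs.append(run)

    chrom_names = [f"bchr{c + 1:02d}" for c in range(n_chromosomes)]
    per_chrom: dict[str, list[list[tuple[str, str]]]] = {c: [] for c in chrom_names}
    for wi, run in enumerate(window_runs):
        per_chrom[chrom_names[wi % n_chromosomes]].append(run)

    genes_b: list[GeneModel] = []
    proteins_b: dict[str, SequenceRecord] = {}
    lengths_b: dict[str, int] = {}
    bg_i = 0
    for chrom in chrom_names:
        flat: list[list[tuple[str, str]]] = list(per_chrom[chrom])
        n_placed = sum(len(r) for r in flat)
        for _ in range(max(0, genes_per_chromosome - n_placed)):
            bg_i += 1
            prot = _random_protein(rng, int(rng.integers(100, 300)))
            flat.append([(f"BBG{bg_i:04d}", _back_translate(rng, prot, False))])
        rng.shuffle(flat)
        pos = 0
        for run in flat:
            for gid, cds in run:
                pos += int(rng.integers(200, 801))
                full = cds + "TAA"
                span = (pos, pos + len(full))
                genes_b.append(GeneModel(gene_id=gid, chromosome=chrom, span=span,
                                         strand="+", exons=[span], cds=full))
                proteins_b[gid] = SequenceRecord(gid, translate(full))
                pos = span[1]
        lengths_b[chrom] = pos + 500
    compute_ranks(genes_b)
    bundle_b = GenomeBundle(genome_id="synthB", chromosomes=lengths_b,
                            genes=genes_b, proteins=proteins_b)
    return bundle_b, expected, shared_ids
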