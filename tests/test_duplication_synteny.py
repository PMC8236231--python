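import itertools
import math

import numpy as np
import pytest

import genefam as gf
from genefam.duplication_synteny import (CodonAlignment, DuplicatePair,
                                         HomologPair, SaturationError,
                                         _pair_differences, _syn_sites, ng86)
from genefam.io_formats import GeneModel, GenomeBundle, SequenceRecord

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TABLE)


# ---------------------------------------------------------------------------
# an independent brute-force NG86 oracle
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon):
    """Count synonymous one-step neighbours naively; stops count nonsyn."""
    s = 0
    for pos, nt in itertools.product(range(3), "ACGT"):
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if alt not in STOPS and CODON_TABLE[alt] == CODON_TABLE[codon]:
            s += 1
    return s / 3.0


def oracle_differences(c1, c2):
    """Average (syn, nonsyn) steps over substitution pathways, skipping
    pathways that pass through a stop codon when any stop-free pathway
    exists."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    clean, dirty = [], []
    for order in itertools.permutations(positions):
        sd = nd = 0
        cur = c1
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS or cur in STOPS:
                hits_stop = True
                nd += 1
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hits_stop else clean).append((sd, nd))
    paths = clean or dirty
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_ng86(codons_a, codons_b):
    S = Sd = Nd = 0.0
    n = 0
    for c1, c2 in zip(codons_a, codons_b):
        n += 1
        S += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
        sd, nd = oracle_differences(c1, c2)
        Sd += sd
        Nd += nd
    N = 3 * n - S
    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3)
    return jc(Nd / N if N else 0.0), jc(Sd / S if S else 0.0)


# ---------------------------------------------------------------------------
# tandem rule
# ---------------------------------------------------------------------------

def _rank_bundle(ranks):
    """A bundle whose family genes sit at the given ranks on one chromosome."""
    genes = []
    for r in range(max(ranks.values()) + 3):
        gid = next((g for g, rr in ranks.items() if rr == r), f"bg{r}")
        genes.append(GeneModel(gid, "chr1", (r * 1000, r * 1000 + 300), "+",
                               [(r * 1000, r * 1000 + 300)]))
    from genefam.io_formats import compute_ranks
    compute_ranks(genes)
    return GenomeBundle("t", {"chr1": 10 ** 6}, genes, {})


@pytest.mark.parametrize("ra,rb,expect_tandem,expect_interv", [
    (7, 8, True, 0),
    (10, 16, True, 5),     # boundary: exactly five intervening loci
    (10, 17, False, None),
])
def test_tandem_rule_boundaries(ra, rb, expect_tandem, expect_interv):
    bundle = _rank_bundle({"famA": ra, "famB": rb})
    pairs = gf.detect_tandem(["famA", "famB"], bundle)
    if expect_tandem:
        assert len(pairs) == 1 and pairs[0].intervening_loci == expect_interv
    else:
        assert pairs == []


# ---------------------------------------------------------------------------
# collinear chaining
# ---------------------------------------------------------------------------

def _two_chrom_bundle(n=40, name="g"):
    genes = []
    for chrom in ("c1", "c2"):
        for r in range(n):
            genes.append(GeneModel(f"{name}_{chrom}_{r}", chrom,
                                   (r * 1000, r * 1000 + 300), "+",
                                   [(r * 1000, r * 1000 + 300)]))
    from genefam.io_formats import compute_ranks
    compute_ranks(genes)
    return GenomeBundle(name, {"c1": 10 ** 6, "c2": 10 ** 6}, genes, {})


def _pairs(bundle, rank_pairs):
    return [HomologPair(id_a=f"{bundle.genome_id}_c1_{ra}",
                        id_b=f"{bundle.genome_id}_c2_{rb}",
                        bitscore=100.0, genome_a=bundle.genome_id,
                        genome_b=bundle.genome_id)
            for ra, rb in rank_pairs]


def test_planted_block_recovered_exactly():
    bundle = _two_chrom_bundle()
    anchors = [(3, 10), (5, 12), (6, 13), (9, 15), (10, 18), (12, 20)]
    blocks = gf.detect_collinear(bundle, bundle, _pairs(bundle, anchors))
    assert len(blocks) == 1
    assert blocks[0].orientation == "same"
    assert blocks[0].ranks == anchors


def test_scattered_anchors_beyond_gap_make_no_block():
    bundle = _two_chrom_bundle()
    anchors = [(0, 0), (30, 1), (31, 35), (5, 20), (12, 8)]
    assert gf.detect_collinear(bundle, bundle, _pairs(bundle, anchors)) == []


def test_inverted_block_orientation():
    bundle = _two_chrom_bundle()
    anchors = [(3, 20), (5, 18), (6, 15), (9, 13), (10, 10)]
    blocks = gf.detect_collinear(bundle, bundle, _pairs(bundle, anchors))
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def test_classification_priority_and_membership():
    tandem = [DuplicatePair("famA", "famB", "tandem", intervening_loci=0)]
    bundle = _two_chrom_bundle()
    blocks = gf.detect_collinear(
        bundle, bundle, _pairs(bundle, [(1, 1), (2, 2), (3, 3), (4, 4), (5, 5)]))
    fam = ["famA", "famB", "g_c1_3", "g_c2_3"]
    out = gf.classify_duplicates(fam, tandem, blocks)
    kinds = {(p.id_a, p.id_b): p.dup_type for p in out}
    assert kinds[("famA", "famB")] == "tandem"
    assert kinds[("g_c1_3", "g_c2_3")] == "segmental"


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def test_codon_align_identity_and_gap():
    ca = gf.codon_align(("MK", "MK"), "ATGAAA", "ATGAAATAA")
    assert ca.codons_a == ["ATG", "AAA"] and ca.codons_b == ["ATG", "AAA"]
    ca = gf.codon_align(("MK-", "MKV"), "ATGAAA", "ATGAAAGTT")
    assert ca.codons_a == ["ATG", "AAA", "---"]
    assert ca.codons_b == ["ATG", "AAA", "GTT"]


def test_codon_align_translation_mismatch_error():
    with pytest.raises(ValueError, match="second"):
        gf.codon_align(("MK", "MK"), "ATGAAA", "ATGAAAGTT")


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def test_ng86_identical_sequences():
    ca = CodonAlignment(["ATG", "AAA"], ["ATG", "AAA"])
    ka, ks, omega = gf.ng86(ca)
    assert ka == 0.0 and ks == 0.0 and omega is None


def test_ng86_fourfold_degenerate_hand_case():
    # GTT vs GTA at a fourfold-degenerate third position: S=2 over the two
    # codons, Sd=1, so pS=1/2 and ks=(3/4)ln3; no nonsynonymous change
    ca = CodonAlignment(["GTT", "GTT"], ["GTA", "GTT"])
    ka, ks, _ = gf.ng86(ca)
    assert ka == 0.0
    assert math.isclose(ks, 0.75 * math.log(3), rel_tol=1e-12)
    assert _syn_sites("GTT") == 1.0


def test_ng86_symmetry_and_site_conservation():
    rng = np.random.default_rng(17)
    for _ in range(30):
        codons_a = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=12)]
        codons_b = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=12)]
        try:
            ka1, ks1, _ = gf.ng86(CodonAlignment(codons_a, codons_b))
            ka2, ks2, _ = gf.ng86(CodonAlignment(codons_b, codons_a))
        except SaturationError:
            continue
        assert math.isclose(ka1, ka2, abs_tol=1e-12)
        assert math.isclose(ks1, ks2, abs_tol=1e-12)
        S = sum((_syn_sites(a) + _syn_sites(b)) / 2
                for a, b in zip(codons_a, codons_b))
        N = 3 * 12 - S
        assert abs((S + N) - 36) < 1e-9


def test_ng86_matches_brute_force_oracle_on_random_pairs():
    rng = np.random.default_rng(23)
    neutral = ["GGT", "GGC", "GGA", "GGG", "CCT", "CCA", "CCG", "CCC", "GCT", "GCA"]
    for _ in range(100):
        c1 = SENSE_CODONS[int(rng.integers(0, 61))]
        c2 = SENSE_CODONS[int(rng.integers(0, 61))]
        a, b = neutral + [c1], neutral + [c2]
        try:
            ka, ks, _ = gf.ng86(CodonAlignment(a, b))
        except SaturationError:
            continue
        oka, oks = oracle_ng86(a, b)
        assert math.isclose(ka, oka, abs_tol=1e-9)
        assert math.isclose(ks, oks, abs_tol=1e-9)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=6, max_size=12),
       st.lists(st.sampled_from(SENSE_CODONS), min_size=6, max_size=12))
def test_ng86_properties_hold_for_arbitrary_codon_strings(ca_list, cb_list):
    """Symmetry, site conservation, and oracle agreement on arbitrary pairs."""
    n = min(len(ca_list), len(cb_list))
    a, b = ca_list[:n], cb_list[:n]
    try:
        ka1, ks1, _ = gf.ng86(CodonAlignment(a, b))
        ka2, ks2, _ = gf.ng86(CodonAlignment(b, a))
    except SaturationError:
        return
    assert math.isclose(ka1, ka2, abs_tol=1e-12)
    assert math.isclose(ks1, ks2, abs_tol=1e-12)
    oka, oks = oracle_ng86(a, b)
    assert math.isclose(ka1, oka, abs_tol=1e-9)
    assert math.isclose(ks1, oks, abs_tol=1e-9)


def test_ng86_rejects_stop_codons_and_empty():
    with pytest.raises(ValueError):
        gf.ng86(CodonAlignment(["TAA"], ["ATG"]))
    with pytest.raises(ValueError):
        gf.ng86(CodonAlignment(["---"], ["---"]))


def test_pathway_averaging_excludes_stop_routes():
    # TGT -> TGG and AGT -> TGG style two-step pairs where one pathway
    # crosses a stop codon: averaged counts must match the oracle
    for c1, c2 in [("TGT", "TGG"), ("AGT", "AGG"), ("TCA", "TTG")]:
        sd, nd = _pair_differences(c1, c2)
        osd, ond = oracle_differences(c1, c2)
        assert math.isclose(sd, osd, abs_tol=1e-12)
        assert math.isclose(nd, ond, abs_tol=1e-12)


# ---------------------------------------------------------------------------
# divergence dating
# ---------------------------------------------------------------------------

def test_divergence_time_formula():
    assert gf.divergence_time(0.0) == 0.0
    assert math.isclose(gf.divergence_time(0.1312), 10.0, rel_tol=1e-12)
    assert gf.divergence_time(0.2) > gf.divergence_time(0.1)
    with pytest.raises(ValueError):
        gf.divergence_time(-0.1)


# ---------------------------------------------------------------------------
# ortholog counting
# ---------------------------------------------------------------------------

def test_ortholog_counts_requires_cross_genome_and_counts_family():
    a = _two_chrom_bundle(name="ga")
    b = _two_chrom_bundle(name="gb")
    pairs = [HomologPair(f"ga_c1_{r}", f"gb_c1_{r}", 100.0, "ga", "gb")
             for r in range(1, 7)]
    blocks = gf.detect_collinear(a, b, pairs)
    assert len(blocks) == 1
    fam = ["ga_c1_2", "ga_c1_3", "ga_c1_4", "ga_c1_30"]
    assert gf.ortholog_counts(blocks, fam) == 3
    assert gf.ortholog_counts([], fam) == 0
    blocks[0].genomes = ("ga", "ga")
    with pytest.raises(ValueError):
        gf.ortholog_counts(blocks, fam)
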