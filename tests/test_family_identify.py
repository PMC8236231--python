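import math

import numpy as np
import pytest

import genefam as gf
from genefam.family_identify import DomainHit, evalue, net_charge

RNG = np.random.default_rng(20240915)
AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


# ---------------------------------------------------------------------------
# profile building
# ---------------------------------------------------------------------------

def test_profile_consensus_maximal_for_identical_sequences():
    seqs = [gf.SequenceRecord(f"s{i}", "MKVWED") for i in range(4)]
    prof = gf.build_profile(seqs)
    for col, expected in zip(prof.log_odds, "MKVWED"):
        assert max(col, key=col.get) == expected


def test_profile_hand_log_odds():
    # a pure-V column with bg(V)=0.05 and vanishing pseudocount: log2(1/0.05)
    seqs = [gf.SequenceRecord(f"s{i}", "V") for i in range(4)]
    bg = {a: 0.05 for a in AA}
    prof = gf.build_profile(seqs, pseudocount=1e-9, background=bg)
    assert math.isclose(prof.log_odds[0]["V"], math.log2(1 / 0.05), rel_tol=1e-6)


def test_profile_single_sequence_is_error():
    with pytest.raises(ValueError):
        gf.build_profile([gf.SequenceRecord("s", "MKV")])


def test_packaged_seed_alignment_drops_gap_columns(packaged_profile):
    # the shipped alignment is 56 columns; two are gapped in 7/8 rows
    assert packaged_profile.n_columns == 54
    assert len(packaged_profile.column_map) == 54


# ---------------------------------------------------------------------------
# domain scanning
# ---------------------------------------------------------------------------

def test_scan_consensus_single_gapfree_hit(packaged_profile):
    cons = packaged_profile.consensus()
    prot = gf.SequenceRecord("p", "M" * 25 + cons + "K" * 25)
    hits = gf.scan_domain(prot, packaged_profile)
    assert len(hits) == 1
    (hit,) = hits
    assert hit.query_span == (25, 25 + len(cons))
    assert "-" not in hit.col_to_residue.values()
    assert hit.residue14 == "V" and hit.residue19 == "E"


def test_scan_finds_published_potato_ap2_region(packaged_profile):
    # AP2 domain region of a potato DREB protein (Pfam match row), with the
    # alignment gap removed; embedded in random flanks it must yield one hit
    region = "PVYRGVRMRNSGKWVCEVREPNKKTRIWLGTFPTAEMAARAHDVAAIALRG"
    rng = np.random.default_rng(7)
    prot = gf.SequenceRecord("potato_dreb",
                             _random_protein(rng, 59) + region + _random_protein(rng, 40))
    hits = gf.scan_domain(prot, packaged_profile)
    assert len(hits) == 1
    start, end = hits[0].query_span
    assert start >= 55 and end <= 59 + len(region) + 4


def test_scan_null_rate_on_shuffled_proteins(packaged_profile):
    cons = packaged_profile.consensus()
    rng = np.random.default_rng(1)
    n_hits = 0
    for _ in range(100):
        shuffled = "".join(rng.permutation(list(cons * 4)))
        if gf.scan_domain(gf.SequenceRecord("r", shuffled), packaged_profile):
            n_hits += 1
    assert n_hits <= 1


def test_scan_two_copies_gives_two_hits(packaged_profile):
    cons = packaged_profile.consensus()
    prot = gf.SequenceRecord("p2", "M" * 15 + cons + "G" * 20 + cons + "K" * 15)
    hits = gf.scan_domain(prot, packaged_profile)
    assert len(hits) == 2
    spans = sorted(h.query_span for h in hits)
    assert spans[0][1] <= spans[1][0]   # non-overlapping


# ---------------------------------------------------------------------------
# homology candidate search
# ---------------------------------------------------------------------------

def test_candidate_search_keeps_identical_target():
    q = [gf.SequenceRecord("q", "MKVWEDLYRAGHPQSTNCIF" * 5)]
    t = [gf.SequenceRecord("t", q[0].residues)]
    assert gf.candidate_search(q, t) == {"t"}


def test_candidate_search_rejects_random_targets():
    rng = np.random.default_rng(3)
    q = [gf.SequenceRecord("q", _random_protein(rng, 150))]
    rejected = 0
    for i in range(50):
        t = [gf.SequenceRecord("t", _random_protein(rng, 300))]
        if not gf.candidate_search(q, t):
            rejected += 1
    assert rejected >= 49


def test_candidate_search_empty_inputs_error():
    with pytest.raises(ValueError):
        gf.candidate_search([], [gf.SequenceRecord("t", "MK")])


def test_evalue_monotone_in_score():
    assert evalue(100, 200, 200) < evalue(50, 200, 200)


# ---------------------------------------------------------------------------
# the V14/E19 filter
# ---------------------------------------------------------------------------

def _hit(pid, r14, r19):
    return DomainHit(protein_id=pid, query_span=(0, 54), score=100.0,
                     col_to_residue={14: r14, 19: r19})


def test_filter_dreb_partitions():
    hits = {
        "both": [_hit("both", "V", "E")],
        "vonly": [_hit("vonly", "V", "Q")],
        "wrong14": [_hit("wrong14", "A", "E")],
        "twodomains": [_hit("twodomains", "V", "E"), _hit("twodomains", "V", "E")],
        "nothing": [],
    }
    accepted, v_and_e, v_only, rejected = gf.filter_dreb(hits)
    assert accepted == {"both", "vonly"}
    assert v_and_e == {"both"} and v_only == {"vonly"}
    assert rejected == {"wrong14": "not_V14", "twodomains": "multiple_domains",
                        "nothing": "no_domain"}
    assert len(accepted) + len(rejected) == len(hits)


def test_filter_dreb_gap_at_column_14_rejected():
    accepted, _, _, rejected = gf.filter_dreb({"g": [_hit("g", "-", "E")]})
    assert not accepted and rejected["g"] == "not_V14"


# ---------------------------------------------------------------------------
# physicochemical properties
# ---------------------------------------------------------------------------

def test_physchem_glycine_mass():
    pc = gf.physchem(gf.SequenceRecord("g", "G"))
    assert math.isclose(pc.mw, 57.0519 + 18.0153, abs_tol=1e-3)


def test_net_charge_zero_at_pi():
    rng = np.random.default_rng(5)
    for _ in range(100):
        seq = _random_protein(rng, int(rng.integers(10, 200)))
        pc = gf.physchem(gf.SequenceRecord("p", seq))
        assert abs(net_charge(seq, pc.pi)) < 1e-4
        assert 0 < pc.pi < 14


def test_basic_peptide_has_higher_pi_than_acidic():
    pk = gf.physchem(gf.SequenceRecord("k", "K" * 20)).pi
    pd_ = gf.physchem(gf.SequenceRecord("d", "D" * 20)).pi
    assert pk > pd_


def test_physchem_rejects_nonstandard_residue():
    with pytest.raises(ValueError):
        gf.physchem(gf.SequenceRecord("x", "MKXV"))


def test_physchem_matches_protparam_reference():
    # same Bjellqvist-style pKa table as the Biopython ProtParam implementation
    from Bio.SeqUtils.ProtParam import ProteinAnalysis
    rng = np.random.default_rng(9)
    for _ in range(10):
        seq = _random_protein(rng, 120)
        ours = gf.physchem(gf.SequenceRecord("p", seq))
        ref = ProteinAnalysis(seq)
        assert math.isclose(ours.mw, ref.molecular_weight(), abs_tol=0.5)
        # near the pI the charge curve can be nearly flat, so compare the
        # charge models at each other's root instead of the pH values
        assert abs(net_charge(seq, ref.isoelectric_point())) < 2e-4
        assert abs(ref.charge_at_pH(ours.pi)) < 2e-4
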