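"""Gene-family member identification.

The stage mirrors how AP2/ERF (DREB) families are delimited in practice:

1. homology search of labeled reference proteins against the proteome
   (Smith-Waterman + Karlin-Altschul E-value, default cutoff 1e-5),
2. a position-specific scoring matrix (PSSM) scan for the ~54-column AP2
   domain, glocal (whole profile vs. any protein substring, affine gaps on
   both sides),
3. the diagnostic residue filter: DREBs carry exactly one AP2 domain with
   valine at profile column 14 (glutamic acid at column 19 is typical but
   not required),
4. ProtParam-style length / molecular weight / isoelectric point.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

log = logging.getLogger("genefam")

# Ungapped Karlin-Altschul parameters for BLOSUM62.
KA_LAMBDA = 0.3176
KA_K = 0.134

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_BIT_THRESHOLD = 25.0

# Diagnostic profile columns (1-based match-column numbering).
V_COLUMN = 14
E_COLUMN = 19


def _load_tables() -> dict:
    with resources.files("genefam.data").joinpath("physchem_tables.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()
BACKGROUND_FREQS: dict[str, float] = _TABLES["background_frequencies"]


def packaged_seed_alignment() -> list[SequenceRecord]:
    """The AP2 seed alignment shipped with the package."""
    from .io_formats import read_fasta
    with resources.as_file(resources.files("genefam.data").joinpath("ap2_seed.fasta")) as p:
        return read_fasta(p)


# ---------------------------------------------------------------------------
# domain profile
# ---------------------------------------------------------------------------

@dataclass
class DomainProfile:
    """Log-odds PSSM over match columns of a seed alignment (bits)."""

    n_columns: int
    log_odds: list[dict[str, float]]
    background: dict[str, float]
    gap_open: float = -6.0
    gap_extend: float = -1.5
    column_map: list[int] = field(default_factory=list)  # kept -> original column

    def consensus(self) -> str:
        return "".join(max(col, key=lambda a: (col[a], a)) for col in self.log_odds)


def build_profile(seed_alignment: list[SequenceRecord],
                  pseudocount: float = 0.5,
                  background: dict[str, float] | None = None,
                  max_gap_fraction: float = 0.5) -> DomainProfile:
    """Build a log-odds profile; columns with >50% gaps are dropped.

    Per column: score(a) = log2(((count_a + pc*bg_a) / (total + pc)) / bg_a).
    """
    if len(seed_alignment) < 2:
        raise ValueError("profile needs at least 2 aligned sequences")
    lengths = {len(r.residues) for r in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("seed alignment rows have unequal lengths")
    ncol_full = lengths.pop()
    bg = dict(background or BACKGROUND_FREQS)
    n = len(seed_alignment)

    kept: list[int] = []
    log_odds: list[dict[str, float]] = []
    for c in range(ncol_full):
        column = [r.residues[c] for r in seed_alignment]
        gaps = column.count("-")
        if gaps / n > max_gap_fraction:
            continue
        residues = [a for a in column if a != "-"]
        total = len(residues)
        scores = {}
        for a in bg:
            count = residues.count(a)
            p = (count + pseudocount * bg[a]) / (total + pseudocount)
            scores[a] = math.log2(p / bg[a])
        kept.append(c)
        log_odds.append(scores)
    if not log_odds:
        raise ValueError("all columns gapped beyond the allowed fraction")
    dropped = [c for c in range(ncol_full) if c not in set(kept)]
    if dropped:
        log.info("profile: dropped %d gap-heavy columns %s", len(dropped), dropped)
    return DomainProfile(n_columns=len(log_odds), log_odds=log_odds,
                         background=bg, column_map=kept)


# ---------------------------------------------------------------------------
# glocal PSSM scan
# ---------------------------------------------------------------------------

@dataclass
class DomainHit:
    protein_id: str
    query_span: tuple[int, int]
    score: float
    col_to_residue: dict[int, str]   # 1-based profile column -> residue or '-'

    @property
    def residue14(self) -> str:
        return self.col_to_residue.get(V_COLUMN, "-")

    @property
    def residue19(self) -> str:
        return self.col_to_residue.get(E_COLUMN, "-")


_NEG = -1e30


def _glocal_dp(profile: DomainProfile, seq: str):
    """Glocal affine-gap DP; returns (M, D, I, best_score, best_end_j)."""
    n = profile.n_columns
    L = len(seq)
    go, ge = profile.gap_open, profile.gap_extend
    # per-column emission scores against the sequence
    emit = np.empty((n, L))
    for i, col in enumerate(profile.log_odds):
        emit[i] = [col.get(a, min(col.values())) for a in seq]

    M = np.full((n + 1, L + 1), _NEG)
    D = np.full((n + 1, L + 1), _NEG)
    I = np.full((n + 1, L + 1), _NEG)
    M[0, :] = 0.0   # free start anywhere in the protein
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = prev_best[:-1] + emit[i - 1]
        D[i] = np.maximum(M[i - 1] + go, D[i - 1] + ge)
        # I[i, j] = max(M[i, j-1] + go, I[i, j-1] + ge)  (running max form)
        t = M[i, :-1] + go - ge * (np.arange(L) + 1)
        I[i, 1:] = np.maximum.accumulate(t) + ge * np.arange(1, L + 1)
    final = np.maximum(M[n], D[n])
    j = int(np.argmax(final))
    return M, D, I, float(final[j]), j


def _traceback(profile: DomainProfile, seq: str, M, D, I, end_j: int):
    """Recover the column->residue map and the consumed protein span."""
    n = profile.n_columns
    go, ge = profile.gap_open, profile.gap_extend
    i, j = n, end_j
    state = "M" if M[n, end_j] >= D[n, end_j] else "D"
    col_to_residue: dict[int, str] = {}
    last_j = end_j
    eps = 1e-9
    while i > 0:
        if state == "M":
            col_to_residue[i] = seq[j - 1]
            prev = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = "M"
            elif abs(D[i - 1, j - 1] - prev) < eps:
                state = "D"
            else:
                state = "I"
            i, j = i - 1, j - 1
        elif state == "D":
            col_to_residue[i] = "-"
            if abs(D[i, j] - (M[i - 1, j] + go)) < eps:
                state = "M"
            else:
                state = "D"
            i = i - 1
        else:  # I: inserted protein residue, no profile column consumed
            if abs(I[i, j] - (M[i, j - 1] + go)) < eps:
                state = "M"
            else:
                state = "I"
            j = j - 1
    start_j = j
    return col_to_residue, (start_j, last_j)


def _scan_segment(profile: DomainProfile, protein_id: str, seq: str,
                  offset: int, threshold: float, out: list[DomainHit]) -> None:
    if len(seq) < 1:
        return
    M, D, I, score, end_j = _glocal_dp(profile, seq)
    if score < threshold:
        return
    col_map, (a, b) = _traceback(profile, seq, M, D, I, end_j)
    if b <= a:       # degenerate all-deletion alignment; nothing consumed
        return
    out.append(DomainHit(protein_id=protein_id,
                         query_span=(offset + a, offset + b),
                         score=score, col_to_residue=col_map))
    _scan_segment(profile, protein_id, seq[:a], offset, threshold, out)
    _scan_segment(profile, protein_id, seq[b:], offset + b, threshold, out)


def scan_domain(protein: SequenceRecord, profile: DomainProfile,
                bit_threshold: float = DEFAULT_BIT_THRESHOLD) -> list[DomainHit]:
    """All non-overlapping profile hits above threshold, best score first.

    Overlaps are resolved greedily: the best hit is taken, then the flanking
    segments are re-scanned.
    """
    hits: list[DomainHit] = []
    _scan_segment(profile, protein.id, protein.residues, 0, bit_threshold, hits)
    hits.sort(key=lambda h: (-h.score, h.query_span))
    return hits


# ---------------------------------------------------------------------------
# homology candidate search
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def evalue(score: float, m: int, n: int,
           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul E = K*m*n*exp(-lambda*S)."""
    return k * m * n * math.exp(-lam * score)


def candidate_search(queries: list[SequenceRecord],
                     targets: list[SequenceRecord],
                     evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> set[str]:
    """Target ids attaining E <= cutoff against any query."""
    if not queries or not targets:
        raise ValueError("candidate_search needs non-empty query and target sets")
    aligner = _make_aligner()
    kept: set[str] = set()
    for t in targets:
        for q in queries:
            s = aligner.score(q.residues, t.residues)
            if s <= 0:
                continue
            if evalue(s, len(q), len(t)) <= evalue_cutoff:
                kept.add(t.id)
                break
    return kept


# ---------------------------------------------------------------------------
# the V14 / E19 filter
# ---------------------------------------------------------------------------

def filter_dreb(hits_by_protein: dict[str, list[DomainHit]]):
    """Partition scanned proteins by the single-domain + V14 rule.

    Returns (accepted, v_and_e, v_only, rejected) where rejected maps a
    protein id to one of {"no_domain", "multiple_domains", "not_V14"}.
    A gap at column 14 counts as not-V.
    """
    accepted: set[str] = set()
    v_and_e: set[str] = set()
    v_only: set[str] = set()
    rejected: dict[str, str] = {}
    for pid, hits in hits_by_protein.items():
        if not hits:
            rejected[pid] = "no_domain"
        elif len(hits) > 1:
            rejected[pid] = "multiple_domains"
        elif hits[0].residue14 != "V":
            rejected[pid] = "not_V14"
        else:
            accepted.add(pid)
            if hits[0].residue19 == "E":
                v_and_e.add(pid)
            else:
                v_only.add(pid)
    return accepted, v_and_e, v_only, rejected


# ---------------------------------------------------------------------------
# physicochemical properties
# ---------------------------------------------------------------------------

@dataclass
class PhysChem:
    length: int
    mw: float      # Daltons
    pi: float      # pH units


_MASSES: dict[str, float] = _TABLES["residue_masses"]
_WATER: float = _TABLES["water_mass"]
_PKA_POS: dict[str, float] = _TABLES["pka_positive"]
_PKA_NEG: dict[str, float] = _TABLES["pka_negative"]
_PKA_NTERM: dict[str, float] = _TABLES["pka_nterm_by_residue"]
_PKA_CTERM: dict[str, float] = _TABLES["pka_cterm_by_residue"]


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge; strictly decreasing in pH.

    Terminal pKa values follow the Bjellqvist convention of residue-specific
    adjustments for the first and last residue.
    """
    nterm_pka = _PKA_NTERM.get(seq[0], _PKA_POS["Nterm"]) if seq else _PKA_POS["Nterm"]
    cterm_pka = _PKA_CTERM.get(seq[-1], _PKA_NEG["Cterm"]) if seq else _PKA_NEG["Cterm"]
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa, pka in _PKA_POS.items():
        if aa == "Nterm":
            continue
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in _PKA_NEG.items():
        if aa == "Cterm":
            continue
        charge -= seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def physchem(protein: SequenceRecord) -> PhysChem:
    """Length, average molecular weight, and isoelectric point by bisection."""
    seq = protein.residues
    bad = set(seq) - set(_MASSES)
    if bad:
        raise ValueError(f"{protein.id}: non-standard residues {sorted(bad)}")
    mw = sum(_MASSES[a] for a in seq) + _WATER
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < 1e-4:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return PhysChem(length=len(seq), mw=mw, pi=mid)
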