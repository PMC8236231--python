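"""Gene structure (exon/intron, splicing phases) and protein motif discovery.

Motif discovery is an expectation-maximization fit of the ZOOPS model
("zero or one occurrence per sequence"): each sequence carries at most one
occurrence of an ungapped width-w motif described by a position weight
matrix; a mixing weight gamma is the prior probability that a sequence has a
site.  Motifs are found sequentially, hard-masking discovered sites, with
the width chosen from a grid by a complexity-penalized log-likelihood ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, SequenceRecord

log = logging.getLogger("genefam")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_MASK = 20          # sentinel for hard-masked (neutral) positions
_PSEUDO = 0.25

DEFAULT_WIDTH_GRID = tuple(list(range(6, 49, 3)) + [50])
DEFAULT_SITE_FLOOR = 0.0     # bits; scan_motif reporting threshold


# ---------------------------------------------------------------------------
# gene structure
# ---------------------------------------------------------------------------

@dataclass
class GeneStructure:
    gene_id: str
    n_exons: int
    n_introns: int
    intron_phases: list[int]


def gene_structure(gene: GeneModel) -> GeneStructure:
    """Exon/intron counts and intron phases in transcription order.

    The phase of intron k is the cumulative coding length upstream of it
    modulo 3 (CDS-only gene models; exon == coding exon).
    """
    lens = gene.exon_lengths_tx_order
    phases = []
    cum = 0
    for ln in lens[:-1]:
        cum += ln
        phases.append(cum % 3)
    return GeneStructure(gene_id=gene.gene_id, n_exons=len(lens),
                         n_introns=len(lens) - 1, intron_phases=phases)


# ---------------------------------------------------------------------------
# motif containers
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    motif_id: str
    width: int
    pwm: np.ndarray          # (width, 20) probabilities, rows sum to 1
    consensus: str
    llr: float
    background: np.ndarray   # (20,) frequencies

    def log_ratio(self) -> np.ndarray:
        """(width, 21) log2(pwm/bg) with a neutral 0 column for masked."""
        lr = np.log2(self.pwm / self.background[None, :])
        return np.hstack([lr, np.zeros((self.width, 1))])


@dataclass
class MotifOccurrence:
    motif_id: str
    protein_id: str
    offset: int
    site_score: float


def _encode(proteins: list[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pad to a (n, Lmax) int matrix (mask sentinel beyond each length)."""
    lengths = np.array([len(p.residues) for p in proteins])
    enc = np.full((len(proteins), int(lengths.max())), _MASK, dtype=np.int64)
    for i, p in enumerate(proteins):
        for j, a in enumerate(p.residues):
            enc[i, j] = _AA_INDEX.get(a, _MASK)
    return enc, lengths


def _background_freqs(enc: np.ndarray) -> np.ndarray:
    counts = np.bincount(enc[enc < 20].ravel(), minlength=20).astype(float)
    counts += 1.0
    return counts / counts.sum()


def _window_scores(enc: np.ndarray, log_ratio: np.ndarray, w: int) -> np.ndarray:
    """(n, P) summed log-ratios of every length-w window (P = Lmax-w+1)."""
    n, Lmax = enc.shape
    P = Lmax - w + 1
    scores = np.zeros((n, P))
    for k in range(w):
        scores += log_ratio[k, enc[:, k:k + P]]
    return scores


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _em_zoops(enc: np.ndarray, lengths: np.ndarray, bg: np.ndarray, w: int,
              rng: np.random.Generator, n_restarts: int, max_iter: int,
              trace: list | None = None):
    """Fit one width; returns (ll_ratio, pwm, gamma, Z) of the best restart."""
    n, Lmax = enc.shape
    P = Lmax - w + 1
    valid = np.arange(P)[None, :] <= (lengths - w)[:, None]   # (n, P)
    n_pos = valid.sum(axis=1).astype(float)                   # positions per seq
    usable = n_pos > 0
    if not usable.any():
        return None
    total_positions = float(n_pos.sum())

    def seed_pwm(si: int, sp: int) -> np.ndarray:
        seed_window = enc[si, sp:sp + w]
        pwm = np.tile(bg, (w, 1)) * 0.4
        for k, a in enumerate(seed_window):
            if a < 20:
                pwm[k, a] += 0.6
        return pwm / pwm.sum(axis=1, keepdims=True)

    def run_em(pwm: np.ndarray, iters: int, run_trace: list | None = None):
        gamma = 0.5
        Z = None
        prev_ll = -np.inf
        for _it in range(iters):
            # E-step on likelihood ratios (background terms cancel)
            lr_log = np.log(np.maximum(pwm, 1e-300) / bg[None, :])
            lr_log = np.hstack([lr_log, np.zeros((w, 1))])
            logS = np.zeros((n, P))
            for k in range(w):
                logS += lr_log[k, enc[:, k:k + P]]
            logS[~valid] = -np.inf
            m = logS.max(axis=1, initial=-np.inf)
            m = np.where(np.isfinite(m), m, 0.0)
            S = np.exp(logS - m[:, None])
            S[~valid] = 0.0
            site_term = np.where(usable, gamma / np.maximum(n_pos, 1.0)
                                 * S.sum(axis=1) * np.exp(m), 0.0)
            denom = (1.0 - gamma) + site_term
            ll = float(np.log(np.maximum(denom, 1e-300)).sum())
            if run_trace is not None:
                run_trace.append(ll)
            Z = (gamma / np.maximum(n_pos, 1.0))[:, None] * S * np.exp(m)[:, None] \
                / denom[:, None]
            # M-step
            q = Z.sum(axis=1)
            gamma = float(np.clip(q[usable].mean(), 1e-4, 1 - 1e-4))
            counts = np.zeros((w, 21))
            zflat = Z.ravel()
            for k in range(w):
                idx = enc[:, k:k + P].ravel()
                counts[k] = np.bincount(idx, weights=zflat, minlength=21)
            pwm = counts[:, :20] + _PSEUDO * bg[None, :]
            pwm /= pwm.sum(axis=1, keepdims=True)
            if ll < prev_ll - (1e-6 + 1e-5 * abs(prev_ll)):
                log.warning("ZOOPS EM objective decreased (%.6g -> %.6g)", prev_ll, ll)
            if abs(ll - prev_ll) < 1e-6:
                prev_ll = ll
                break
            prev_ll = ll
        return prev_ll, pwm, gamma, Z

    # screen many candidate seed windows in one vectorized pass (one EM
    # E-step each), then refine only the most promising by full EM
    cand_si, cand_sp = _sample_seed_windows(enc, lengths, w, rng,
                                            n_candidates=150)
    if len(cand_si) == 0:
        return None
    order = _batch_screen(enc, bg, valid, n_pos, usable, w, cand_si, cand_sp)
    # stage 2: a short EM burn-in separates seeds that sharpen into a real
    # motif from broad weak-conservation windows that plateau
    shortlist = []
    for idx in order[:10]:
        pwm0 = seed_pwm(int(cand_si[idx]), int(cand_sp[idx]))
        ll5, pwm5, _, _ = run_em(pwm0, 5)
        shortlist.append((ll5, int(idx), pwm5))
    shortlist.sort(key=lambda t: (-t[0], t[1]))
    best = None
    for _, _, pwm0 in shortlist[:max(n_restarts, 2)]:
        run_trace: list[float] = []
        ll, pwm, gamma, Z = run_em(pwm0, max_iter, run_trace)
        if best is None or ll > best[0]:
            best = (ll, pwm, gamma, Z, total_positions)
            if trace is not None:
                trace[:] = run_trace
    return best


def _sample_seed_windows(enc: np.ndarray, lengths: np.ndarray, w: int,
                         rng: np.random.Generator, n_candidates: int):
    """Sample candidate (sequence, offset) windows, skipping masked regions."""
    n, Lmax = enc.shape
    P = Lmax - w + 1
    pool_si, pool_sp = [], []
    for i in range(n):
        for p in range(max(0, int(lengths[i]) - w + 1)):
            window = enc[i, p:p + w]
            if (window == _MASK).mean() <= 0.3:
                pool_si.append(i)
                pool_sp.append(p)
    pool_si = np.array(pool_si, dtype=int)
    pool_sp = np.array(pool_sp, dtype=int)
    if len(pool_si) == 0:
        return pool_si, pool_sp
    take = min(n_candidates, len(pool_si))
    pick = rng.choice(len(pool_si), size=take, replace=False)
    return pool_si[pick], pool_sp[pick]


def _batch_screen(enc, bg, valid, n_pos, usable, w, cand_si, cand_sp):
    """One-step ZOOPS log-likelihood for every candidate seed, vectorized.

    Returns candidate indices ordered best first.
    """
    C = len(cand_si)
    n, Lmax = enc.shape
    P = Lmax - w + 1
    # per-candidate seed log-ratio matrices (C, w, 21)
    lr = np.zeros((C, w, 21))
    base = np.log(0.4 + 1e-12)          # background mixture of the seed pwm
    for c in range(C):
        window = enc[cand_si[c], cand_sp[c]:cand_sp[c] + w]
        pwm = np.tile(bg, (w, 1)) * 0.4
        rows = np.arange(w)[window < 20]
        pwm[rows, window[window < 20]] += 0.6
        pwm /= pwm.sum(axis=1, keepdims=True)
        lr[c, :, :20] = np.log(pwm / bg[None, :])
    del base
    scores = np.zeros((C, n, P))
    for k in range(w):
        scores += lr[:, k, :][:, enc[:, k:k + P]]
    scores[:, ~valid] = -np.inf
    m = scores.max(axis=2)
    m = np.where(np.isfinite(m), m, 0.0)
    S = np.exp(scores - m[:, :, None]).sum(axis=2)
    gamma = 0.5
    site = np.where(usable[None, :], gamma / np.maximum(n_pos, 1.0)[None, :]
                    * S * np.exp(m), 0.0)
    ll = np.log(np.maximum((1 - gamma) + site, 1e-300)).sum(axis=1)
    return np.argsort(-ll, kind="stable")


def discover_motifs(proteins: list[SequenceRecord],
                    widths: list[int] | tuple[int, ...] = DEFAULT_WIDTH_GRID,
                    max_motifs: int = 15,
                    seed: int = 0,
                    n_restarts: int = 2,
                    max_iter: int = 50,
                    llr_floor: float = 0.0) -> list[MotifModel]:
    """Sequential ZOOPS motif discovery with hard masking.

    For each motif slot every candidate width is fit by EM; the width
    maximizing llr - width*log(total positions) wins.  Sites with posterior
    occurrence probability >= 0.5 are masked before the next slot.  Stops
    early when the penalized llr falls below ``llr_floor``.
    """
    if len(proteins) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    for w in widths:
        if not 6 <= w <= 50:
            raise ValueError(f"motif width {w} outside [6, 50]")
    enc, lengths = _encode(proteins)
    bg = _background_freqs(enc)
    rng = np.random.default_rng(seed)
    motifs: list[MotifModel] = []
    for slot in range(max_motifs):
        best_model = None
        for w in sorted(widths):
            if w > lengths.max():
                log.warning("width %d exceeds longest sequence; skipped", w)
                continue
            fit = _em_zoops(enc, lengths, bg, w, rng, n_restarts, max_iter)
            if fit is None:
                continue
            ll, pwm, gamma, Z, total_positions = fit
            penalized = ll - w * np.log(max(total_positions, 2.0))
            if best_model is None or penalized > best_model[0]:
                best_model = (penalized, ll, w, pwm, gamma, Z)
        if best_model is None or best_model[0] < llr_floor:
            break
        penalized, ll, w, pwm, gamma, Z = best_model
        consensus = "".join(_AA[int(k)] for k in pwm.argmax(axis=1))
        motif = MotifModel(motif_id=f"motif{slot + 1}", width=w, pwm=pwm,
                           consensus=consensus, llr=ll, background=bg)
        motifs.append(motif)
        # hard-mask posterior sites before the next slot
        q = Z.sum(axis=1)
        for i in np.flatnonzero(q >= 0.5):
            p = int(Z[i].argmax())
            enc[i, p:p + w] = _MASK
    return motifs


# ---------------------------------------------------------------------------
# site scanning and presence matrix
# ---------------------------------------------------------------------------

def scan_motif(protein: SequenceRecord, motif: MotifModel,
               score_floor: float = DEFAULT_SITE_FLOOR) -> MotifOccurrence | None:
    """Best-scoring window (bits, log2 pwm/background); one per sequence."""
    if len(protein.residues) < motif.width:
        return None
    enc, _ = _encode([protein])
    scores = _window_scores(enc, motif.log_ratio(), motif.width)[0]
    p = int(scores.argmax())
    if scores[p] < score_floor:
        return None
    return MotifOccurrence(motif_id=motif.motif_id, protein_id=protein.id,
                           offset=p, site_score=float(scores[p]))


def presence_matrix(family: list[str], motifs: list[MotifModel],
                    occurrences: list[MotifOccurrence]) -> "pd.DataFrame":
    """Binary gene x motif occurrence matrix with deterministic ordering."""
    import pandas as pd
    rows = sorted(family)
    cols = [m.motif_id for m in motifs]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for occ in occurrences:
        if occ.protein_id in mat.index and occ.motif_id in mat.columns:
            mat.loc[occ.protein_id, occ.motif_id] = 1
    return mat
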