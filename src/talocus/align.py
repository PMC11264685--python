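"""Seed-and-extend local nucleotide alignment with Karlin-Altschul statistics.

The search pipeline is: exact word seeding on both strands -> ungapped X-drop
extension along the seed diagonal -> banded gapped extension (affine gaps)
around the best ungapped segment -> overlap suppression, E-value filtering and
deterministic sorting.  A full Smith-Waterman implementation (`smith_waterman`)
is provided as an independent optimal-alignment oracle; it shares no DP code
with the banded search path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from ._seq import Interval, SequenceRecord, encode, revcomp

X_DROP = 20          # raw-score drop tolerated during ungapped extension
BAND_WIDTH = 40      # half-width of the gapped extension band
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)

_GAP = 5             # code for '-' in traceback column arrays
_DECODE = np.array(list("ACGTN-"))


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul constants.

    A gap of length L costs ``gap_open + gap_extend * L``.  ``lam`` is the
    Karlin-Altschul lambda; when None it is solved for the uniform background
    on first use.  ``K`` has no closed form at this level and defaults to the
    tabulated value for the +2/-3/5/2 nucleotide scheme.
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    lam: float | None = None
    K: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.K <= 0:
            raise ValueError("K must be positive")

    def calibrated(self, background: Sequence[float] = UNIFORM_BG) -> "ScoringScheme":
        if self.lam is not None:
            return self
        return replace(self, lam=karlin_lambda(self, background))


@dataclass(frozen=True)
class AlignmentHit:
    """One gapped local alignment between a query and a subject replicon.

    ``subject_interval`` is always on the forward strand of the subject.  The
    gapped strings are in query orientation: for a minus-strand hit,
    ungapping ``aligned_subject`` reproduces the reverse complement of the
    forward-strand subject slice.
    """

    query_id: str
    subject_id: str
    query_interval: Interval
    subject_interval: Interval
    strand: str
    aligned_query: str
    aligned_subject: str
    raw_score: int
    bit_score: float
    evalue: float
    percent_identity: float
    query_coverage: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("gapped strings differ in length")

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_query)

    @property
    def n_mismatch(self) -> int:
        return sum(1 for a, b in zip(self.aligned_query, self.aligned_subject)
                   if a != "-" and b != "-" and a != b)

    @property
    def n_gap_opens(self) -> int:
        opens = 0
        for s in (self.aligned_query, self.aligned_subject):
            in_gap = False
            for c in s:
                if c == "-" and not in_gap:
                    opens += 1
                in_gap = c == "-"
        return opens


def karlin_lambda(scheme: ScoringScheme,
                  background: Sequence[float] = UNIFORM_BG) -> float:
    """Unique positive root lambda of sum_ij p_i p_j exp(lambda * s(i,j)) = 1."""
    p = np.asarray(background, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    r, q = scheme.match_reward, scheme.mismatch_penalty
    p_match = float((p * p).sum())
    p_mis = 1.0 - p_match
    expected = p_match * r + p_mis * q
    if expected >= 0:
        raise ValueError("expected score must be negative for lambda to exist")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * r) + p_mis * math.exp(lam * q) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket lambda")
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12))


def bit_score_and_evalue(raw: int, scheme: ScoringScheme, m: int, n: int) -> tuple[float, float]:
    """bits = (lambda*raw - ln K) / ln 2; evalue = m * n * 2**(-bits).

    Uses the raw ``m * n`` search space (no finite-size length correction).
    """
    if scheme.lam is None:
        raise ValueError("scheme lambda not set; call scheme.calibrated()")
    bits = (scheme.lam * raw - math.log(scheme.K)) / math.log(2.0)
    evalue = float(m) * float(n) * 2.0 ** (-bits)
    return bits, evalue


def rescore(aligned_a: str, aligned_b: str, scheme: ScoringScheme) -> int:
    """Recompute the raw score of a gapped alignment (invariant check)."""
    score = 0
    in_gap = False
    for a, b in zip(aligned_a, aligned_b):
        if a == "-" or b == "-":
            score -= scheme.gap_extend + (scheme.gap_open if not in_gap else 0)
            in_gap = True
        else:
            in_gap = False
            ok = a == b and a in "ACGT"
            score += scheme.match_reward if ok else scheme.mismatch_penalty
    return score


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _ungapped_extend(q, s, qpos, spos, w, reward, penalty, xdrop):
    lq, ls = q.shape[0], s.shape[0]
    score = w * reward
    best = score
    qe, se = qpos + w, spos + w
    cur = score
    i, j = qpos + w, spos + w
    while i < lq and j < ls:
        if q[i] == s[j] and q[i] < 4:
            cur += reward
        else:
            cur += penalty
        i += 1
        j += 1
        if cur > best:
            best = cur
            qe, se = i, j
        elif best - cur > xdrop:
            break
    cur = best
    qs, ss = qpos, spos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        if q[i] == s[j] and q[i] < 4:
            cur += reward
        else:
            cur += penalty
        if cur > best:
            best = cur
            qs, ss = i, j
        elif best - cur > xdrop:
            i -= 1
            j -= 1
            break
        i -= 1
        j -= 1
    return qs, qe, ss, se, best


@njit(cache=True)
def _banded_local_dp(q, s, diag, band, reward, penalty, go, ge):
    """Local affine-gap DP restricted to |(j - i) - diag| <= band.

    Returns (score, qstart, qend, sstart, send, cols_q, cols_s, ncols) where
    cols hold residue codes (5 = gap) of the alignment, reversed.
    """
    lq, ls = q.shape[0], s.shape[0]
    W = 2 * band + 1
    NEG = -(10 ** 9)
    H = np.full((lq + 1, W), NEG, np.int64)
    E = np.full((lq + 1, W), NEG, np.int64)
    F = np.full((lq + 1, W), NEG, np.int64)
    PH = np.zeros((lq + 1, W), np.uint8)
    PE = np.zeros((lq + 1, W), np.uint8)
    PF = np.zeros((lq + 1, W), np.uint8)
    open_cost = go + ge
    # row 0
    for k in range(W):
        j = diag - band + k
        if 0 <= j <= ls:
            H[0, k] = 0
    best = 0
    bi = -1
    bk = -1
    for i in range(1, lq + 1):
        for k in range(W):
            j = i + diag - band + k
            if j < 0 or j > ls:
                continue
            if j == 0:
                H[i, k] = 0
                continue
            e = NEG
            if k - 1 >= 0:
                h_left = H[i, k - 1]
                e_left = E[i, k - 1]
                if h_left > NEG // 2:
                    e = h_left - open_cost
                if e_left > NEG // 2 and e_left - ge > e:
                    e = e_left - ge
                    PE[i, k] = 1
            f = NEG
            if k + 1 < W:
                h_up = H[i - 1, k + 1]
                f_up = F[i - 1, k + 1]
                if h_up > NEG // 2:
                    f = h_up - open_cost
                if f_up > NEG // 2 and f_up - ge > f:
                    f = f_up - ge
                    PF[i, k] = 1
            sub = NEG
            if H[i - 1, k] > NEG // 2:
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    sub = H[i - 1, k] + reward
                else:
                    sub = H[i - 1, k] + penalty
            E[i, k] = e
            F[i, k] = f
            h = 0
            ph = 0
            if sub > h:
                h = sub
                ph = 1
            if e > h:
                h = e
                ph = 2
            if f > h:
                h = f
                ph = 3
            H[i, k] = h
            PH[i, k] = ph
            if h > best:
                best = h
                bi, bk = i, k
    cols_q = np.empty(lq + ls, np.uint8)
    cols_s = np.empty(lq + ls, np.uint8)
    ncols = 0
    if best <= 0:
        return 0, 0, 0, 0, 0, cols_q, cols_s, 0
    i, k = bi, bk
    qend = bi
    send = bi + diag - band + bk
    state = 0
    while True:
        j = i + diag - band + k
        if state == 0:
            p = PH[i, k]
            if p == 0 or H[i, k] <= 0:
                break
            if p == 1:
                cols_q[ncols] = q[i - 1]
                cols_s[ncols] = s[j - 1]
                ncols += 1
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in query, consume subject
            cont = PE[i, k]
            cols_q[ncols] = _GAP
            cols_s[ncols] = s[j - 1]
            ncols += 1
            k -= 1
            if cont == 0:
                state = 0
        else:  # gap in subject, consume query
            cont = PF[i, k]
            cols_q[ncols] = q[i - 1]
            cols_s[ncols] = _GAP
            ncols += 1
            i -= 1
            k += 1
            if cont == 0:
                state = 0
    qstart = i
    sstart = i + diag - band + k
    return best, qstart, qend, sstart, send, cols_q, cols_s, ncols


@njit(cache=True)
def _sw_full_dp(a, b, reward, penalty, go, ge):
    """Full Smith-Waterman (Gotoh).  Independent of the banded search path.

    Ties in the maximum broken by smallest end in b, then in a.
    """
    la, lb = a.shape[0], b.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((la + 1, lb + 1), np.int64)
    E = np.full((la + 1, lb + 1), NEG, np.int64)
    F = np.full((la + 1, lb + 1), NEG, np.int64)
    PH = np.zeros((la + 1, lb + 1), np.uint8)
    PE = np.zeros((la + 1, lb + 1), np.uint8)
    PF = np.zeros((la + 1, lb + 1), np.uint8)
    open_cost = go + ge
    best = 0
    bi, bj = 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e = H[i, j - 1] - open_cost
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
                PE[i, j] = 1
            f = H[i - 1, j] - open_cost
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
                PF[i, j] = 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                sub = H[i - 1, j - 1] + reward
            else:
                sub = H[i - 1, j - 1] + penalty
            E[i, j] = e
            F[i, j] = f
            h = 0
            ph = 0
            if sub > h:
                h = sub
                ph = 1
            if e > h:
                h = e
                ph = 2
            if f > h:
                h = f
                ph = 3
            H[i, j] = h
            PH[i, j] = ph
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best = h
                bi, bj = i, j
    cols_a = np.empty(la + lb, np.uint8)
    cols_b = np.empty(la + lb, np.uint8)
    ncols = 0
    if best <= 0:
        return 0, 0, 0, 0, 0, cols_a, cols_b, 0
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0 or H[i, j] <= 0:
                break
            if p == 1:
                cols_a[ncols] = a[i - 1]
                cols_b[ncols] = b[j - 1]
                ncols += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cont = PE[i, j]
            cols_a[ncols] = _GAP
            cols_b[ncols] = b[j - 1]
            ncols += 1
            j -= 1
            if cont == 0:
                state = 0
        else:
            cont = PF[i, j]
            cols_a[ncols] = a[i - 1]
            cols_b[ncols] = _GAP
            ncols += 1
            i -= 1
            if cont == 0:
                state = 0
    return best, i, bi, j, bj, cols_a, cols_b, ncols


def _cols_to_str(cols: np.ndarray, ncols: int) -> str:
    return "".join(_DECODE[cols[:ncols][::-1]])


@dataclass(frozen=True)
class LocalAlignment:
    a_interval: Interval
    b_interval: Interval
    aligned_a: str
    aligned_b: str


def smith_waterman(a: str, b: str, scheme: ScoringScheme) -> tuple[int, LocalAlignment]:
    """Optimal local alignment under affine gap costs (test oracle).

    Returns score 0 and an empty alignment when no positive-scoring local
    alignment exists.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    score, ai, ae, bi, be, cols_a, cols_b, ncols = _sw_full_dp(
        encode(a), encode(b), scheme.match_reward, scheme.mismatch_penalty,
        scheme.gap_open, scheme.gap_extend)
    return int(score), LocalAlignment(Interval(int(ai), int(ae)), Interval(int(bi), int(be)),
                                      _cols_to_str(cols_a, ncols), _cols_to_str(cols_b, ncols))


# ---------------------------------------------------------------------------
# seeding

def _kmer_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.shape[0] - w + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (win < 4).all(axis=1)
    base = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    vals = (win.astype(np.int64) * base).sum(axis=1)
    pos = np.nonzero(valid)[0]
    return vals[valid], pos


def _find_seeds(q_codes: np.ndarray, s_codes: np.ndarray, w: int) -> list[tuple[int, int]]:
    """All (qpos, spos) pairs sharing an exact ACGT-only w-mer."""
    qvals, qpos = _kmer_codes(q_codes, w)
    svals, spos = _kmer_codes(s_codes, w)
    if qvals.size == 0 or svals.size == 0:
        return []
    index: dict[int, list[int]] = {}
    for v, p in zip(qvals.tolist(), qpos.tolist()):
        index.setdefault(v, []).append(p)
    mask = np.isin(svals, qvals)
    seeds = []
    for v, sp in zip(svals[mask].tolist(), spos[mask].tolist()):
        for qp in index[v]:
            seeds.append((qp, sp))
    return seeds


def _overlapping(q1: Interval, s1: Interval, q2: Interval, s2: Interval) -> bool:
    return q1.overlaps(q2) and s1.overlaps(s2)


def _search_one_strand(q_codes: np.ndarray, s_codes: np.ndarray,
                       scheme: ScoringScheme) -> list[tuple[int, int, int, int, int, str, str]]:
    """Raw gapped HSPs (score, qs, qe, ss, se, aq, asub) on one subject strand."""
    w = scheme.word_size
    seeds = _find_seeds(q_codes, s_codes, w)
    if not seeds:
        return []
    # one ungapped extension per diagonal stretch of seeds
    seeds.sort(key=lambda t: (t[1] - t[0], t[1]))
    hsps = []
    last_diag = None
    last_se = -1
    for qp, sp in seeds:
        diag = sp - qp
        if diag == last_diag and sp < last_se:
            continue
        qs, qe, ss, se, score = _ungapped_extend(
            q_codes, s_codes, qp, sp, w, scheme.match_reward,
            scheme.mismatch_penalty, X_DROP)
        last_diag, last_se = diag, se
        hsps.append((int(score), int(qs), int(qe), int(ss), int(se)))
    hsps.sort(key=lambda t: (-t[0], t[3], t[1]))

    m = q_codes.shape[0]
    ls = s_codes.shape[0]
    accepted: list[tuple[int, int, int, int, int, str, str]] = []
    for score, qs, qe, ss, se in hsps:
        qiv, siv = Interval(qs, qe), Interval(ss, se)
        if any(_overlapping(qiv, siv, Interval(h[1], h[2]), Interval(h[3], h[4]))
               for h in accepted):
            continue
        win_start = max(0, ss - qs - BAND_WIDTH - 20)
        win_end = min(ls, se + (m - qe) + BAND_WIDTH + 20)
        window = s_codes[win_start:win_end]
        diag = ss - qs - win_start
        gscore, gqs, gqe, gss, gse, cq, cs, nc = _banded_local_dp(
            q_codes, window, diag, BAND_WIDTH, scheme.match_reward,
            scheme.mismatch_penalty, scheme.gap_open, scheme.gap_extend)
        if gscore <= 0:
            continue
        gss += win_start
        gse += win_start
        giv_q, giv_s = Interval(int(gqs), int(gqe)), Interval(int(gss), int(gse))
        if any(_overlapping(giv_q, giv_s, Interval(h[1], h[2]), Interval(h[3], h[4]))
               for h in accepted):
            continue
        accepted.append((int(gscore), int(gqs), int(gqe), int(gss), int(gse),
                         _cols_to_str(cq, nc), _cols_to_str(cs, nc)))
    return accepted


def search(query: SequenceRecord, subjects: Sequence[SequenceRecord],
           scheme: ScoringScheme | None = None, evalue_cutoff: float = 10.0,
           max_targets: int = 10000) -> list[AlignmentHit]:
    """Seed-and-extend local search of one query against subject replicons.

    Hits with E-value above ``evalue_cutoff`` are dropped; at most
    ``max_targets`` distinct subjects are reported.  Output is sorted by
    (bit score desc, subject id asc, subject start asc).
    """
    scheme = (scheme or ScoringScheme()).calibrated()
    if len(query.seq) == 0:
        raise ValueError("empty query")
    if not subjects:
        raise ValueError("no subjects")
    if scheme.word_size > len(query.seq):
        raise ValueError("word_size exceeds query length")
    m = len(query.seq)
    n_total = sum(len(s) for s in subjects)
    q_codes = encode(query.seq)
    hits: list[AlignmentHit] = []
    for subj in subjects:
        ls = len(subj.seq)
        if ls == 0:
            continue
        for strand in "+-":
            s_seq = subj.seq if strand == "+" else revcomp(subj.seq)
            raw_hsps = _search_one_strand(q_codes, encode(s_seq), scheme)
            for score, qs, qe, ss, se, aq, asub in raw_hsps:
                if strand == "-":
                    fwd = Interval(ls - se, ls - ss)
                else:
                    fwd = Interval(ss, se)
                bits, evalue = bit_score_and_evalue(score, scheme, m, n_total)
                if evalue > evalue_cutoff:
                    continue
                ident = sum(1 for x, y in zip(aq, asub) if x == y and x != "-")
                hits.append(AlignmentHit(
                    query_id=query.id, subject_id=subj.id,
                    query_interval=Interval(qs, qe), subject_interval=fwd,
                    strand=strand, aligned_query=aq, aligned_subject=asub,
                    raw_score=score, bit_score=bits, evalue=evalue,
                    percent_identity=100.0 * ident / max(1, len(aq)),
                    query_coverage=(qe - qs) / m))
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id, h.subject_interval.start))
    if max_targets is not None:
        keep_subjects: list[str] = []
        for h in hits:
            if h.subject_id not in keep_subjects:
                if len(keep_subjects) >= max_targets:
                    continue
                keep_subjects.append(h.subject_id)
        allowed = set(keep_subjects)
        hits = [h for h in hits if h.subject_id in allowed]
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) interoperability; 1-based inclusive coordinates

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def write_outfmt6(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.subject_interval.start + 1, h.subject_interval.end
            else:
                sstart, send = h.subject_interval.end, h.subject_interval.start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.percent_identity:.3f}",
                h.alignment_length, h.n_mismatch, h.n_gap_opens,
                h.query_interval.start + 1, h.query_interval.end,
                sstart, send, f"{h.evalue:.3g}", f"{h.bit_score:.1f}"])) + "\n")


def read_outfmt6(path: str | Path):
    """Read a BLAST outfmt-6 table (ours or NCBI's) into a DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, header=None)
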