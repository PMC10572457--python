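"""BLAST-style search over structural-alphabet sequences.

The search stage finds regions of structural similarity by local alignment
of SA strings: exact and high-scoring 3-letter words seed ungapped x-drop
extensions along diagonals, surviving diagonals are refined by banded
affine-gap Smith-Waterman, and each hit's significance is reported as a
Karlin-Altschul E-value ``E = K m n exp(-lambda S)``.  The statistics
(lambda as the positive root of ``sum p_i p_j exp(lambda s_ij) = 1``; K by
the standard convolution series for integer-lattice scores) are computed
in-repo, so no external alignment engine is required.

An exhaustive Smith-Waterman (``local_align`` without a band) is the exact
reference the heuristic can never exceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, gcd
from typing import NamedTuple

import numpy as np

from .alphabet import GAP, SARecord, SubstitutionMatrix
from .errors import CalibrationError

__all__ = [
    "SearchDatabase",
    "KarlinAltschulParams",
    "Alignment",
    "SearchParams",
    "SearchHit",
    "EVALUE_PRESETS",
    "build_database",
    "karlin_altschul",
    "evalue",
    "local_align",
    "seeded_search",
    "write_fasta",
    "read_fasta",
]

_NEG = -(10**5)  # score used for the reserved gap symbol: never alignable

#: E-value cutoff presets: ``short`` for queries under ~30 residues,
#: ``medium`` for 30-100, ``long`` for >100.
EVALUE_PRESETS = {"short": 1.0, "medium": 1e-3, "long": 1e-5}


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Extreme-value scale constants of ungapped local alignment scores."""

    lam: float  # nats per score unit
    K: float
    H: float  # relative entropy per aligned pair (nats)

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass
class SearchDatabase:
    """SA records plus the aggregate statistics the search needs."""

    records: list[SARecord]
    total_length: int = 0
    frequencies: np.ndarray | None = None  # observed letter frequencies
    letters: str = ""
    _word_index: dict = field(default_factory=dict, repr=False)

    def record_by_id(self, rid: str) -> SARecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)


def build_database(records: list[SARecord], letters: str) -> SearchDatabase:
    """Assemble a database from encoded records (observed letter frequencies
    exclude the gap symbol)."""
    if not records:
        raise ValueError("database must contain at least one record")
    counts = np.zeros(len(letters))
    total = 0
    index = {c: i for i, c in enumerate(letters)}
    for r in records:
        total += len(r.sa_seq)
        for c in r.sa_seq:
            if c != GAP:
                counts[index[c]] += 1
    if total == 0:
        raise ValueError("database has zero total length")
    freq = counts / counts.sum() if counts.sum() > 0 else np.full(len(letters), 1.0 / len(letters))
    return SearchDatabase(
        records=list(records), total_length=total, frequencies=freq, letters=letters
    )


@dataclass(frozen=True)
class SearchParams:
    """Seeding and reporting knobs (BLASTP-like defaults in half-bit units)."""

    word_size: int = 3
    neighborhood_threshold: int = 11
    x_drop: int = 15
    evalue_cutoff: float = 1.0
    max_hits: int = 2048
    band_width: int = 16
    max_diags_per_record: int = 8

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.evalue_cutoff < 0:
            raise ValueError("evalue_cutoff must be >= 0")


@dataclass
class Alignment:
    """A scored local alignment.

    ``columns`` lists ``(qi, sj)`` pairs where either side may be ``None``
    for a gap; spans are 0-based half-open over the aligned region.
    """

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    columns: list[tuple[int | None, int | None]]
    score: int

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(q, s) for q, s in self.columns if q is not None and s is not None]

    def pretty(self, q: str, s: str) -> str:
        top = "".join(q[c[0]] if c[0] is not None else "-" for c in self.columns)
        bot = "".join(s[c[1]] if c[1] is not None else "-" for c in self.columns)
        return f"{top}/{bot}"


class SearchHit(NamedTuple):
    record: SARecord
    alignment: Alignment
    evalue: float


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def _score_distribution(matrix: SubstitutionMatrix, freqs: np.ndarray):
    """Probability of each integer score for one aligned background pair."""
    s = matrix.scores
    lo, hi = int(s.min()), int(s.max())
    probs = np.zeros(hi - lo + 1)
    p = np.outer(freqs, freqs)
    for val in range(lo, hi + 1):
        probs[val - lo] = p[s == val].sum()
    return lo, probs


def karlin_altschul(matrix: SubstitutionMatrix, freqs: np.ndarray) -> KarlinAltschulParams:
    """Compute (lambda, K, H) for an integer substitution matrix and
    background letter frequencies.

    lambda is the unique positive root of ``sum_ij p_i p_j e^(lambda s_ij) = 1``
    (bisection to 1e-9); K follows the standard convolution series for
    lattice scores, truncated at 1e-6 relative change.  Raises
    :class:`CalibrationError` when the expected score is non-negative or no
    positive score exists.
    """
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    s = matrix.scores
    expected = float(np.einsum("i,j,ij->", freqs, freqs, s))
    if expected >= 0:
        raise CalibrationError(
            f"expected background score {expected:.6f} >= 0; statistics undefined"
        )
    if s.max() <= 0:
        raise CalibrationError("no positive substitution score; statistics undefined")

    lo, probs = _score_distribution(matrix, freqs)
    vals = np.arange(lo, lo + len(probs))
    support = vals[probs > 0]

    def f(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * vals))) - 1.0

    hi_l = 1.0
    while f(hi_l) < 0:
        hi_l *= 2.0
        if hi_l > 1e4:  # pragma: no cover - cannot happen with s.max() > 0
            raise CalibrationError("failed to bracket lambda")
    lo_l = 1e-12
    for _ in range(200):
        mid = 0.5 * (lo_l + hi_l)
        if f(mid) < 0:
            lo_l = mid
        else:
            hi_l = mid
        if hi_l - lo_l < 1e-12:
            break
    lam = 0.5 * (lo_l + hi_l)

    H = lam * float(np.sum(probs * vals * np.exp(lam * vals)))

    # lattice step of the score support
    d = 0
    for v in support:
        d = gcd(d, abs(int(v)))
    d = max(d, 1)

    # sigma = sum_j (1/j) [ E(e^{lam S_j}; S_j < 0) + P(S_j >= 0) ]
    sigma = 0.0
    dist = probs.copy()
    dist_lo = lo
    for j in range(1, 400):
        y = np.arange(dist_lo, dist_lo + len(dist))
        neg = y < 0
        term = float(np.sum(dist[neg] * np.exp(lam * y[neg])) + dist[~neg].sum()) / j
        sigma += term
        if j > 5 and term < 1e-6 * max(sigma, 1e-300):
            break
        dist = np.convolve(dist, probs)
        dist_lo += lo
        # prune negligible tails to bound the support
        nz = np.flatnonzero(dist > 1e-14)
        if nz.size:
            dist_lo += int(nz[0])
            dist = dist[nz[0] : nz[-1] + 1]

    K = d * lam * exp(-2.0 * sigma) / (H * (1.0 - exp(-lam * d)))
    if K <= 0:  # pragma: no cover - guarded by the checks above
        raise CalibrationError(f"computed K={K} <= 0")
    return KarlinAltschulParams(lam=lam, K=K, H=H)


def evalue(score: float, params: KarlinAltschulParams, m: int, n: int) -> float:
    """Expected number of chance alignments scoring >= ``score`` in an
    ``m x n`` search space: ``E = K m n exp(-lambda score)``."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.K * m * n * exp(-params.lam * score)


# ---------------------------------------------------------------------------
# alignment


def _extended_scores(matrix: SubstitutionMatrix) -> np.ndarray:
    k = len(matrix.letters)
    ext = np.full((k + 1, k + 1), _NEG, dtype=np.int64)
    ext[:k, :k] = matrix.scores
    return ext


def local_align(
    q: str,
    s: str,
    matrix: SubstitutionMatrix,
    band: tuple[int, int] | None = None,
) -> Alignment:
    """Optimal local alignment (Smith-Waterman / Gotoh affine gaps).

    A gap of length g costs ``gap_open + g * gap_extend``.  Traceback is
    deterministic with preference diagonal > up (gap in subject) > left
    (gap in query), and the best cell is the one with the smallest (i, j)
    among maxima.  ``band``, if given, is ``(center_diagonal, half_width)``
    and restricts cells to ``|(j - i) - center| <= half_width`` — the
    banded score can never exceed the unbanded optimum.

    The reserved gap symbol ``-`` may appear in the inputs but scores so
    negatively it never enters an alignment.
    """
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    qi = matrix.encode(q)
    si = matrix.encode(s)
    ext = _extended_scores(matrix)
    go, ge = matrix.gap_open, matrix.gap_extend
    open_cost = go + ge  # cost of a gap of length 1
    m, n = len(qi), len(si)

    NEG = float(-1e18)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in query (consumes subject)
    F = np.full((m + 1, n + 1), NEG)  # gap in subject (consumes query)

    def in_band(i: int, j: int) -> bool:
        if band is None:
            return True
        c, w = band
        return abs((j - i) - c) <= w

    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        row_s = ext[qi[i - 1]]
        for j in range(1, n + 1):
            if not in_band(i, j):
                H[i, j] = 0.0
                continue
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - ge)
            diag = H[i - 1, j - 1] + row_s[si[j - 1]]
            H[i, j] = max(0.0, diag, F[i, j], E[i, j])
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j

    if best <= 0:
        return Alignment(query_span=(0, 0), subject_span=(0, 0), columns=[], score=0)

    # traceback with diagonal > up > left preference
    cols: list[tuple[int | None, int | None]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + ext[qi[i - 1], si[j - 1]]
            if H[i, j] == diag:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("traceback inconsistency")
        elif state == "F":
            cols.append((i - 1, None))
            opened = H[i - 1, j] - open_cost
            state = "H" if F[i, j] == opened else "F"
            i -= 1
        else:  # state == "E"
            cols.append((None, j - 1))
            opened = H[i, j - 1] - open_cost
            state = "H" if E[i, j] == opened else "E"
            j -= 1
    cols.reverse()
    q_idx = [c[0] for c in cols if c[0] is not None]
    s_idx = [c[1] for c in cols if c[1] is not None]
    return Alignment(
        query_span=(q_idx[0], q_idx[-1] + 1),
        subject_span=(s_idx[0], s_idx[-1] + 1),
        columns=cols,
        score=int(round(best)),
    )


# ---------------------------------------------------------------------------
# seeded search


def _db_word_index(db: SearchDatabase, matrix: SubstitutionMatrix, w: int):
    key = (w, matrix.letters)
    if key in db._word_index:
        return db._word_index[key]
    index: dict[tuple, list[tuple[int, int]]] = {}
    for ri, rec in enumerate(db.records):
        enc = matrix.encode(rec.sa_seq)
        for pos in range(len(enc) - w + 1):
            word = tuple(enc[pos : pos + w])
            if any(c < 0 for c in word):
                continue
            index.setdefault(word, []).append((ri, pos))
    db._word_index[key] = index
    return index


def _ungapped_extend(qi, si, qpos, spos, w, ext, x_drop):
    """X-drop ungapped extension of a seed word along its diagonal."""
    score = int(sum(ext[qi[qpos + t], si[spos + t]] for t in range(w)))
    best = score
    # right
    cur, i, j = score, qpos + w, spos + w
    while i < len(qi) and j < len(si):
        cur += ext[qi[i], si[j]]
        if cur > best:
            best = cur
        if cur < best - x_drop:
            break
        i, j = i + 1, j + 1
    # left
    cur = best
    tmp = best
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        cur += ext[qi[i], si[j]]
        if cur > tmp:
            tmp = cur
        if cur < tmp - x_drop:
            break
        i, j = i - 1, j - 1
    return tmp


def seeded_search(
    query: SARecord,
    db: SearchDatabase,
    matrix: SubstitutionMatrix,
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """Word-seeded, x-drop-extended, band-refined search of an SA database.

    Returns hits with ``E <= evalue_cutoff`` sorted by (E-value, subject id)
    and truncated to ``max_hits``.  Every reported score is bounded above by
    the exhaustive ``local_align`` optimum for that pair.  E-values use the
    substitution matrix's own background frequencies (the database letter
    composition may be arbitrarily skewed); ``m`` is the query length and
    ``n`` the total database length, without edge-effect correction.
    """
    if params is None:
        params = SearchParams()
    if not db.records:
        raise ValueError("database is empty")
    bg = matrix.background if matrix.background is not None else db.frequencies
    ka = karlin_altschul(matrix, bg)
    qi = matrix.encode(query.sa_seq)
    m = len(qi)
    ext = _extended_scores(matrix)
    w = params.word_size

    enc_records = [matrix.encode(r.sa_seq) for r in db.records]

    # candidate diagonals per record
    diag_scores: dict[int, dict[int, int]] = {}
    if m >= w:
        index = _db_word_index(db, matrix, w)
        vocab = list(index.keys())
        if vocab:
            vocab_arr = np.array(vocab)  # (nv, w)
            for qpos in range(m - w + 1):
                word = qi[qpos : qpos + w]
                if (word < 0).any():
                    continue
                wscores = ext[word[:, None], vocab_arr.T].sum(axis=0)
                for vi in np.flatnonzero(wscores >= params.neighborhood_threshold):
                    for ri, spos in index[vocab[vi]]:
                        sc = _ungapped_extend(qi, enc_records[ri], qpos, spos, w, ext, params.x_drop)
                        diag = spos - qpos
                        per = diag_scores.setdefault(ri, {})
                        if sc > per.get(diag, _NEG):
                            per[diag] = sc
    else:
        # query shorter than a word: every record is a candidate
        diag_scores = {ri: {0: 0} for ri in range(len(db.records))}

    hits: list[SearchHit] = []
    for ri, diags in diag_scores.items():
        rec = db.records[ri]
        top = sorted(diags.items(), key=lambda kv: (-kv[1], kv[0]))
        top = top[: params.max_diags_per_record]
        best_aln: Alignment | None = None
        seen_bands: list[int] = []
        for diag, _sc in top:
            if any(abs(diag - b) <= params.band_width // 2 for b in seen_bands):
                continue
            seen_bands.append(diag)
            aln = local_align(query.sa_seq, rec.sa_seq, matrix, band=(diag, params.band_width))
            if best_aln is None or aln.score > best_aln.score:
                best_aln = aln
        if best_aln is None or best_aln.score <= 0:
            continue
        e = evalue(best_aln.score, ka, m, db.total_length)
        if e <= params.evalue_cutoff:
            hits.append(SearchHit(record=rec, alignment=best_aln, evalue=e))

    hits.sort(key=lambda h: (h.evalue, h.record.id))
    return hits[: params.max_hits]


# ---------------------------------------------------------------------------
# FASTA serialisation of SA sequences


def write_fasta(records: list[SARecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sa_seq}\n")


def read_fasta(path: str) -> list[SARecord]:
    records: list[SARecord] = []
    rid, seq = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records.append(SARecord(id=rid, sa_seq="".join(seq)))
                rid, seq = line[1:].strip(), []
            elif line:
                seq.append(line.strip())
    if rid is not None:
        records.append(SARecord(id=rid, sa_seq="".join(seq)))
    return records
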