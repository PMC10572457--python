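import numpy as np
import pytest
from scipy.optimize import brentq

from safold.alphabet import SARecord
from safold.errors import CalibrationError
from safold.search import (
    SearchParams,
    build_database,
    evalue,
    karlin_altschul,
    local_align,
    read_fasta,
    seeded_search,
    write_fasta,
)

from conftest import make_simple_matrix


def biopython_score(q, s, matrix):
    """Independent local-alignment oracle (Biopython PairwiseAligner)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    sub = substitution_matrices.Array(alphabet=matrix.letters, dims=2)
    for i, a in enumerate(matrix.letters):
        for j, b in enumerate(matrix.letters):
            sub[a, b] = matrix.scores[i, j]
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -(matrix.gap_open + matrix.gap_extend)
    aligner.extend_gap_score = -matrix.gap_extend
    return int(aligner.score(q, s))


def enumerate_score(q, s, matrix):
    """Exponential-time oracle: DFS over every local alignment path."""
    go, ge = matrix.gap_open, matrix.gap_extend
    best = 0

    def walk(i, j, score, in_gap):
        nonlocal best
        best = max(best, score)
        if i < len(q) and j < len(s):
            walk(i + 1, j + 1, score + matrix.score(q[i], s[j]), None)
        if i < len(q):
            cost = ge if in_gap == "q" else go + ge
            walk(i + 1, j, score - cost, "q")
        if j < len(s):
            cost = ge if in_gap == "s" else go + ge
            walk(i, j + 1, score - cost, "s")

    for i0 in range(len(q)):
        for j0 in range(len(s)):
            walk(i0, j0, 0, None)
    return best


class TestKarlinAltschul:
    def test_lambda_matches_bisection_oracle(self):
        mat = make_simple_matrix("AB", 1, -2, 11, 1)
        params = karlin_altschul(mat, np.array([0.5, 0.5]))
        oracle = brentq(lambda l: 0.5 * np.exp(l) + 0.5 * np.exp(-2 * l) - 1, 1e-9, 10)
        assert params.lam == pytest.approx(oracle, abs=1e-9)
        assert params.K > 0

    def test_zero_expectation_is_degenerate(self):
        mat = make_simple_matrix("AB", 1, -1, 11, 1)
        with pytest.raises(CalibrationError):
            karlin_altschul(mat, np.array([0.5, 0.5]))

    def test_all_negative_scores_degenerate(self):
        mat = make_simple_matrix("AB", -1, -2, 11, 1)
        with pytest.raises(CalibrationError):
            karlin_altschul(mat, np.array([0.5, 0.5]))

    def test_score_scaling_halves_lambda(self):
        m1 = make_simple_matrix("AB", 1, -2, 11, 1)
        m2 = make_simple_matrix("AB", 2, -4, 11, 1)
        p1 = karlin_altschul(m1, np.array([0.5, 0.5]))
        p2 = karlin_altschul(m2, np.array([0.5, 0.5]))
        assert p2.lam == pytest.approx(p1.lam / 2, rel=1e-6)


class TestEvalue:
    def test_closed_form(self):
        from safold.search import KarlinAltschulParams

        params = KarlinAltschulParams(lam=0.5, K=0.1, H=1.0)
        assert evalue(0, params, 10, 1000) == pytest.approx(0.1 * 10 * 1000)
        assert evalue(20, params, 10, 1000) == pytest.approx(1000 * np.exp(-10.0))
        scores = np.arange(0, 50, 5)
        es = [evalue(s, params, 10, 1000) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestLocalAlign:
    def test_perfect_match_hand_score(self):
        mat = make_simple_matrix("AB", 2, -1, 2, 1)
        aln = local_align("ABBA", "ABBA", mat)
        assert aln.score == 8
        assert aln.query_span == (0, 4) and aln.subject_span == (0, 4)
        assert aln.aligned_pairs == [(i, i) for i in range(4)]

    def test_no_positive_pair_gives_empty(self):
        mat = make_simple_matrix("ABC", 2, -1, 2, 1)
        aln = local_align("AAB", "CCC", mat)
        assert aln.score == 0 and aln.columns == []

    def test_score_equals_recomputed_column_sum(self):
        mat = make_simple_matrix("ABCD", 3, -2, 3, 1)
        rng = np.random.default_rng(0)
        for _ in range(30):
            q = "".join(rng.choice(list("ABCD"), size=12))
            s = "".join(rng.choice(list("ABCD"), size=15))
            aln = local_align(q, s, mat)
            if not aln.columns:
                continue
            total, gap_run = 0, 0
            for qi, sj in aln.columns:
                if qi is None or sj is None:
                    gap_run += 1
                    total -= mat.gap_extend + (mat.gap_open if gap_run == 1 else 0)
                else:
                    gap_run = 0
                    total += mat.score(q[qi], s[sj])
            assert total == aln.score

    def test_matches_exponential_enumeration(self):
        mat = make_simple_matrix("ABC", 2, -2, 2, 1)
        rng = np.random.default_rng(1)
        for _ in range(25):
            q = "".join(rng.choice(list("ABC"), size=int(rng.integers(1, 6))))
            s = "".join(rng.choice(list("ABC"), size=int(rng.integers(1, 6))))
            assert local_align(q, s, mat).score == enumerate_score(q, s, mat)

    def test_matches_biopython_oracle(self, matrix):
        rng = np.random.default_rng(2)
        letters = list(matrix.letters)
        for _ in range(50):
            q = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            s = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            assert local_align(q, s, matrix).score == biopython_score(q, s, matrix)

    def test_band_never_beats_full(self, matrix):
        rng = np.random.default_rng(3)
        letters = list(matrix.letters)
        for _ in range(20):
            q = "".join(rng.choice(letters, size=20))
            s = "".join(rng.choice(letters, size=30))
            full = local_align(q, s, matrix).score
            banded = local_align(q, s, matrix, band=(0, 4)).score
            assert banded <= full

    def test_non_alphabet_character_rejected(self, matrix):
        with pytest.raises(ValueError):
            local_align("A?", "AA", matrix)

    def test_gap_symbol_never_aligned(self, matrix):
        aln = local_align("AAAA-AAAA", "AAAAAAAAA", matrix)
        # the break symbol may be skipped by a gap column but never pairs
        # with a subject letter
        assert all("AAAA-AAAA"[q] != "-" for q, s in aln.aligned_pairs)


def random_record(rng, letters, n, rid):
    return SARecord(id=rid, sa_seq="".join(rng.choice(list(letters), size=n)))


class TestSeededSearch:
    def test_verbatim_self_hit(self, library, matrix):
        rng = np.random.default_rng(4)
        records = [random_record(rng, library.letters, 40, f"r{i:03d}") for i in range(20)]
        db = build_database(records, library.letters)
        hits = seeded_search(records[7], db, matrix)
        assert hits[0].record.id == "r007"
        assert hits[0].alignment.query_span == (0, 40)
        assert hits[0].evalue == min(h.evalue for h in hits)

    def test_planted_hit_ranks_first(self, library, matrix):
        rng = np.random.default_rng(5)
        query = random_record(rng, library.letters, 15, "query")
        records = [random_record(rng, library.letters, 60, f"bg{i:03d}") for i in range(100)]
        host = random_record(rng, library.letters, 60, "host")
        host.sa_seq = host.sa_seq[:20] + query.sa_seq + host.sa_seq[35:]
        records.append(host)
        db = build_database(records, library.letters)
        hits = seeded_search(query, db, matrix)
        assert hits and hits[0].record.id == "host"
        assert hits[0].alignment.subject_span == (20, 35)

    def test_zero_cutoff_gives_empty(self, library, matrix, db50):
        rng = np.random.default_rng(6)
        q = random_record(rng, library.letters, 30, "q")
        params = SearchParams(evalue_cutoff=0.0)
        assert seeded_search(q, db50, matrix, params) == []

    def test_scores_admissible_vs_full_alignment(self, library, matrix):
        rng = np.random.default_rng(7)
        records = [random_record(rng, library.letters, 50, f"r{i}") for i in range(30)]
        db = build_database(records, library.letters)
        q = random_record(rng, library.letters, 25, "q")
        params = SearchParams(evalue_cutoff=np.inf)
        for hit in seeded_search(q, db, matrix, params):
            exact = local_align(q.sa_seq, hit.record.sa_seq, matrix).score
            assert hit.alignment.score <= exact

    def test_evalue_calibration_on_background(self, matrix, library):
        # on i.i.d. background databases the number of hits with E <= e
        # should be O(e); generous constant, fixed seed
        rng = np.random.default_rng(8)
        p = matrix.background
        letters = list(library.letters)
        n_hits = 0
        trials = 20
        for t in range(trials):
            records = [
                SARecord(id=f"r{t}_{i}", sa_seq="".join(rng.choice(letters, size=80, p=p)))
                for i in range(40)
            ]
            db = build_database(records, library.letters)
            q = SARecord(id="q", sa_seq="".join(rng.choice(letters, size=40, p=p)))
            params = SearchParams(evalue_cutoff=0.1)
            n_hits += len(seeded_search(q, db, matrix, params))
        # ungapped (lambda, K) applied to gapped scores undercount E slightly,
        # so allow a generous linear constant
        assert n_hits <= 10 * 0.1 * trials + 3

    def test_sorted_by_evalue_then_id(self, library, matrix, corpus50, db50):
        from safold.alphabet import encode_geometric

        hits = seeded_search(encode_geometric(corpus50[0], library), db50, matrix)
        keys = [(h.evalue, h.record.id) for h in hits]
        assert keys == sorted(keys)


class TestFasta:
    def test_round_trip(self, tmp_path):
        records = [SARecord(id="a:1", sa_seq="AYBCD"), SARecord(id="b:2", sa_seq="KN-ST")]
        path = tmp_path / "db.fasta"
        write_fasta(records, str(path))
        back = read_fasta(str(path))
        assert [(r.id, r.sa_seq) for r in back] == [("a:1", "AYBCD"), ("b:2", "KN-ST")]
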