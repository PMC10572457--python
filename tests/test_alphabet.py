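import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from safold.alphabet import (
    GAP,
    LETTERS,
    Fragment,
    assign_letter,
    build_substitution_matrix,
    encode_geometric,
    fragment_rmsd,
    fragment_windows,
    learn_prototypes,
    load_library,
    save_library,
)
from safold.errors import CalibrationError
from safold.fixtures import GeneratorSpec, generate_chain
from safold.alphabet import PrototypeLibrary


def quaternion_rmsd(P, Q):
    """Independent superposition-RMSD oracle (Horn's quaternion method)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((P**2).sum() + (Q**2).sum() - 2.0 * lam) / P.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def frag(coords, start=0):
    return Fragment(coords=np.asarray(coords, dtype=float), source=("t", start))


def helix_window(index=2, noise=0.0, seed=0):
    chain = generate_chain(GeneratorSpec(kind="helix", length=12, noise_sigma=noise, seed=seed))
    return fragment_windows(chain)[index]


def planted_fragments(n_per=20, noise=0.05, seed=42):
    """Three well-separated geometric clusters (helix/strand/turn windows)."""
    bases = [
        fragment_windows(generate_chain(GeneratorSpec(kind=k, length=9)))[2].coords
        for k in ("helix", "strand", "turnlib")
    ]
    rng = np.random.default_rng(seed)
    frags, labels = [], []
    for ci, base in enumerate(bases):
        for j in range(n_per):
            frags.append(frag(base + rng.normal(scale=noise, size=(5, 3)), j))
            labels.append(ci)
    return frags, labels


class TestFragmentWindows:
    @pytest.mark.parametrize("L,expected", [(16, 12), (5, 1), (20, 16)])
    def test_length_law(self, L, expected):
        chain = generate_chain(GeneratorSpec(kind="random", length=L, seed=1))
        assert len(fragment_windows(chain)) == expected

    def test_windows_never_span_breaks(self):
        chain = generate_chain(GeneratorSpec(kind="random", length=10, seed=2))
        chain.break_after = {4}
        frags = fragment_windows(chain)
        assert len(frags) == 2
        assert [f.source[1] for f in frags] == [0, 5]


class TestFragmentRmsd:
    def test_self_is_zero(self):
        f = helix_window()
        assert fragment_rmsd(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        f = helix_window()
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        g = frag(f.coords @ R.T + np.array([5.0, -2.0, 1.0]))
        assert fragment_rmsd(f, g) == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle(self):
        a = frag([[0, 0, 0], [3.8, 0, 0], [5.0, 3.0, 0.5], [7.0, 4.0, 2.0], [9.5, 2.0, 3.0]])
        b = frag([[0, 0, 0], [3.5, 1.0, 0], [5.5, 3.5, 1.0], [6.5, 5.0, 3.0], [9.0, 3.0, 4.0]])
        expected = quaternion_rmsd(a.coords.copy(), b.coords.copy())
        assert fragment_rmsd(a, b) == pytest.approx(expected, abs=1e-8)
        assert fragment_rmsd(b, a) == pytest.approx(expected, abs=1e-8)


class TestLearnPrototypes:
    def test_planted_clusters_recovered_exactly(self):
        frags, labels = planted_fragments()
        lib = learn_prototypes(frags, k=3, seed=1)
        assigned = [lib.letters.index(assign_letter(f, lib)) for f in frags]
        match = any(
            all(assigned[i] == perm[labels[i]] for i in range(len(frags)))
            for perm in itertools.permutations(range(3))
        )
        assert match
        assert np.isclose(lib.frequencies.sum(), 1.0)

    def test_objective_non_increasing(self):
        frags, _ = planted_fragments(noise=0.3)
        lib = learn_prototypes(frags, k=5, seed=3)
        hist = lib.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_k_equals_n_gives_zero_cost(self):
        frags, _ = planted_fragments(n_per=2, noise=0.4)
        lib = learn_prototypes(frags, k=len(frags), seed=0)
        assert lib.objective_history[-1] == pytest.approx(0.0, abs=1e-6)

    def test_seed_determinism(self):
        frags, _ = planted_fragments(noise=0.2)
        a = learn_prototypes(frags, k=4, seed=11)
        b = learn_prototypes(frags, k=4, seed=11)
        assert np.array_equal(a.templates, b.templates)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_too_few_fragments_rejected(self):
        frags, _ = planted_fragments(n_per=1)
        with pytest.raises(ValueError):
            learn_prototypes(frags, k=10)


class TestAssignLetter:
    def test_template_maps_to_its_letter(self, library):
        for i in (0, 7, 22):
            f = frag(library.templates[i])
            assert assign_letter(f, library) == library.letters[i]

    def test_helix_windows_share_one_letter(self, library):
        chain = generate_chain(GeneratorSpec(kind="helix", length=20))
        letters = {assign_letter(f, library) for f in fragment_windows(chain)}
        assert len(letters) == 1

    def test_rigid_motion_invariance(self, library):
        f = helix_window(noise=0.3, seed=5)
        R = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
        g = frag(f.coords @ R.T + 10.0)
        assert assign_letter(f, library) == assign_letter(g, library)

    def test_tie_breaks_lexicographically(self):
        base = helix_window().coords
        lib = PrototypeLibrary(
            letters="ZQA",
            templates=np.stack([base, base * 1.5, base]),  # Z and A tie exactly
            frequencies=np.full(3, 1 / 3),
        )
        assert assign_letter(frag(base), lib) == "A"


class TestEncodeGeometric:
    def test_length_law(self, library):
        for L in (5, 16, 41):
            chain = generate_chain(GeneratorSpec(kind="random", length=L, seed=L))
            assert len(encode_geometric(chain, library).sa_seq) == L - 4

    def test_helix_constant_run(self, library):
        chain = generate_chain(GeneratorSpec(kind="helix", length=20))
        seq = encode_geometric(chain, library).sa_seq
        assert len(seq) == 16 and len(set(seq)) == 1

    def test_too_short_rejected(self, library):
        chain = generate_chain(GeneratorSpec(kind="helix", length=4))
        with pytest.raises(ValueError):
            encode_geometric(chain, library)

    def test_break_windows_emit_gap(self, library):
        chain = generate_chain(GeneratorSpec(kind="random", length=14, seed=3))
        chain.break_after = {6}
        seq = encode_geometric(chain, library).sa_seq
        assert len(seq) == 10
        assert [i for i, c in enumerate(seq) if c == GAP] == [3, 4, 5, 6]

    def test_noise_perturbation_stability(self, library):
        clean = generate_chain(GeneratorSpec(kind="helix", length=50, seed=8))
        noisy = generate_chain(GeneratorSpec(kind="helix", length=50, noise_sigma=0.1, seed=8))
        a = encode_geometric(clean, library).sa_seq
        b = encode_geometric(noisy, library).sa_seq
        flips = sum(x != y for x, y in zip(a, b))
        assert flips <= 0.1 * len(a)


class TestSubstitutionMatrix:
    def test_hand_computed_toy_log_odds(self):
        # three geometrically distinct templates, uniform frequencies
        libs = [
            fragment_windows(generate_chain(GeneratorSpec(kind=k, length=9)))[2].coords
            for k in ("helix", "strand", "turnlib")
        ]
        lib = PrototypeLibrary(
            letters="ABC", templates=np.stack(libs), frequencies=np.full(3, 1 / 3)
        )
        sigma = 0.8
        mat = build_substitution_matrix(lib, scale=0.5, sigma=sigma)
        expected_diag = round(np.log2(3.0) / 0.5)
        assert (np.diag(mat.scores) == expected_diag).all()
        for i, j in ((0, 1), (0, 2), (1, 2)):
            d = fragment_rmsd(frag(lib.templates[i]), frag(lib.templates[j]))
            raw = (-(d**2) / (2 * sigma**2) * np.log2(np.e) + np.log2(3.0)) / 0.5
            assert mat.scores[i, j] == max(round(raw), -64)

    def test_structural_invariants(self, matrix):
        s = matrix.scores
        assert np.array_equal(s, s.T)
        for i in range(s.shape[0]):
            assert all(s[i, i] >= s[i, j] for j in range(s.shape[1]))
        f = matrix.background
        assert float(np.einsum("i,j,ij->", f, f, s)) < 0

    def test_identical_templates_give_equal_rows(self):
        # A and B share a template; C and D are far away so the matrix is
        # still calibratable (negative expected background score)
        helix = helix_window().coords
        others = [
            fragment_windows(generate_chain(GeneratorSpec(kind=k, length=9)))[2].coords
            for k in ("strand", "turnlib")
        ]
        lib = PrototypeLibrary(
            letters="ABCD",
            templates=np.stack([helix, helix] + others),
            frequencies=np.full(4, 0.25),
        )
        mat = build_substitution_matrix(lib, sigma=0.5)
        assert np.array_equal(mat.scores[0], mat.scores[1])

    def test_bad_sigma_raises_calibration_error(self, library):
        with pytest.raises(CalibrationError):
            build_substitution_matrix(library, sigma=100.0)


class TestLibraryIO:
    def test_round_trip(self, tmp_path, library):
        path = tmp_path / "lib.json"
        save_library(library, str(path))
        back = load_library(str(path))
        assert back.letters == library.letters
        assert np.abs(back.templates - library.templates).max() < 1e-3
        assert np.abs(back.frequencies - library.frequencies).max() < 1e-9

    def test_default_library_shape(self, library):
        assert library.letters == LETTERS
        assert library.templates.shape == (23, 5, 3)
        assert np.abs(library.templates.mean(axis=1)).max() < 1e-6
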