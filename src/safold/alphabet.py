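"""The 23-letter structural alphabet (SA) over 5-residue CA fragments.

A structural alphabet transcribes 3D backbone geometry into a 1D string: each
letter is a prototype — a representative 5-residue CA template — and every
5-residue window of a chain is assigned the letter of its nearest prototype
under superposition RMSD.  A chain of L residues therefore encodes to a
string of L - 4 letters.

The prototype library is a first-class learned artifact: it is recovered by
exact k-medoids clustering in the fragment metric space (superposition RMSD),
which avoids the frame-dependence of coordinate averaging.  A default
23-letter library learned from a fixed-seed synthetic corpus ships with the
package; any library with the same JSON schema can be loaded in its place.

The module also derives the substitution matrix used by the search stage:
Gaussian-kernel log-odds over template-template RMSD, in half-bit units,
calibrated so the expected score under the background letter frequencies is
strictly negative (a requirement of Karlin-Altschul statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import CalibrationError
from .geometry import kabsch_superpose, pairwise_rmsd
from .pdb_io import Chain

__all__ = [
    "LETTERS",
    "GAP",
    "Fragment",
    "PrototypeLibrary",
    "SARecord",
    "SubstitutionMatrix",
    "fragment_windows",
    "fragment_rmsd",
    "learn_prototypes",
    "assign_letter",
    "encode_geometric",
    "build_substitution_matrix",
    "load_library",
    "save_library",
    "load_default_library",
]

#: Canonical letter order.  The first groups are the helix / helix-like /
#: strand / strand-like / other categories; cluster-to-letter assignment is a
#: readability convention only.
LETTERS = "AYBCDGILEFHKNSTVWXMPQRZ"

#: Reserved non-alphabet symbol emitted for windows that span a chain break;
#: it can never seed or extend an alignment.
GAP = "-"

_ASSIGN_TIE_TOL = 1e-9
_SCORE_FLOOR = -64  # half-bits; keeps the integer matrix bounded


@dataclass(frozen=True)
class Fragment:
    """Five consecutive CA positions and where they came from."""

    coords: np.ndarray  # (5, 3)
    source: tuple[str, int]  # (chain id, 0-based start index)

    def __post_init__(self) -> None:
        if self.coords.shape != (5, 3):
            raise ValueError(f"fragment must be (5, 3), got {self.coords.shape}")


@dataclass
class PrototypeLibrary:
    """Lettered 5-residue CA templates plus background letter frequencies."""

    letters: str
    templates: np.ndarray  # (k, 5, 3), each centered at the origin
    frequencies: np.ndarray  # (k,), sums to 1
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.letters)
        if self.templates.shape != (k, 5, 3):
            raise ValueError("templates shape must be (k, 5, 3)")
        if self.frequencies.shape != (k,):
            raise ValueError("frequencies shape must be (k,)")
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must sum to 1")
        self.templates = self.templates - self.templates.mean(axis=1, keepdims=True)

    @property
    def k(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        i = self.letters.find(letter)
        if i < 0:
            raise ValueError(f"letter {letter!r} not in library")
        return i


@dataclass
class SARecord:
    """A chain transcribed into the structural alphabet.

    ``sa_seq`` has length L - 4 (break windows carry the gap symbol);
    ``ss_seq`` is the optional per-residue 8-letter secondary structure.
    """

    id: str
    sa_seq: str
    ss_seq: str | None = None
    chain: Chain | None = None


@dataclass
class SubstitutionMatrix:
    """Integer (half-bit) SA substitution scores with affine gap penalties.

    ``background`` stores the letter frequencies the log-odds were computed
    against; the search stage uses them for Karlin-Altschul statistics.
    """

    letters: str
    scores: np.ndarray  # (k, k) int
    gap_open: int = 11
    gap_extend: int = 1
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.letters)
        if self.scores.shape != (k, k):
            raise ValueError("scores must be (k, k)")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        self._index = {c: i for i, c in enumerate(self.letters)}

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def encode(self, seq: str) -> np.ndarray:
        """Letters to row indices; the gap symbol maps to -1."""
        try:
            return np.array(
                [-1 if c == GAP else self._index[c] for c in seq], dtype=int
            )
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} not in alphabet") from exc


def fragment_windows(chain: Chain) -> list[Fragment]:
    """All break-free 5-residue windows of a chain, in order."""
    ca = chain.ca_coords()
    frags = []
    for start, end in chain.segments():
        for i in range(start, end - 4):
            frags.append(
                Fragment(coords=ca[i : i + 5].copy(), source=(chain.structure_id, i))
            )
    return frags


def fragment_rmsd(a: Fragment, b: Fragment) -> float:
    """Superposition RMSD between two 5-residue fragments."""
    _, rmsd = kabsch_superpose(a.coords, b.coords)
    return rmsd


def _pairwise_blocked(A: np.ndarray, B: np.ndarray, block: int = 256) -> np.ndarray:
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(0, A.shape[0], block):
        out[i : i + block] = pairwise_rmsd(A[i : i + block], B)
    return out


def _assign(D: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment with deterministic tie-break (lowest index)."""
    # argmin already returns the first minimum; guard against float fuzz by
    # snapping near-ties to the minimum before argmin
    m = D.min(axis=1, keepdims=True)
    return np.argmax(D <= m + _ASSIGN_TIE_TOL, axis=1)


def learn_prototypes(
    fragments: list[Fragment],
    k: int = 23,
    seed: int = 0,
    max_iter: int = 100,
    max_fragments: int = 2000,
) -> PrototypeLibrary:
    """Learn a k-letter prototype library by k-medoids under fragment RMSD.

    Initialisation is k-medoids++ (distance-squared sampling driven solely by
    ``seed``); the update step picks each cluster's exact medoid.  The
    objective (sum of assignment RMSDs) is non-increasing and recorded in
    ``objective_history``.  When more than ``max_fragments`` fragments are
    given, medoids are found on a seed-deterministic subsample and the
    background frequencies are computed from the full set.
    """
    n = len(fragments)
    if n < k:
        raise ValueError(f"need at least k={k} fragments, got {n}")
    coords = np.stack([f.coords for f in fragments])
    coords = coords - coords.mean(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    if n > max_fragments:
        subset = np.sort(rng.choice(n, size=max_fragments, replace=False))
        pool = coords[subset]
    else:
        pool = coords
    m = pool.shape[0]
    D = _pairwise_blocked(pool, pool)

    # k-medoids++ seeding
    medoids = [int(rng.integers(m))]
    for _ in range(k - 1):
        d2 = D[:, medoids].min(axis=1) ** 2
        d2[medoids] = 0.0
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; take lowest unused
            candidates = [i for i in range(m) if i not in medoids]
            medoids.append(candidates[0])
            continue
        medoids.append(int(rng.choice(m, p=d2 / total)))

    history: list[float] = []
    for _ in range(max_iter):
        Dm = D[:, medoids]
        labels = _assign(Dm)
        history.append(float(Dm[np.arange(m), labels].sum()))
        new_medoids = list(medoids)
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster with the worst-served point
                nearest = D[:, new_medoids].min(axis=1)
                new_medoids[c] = int(np.argmax(nearest))
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = int(members[np.argmin(within)])
        if new_medoids == medoids:
            break
        medoids = new_medoids

    templates = pool[medoids].copy()
    # frequencies from the full fragment set
    D_full = _pairwise_blocked(coords, templates)
    full_labels = _assign(D_full)
    freq = np.bincount(full_labels, minlength=k).astype(float)
    freq /= freq.sum()
    return PrototypeLibrary(
        letters=LETTERS[:k],
        templates=templates,
        frequencies=freq,
        objective_history=history,
    )


def assign_letter(fragment: Fragment, library: PrototypeLibrary) -> str:
    """Letter of the nearest template (RMSD argmin; ties -> lexicographically
    smallest letter)."""
    coords = fragment.coords - fragment.coords.mean(axis=0)
    d = pairwise_rmsd(coords[None], library.templates)[0]
    best = d.min()
    tied = [library.letters[i] for i in np.flatnonzero(d <= best + _ASSIGN_TIE_TOL)]
    return min(tied)


def encode_geometric(chain: Chain, library: PrototypeLibrary) -> SARecord:
    """Transcribe a chain into its SA string (length L - 4).

    Windows that span a chain break emit the gap symbol ``-``, which the
    search stage can never seed on or extend through.
    """
    L = len(chain)
    if L < 5:
        raise ValueError(f"chain too short to encode: L={L} < 5")
    ca = chain.ca_coords()
    valid = np.ones(L - 4, dtype=bool)
    for b in chain.break_after:
        lo = max(0, b - 3)
        for i in range(lo, min(b + 1, L - 4)):
            valid[i] = False
    letters = [GAP] * (L - 4)
    idx = np.flatnonzero(valid)
    if idx.size:
        windows = np.stack([ca[i : i + 5] for i in idx])
        windows = windows - windows.mean(axis=1, keepdims=True)
        D = _pairwise_blocked(windows, library.templates)
        for row, i in enumerate(idx):
            d = D[row]
            best = d.min()
            tied = [
                library.letters[j] for j in np.flatnonzero(d <= best + _ASSIGN_TIE_TOL)
            ]
            letters[i] = min(tied)
    return SARecord(
        id=f"{chain.structure_id}:{chain.chain_id}",
        sa_seq="".join(letters),
        ss_seq=chain.ss,
        chain=chain,
    )


def build_substitution_matrix(
    library: PrototypeLibrary,
    scale: float = 0.5,
    sigma: float | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> SubstitutionMatrix:
    """Derive the integer SA substitution matrix from template geometry.

    Scores are Gaussian-kernel log-odds in units of ``scale`` bits
    (default half-bits)::

        s(i, j) = round( log2( exp(-d_ij^2 / 2 sigma^2)
                               / sqrt(f_i f_j) ) / scale )

    with ``d_ij`` the template-template superposition RMSD and ``f`` the
    (floored, renormalised) background frequencies.  ``sigma`` defaults to
    the median pairwise template RMSD and is geometrically shrunk until the
    expected background score is strictly negative; an explicitly supplied
    ``sigma`` that fails this Karlin-Altschul requirement raises
    :class:`CalibrationError`.
    """
    d = pairwise_rmsd(library.templates, library.templates)
    d = (d + d.T) / 2.0  # exact symmetry against float fuzz
    f = np.maximum(library.frequencies, 1e-4)
    f = f / f.sum()

    off = d[~np.eye(library.k, dtype=bool)]
    auto = sigma is None
    sig = float(np.median(off)) if auto else float(sigma)
    if sig <= 0:
        raise ValueError("sigma must be positive")

    log_odds_const = -np.log2(np.sqrt(np.outer(f, f)))
    for _ in range(200):
        raw = (-(d**2) / (2.0 * sig**2)) * np.log2(np.e) + log_odds_const
        s = np.rint(raw / scale)
        s = np.maximum(s, _SCORE_FLOOR)
        # enforce row-wise diagonal dominance while preserving symmetry
        diag = np.diag(s)
        s = np.minimum(s, np.minimum.outer(diag, diag))
        np.fill_diagonal(s, diag)
        s = s.astype(int)
        expected = float(np.einsum("i,j,ij->", f, f, s))
        if expected < 0 and s.max() > 0:
            return SubstitutionMatrix(
                letters=library.letters,
                scores=s,
                gap_open=gap_open,
                gap_extend=gap_extend,
                background=f,
            )
        if not auto:
            raise CalibrationError(
                f"expected background score {expected:.4f} >= 0 (or no positive "
                f"score) at sigma={sig:.4f}; decrease sigma"
            )
        sig *= 0.7
    raise CalibrationError("could not calibrate substitution matrix; sigma shrink failed")


# ---------------------------------------------------------------------------
# library (de)serialisation

def save_library(library: PrototypeLibrary, path: str) -> None:
    payload = {
        "format": "safold-prototype-library",
        "version": 1,
        "letters": library.letters,
        "templates": {
            library.letters[i]: np.round(library.templates[i], 4).tolist()
            for i in range(library.k)
        },
        "frequencies": {
            library.letters[i]: float(library.frequencies[i]) for i in range(library.k)
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _library_from_payload(payload: dict) -> PrototypeLibrary:
    letters = payload["letters"]
    templates = np.array([payload["templates"][c] for c in letters], dtype=float)
    freq = np.array([payload["frequencies"][c] for c in letters], dtype=float)
    freq = freq / freq.sum()
    return PrototypeLibrary(letters=letters, templates=templates, frequencies=freq)


def load_library(path: str) -> PrototypeLibrary:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "safold-prototype-library":
        raise ValueError(f"{path!r} is not a safold prototype library")
    return _library_from_payload(payload)


def load_default_library() -> PrototypeLibrary:
    """The 23-letter library shipped with the package (learned once, with a
    fixed seed, from a synthetic helix/strand/turn/coil corpus)."""
    text = resources.files("safold").joinpath("data/default_library.json").read_text()
    return _library_from_payload(json.loads(text))
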