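"""Chain -> KNN feature graph conversion.

Each residue becomes a graph node anchored at its CA atom and connected to
its k nearest CA neighbours.  Node features are the backbone torsion angles
(as sin/cos pairs; CA-only traces fall back to pseudo-torsions over four
consecutive CA atoms) plus a 21-way residue one-hot, together with unit
direction vectors to the neighbouring CA and C atoms and to CB.  Edge
features are the unit edge direction, a Gaussian radial-basis encoding of
the CA-CA distance and a sinusoidal encoding of the sequence offset.

All scalar features are invariant, and all vector features equivariant,
under rigid motion of the input chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import dihedral
from .pdb_io import Chain

__all__ = [
    "FeaturizeConfig",
    "StructureGraph",
    "build_knn_graph",
    "node_features",
    "rbf_encode",
    "positional_encode",
    "assign_secondary_structure",
]

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # one-hot position 20 = unknown 'X'


@dataclass(frozen=True)
class FeaturizeConfig:
    """Featurization knobs: neighbour count, RBF grid, positional dims."""

    k: int = 32
    rbf_centers: int = 16
    rbf_max: float = 20.0
    rbf_sigma: float | None = None  # default: center spacing
    pe_dims: int = 16

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rbf_centers < 2:
            raise ValueError("need at least 2 RBF centers")
        if self.pe_dims % 2 != 0 or self.pe_dims < 2:
            raise ValueError("pe_dims must be a positive even number")

    @property
    def sigma(self) -> float:
        if self.rbf_sigma is not None:
            return self.rbf_sigma
        return self.rbf_max / (self.rbf_centers - 1)


@dataclass
class StructureGraph:
    """KNN graph with scalar/vector node and edge features.

    ``node_vector_mask`` flags which of the per-node direction vectors are
    defined (termini, chain breaks and missing atoms give zero vectors with
    mask 0).  Edges are directed i -> j with j among the k nearest CA
    neighbours of i.
    """

    length: int
    node_scalars: np.ndarray  # (L, 4 + 21)
    node_vectors: np.ndarray  # (L, 5, 3)
    node_vector_mask: np.ndarray  # (L, 5)
    edges: np.ndarray  # (E, 2) int
    edge_scalars: np.ndarray  # (E, rbf_centers + pe_dims)
    edge_vectors: np.ndarray  # (E, 3)
    config: FeaturizeConfig


def rbf_encode(d: float | np.ndarray, config: FeaturizeConfig) -> np.ndarray:
    """Gaussian radial basis expansion of a distance (Angstrom).

    Component m is ``exp(-(d - c_m)^2 / (2 sigma^2))`` with centers evenly
    spaced on ``[0, rbf_max]``.
    """
    d = np.asarray(d, dtype=float)
    centers = np.linspace(0.0, config.rbf_max, config.rbf_centers)
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * config.sigma**2))


def positional_encode(offset: int | np.ndarray, pe_dims: int = 16) -> np.ndarray:
    """Standard sinusoidal encoding of a signed sequence offset.

    Returns ``pe_dims`` values: interleaved ``sin(offset / 10000^(2m/D))``,
    ``cos(...)`` pairs; offset 0 gives the (0, 1, 0, 1, ...) pattern, and
    negating the offset negates the sin components only.
    """
    if pe_dims % 2 != 0:
        raise ValueError("pe_dims must be even")
    offset = np.asarray(offset, dtype=float)
    m = np.arange(pe_dims // 2)
    freq = 1.0 / (10000.0 ** (2.0 * m / pe_dims))
    ang = offset[..., None] * freq
    out = np.empty(offset.shape + (pe_dims,))
    out[..., 0::2] = np.sin(ang)
    out[..., 1::2] = np.cos(ang)
    return out


def _unit_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(n > 1e-12, v / np.where(n > 1e-12, n, 1.0), 0.0)


def _bonded(chain: Chain, i: int, j: int) -> bool:
    """True when residues i < j are consecutive with no break between."""
    return j == i + 1 and i not in chain.break_after


def _torsions(chain: Chain) -> np.ndarray:
    """(L, 2) phi/psi in radians; NaN where undefined.

    Uses the full backbone when N and C atoms are present, otherwise falls
    back to pseudo-torsions over four consecutive CA atoms.  Neither form is
    evaluated across a chain break.
    """
    L = len(chain)
    res = chain.residues
    ca = chain.ca_coords()
    out = np.full((L, 2), np.nan)
    for i in range(L):
        has = lambda j, a: 0 <= j < L and a in res[j].coords  # noqa: E731
        # phi_i = C(i-1) N(i) CA(i) C(i)
        if i > 0 and _bonded(chain, i - 1, i) and has(i - 1, "C") and has(i, "N") and has(i, "C"):
            out[i, 0] = dihedral(res[i - 1].coords["C"], res[i].coords["N"], ca[i], res[i].coords["C"])
        elif 2 <= i <= L - 2 and not ({i - 2, i - 1, i} & chain.break_after):
            out[i, 0] = dihedral(ca[i - 2], ca[i - 1], ca[i], ca[i + 1])
        # psi_i = N(i) CA(i) C(i) N(i+1)
        if i < L - 1 and _bonded(chain, i, i + 1) and has(i, "N") and has(i, "C") and has(i + 1, "N"):
            out[i, 1] = dihedral(res[i].coords["N"], ca[i], res[i].coords["C"], res[i + 1].coords["N"])
        elif 1 <= i <= L - 3 and not ({i - 1, i, i + 1} & chain.break_after):
            out[i, 1] = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
    return out


def node_features(chain: Chain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue scalar and vector features.

    Returns ``(scalars, vectors, vector_mask)``: scalars are
    ``[sin phi, cos phi, sin psi, cos psi, one-hot(21)]`` (undefined torsions
    contribute zeros); vectors are unit directions to the previous CA, next
    CA, previous C, own C and own CB, zeroed with mask 0 when undefined.
    """
    L = len(chain)
    res = chain.residues
    ca = chain.ca_coords()
    tor = _torsions(chain)

    scalars = np.zeros((L, 4 + 21))
    defined = ~np.isnan(tor)
    scalars[:, 0] = np.where(defined[:, 0], np.sin(np.nan_to_num(tor[:, 0])), 0.0)
    scalars[:, 1] = np.where(defined[:, 0], np.cos(np.nan_to_num(tor[:, 0])), 0.0)
    scalars[:, 2] = np.where(defined[:, 1], np.sin(np.nan_to_num(tor[:, 1])), 0.0)
    scalars[:, 3] = np.where(defined[:, 1], np.cos(np.nan_to_num(tor[:, 1])), 0.0)
    for i, r in enumerate(res):
        pos = _AA_ORDER.find(r.aa)
        scalars[i, 4 + (pos if pos >= 0 else 20)] = 1.0

    vectors = np.zeros((L, 5, 3))
    mask = np.zeros((L, 5))
    for i in range(L):
        if i > 0 and _bonded(chain, i - 1, i):
            vectors[i, 0] = ca[i - 1] - ca[i]
            mask[i, 0] = 1.0
            if "C" in res[i - 1].coords:
                vectors[i, 2] = res[i - 1].coords["C"] - ca[i]
                mask[i, 2] = 1.0
        if i < L - 1 and _bonded(chain, i, i + 1):
            vectors[i, 1] = ca[i + 1] - ca[i]
            mask[i, 1] = 1.0
        if "C" in res[i].coords:
            vectors[i, 3] = res[i].coords["C"] - ca[i]
            mask[i, 3] = 1.0
        if "CB" in res[i].coords and res[i].aa != "G":
            vectors[i, 4] = res[i].coords["CB"] - ca[i]
            mask[i, 4] = 1.0
    vectors = _unit_rows(vectors)
    return scalars, vectors, mask


def build_knn_graph(chain: Chain, config: FeaturizeConfig | None = None) -> StructureGraph:
    """Assemble the full feature graph (k clamped to L - 1; distance ties
    broken by residue index)."""
    if config is None:
        config = FeaturizeConfig()
    L = len(chain)
    if L < 2:
        raise ValueError(f"need at least 2 residues to build a graph, got L={L}")
    ca = chain.ca_coords()
    k = min(config.k, L - 1)

    D = cdist(ca, ca)
    np.fill_diagonal(D, np.inf)
    # quantize so the neighbour order is stable under rigid motion round-off;
    # residual ties break by residue index
    Dq = np.round(D, 6)
    idx = np.arange(L)
    edges = []
    for i in range(L):
        order = np.lexsort((idx, Dq[i]))[:k]
        edges.extend((i, int(j)) for j in order)
    edges = np.array(edges, dtype=int)

    src, dst = edges[:, 0], edges[:, 1]
    vec = ca[dst] - ca[src]
    dist = np.linalg.norm(vec, axis=1)
    edge_scalars = np.concatenate(
        [rbf_encode(dist, config), positional_encode(dst - src, config.pe_dims)], axis=1
    )
    edge_vectors = _unit_rows(vec)

    scalars, vectors, mask = node_features(chain)
    return StructureGraph(
        length=L,
        node_scalars=scalars,
        node_vectors=vectors,
        node_vector_mask=mask,
        edges=edges,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        config=config,
    )


def assign_secondary_structure(chain: Chain, use_truth: bool = True) -> str:
    """Heuristic 8-state secondary structure from backbone geometry.

    Fixture chains carry ground-truth labels in ``chain.ss``, which callers
    should prefer; this phi/psi + CA-contact rule covers real structures
    without an external assignment program.  Only the H, E, T and C states
    are ever emitted; the remaining classes of the 8-letter alphabet are
    reserved.
    """
    if use_truth and chain.ss is not None:
        return chain.ss
    L = len(chain)
    tor = np.rad2deg(_torsions(chain))
    ca = chain.ca_coords()
    out = []
    for i in range(L):
        phi, psi = tor[i]
        label = "C"
        if not np.isnan(phi) and not np.isnan(psi):
            if -120 <= phi <= -20 and -100 <= psi <= 30:
                label = "H"
            elif -180 <= phi <= -60 and (psi >= 80 or psi <= -150):
                label = "E"
        if label == "C" and i + 3 < L and not ({i, i + 1, i + 2} & chain.break_after):
            if np.linalg.norm(ca[i + 3] - ca[i]) < 7.0:
                label = "T"
        out.append(label)
    return "".join(out)
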