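"""Deterministic synthetic protein backbones for building and testing.

Generates CA traces of ideal alpha-helices (cylindrical spiral: rise 1.5 A,
twist 100 deg, radius 2.3 A), extended strands (pleated zig-zag, 3.8 A CA-CA),
tight turns (circular arc) and random coils (correlated random walk with a
fixed 3.8 A step), then places N / C / CB atoms by idealised local-frame
geometry around the CA trace.  Every output is a pure function of its
:class:`GeneratorSpec` (seed included) and carries ground-truth
secondary-structure labels, so no external structure database or assignment
program is needed anywhere in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pdb_io import Chain, Residue

__all__ = ["GeneratorSpec", "generate_chain", "generate_corpus", "write_pdb"]

KINDS = ("helix", "strand", "turnlib", "random")

# amino acids sampled for synthetic sequences (glycine included so the
# no-CB code path is exercised)
_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"

# 8-letter secondary-structure alphabet used throughout the package
# (alpha-helix, 3-10, pi, strand, bridge, turn, bend, coil)
SS_ALPHABET = "HGIEBTSC"

_SS_BY_KIND = {"helix": "H", "strand": "E", "turnlib": "T", "random": "C"}

_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic chain.

    Parameters
    ----------
    kind : {"helix", "strand", "turnlib", "random"}
    length : int
        Number of residues (>= 1).
    rise, twist, radius : float
        Helix geometry: rise per residue (A), twist per residue (degrees),
        cylinder radius (A).  Canonical alpha-helix defaults.
    noise_sigma : float
        Std-dev of isotropic Gaussian noise added to the CA trace (A).
    seed : int
        Drives the sequence draw, the coil walk and the noise.
    """

    kind: str = "helix"
    length: int = 20
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _helix_trace(spec: GeneratorSpec) -> np.ndarray:
    i = np.arange(spec.length)
    theta = np.deg2rad(spec.twist) * i
    return np.column_stack(
        [spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * i]
    )


def _strand_trace(length: int) -> np.ndarray:
    # pleated zig-zag: 3.46 A rise along the axis, alternating offset chosen
    # so consecutive CA-CA distances are exactly 3.8 A
    rise = 3.46
    h = np.sqrt(3.8**2 - rise**2) / 2.0
    i = np.arange(length)
    return np.column_stack([rise * i, h * (-1.0) ** i, np.zeros(length)])


def _turn_trace(length: int) -> np.ndarray:
    # circular arc of radius 4.5 A with 3.8 A chords: much tighter curvature
    # than a helix, no rise
    R = 4.5
    step = 2.0 * np.arcsin(3.8 / (2.0 * R))
    i = np.arange(length)
    return np.column_stack([R * np.cos(step * i), R * np.sin(step * i), np.zeros(length)])


def _coil_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(length - 1):
        # correlated walk: blend previous direction with a fresh random one;
        # keeps pseudo-bond angles in a plausible range
        r = rng.normal(size=3)
        d = 0.6 * d + r / np.linalg.norm(r)
        d = d / np.linalg.norm(d)
        pts.append(pts[-1] + 3.8 * d)
    return np.array(pts)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _place_backbone(ca: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Place N, C, CB around each CA by an idealised local frame.

    Bond lengths: N-CA 1.46 A, CA-C 1.52 A, CA-CB 1.53 A.  The construction
    is deterministic and yields finite, non-degenerate backbone dihedrals;
    it does not claim chemically exact peptide geometry.
    """
    L = ca.shape[0]
    out: list[dict[str, np.ndarray]] = []
    for i in range(L):
        prev_dir = _unit(ca[i - 1] - ca[i]) if i > 0 else -_unit(ca[i + 1] - ca[i]) if L > 1 else np.array([-1.0, 0.0, 0.0])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < L - 1 else -prev_dir
        normal = np.cross(prev_dir, next_dir)
        if np.linalg.norm(normal) < 1e-8:
            normal = np.cross(prev_dir, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(normal) < 1e-8:
                normal = np.cross(prev_dir, np.array([0.0, 1.0, 0.0]))
        normal = _unit(normal)
        n_atom = ca[i] + 1.46 * _unit(prev_dir + 0.5 * normal)
        c_atom = ca[i] + 1.52 * _unit(next_dir + 0.5 * normal)
        n1 = _unit(n_atom - ca[i])
        n2 = _unit(c_atom - ca[i])
        bis = _unit(n1 + n2)
        perp = _unit(np.cross(n1, n2))
        cb = ca[i] + 1.53 * _unit(-bis + 1.2 * perp)
        out.append({"CA": ca[i].copy(), "N": n_atom, "C": c_atom, "CB": cb})
    return out


def generate_chain(spec: GeneratorSpec) -> Chain:
    """Build one synthetic :class:`Chain` with full backbone atoms.

    The returned chain carries its ground-truth secondary-structure string in
    ``chain.ss`` (``H``/``E``/``T``/``C`` by construction).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "helix":
        ca = _helix_trace(spec)
    elif spec.kind == "strand":
        ca = _strand_trace(spec.length)
    elif spec.kind == "turnlib":
        ca = _turn_trace(spec.length)
    else:
        ca = _coil_trace(spec.length, rng)

    # sequence drawn before noise so noise level never changes the sequence
    seq = "".join(rng.choice(list(_AA_POOL)) for _ in range(spec.length))
    if spec.noise_sigma > 0:
        ca = ca + rng.normal(scale=spec.noise_sigma, size=ca.shape)

    backbone = _place_backbone(ca)
    residues = [
        Residue(index=i, aa=seq[i], coords=backbone[i]) for i in range(spec.length)
    ]
    return Chain(
        structure_id=f"SYN_{spec.kind.upper()}_{spec.seed}",
        chain_id="A",
        residues=residues,
        resolution=None,
        ss=_SS_BY_KIND[spec.kind] * spec.length,
    )


def generate_corpus(
    n_chains: int,
    specs: list[GeneratorSpec] | None = None,
    seed: int = 0,
) -> list[Chain]:
    """A reproducible mixed corpus: ``n_chains`` chains cycling through the
    given recipe list (default: helix / strand / turn / coil, lengths 20-40,
    noise 0.05 A), each re-seeded deterministically from ``seed``."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if specs is None:
        specs = [
            GeneratorSpec(kind="helix", length=30, noise_sigma=0.05),
            GeneratorSpec(kind="strand", length=24, noise_sigma=0.05),
            GeneratorSpec(kind="turnlib", length=20, noise_sigma=0.05),
            GeneratorSpec(kind="random", length=40, noise_sigma=0.05),
        ]
    rng = np.random.default_rng(seed)
    chains = []
    for i in range(n_chains):
        base = specs[i % len(specs)]
        chain_seed = int(rng.integers(0, 2**31 - 1))
        chain = generate_chain(replace(base, seed=chain_seed))
        chain.structure_id = f"{chain.structure_id}_{i:04d}"
        chains.append(chain)
    return chains


def write_pdb(chain: Chain, path: str) -> None:
    """Write standard fixed-width ATOM records (plus TER/END).

    Coordinates outside the PDB field range (-999.999 .. 9999.999) raise a
    ``ValueError`` rather than being silently truncated.  Glycine residues
    never emit a CB atom.
    """
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    element = {"N": "N", "CA": "C", "C": "C", "CB": "C"}
    lines = []
    serial = 1
    for res in chain.residues:
        resname = three.get(res.aa, "UNK")
        for role in ("N", "CA", "C", "CB"):
            if role not in res.coords:
                continue
            if res.aa == "G" and role == "CB":
                continue
            x, y, z = res.coords[role]
            for v in (x, y, z):
                if not (_PDB_COORD_MIN <= v <= _PDB_COORD_MAX):
                    raise ValueError(
                        f"coordinate {v:.3f} exceeds PDB fixed-width field range"
                    )
            lines.append(
                f"ATOM  {serial:5d}  {role:<3s} {resname:>3s} {chain.chain_id:1s}"
                f"{res.index + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element[role]:>2s}"
            )
            serial += 1
    lines.append(f"TER   {serial:5d}      {three.get(chain.residues[-1].aa, 'UNK'):>3s} "
                 f"{chain.chain_id:1s}{chain.residues[-1].index + 1:4d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
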