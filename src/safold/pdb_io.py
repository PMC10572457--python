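"""Structure ingestion: PDB parsing, corpus filters, dataset splitting.

A :class:`Chain` is the universal input of the pipeline: an ordered list of
residues carrying backbone coordinates (CA mandatory; N, C, CB optional).
Chain breaks — gaps in author numbering or an unphysical CA-CA jump — are
recorded as flags so that downstream fragment windows and torsion angles
never span them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import ChainNotFoundError, ParseError

__all__ = [
    "Residue",
    "Chain",
    "DatasetSplit",
    "read_structure",
    "filter_chains",
    "split_dataset",
    "MAX_CA_CA_DISTANCE",
]

# CA-CA distance above which two consecutive residues are considered
# disconnected (trans peptide ~3.8 A; cis ~2.9 A; 4.5 A is a safe ceiling).
MAX_CA_CA_DISTANCE = 4.5

_BACKBONE_ATOMS = ("N", "CA", "C", "CB")


@dataclass
class Residue:
    """One amino-acid residue: 0-based chain position, one-letter code,
    and a role -> 3-vector coordinate map (Angstrom). CA is mandatory."""

    index: int
    aa: str
    coords: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        ca = self.coords.get("CA")
        if ca is None or not np.all(np.isfinite(ca)):
            raise ValueError(f"residue {self.index}: CA coordinate missing or non-finite")

    @property
    def ca(self) -> np.ndarray:
        return self.coords["CA"]


@dataclass
class Chain:
    """An ordered residue list with structure metadata.

    ``break_after`` holds residue indices ``i`` such that the bond between
    residue ``i`` and ``i+1`` is broken.  ``ss`` optionally carries a
    per-residue secondary-structure string (fixture ground truth).
    """

    structure_id: str
    chain_id: str
    residues: list[Residue]
    resolution: float | None = None
    break_after: set[int] = field(default_factory=set)
    ss: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("chain must contain at least one residue")
        idx = [r.index for r in self.residues]
        if any(b >= a for a, b in zip(idx[1:], idx[:-1])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of CA positions."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def segments(self) -> list[tuple[int, int]]:
        """Break-free runs as 0-based half-open ``(start, end)`` index ranges."""
        segs: list[tuple[int, int]] = []
        start = 0
        for i in range(len(self.residues) - 1):
            if i in self.break_after:
                segs.append((start, i + 1))
                start = i + 1
        segs.append((start, len(self.residues)))
        return segs

    def subchain(self, start: int, end: int, structure_id: str | None = None) -> "Chain":
        """Residues ``[start, end)`` as a new chain with re-based indices."""
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(f"invalid span [{start}, {end}) for length {len(self.residues)}")
        res = [
            Residue(index=i - start, aa=r.aa, coords=dict(r.coords))
            for i, r in enumerate(self.residues[start:end], start=start)
        ]
        breaks = {b - start for b in self.break_after if start <= b < end - 1}
        ss = self.ss[start:end] if self.ss is not None else None
        return Chain(
            structure_id=structure_id or f"{self.structure_id}_{start}_{end}",
            chain_id=self.chain_id,
            residues=res,
            resolution=self.resolution,
            break_after=breaks,
            ss=ss,
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint training / test / validation id lists covering the input."""

    training: list[str]
    test: list[str]
    validation: list[str]
    fractions: tuple[float, float, float]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.training), len(self.test), len(self.validation))


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _detect_breaks(residues: list[Residue], seqids: list[int]) -> set[int]:
    breaks: set[int] = set()
    for i in range(len(residues) - 1):
        if seqids[i + 1] - seqids[i] != 1:
            breaks.add(i)
            continue
        d = float(np.linalg.norm(residues[i + 1].ca - residues[i].ca))
        if d > MAX_CA_CA_DISTANCE:
            breaks.add(i)
    return breaks


def read_structure(path: str, chain_id: str | None = None) -> list[Chain]:
    """Read a PDB file into per-polymer-chain :class:`Chain` objects.

    Residues lacking a CA atom are dropped (a break flag is set at the gap).
    Altlocs keep the highest-occupancy conformer; insertion codes collapse
    into sequential 0-based indices.  HETATM records are ignored except
    selenomethionine (MSE), which is read as MET.

    Parameters
    ----------
    path : str
        PDB file path.
    chain_id : str, optional
        Return only this chain; raises :class:`ChainNotFoundError` if absent.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse PDB file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path!r}")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        seqids: list[int] = []
        dropped_at: set[int] = set()
        for res in ch:
            if res.het_flag == "H" and res.name != "MSE":
                continue
            name = "MET" if res.name == "MSE" else res.name
            coords: dict[str, np.ndarray] = {}
            for role in _BACKBONE_ATOMS:
                best = None
                for atom in res:
                    if atom.name != role:
                        continue
                    if best is None or atom.occ > best.occ:
                        best = atom
                if best is not None:
                    coords[role] = np.array([best.pos.x, best.pos.y, best.pos.z])
            if "CA" not in coords:
                # residue unusable; mark a break at the preceding kept residue
                if residues:
                    dropped_at.add(len(residues) - 1)
                continue
            residues.append(Residue(index=len(residues), aa=_one_letter(name), coords=coords))
            seqids.append(res.seqid.num)
        if not residues:
            continue
        breaks = _detect_breaks(residues, seqids) | {
            i for i in dropped_at if i < len(residues) - 1
        }
        chains.append(
            Chain(
                structure_id=st.name or "UNKNOWN",
                chain_id=ch.name,
                residues=residues,
                resolution=resolution,
                break_after=breaks,
            )
        )

    if chain_id is not None:
        selected = [c for c in chains if c.chain_id == chain_id]
        if not selected:
            raise ChainNotFoundError(f"chain {chain_id!r} not found in {path!r}")
        return selected
    return chains


def filter_chains(
    chains: list[Chain], min_len: int = 16, max_resolution: float = 3.5
) -> list[Chain]:
    """Corpus filter: drop chains shorter than ``min_len`` residues or with a
    crystallographic resolution worse than ``max_resolution`` Angstrom.
    Chains without a resolution record (NMR, predicted models) are retained.
    Idempotent."""
    return [
        c
        for c in chains
        if len(c) >= min_len and (c.resolution is None or c.resolution <= max_resolution)
    ]


def split_dataset(
    ids: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle ``ids`` with ``seed`` and partition into training / test /
    validation sets whose sizes follow ``fractions`` by largest-remainder
    rounding (ties broken in set order: training, test, validation)."""
    if len(fractions) != 3:
        raise ValueError("fractions must have exactly three entries")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = len(ids)
    exact = [f * n for f in fractions]
    sizes = [int(math.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    # largest remainder; ties broken by set order (stable sort on -remainder)
    order = sorted(range(3), key=lambda i: -(exact[i] - sizes[i]))
    for i in range(remainder):
        sizes[order[i]] += 1

    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(
        training=shuffled[:a],
        test=shuffled[a:b],
        validation=shuffled[b:],
        fractions=tuple(fractions),
    )
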