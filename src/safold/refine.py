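"""Hit refinement: localization, Kabsch superposition, identities, reports.

Given a search hit, the structural-alphabet alignment is mapped back to
residue coordinates (SA window i covers residues [i, i+5), so an alignment
spanning windows [a, b) covers residues [a, b+4)), the query is superposed
onto the subject by the Kabsch algorithm over the CA atoms of aligned
columns, and sequence / secondary-structure identities are computed over the
same residue footprint.  For fragment queries with neural embeddings
enabled, the location is refined by sliding the query embedding rows along
the subject and taking the offset of minimal mean distance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import encoder as encoder_mod
from .alphabet import (
    PrototypeLibrary,
    SARecord,
    SubstitutionMatrix,
    build_substitution_matrix,
    encode_geometric,
    load_default_library,
)
from .featurize import FeaturizeConfig, assign_secondary_structure, build_knn_graph
from .geometry import RigidTransform, kabsch_superpose
from .pdb_io import Chain
from .search import Alignment, SearchDatabase, SearchParams, seeded_search

__all__ = [
    "RigidTransform",
    "HitRecord",
    "kabsch_superpose",
    "localize",
    "identity_metrics",
    "run_pipeline",
    "write_report",
    "REPORT_COLUMNS",
]

#: A window alignment covering SA positions [a, b) spans residues [a, b + 4).
SA_WINDOW = 5

REPORT_COLUMNS = [
    "subject_id", "chain", "start", "end", "evalue", "rmsd",
    "seq_identity", "ss_identity", "sa_alignment",
]


@dataclass
class HitRecord:
    """One refined search result (a report row)."""

    subject_id: str
    chain_id: str
    location: tuple[int, int]  # 0-based half-open residue span in subject
    evalue: float
    rmsd: float
    seq_identity: float
    ss_identity: float
    alignment: Alignment
    sa_alignment: str = ""
    transform: RigidTransform | None = None


def localize(query_emb: np.ndarray, subject_emb: np.ndarray) -> tuple[int, float]:
    """Best placement of a query embedding block inside a subject.

    Scans every offset ``o`` in ``[0, Ls - Lq]`` and returns the one
    minimising the mean Euclidean row distance
    ``mean_i ||query_emb[i] - subject_emb[o + i]||`` (ties -> smallest
    offset).  Equivalent to scanning the diagonals of the full pairwise
    embedding-distance matrix.
    """
    query_emb = np.asarray(query_emb, dtype=float)
    subject_emb = np.asarray(subject_emb, dtype=float)
    Lq, Ls = query_emb.shape[0], subject_emb.shape[0]
    if Lq > Ls:
        raise ValueError(f"query length {Lq} exceeds subject length {Ls}")
    n_off = Ls - Lq + 1
    means = np.empty(n_off)
    for o in range(n_off):
        d = np.linalg.norm(subject_emb[o : o + Lq] - query_emb, axis=1)
        means[o] = d.mean()
    best = int(np.argmin(means))  # argmin returns the first (smallest) offset
    return best, float(means[best])


def _residue_pairs(alignment: Alignment) -> list[tuple[int, int]]:
    """Map aligned SA columns to aligned residue index pairs.

    Each aligned window column (qi, sj) pairs residue qi with sj; the final
    column additionally contributes its remaining 4-residue footprint so the
    full extent of the last window is covered.
    """
    pairs = [(q, s) for q, s in alignment.aligned_pairs]
    if pairs:
        ql, sl = pairs[-1]
        pairs.extend((ql + t, sl + t) for t in range(1, SA_WINDOW))
    return pairs


def identity_metrics(
    alignment: Alignment,
    q_aa: str,
    s_aa: str,
    q_ss: str,
    s_ss: str,
    sa_windows: bool = True,
) -> tuple[float, float]:
    """Fractional sequence and secondary-structure identity of a hit.

    With ``sa_windows=True`` the alignment columns are SA windows and the
    comparison runs over their residue footprint; with ``sa_windows=False``
    the columns are taken as residue positions directly.  Gap columns are
    excluded from both numerator and denominator.
    """
    pairs = _residue_pairs(alignment) if sa_windows else list(alignment.aligned_pairs)
    if not pairs:
        return 0.0, 0.0
    for qi, sj in pairs:
        if qi >= len(q_aa) or sj >= len(s_aa) or qi >= len(q_ss) or sj >= len(s_ss):
            raise ValueError(f"alignment column ({qi}, {sj}) outside sequence bounds")
    seq = sum(1 for qi, sj in pairs if q_aa[qi] == s_aa[sj]) / len(pairs)
    ss = sum(1 for qi, sj in pairs if q_ss[qi] == s_ss[sj]) / len(pairs)
    return seq, ss


@dataclass
class PipelineOptions:
    """Knobs of :func:`run_pipeline`."""

    encoder: str = "geometric"  # "geometric" | "neural"
    search: SearchParams | None = None
    featurize: FeaturizeConfig | None = None
    model: "encoder_mod.Model | None" = None
    use_embeddings: bool | None = None  # default: True iff encoder == "neural"
    min_query_len: int = 5


def run_pipeline(
    query: Chain,
    db: SearchDatabase,
    library: PrototypeLibrary | None = None,
    matrix: SubstitutionMatrix | None = None,
    options: PipelineOptions | None = None,
    structures: dict[str, Chain] | None = None,
) -> list[HitRecord]:
    """Full search: encode the query, search the SA database, refine each hit.

    ``structures`` supplies subject coordinates by record id when the
    database records do not carry their chains.  Hits are returned sorted by
    (E-value, subject id).
    """
    options = options or PipelineOptions()
    if len(query) < options.min_query_len:
        raise ValueError(
            f"query fails filters: L={len(query)} < {options.min_query_len}"
        )
    if library is None:
        library = load_default_library()
    if matrix is None:
        matrix = build_substitution_matrix(library)

    if options.encoder == "neural":
        if options.model is None:
            raise ValueError("neural encoder requested but no model given")
        graph = build_knn_graph(query, options.model.featurize_config)
        preds = encoder_mod.decode(options.model, graph)
        q_record = SARecord(
            id=f"{query.structure_id}:{query.chain_id}",
            sa_seq=preds.sa_string(library.letters),
            ss_seq=query.ss,
            chain=query,
        )
        q_emb = encoder_mod.encode(options.model, graph)
    elif options.encoder == "geometric":
        q_record = encode_geometric(query, library)
        q_emb = None
    else:
        raise ValueError(f"unknown encoder {options.encoder!r}")

    use_emb = options.use_embeddings
    if use_emb is None:
        use_emb = options.encoder == "neural"

    hits = seeded_search(q_record, db, matrix, options.search)

    records: list[HitRecord] = []
    q_aa = query.sequence()
    q_ca = query.ca_coords()
    for hit in hits:
        subject = hit.record.chain
        if subject is None and structures is not None:
            subject = structures.get(hit.record.id)
        if subject is None:
            raise ValueError(f"no coordinates available for subject {hit.record.id!r}")
        s_aa = subject.sequence()
        # SS identity is only meaningful when both sides are labelled by the
        # same scheme: ground truth if both carry it, the geometric heuristic
        # for both otherwise
        both_truth = query.ss is not None and subject.ss is not None
        q_ss = assign_secondary_structure(query, use_truth=both_truth)
        s_ss = assign_secondary_structure(subject, use_truth=both_truth)
        s_ca = subject.ca_coords()

        aln = hit.alignment
        sa, sb = aln.subject_span
        location = (sa, min(sb + SA_WINDOW - 1, len(subject)))
        pairs = _residue_pairs(aln)

        # fragment queries with embeddings: refine location by embedding scan
        covers_subject = sa == 0 and sb == len(hit.record.sa_seq)
        if use_emb and q_emb is not None and not covers_subject and len(query) <= len(subject):
            s_graph = build_knn_graph(subject, options.model.featurize_config)
            s_emb = encoder_mod.encode(options.model, s_graph)
            offset, _ = localize(q_emb, s_emb)
            location = (offset, offset + len(query))
            pairs = [(i, offset + i) for i in range(len(query))]

        if len(pairs) >= 3:
            P = q_ca[[p[0] for p in pairs]]
            Q = s_ca[[p[1] for p in pairs]]
            transform, rmsd = kabsch_superpose(P, Q)
        else:
            transform, rmsd = None, float("nan")
        seq_id, ss_id = identity_metrics(aln, q_aa, s_aa, q_ss, s_ss)
        records.append(
            HitRecord(
                subject_id=subject.structure_id,
                chain_id=subject.chain_id,
                location=location,
                evalue=hit.evalue,
                rmsd=rmsd,
                seq_identity=seq_id,
                ss_identity=ss_id,
                alignment=aln,
                sa_alignment=aln.pretty(q_record.sa_seq, hit.record.sa_seq),
                transform=transform,
            )
        )
    records.sort(key=_hit_order)
    return records


def _hit_order(r: HitRecord) -> tuple:
    """Report ordering: E-value, then RMSD (NaN last), then subject id."""
    rmsd = r.rmsd if np.isfinite(r.rmsd) else float("inf")
    return (r.evalue, rmsd, r.subject_id)


def write_report(records: list[HitRecord], path: str) -> None:
    """Write hit records as CSV, ordered by E-value, then RMSD, then
    subject id (ties in both E-value and RMSD fall back to subject id, so
    row order is always deterministic)."""
    rows = sorted(records, key=_hit_order)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for r in rows:
            writer.writerow([
                r.subject_id, r.chain_id, r.location[0], r.location[1],
                f"{r.evalue:.6g}", f"{r.rmsd:.6f}",
                f"{r.seq_identity:.6f}", f"{r.ss_identity:.6f}", r.sa_alignment,
            ])
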