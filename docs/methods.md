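# Methods

This note records the models, numerical choices and open design decisions
behind safold, in the spirit of a package's model documentation. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The structural alphabet

A structural alphabet transcribes backbone geometry into a string: each
letter is a *prototype*, a representative 5-residue CA template, and window
*i* of a chain (residues [*i*, *i*+5)) is assigned the letter of the nearest
prototype under optimal-superposition RMSD. A break-free chain of *L*
residues therefore encodes to exactly *L* − 4 letters. Windows that span a
chain break emit the reserved symbol `-`, which scores so negatively in the
substitution model that it can never seed or extend an alignment (it may be
skipped by a gap).

**Prototype learning.** The 23-letter library is learned by k-medoids in the
fragment metric space (superposition RMSD), not by coordinate averaging:
averaging requires choosing a superposition frame per cluster and can
produce non-representative mean shapes, whereas a medoid is always a real
fragment. Initialisation is k-medoids++ (distance-squared sampling, fully
seed-driven); the update step takes each cluster's exact medoid; empty
clusters are re-seeded with the worst-served fragment. The objective (sum of
assignment RMSDs) is non-increasing by construction and is recorded on the
library. Assignment ties (within 1e-9 Å) break to the lexicographically
smallest letter. Above 2,000 fragments the medoid search runs on a
seed-deterministic subsample; background letter frequencies always come from
the full input.

The shipped default library was learned once, with a fixed seed, from a
synthetic corpus of helices, strands, turns and random coils at three noise
levels (`scripts/build_default_library.py`). Letter order follows the
helix / helix-like / strand / strand-like / other category convention —
helix-dominated clusters receive the helix-category letters — purely for
readability; nothing downstream depends on which letter names which shape.
Any library with the same JSON schema (letters, 5×3 templates, frequencies)
can be loaded in its place, and `k` is a free parameter of
`learn_prototypes` even though 23 is the canonical size.

**Substitution matrix.** Scores are Gaussian-kernel log-odds over
template–template RMSD *d*ᵢⱼ, rounded to integers in units of `scale` bits
(default half-bits):

    s(i,j) = round( log2( exp(−dᵢⱼ² / 2σ²) / √(fᵢ fⱼ) ) / scale )

The symmetric √(fᵢfⱼ) background keeps the matrix symmetric for non-uniform
frequencies (for uniform frequencies it reduces to the plain 1/fⱼ odds).
Frequencies are floored at 1e-4 and renormalised so unused letters stay
finite; scores are floored at −64 half-bits; off-diagonal entries are capped
at min(s(i,i), s(j,j)), which preserves symmetry and enforces row-wise
diagonal dominance. Karlin–Altschul theory requires a strictly negative
expected background score, and for a 23-letter alphabet the diagonal's
log₂(23) bonus can defeat that at large σ: σ therefore defaults to the
median pairwise template RMSD and shrinks geometrically (×0.7) until the
expectation is negative. An explicitly supplied σ that fails calibration
raises `CalibrationError` instead of being silently adjusted. Gap penalties
default to open 11 / extend 1, the standard protein-search convention in
half-bit units.

## Feature graph

Each residue becomes a node at its CA atom, with directed edges to its
k = 32 nearest CA neighbours (k clamps to *L* − 1; distances are quantized
to 1e-6 Å before sorting so neighbour order is stable under rigid-motion
round-off, with residual ties broken by residue index; edges are not
symmetrized). Node scalars are sin/cos of φ and ψ plus a 21-way residue
one-hot; ω is deliberately excluded. CA-only traces fall back to
pseudo-torsions over four consecutive CA atoms, so search works on
backbone-sparse files. Node vectors are unit directions to the previous and
next CA, the previous and own C, and CB; anything undefined (termini,
breaks, missing atoms, glycine CB) is a zero vector with mask 0. Edge
features are the unit edge direction, a 16-centre Gaussian RBF expansion of
the CA–CA distance on [0, 20] Å with σ equal to the centre spacing, and a
16-dimensional sinusoidal encoding of the signed sequence offset. The RBF
grid, positional dimensionality and torsion handling at termini are not
constrained by the underlying method description; the defaults above are the
common practice in geometric protein networks and are all configurable.

## Encoder–decoder

The network is implemented in NumPy. Node state is split into scalar
channels (rotation-invariant) and 3-vector channels (rotation-equivariant),
GVP-style: messages are built only from invariants (neighbour scalars, edge
scalars, vector-channel norms, vector·edge-direction products), and vector
channels are updated only by channel mixing, invariant sigmoid gates and
edge directions scaled by invariants — so invariance/equivariance holds by
construction, not by training, and is verified to 1e-4 (observed at machine
precision).

The trunk (2 message-passing layers, 64 scalar / 16 vector channels) is
drawn once from the model seed and kept frozen — a random-features design;
the trainable part is the two decoder heads: a 23-way SA classifier over
concatenated 5-window embeddings and an 8-way per-residue secondary-
structure classifier, each a one-hidden-layer ReLU network trained with Adam
(lr 1e-3, batch 8 chains) on the summed mean negative log-likelihoods of the
two heads, equally weighted. Final-layer weights start at zero, so an
untrained model predicts the uniform distribution exactly. Early stopping
watches validation accuracy (mean of the SA and SS accuracies, 15%
validation split): training stops when it has not improved by more than
1e-4 for more than `patience` epochs (default 5), and the best-validation
parameters are restored. Per-residue embeddings are the trunk's scalar
channels (width 64). This head-only training keeps the full cycle at a few
seconds on one CPU while exceeding 5× chance on held-out synthetic SA labels
by a wide margin; full trunk backpropagation would be the natural extension
if harder label sets demanded it.

**Labels.** SA labels come from the geometric nearest-prototype oracle
(`encode_geometric`) — the documented labelling convention of this package.
Secondary-structure labels come from the generator's ground truth for
synthetic chains; real chains fall back to an internal φ/ψ + CA-contact
heuristic over the 8-letter alphabet `HGIEBTSC` (only H, E, T and C are ever
emitted; the remaining classes are reserved). Identity metrics always
compare like with like: ground truth on both sides if both chains carry it,
the heuristic on both sides otherwise.

## Search statistics

λ is found by bisection (to 1e-12) on Σᵢⱼ pᵢpⱼ e^(λsᵢⱼ) = 1; K by the
standard convolution series for integer lattice scores, truncated at 1e-6
relative change; both raise `CalibrationError` when the expected score is
non-negative or no positive score exists. E = K·m·n·e^(−λS) uses the query
length m and total database length n with no edge-effect correction — the
sequences here are short and the omission is conservative in the direction
of reporting slightly larger search spaces.

Two deliberate choices:

- **Background frequencies.** E-values are computed under the substitution
  matrix's own background (the library frequencies), not the observed
  database composition: a small or single-fold database (e.g. all helices)
  can be so skewed that its observed-frequency expected score turns
  non-negative and the statistics become undefined. The database's observed
  frequencies are still recorded on the `SearchDatabase`.
- **Ungapped constants for gapped scores.** As in classic practice when no
  empirical gapped fit is available, the ungapped (λ, K) are applied to
  gapped alignment scores. Gapped optima run slightly higher than ungapped
  theory assumes, so E-values are mildly anti-conservative; the calibration
  test bounds the excess with a generous constant rather than pretending
  the approximation is exact.

**Seeding.** 3-letter words with a score-≥11 neighbourhood (computed against
the database's observed word vocabulary, which is equivalent to and cheaper
than enumerating all 23³ words), per-diagonal x-drop ungapped extension
(x-drop 15), then banded affine-gap Smith–Waterman (half-width 16) around
the best ≤8 distinct diagonals per record, keeping the best alignment per
record. A banded score can never exceed the exhaustive Smith–Waterman
optimum, which the tests verify directly. Queries shorter than one word fall
back to aligning against every record. Traceback preference is diagonal >
gap-in-subject > gap-in-query, and the best cell is the smallest (i, j)
among maxima, so alignments are fully deterministic.

## Refinement and reporting

The single coordinate convention that fixes all reported loci: SA position
*i* covers residues [*i*, *i*+5), so an alignment spanning windows [a, b)
spans residues [a, b+4). RMSD is computed over the CA atoms of aligned
(non-gap) columns only — one residue pair per aligned window column plus the
4-residue footprint of the final column; gapped columns contribute no atom
pairs. Computing RMSD over the full overlapped chains instead is a
documented alternative a caller can get by superposing `location` spans
directly. Identities use the same residue footprint, with gaps excluded from
numerator and denominator.

Embedding localization scans every offset of the query's embedding rows
along the subject and takes the minimal mean Euclidean row distance
(equivalently, the best diagonal of the full pairwise distance matrix); ties
take the smallest offset. It runs only for fragment queries (alignment not
covering the subject end-to-end) under the neural encoder, where embeddings
exist.

Hits are ordered by (E-value, RMSD, subject id) — the search layer's
(E-value, subject id) rule plus an RMSD tie-break, because synthetic
databases legitimately contain near-duplicate geometries whose E-values tie
exactly, and among equally significant hits the better superposition should
lead. Kabsch superposition corrects reflections via the determinant sign and
flags rank-deficient (e.g. collinear) inputs as degenerate rather than
failing.

## Synthetic data: what it does and does not show

The generator emulates the geometric regimes the encoder must separate:
ideal α-helices (rise 1.5 Å, twist 100°, radius 2.3 Å — canonical values,
stated as fixture conventions), pleated strands (3.8 Å CA–CA, 3.46 Å axial
rise), tight circular-arc turns, and correlated-random-walk coils with a
fixed 3.8 Å step. N, C and CB atoms are placed by an idealised local-frame
construction that yields finite, consistent dihedrals but does not claim
chemically exact peptide geometry. Noise is isotropic Gaussian on the CA
trace before backbone placement; every output is a pure function of its spec
(seed included).

Consequences for interpreting green tests: passing the self-search,
planted-fragment and clustering suites shows the machinery is correct —
encoding is rigid-motion invariant, alignment is optimal, statistics are
calibrated against their own model, loci map back exactly. It does not show
that 23 letters optimally quantize *real* loop space, nor how the encoder
degrades on experimental artefacts (missing atoms beyond CA, altlocs,
crystal contacts), nor PDB-scale retrieval accuracy. Ideal helices and
strands are translationally self-similar, so fragment loci within them are
intrinsically degenerate; locus-recovery rates are therefore measured on
coil cuts, where the question is well-posed.

Desk-scale problem sizes used throughout (the package's own choice of scale):
50-chain databases, 100-trial recovery experiments, 120-chain training
corpora, 30-chain held-out sets.

## Corpus handling

Chains are filtered at <16 residues and >3.5 Å resolution; structures
without a resolution record (NMR, predicted models) are retained, since the
filter targets crystallographic quality. A chain break is declared at a gap
in author numbering or a CA–CA step above 4.5 Å; fragment windows and
torsions never span one. Altlocs keep the highest-occupancy conformer;
MSE is read as MET; other HETATM records are ignored. Dataset splits use
largest-remainder rounding with ties resolved in (training, test,
validation) order, which reproduces exact set sizes such as
53,064 / 26,532 / 8,844 from 88,440 at (0.6, 0.3, 0.1).

## Known limitations

- E-values inherit the ungapped-statistics approximation described above and
  carry no edge-effect or composition-based correction.
- The secondary-structure heuristic is a coarse φ/ψ rule, not a
  hydrogen-bond assignment; it exists to make identity metrics computable
  without an external program.
- The neural path trains only the decoder heads; embeddings are
  random-feature projections of geometry rather than task-tuned
  representations.
- mmCIF ingestion, biological-assembly expansion and profile/PSSM search are
  out of scope.
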