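"""Build the default 23-letter prototype library shipped as package data.

Learns the library once, with a fixed seed, from a mixed synthetic corpus of
helices, strands, turns and random coils at several noise levels, then orders
the clusters so that helix-dominated letters come first (matching the
helix / helix-like / strand / strand-like / other letter categories) and
writes ``src/safold/data/default_library.json``.

Run from the repository root:  python scripts/build_default_library.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from safold.alphabet import LETTERS, PrototypeLibrary, fragment_windows, learn_prototypes
from safold.fixtures import GeneratorSpec, generate_corpus
from safold.geometry import pairwise_rmsd

SEED = 20230922
OUT = Path(__file__).resolve().parents[1] / "src" / "safold" / "data" / "default_library.json"


def main() -> None:
    specs = []
    for noise in (0.0, 0.15, 0.3):
        specs += [
            GeneratorSpec(kind="helix", length=30, noise_sigma=noise),
            GeneratorSpec(kind="strand", length=24, noise_sigma=noise),
            GeneratorSpec(kind="turnlib", length=18, noise_sigma=noise),
            GeneratorSpec(kind="random", length=40, noise_sigma=noise),
            GeneratorSpec(kind="random", length=40, noise_sigma=noise),
        ]
    chains = generate_corpus(150, specs, seed=SEED)
    fragments = [f for c in chains for f in fragment_windows(c)]
    print(f"corpus: {len(chains)} chains, {len(fragments)} fragments")

    lib = learn_prototypes(fragments, k=23, seed=SEED, max_iter=100, max_fragments=1500)
    print(f"k-medoids objective: {lib.objective_history[0]:.1f} -> {lib.objective_history[-1]:.1f}"
          f" in {len(lib.objective_history)} iterations")

    # order clusters: helix-like first (small RMSD to the ideal helix window),
    # then strand-like, then the rest by decreasing frequency
    helix = generate_corpus(1, [GeneratorSpec(kind="helix", length=9)], seed=0)[0]
    strand = generate_corpus(1, [GeneratorSpec(kind="strand", length=9)], seed=0)[0]
    h_tpl = fragment_windows(helix)[2].coords
    e_tpl = fragment_windows(strand)[2].coords
    d_h = pairwise_rmsd(lib.templates, h_tpl[None] - h_tpl.mean(0))[:, 0]
    d_e = pairwise_rmsd(lib.templates, e_tpl[None] - e_tpl.mean(0))[:, 0]

    category = np.where(d_h < 0.5, 0, np.where(d_e < 0.7, 2, 4))
    order = sorted(range(23), key=lambda i: (category[i], -lib.frequencies[i], float(d_h[i])))
    lib = PrototypeLibrary(
        letters=LETTERS,
        templates=lib.templates[order],
        frequencies=lib.frequencies[order],
    )
    for i, c in enumerate(LETTERS):
        print(f"  {c}: freq={lib.frequencies[i]:.4f} d_helix={d_h[order[i]]:.2f} "
              f"d_strand={d_e[order[i]]:.2f}")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    from safold.alphabet import save_library

    save_library(lib, str(OUT))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
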