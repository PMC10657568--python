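#!/usr/bin/env python
"""Generate the synthetic study: a labelled landmark dataset shaped like a
replicated ant-head digitization study (8 species, 2 sites, 2 replicates)
and a 108-sequence barcode alignment with five ingroup units and three deep
outgroups.  Writes TPS + sliders + labels and FASTA + labels under
results/synthetic_study/data/.
"""

from pathlib import Path

import numpy as np

from cryptomorph import (
    SeqSimSpec,
    ShapeSimSpec,
    head_like_sliders,
    head_like_template,
    simulate_sequences,
    simulate_shapes,
    write_fasta,
    write_sliders,
    write_tps,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_study" / "data"

GROUPS = ["jspA", "jspB", "jspC", "jspD", "jspE", "out1", "out2", "out3"]
SPLIT_HEIGHTS = {
    frozenset(["jspC", "jspD"]): 0.042,
    frozenset(["jspC", "jspD", "jspE"]): 0.050,
    frozenset(["jspB", "jspC", "jspD", "jspE"]): 0.058,
    frozenset(["jspA", "jspB", "jspC", "jspD", "jspE"]): 0.106,
    frozenset(GROUPS[:6]): 0.189,
    frozenset(GROUPS[:7]): 0.200,
    frozenset(GROUPS): 0.220,
}
WITHIN = 0.008
SIZES = [2, 1, 20, 15, 50, 10, 5, 5]  # 108 sequences total


def divergence_matrix() -> np.ndarray:
    g = len(GROUPS)
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            for clade in sorted(SPLIT_HEIGHTS, key=len):
                if GROUPS[i] in clade and GROUPS[j] in clade:
                    # split heights are minimum between-group distances;
                    # the generator targets means, one within-rate higher
                    D[i, j] = D[j, i] = SPLIT_HEIGHTS[clade] + WITHIN
                    break
    return D


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    spec = ShapeSimSpec(
        template=head_like_template(),
        n_species=8,
        n_sites=2,
        n_specimens=8,
        n_replicates=2,
        species_effect_scale=0.05,
        site_effect_scale=0.015,
        sigma=0.01,
        sigma_rep=0.003,
        seed=SEED,
    )
    ds = simulate_shapes(spec)
    write_tps(ds, DATA / "head.tps")
    write_sliders(head_like_sliders(), DATA / "head_sliders.txt")
    ds.labels.to_csv(DATA / "head_labels.csv")
    print(f"shapes: {ds.n} configurations x {ds.k} landmarks "
          f"({spec.n_species} species, {spec.n_sites} sites, "
          f"{spec.n_replicates} replicates)")

    seqs, labels = simulate_sequences(
        SeqSimSpec(
            divergence=divergence_matrix(),
            sizes=SIZES,
            within=WITHIN,
            seed=SEED,
            group_names=GROUPS,
        )
    )
    write_fasta(seqs, DATA / "barcodes.fasta")
    labels.to_csv(DATA / "barcode_labels.csv")
    print(f"barcodes: {seqs.n} aligned sequences of {seqs.length} bp, "
          f"{len(GROUPS)} planted units (splits 4.2%..22%)")


if __name__ == "__main__":
    main()
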