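"""Candidate gene triangulation on synthetic multi-omic evidence.

Simulates two mouse differential-expression comparisons, a human
copy-number cohort and a mutation catalog with planted overlaps, then
runs the full selection: paired DE (p < 0.01, FC > 1.5), amplification
recurrence (>= 1.5x in >= 5% of samples), validated-missense rescue,
and the final set triangulation.
"""

from pathlib import Path

import pandas as pd

from metscreen.candidates import (
    amplification_recurrence_filter,
    amplified_mutated_intersect,
    paired_differential_expression,
    passing_genes,
    triangulate,
)
from metscreen.simulate import simulate_cna_mutations, simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results" / "candidates"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    up_sets = []
    for i, sub_seed in enumerate((SEED, SEED + 1)):
        mat, pairs, truth = simulate_expression(
            n_genes=500, n_per_group=4, planted_log2_fold=1.5, n_planted=80,
            noise_sd_log2=0.3, paired=True, seed=sub_seed,
        )
        de = paired_differential_expression(mat, pairs, p_threshold=0.01, fc_threshold=1.5)
        de.to_csv(OUT / f"de_comparison_{i + 1}.tsv", sep="\t", index=False)
        up = passing_genes(de, "up")
        up_sets.append(up)
        print(f"comparison {i + 1}: {len(up)} genes up-regulated "
              f"(p<0.01, FC>1.5) of {len(truth.loc[truth.is_planted])} planted")

    cna, muts, cna_truth = simulate_cna_mutations(
        n_genes=500, n_samples=154, n_amp_genes=60, amp_fraction=0.05,
        n_mut_genes=15, seed=SEED,
    )
    amplified = amplification_recurrence_filter(cna, fold_threshold=1.5, min_fraction=0.05)
    amp_mut = amplified_mutated_intersect(amplified, muts)
    print(f"amplified >=1.5x in >=5% of {cna.shape[1]} samples: {len(amplified)} genes")
    print(f"amplified with validated missense mutation: {len(amp_mut)} genes")

    candidates = triangulate(up_sets[0], up_sets[1], amplified, amp_mut)
    candidates.to_csv(OUT / "candidate_genes.tsv", sep="\t", index=False)
    core = candidates[candidates["amplified"]]
    print(f"triangulated candidates: {len(candidates)} "
          f"({len(core)} via DE+amplification, "
          f"{int(candidates['amplified_and_mutated'].sum())} via mutation rescue)")


if __name__ == "__main__":
    main()
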