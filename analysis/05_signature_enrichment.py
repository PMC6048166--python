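"""Differential expression and gene-set over-representation on synthetic data.

Simulates an induced-oncogene expression experiment with a planted
up-regulated program, runs the homoscedastic DE filter (FC > 1.5,
p < 0.01) with Grubbs outlier pre-filtering, and tests a small GMT
collection for over-representation of the significant genes.
"""

from pathlib import Path

import pandas as pd

from metscreen.signatures import de_with_fold_change, overrepresentation, write_gmt
from metscreen.simulate import simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results" / "signatures"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mat, design, truth = simulate_expression(
        n_genes=2_000, n_per_group=4, planted_log2_fold=1.2, n_planted=150,
        noise_sd_log2=0.3, seed=SEED,
    )
    groups = dict(zip(design["sample_id"], design["group"]))
    de = de_with_fold_change(mat, groups, "g1", "g2", grubbs=True)
    de.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    sig = set(de.loc[de["passes"], "gene_id"])
    planted = set(truth.loc[truth["is_planted"], "gene_id"])
    print(f"significant genes (FC>1.5, p<0.01): {len(sig)}; "
          f"planted program: {len(planted)}")

    universe = set(mat.index)
    sets = {
        "planted_program": planted,
        "random_set_a": set(truth["gene_id"].sample(150, random_state=1)),
        "random_set_b": set(truth["gene_id"].sample(80, random_state=2)),
    }
    write_gmt(sets, OUT / "sets.gmt")
    enr = overrepresentation(sig, universe, sets)
    enr.to_csv(OUT / "overrepresentation.tsv", sep="\t", index=False)
    print(enr.to_string(index=False))


if __name__ == "__main__":
    main()
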