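"""Simulate the pooled in vivo screen at study scale and write its tables.

Generates a 218-clone screen (12 pools of <= 20 clones incl. a shared
control, 10 mice per pool, quadruplicate input, triplicate SQ cores,
Poisson metastasis burden) with planted growth and metastasis drivers,
and writes the design, truth and count tables under results/screen/.
"""

from pathlib import Path

from metscreen.simulate import SimulationConfig, simulate_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    screen = simulate_screen(SimulationConfig(seed=SEED))
    screen.library.to_tsv(OUT / "barcode_library.tsv")
    screen.design.to_tsv(OUT / "sample_sheet.tsv", OUT / "pools.tsv")
    screen.counts.counts.to_csv(OUT / "counts.tsv", sep="\t")
    screen.truth_orfs.to_csv(OUT / "truth_orfs.tsv", sep="\t", index=False)

    n_samples = screen.counts.counts.shape[0]
    n_mets = (screen.design.samples["tissue"] == "lung_met").sum()
    print(f"simulated screen: {len(screen.library)} clones, "
          f"{len(screen.design.pools)} pools, {len(screen.design.mice)} mice")
    print(f"{n_samples} sequenced samples ({n_mets} metastasis lesions)")
    print(f"planted drivers: {len(screen.sq_driver_set())} SQ-fitness, "
          f"{len(screen.met_driver_set())} metastasis")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
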