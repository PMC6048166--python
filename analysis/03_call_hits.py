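"""Score the simulated screen: abundances, enrichment, SQ and metastasis hits.

Reproduces the screen's hit-calling logic end to end and reports the
recovery of the planted metastasis drivers.
"""

from pathlib import Path

import pandas as pd

from metscreen.evaluation import sensitivity_fdp
from metscreen.screen import (
    call_met_hits,
    call_sq_hits,
    classify_hits,
    enrichment_table,
    relative_abundance,
)
from metscreen.simulate import SimulationConfig, simulate_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "hits"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    screen = simulate_screen(SimulationConfig(seed=SEED))
    abundance, failed = relative_abundance(screen.counts.counts)
    enr = enrichment_table(abundance, screen.design, detection_floor=0.01)
    sq = call_sq_hits(enr, screen.design, fold_threshold=100.0)
    met = call_met_hits(enr, screen.design, min_met_samples=2, min_mice=2)
    combined = classify_hits(sq, met)

    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    sq.to_csv(OUT / "sq_hits.tsv", sep="\t", index=False)
    met.to_csv(OUT / "met_hits.tsv", sep="\t", index=False)
    combined.to_csv(OUT / "hit_classes.tsv", sep="\t", index=False)

    met_called = set(met.loc[met["is_hit"], "orf_id"])
    sens, fdp = sensitivity_fdp(met_called, screen.met_driver_set())
    print(f"failed samples: {len(failed)}")
    print(f"SQ hits (>=100x in >=1 mouse): {int(sq['is_hit'].sum())}")
    print(f"met hits (>=2 samples, >=2 mice): {len(met_called)} "
          f"of {len(screen.met_driver_set())} planted drivers")
    print(f"met-driver recovery: sensitivity {sens:.3f}, FDP {fdp:.3f}")
    print(combined["hit_class"].value_counts().to_string())


if __name__ == "__main__":
    main()
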