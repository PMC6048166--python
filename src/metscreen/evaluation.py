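"""Reference implementations and truth-based performance evaluation.

``exhaustive_scan_reference`` is a deliberately simple pure-Python
read x barcode x offset Hamming scan used as an independent cross-check
of the vectorized deconvolution path. ``met_hit_performance`` scores a
hit caller against a simulated screen's planted truth.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .barcodes import BarcodeCounts, BarcodeLibrary
from .screen import (
    ScreenDesign,
    call_met_hits,
    enrichment_table,
    relative_abundance,
)
from .simulate import SimulatedScreen

__all__ = [
    "exhaustive_scan_reference",
    "sensitivity_fdp",
    "met_hits_from_counts",
    "met_hit_performance",
]


def _hamming_capped(a: str, b: str, cap: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return d
    return d


def exhaustive_scan_reference(
    reads: Iterable[str],
    library: BarcodeLibrary,
    max_mismatch: int = 1,
    search_window: tuple[int, int] | None = None,
) -> BarcodeCounts:
    """Assign reads by brute force over every read x barcode x offset triple.

    Semantics match the production counter: a read is assigned to the
    single barcode attaining the global minimum distance when that
    minimum is within ``max_mismatch``; ties between distinct barcodes
    are ambiguous; everything else is unassigned.
    """
    L = library.length
    counts = {orf: 0 for orf in library.orf_ids}
    unassigned = ambiguous = total = 0
    entries = list(zip(library.orf_ids, library.barcodes))
    for read in reads:
        total += 1
        n_off = len(read) - L + 1
        if n_off <= 0:
            unassigned += 1
            continue
        lo, hi = 0, n_off
        if search_window is not None:
            lo, hi = max(0, search_window[0]), min(n_off, search_window[1])
        if lo >= hi:
            unassigned += 1
            continue
        best = L + 1
        best_orfs: set[str] = set()
        for orf, bc in entries:
            for off in range(lo, hi):
                d = _hamming_capped(read[off : off + L], bc, best)
                if d < best:
                    best = d
                    best_orfs = {orf}
                elif d == best:
                    best_orfs.add(orf)
        if best > max_mismatch:
            unassigned += 1
        elif len(best_orfs) > 1:
            ambiguous += 1
        else:
            counts[next(iter(best_orfs))] += 1
    return BarcodeCounts(
        counts=pd.Series(counts, name="count").reindex(library.orf_ids),
        unassigned=unassigned,
        ambiguous=ambiguous,
        total=total,
    )


def sensitivity_fdp(called: Iterable[str], truth: Iterable[str]) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of a called set vs truth.

    Sensitivity = |called & truth| / |truth|; FDP = |called - truth| /
    |called| (0 when nothing is called).
    """
    called, truth = set(called), set(truth)
    sens = len(called & truth) / len(truth) if truth else float("nan")
    fdp = len(called - truth) / len(called) if called else 0.0
    return sens, fdp


def met_hits_from_counts(
    counts: pd.DataFrame,
    design: ScreenDesign,
    detection_floor: float = 0.01,
    min_met_samples: int = 2,
    min_mice: int = 2,
    enrichment_floor: float = 1.0,
) -> set[str]:
    """Counts -> abundance -> enrichment -> metastasis hit set."""
    abundance, _ = relative_abundance(counts)
    enr = enrichment_table(abundance, design, detection_floor=detection_floor)
    hits = call_met_hits(
        enr,
        design,
        min_met_samples=min_met_samples,
        min_mice=min_mice,
        enrichment_floor=enrichment_floor,
    )
    if hits.empty:
        return set()
    return set(hits.loc[hits["is_hit"], "orf_id"])


def met_hit_performance(screen: SimulatedScreen, **hit_kwargs) -> tuple[float, float]:
    """Sensitivity and FDP of the metastasis hit rule on a simulated screen."""
    called = met_hits_from_counts(screen.counts.counts, screen.design, **hit_kwargs)
    return sensitivity_fdp(called, screen.met_driver_set())
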