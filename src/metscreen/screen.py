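"""Pooled in vivo screen scoring: abundances, enrichment and hit calling.

The screen layout is pools of barcoded clones injected into cohorts of
mice. Sequenced samples are the pre-injection *input* (pool-level
replicates), subcutaneous (SQ) tumor cores, and metastasis lesions.
Scoring follows the enrichment-ratio logic: a clone's relative abundance
in each sample (count / total library counts) divided by its aggregated
input abundance. Hit rules:

* **SQ hit** — enrichment over input of at least ``fold_threshold``
  (default 100x) in at least one SQ sample of at least one mouse; the
  %-positive-mice summary is computed over mice with more than
  ``min_samples_per_mouse`` analyzable SQ samples.
* **Metastasis hit** — positive enrichment (ratio above
  ``enrichment_floor`` and abundance above the detection floor) in at
  least ``min_met_samples`` metastasis samples spanning at least
  ``min_mice`` mice of one pool cohort (defaults 2 and 2).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import BarcodeCounts

TISSUES = ("input", "sq_tumor", "lung_met", "other_met")
MET_TISSUES = ("lung_met", "other_met")

__all__ = [
    "ScreenDesign",
    "ScreenCounts",
    "relative_abundance",
    "aggregate_replicates",
    "pool_input_profile",
    "enrichment_table",
    "call_sq_hits",
    "call_met_hits",
    "classify_hits",
]


@dataclass
class ScreenDesign:
    """Pools, mice and samples of a pooled screen.

    ``samples`` columns: sample_id, pool_id, mouse_id (empty for
    pool-level input samples), tissue (one of ``TISSUES``), replicate.
    """

    pools: dict[str, set[str]]  # pool_id -> orf_ids
    mice: dict[str, str]  # mouse_id -> pool_id
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "pool_id", "mouse_id", "tissue", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
        bad = set(self.samples["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels {sorted(bad)}; expected {TISSUES}")
        for _, row in self.samples.iterrows():
            if row["tissue"] == "input":
                if not pd.isna(row["mouse_id"]) and row["mouse_id"] != "":
                    raise ValueError(f"input sample {row['sample_id']} must be pool-level")
            else:
                mouse = row["mouse_id"]
                if mouse not in self.mice:
                    raise ValueError(f"sample {row['sample_id']}: unknown mouse {mouse!r}")
                if self.mice[mouse] != row["pool_id"]:
                    raise ValueError(
                        f"sample {row['sample_id']}: mouse {mouse} belongs to pool "
                        f"{self.mice[mouse]}, not {row['pool_id']}"
                    )

    def pool_of_sample(self, sample_id: str) -> str:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["pool_id"].iloc[0])

    def input_samples(self, pool_id: str) -> list[str]:
        sel = (self.samples["tissue"] == "input") & (self.samples["pool_id"] == pool_id)
        return self.samples.loc[sel, "sample_id"].tolist()

    def tissue_samples(self, tissues: tuple[str, ...]) -> pd.DataFrame:
        return self.samples[self.samples["tissue"].isin(tissues)].copy()

    def to_tsv(self, sample_sheet: str | Path, pool_table: str | Path) -> None:
        self.samples.to_csv(sample_sheet, sep="\t", index=False)
        rows = [
            {"pool_id": p, "orf_id": o} for p, orfs in self.pools.items() for o in sorted(orfs)
        ]
        pd.DataFrame(rows).to_csv(pool_table, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, sample_sheet: str | Path, pool_table: str | Path) -> "ScreenDesign":
        samples = pd.read_csv(sample_sheet, sep="\t", dtype={"mouse_id": str}, keep_default_na=False)
        samples["mouse_id"] = samples["mouse_id"].replace("", np.nan)
        pool_df = pd.read_csv(pool_table, sep="\t")
        pools: dict[str, set[str]] = {}
        for p, orf in zip(pool_df["pool_id"], pool_df["orf_id"]):
            pools.setdefault(str(p), set()).add(str(orf))
        mice: dict[str, str] = {}
        for _, row in samples.iterrows():
            if row["tissue"] != "input" and not pd.isna(row["mouse_id"]):
                mice[str(row["mouse_id"])] = str(row["pool_id"])
        return cls(pools=pools, mice=mice, samples=samples)


@dataclass
class ScreenCounts:
    """Sample x ORF count matrix plus per-sample read bookkeeping."""

    counts: pd.DataFrame  # index sample_id, columns orf_id
    qc: pd.DataFrame = field(default=None)  # assigned/unassigned/ambiguous/total

    @classmethod
    def from_rows(cls, rows: Mapping[str, BarcodeCounts]) -> "ScreenCounts":
        counts = pd.DataFrame({s: bc.counts for s, bc in rows.items()}).T
        counts.index.name = "sample_id"
        qc = pd.DataFrame(
            {
                s: {
                    "assigned": bc.assigned,
                    "unassigned": bc.unassigned,
                    "ambiguous": bc.ambiguous,
                    "total": bc.total,
                }
                for s, bc in rows.items()
            }
        ).T
        qc.index.name = "sample_id"
        return cls(counts=counts, qc=qc)


def relative_abundance(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalize counts to relative abundances.

    Abundance is each barcode's count divided by the total library
    barcode count in that sample (no pseudocount). Samples with zero
    assigned reads are flagged failed and excluded; their ids are
    returned alongside.
    """
    totals = counts.sum(axis=1)
    failed = totals[totals == 0].index.tolist()
    if failed:
        warnings.warn(f"samples with zero assigned reads excluded: {failed}", stacklevel=2)
    ok = counts.loc[totals > 0]
    abund = ok.div(ok.sum(axis=1), axis=0)
    return abund, failed


def aggregate_replicates(
    abundance: pd.DataFrame, grouping: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Arithmetic mean and sample SD of abundance profiles per replicate group.

    Groups of size one get SD marked unavailable (NaN). Samples missing
    from ``grouping`` are ignored.
    """
    labels = pd.Series({s: grouping[s] for s in abundance.index if s in grouping})
    sub = abundance.loc[labels.index]
    mean = sub.groupby(labels).mean()
    sd = sub.groupby(labels).std(ddof=1)
    n = labels.groupby(labels).size()
    sd.loc[n[n < 2].index] = np.nan
    return mean, sd, n


def pool_input_profile(
    abundance: pd.DataFrame, design: ScreenDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-aggregated (mean, SD) input abundance per pool."""
    grouping = {}
    for pool in design.pools:
        for s in design.input_samples(pool):
            if s in abundance.index:
                grouping[s] = pool
    if not grouping:
        raise ValueError("no input samples present in the abundance table")
    mean, sd, _ = aggregate_replicates(abundance, grouping)
    return mean, sd


def enrichment_table(
    abundance: pd.DataFrame,
    design: ScreenDesign,
    detection_floor: float = 0.01,
) -> pd.DataFrame:
    """Long-format per-(sample, ORF) enrichment over aggregated pool input.

    Restricted to each sample's pool members. ORFs with zero input
    abundance are flagged ``dropout`` and carry no numeric ratio (NaN),
    never infinity. ``detected`` marks sample abundance at or above the
    detection floor.
    """
    input_mean, _ = pool_input_profile(abundance, design)
    rows = []
    meta = design.samples.set_index("sample_id")
    for sample in abundance.index:
        if sample not in meta.index:
            continue
        tissue = meta.loc[sample, "tissue"]
        if tissue == "input":
            continue
        pool = str(meta.loc[sample, "pool_id"])
        mouse = meta.loc[sample, "mouse_id"]
        pool_orfs = sorted(design.pools[pool] & set(abundance.columns))
        dropped = design.pools[pool] - set(abundance.columns)
        if dropped:
            warnings.warn(
                f"pool {pool}: ORFs absent from abundance table excluded: {sorted(dropped)[:5]}",
                stacklevel=2,
            )
        ab = abundance.loc[sample, pool_orfs]
        inp = input_mean.loc[pool, pool_orfs]
        for orf in pool_orfs:
            i = float(inp[orf])
            a = float(ab[orf])
            dropout = i == 0.0
            rows.append(
                {
                    "sample_id": sample,
                    "pool_id": pool,
                    "mouse_id": mouse,
                    "tissue": tissue,
                    "orf_id": orf,
                    "abundance": a,
                    "input_abundance": i,
                    "enrichment": np.nan if dropout else a / i,
                    "detected": a >= detection_floor,
                    "dropout": dropout,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "pool_id",
            "mouse_id",
            "tissue",
            "orf_id",
            "abundance",
            "input_abundance",
            "enrichment",
            "detected",
            "dropout",
        ],
    )


_SQ_RULE_NOTE = (
    "mouse positive if any SQ sample enrichment >= fold_threshold; hit if >=1 positive "
    "mouse; % positive mice over mice with > min_samples_per_mouse analyzable SQ samples"
)


def call_sq_hits(
    enrichments: pd.DataFrame,
    design: ScreenDesign,
    fold_threshold: float = 100.0,
    min_samples_per_mouse: int = 2,
) -> pd.DataFrame:
    """Subcutaneous-growth hits from the enrichment table.

    A mouse is positive for an ORF when any of its SQ samples shows
    enrichment >= ``fold_threshold`` (inclusive at the edge); an ORF is
    an SQ hit when positive in at least one mouse. The percentage of
    positive mice is reported over mice with more than
    ``min_samples_per_mouse`` analyzable SQ samples. The rule text is
    attached as frame metadata for auditability.
    """
    sq = enrichments[(enrichments["tissue"] == "sq_tumor") & ~enrichments["dropout"]]
    if sq.empty:
        warnings.warn("no SQ tumor samples: returning empty hit table", stacklevel=2)
        out = pd.DataFrame(
            columns=[
                "orf_id",
                "n_positive_samples",
                "n_positive_mice",
                "n_mice_analyzed",
                "pct_positive_mice",
                "mean_enrichment",
                "sd_enrichment",
                "is_hit",
            ]
        )
        out.attrs["rule"] = _SQ_RULE_NOTE
        return out

    positive = sq["enrichment"] >= fold_threshold
    rows = []
    samples_per_mouse = sq.groupby(["orf_id", "mouse_id"])["sample_id"].nunique()
    for orf, grp in sq.groupby("orf_id"):
        pos_mice = set(grp.loc[positive.loc[grp.index], "mouse_id"])
        per_mouse = samples_per_mouse.loc[orf]
        denom_mice = set(per_mouse[per_mouse > min_samples_per_mouse].index)
        pct = 100.0 * len(pos_mice & denom_mice) / len(denom_mice) if denom_mice else np.nan
        enr = grp["enrichment"]
        rows.append(
            {
                "orf_id": orf,
                "n_positive_samples": int(positive.loc[grp.index].sum()),
                "n_positive_mice": len(pos_mice),
                "n_mice_analyzed": len(denom_mice),
                "pct_positive_mice": pct,
                "mean_enrichment": float(enr.mean()),
                "sd_enrichment": float(enr.std(ddof=1)) if len(enr) > 1 else np.nan,
                "is_hit": len(pos_mice) >= 1,
            }
        )
    out = pd.DataFrame(rows).sort_values("orf_id", ignore_index=True)
    out.attrs["rule"] = _SQ_RULE_NOTE
    return out


def call_met_hits(
    enrichments: pd.DataFrame,
    design: ScreenDesign,
    min_met_samples: int = 2,
    min_mice: int = 2,
    enrichment_floor: float = 1.0,
    met_tissues: tuple[str, ...] = MET_TISSUES,
) -> pd.DataFrame:
    """Metastasis hits: positive enrichment in multiple samples across mice.

    An ORF is a metastasis hit when positively enriched (enrichment
    strictly above ``enrichment_floor``, detected above the detection
    floor, not a dropout) in at least ``min_met_samples`` metastasis
    samples spanning at least ``min_mice`` distinct mice within one pool
    cohort.
    """
    met = enrichments[enrichments["tissue"].isin(met_tissues) & ~enrichments["dropout"]]
    rows = []
    if not met.empty:
        positive = (met["enrichment"] > enrichment_floor) & met["detected"]
        pos = met[positive]
        for (orf, pool), grp in pos.groupby(["orf_id", "pool_id"]):
            n_samples = grp["sample_id"].nunique()
            n_mice = grp["mouse_id"].nunique()
            rows.append(
                {
                    "orf_id": orf,
                    "pool_id": pool,
                    "n_positive_samples": n_samples,
                    "n_positive_mice": n_mice,
                    "mean_enrichment": float(grp["enrichment"].mean()),
                    "sd_enrichment": (
                        float(grp["enrichment"].std(ddof=1)) if len(grp) > 1 else np.nan
                    ),
                    "is_hit": n_samples >= min_met_samples and n_mice >= min_mice,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "pool_id",
            "n_positive_samples",
            "n_positive_mice",
            "mean_enrichment",
            "sd_enrichment",
            "is_hit",
        ],
    ).sort_values(["orf_id", "pool_id"], ignore_index=True)


def classify_hits(sq_hits: pd.DataFrame, met_hits: pd.DataFrame) -> pd.DataFrame:
    """Set algebra over hit classes: sq-only, met-only, both."""
    sq = set(sq_hits.loc[sq_hits["is_hit"], "orf_id"]) if not sq_hits.empty else set()
    met = set(met_hits.loc[met_hits["is_hit"], "orf_id"]) if not met_hits.empty else set()
    rows = []
    for orf in sorted(sq | met):
        if orf in sq and orf in met:
            cls = "both"
        elif orf in sq:
            cls = "sq"
        else:
            cls = "met"
        rows.append({"orf_id": orf, "hit_class": cls})
    return pd.DataFrame(rows, columns=["orf_id", "hit_class"])
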