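"""Downstream expression/protein statistics and gene-set over-representation.

One statistical engine serves both transcriptome and reverse-phase
protein array (RPPA) readouts: homoscedastic two-sided t-tests on
log-transformed values with a strict fold-change filter, an optional
iterative Grubbs outlier pre-filter per group, and one-sided Fisher
(hypergeometric upper-tail) over-representation of query gene lists in
GMT gene-set collections with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .candidates import unpaired_differential_expression

__all__ = [
    "grubbs_critical_value",
    "grubbs_filter",
    "de_with_fold_change",
    "read_gmt",
    "write_gmt",
    "overrepresentation",
]


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), df=n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Iterable[float],
    alpha: float = 0.05,
    max_removals: int = 1,
) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove the most extreme value while Grubbs rejects.

    Returns the kept values (original order preserved) and the indices
    (into the input) of removed points. At most ``max_removals`` points
    are removed. Samples with n < 3 or zero spread are returned
    unchanged (the latter cannot contain a Grubbs outlier).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        warnings.warn("Grubbs test skipped: fewer than 3 values", stacklevel=2)
        return x, []
    keep = np.arange(x.size)
    removed: list[int] = []
    while len(removed) < max_removals and keep.size >= 3:
        sub = x[keep]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(dev.argmax())
        g = dev[i] / sd
        if g > grubbs_critical_value(keep.size, alpha):
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return x[keep], removed


def de_with_fold_change(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group1: str,
    group2: str,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
    grubbs: bool = False,
    grubbs_alpha: float = 0.05,
    grubbs_min_n: int = 4,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Homoscedastic DE with the standard FC > 1.5 / p < 0.01 filter.

    Delegates to the shared pooled-variance t-test engine. With
    ``grubbs=True`` each gene's per-group values are pre-filtered with a
    single-removal Grubbs test (applied only when the group has at least
    ``grubbs_min_n`` values); genes are then tested gene-by-gene on the
    surviving samples.
    """
    if not grubbs:
        return unpaired_differential_expression(
            expr, groups, group1, group2, p_threshold, fc_threshold, log_offset=log_offset
        )

    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    s1 = [s for s in expr.columns if groups.get(s) == group1]
    s2 = [s for s in expr.columns if groups.get(s) == group2]
    results = []
    for gene in expr.index:
        cols: dict[str, float] = {}
        labels: dict[str, str] = {}
        for grp_label, samples in ((group1, s1), (group2, s2)):
            vals = expr.loc[gene, samples].to_numpy(dtype=float)
            if len(vals) >= grubbs_min_n:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    log_vals = np.log2(vals + log_offset)
                _, removed = grubbs_filter(log_vals, alpha=grubbs_alpha, max_removals=1)
            else:
                removed = []
            for j, s in enumerate(samples):
                if j not in removed:
                    cols[s] = vals[j]
                    labels[s] = grp_label
        row = pd.DataFrame([cols], index=[gene])
        res = unpaired_differential_expression(
            row, labels, group1, group2, p_threshold, fc_threshold, log_offset=log_offset
        )
        results.append(res)
    out = pd.concat(results, ignore_index=True)
    # recompute BH across the full gene list (per-gene calls each saw one p)
    out["fdr_q"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {line_no}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {line_no}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"GMT line {line_no}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *sorted(members)]) + "\n")


def overrepresentation(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each gene set.

    Each set is intersected with the universe before testing; the
    p-value is the hypergeometric upper tail P(X >= overlap) for drawing
    ``len(query)`` genes from the universe. BH FDR is computed across
    all tested sets. A query equal to the whole universe is degenerate
    (every p = 1) and flagged.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValueError(f"query genes missing from universe: {extra[:5]}")
    degenerate = query == universe
    if degenerate:
        warnings.warn("query equals universe: over-representation is degenerate", stacklevel=2)

    M, n_query = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_query))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": M,
                "p_value": min(p, 1.0),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "p_value",
            "degenerate",
        ],
    )
    if not out.empty:
        out["fdr_q"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr_q"] = pd.Series(dtype=float)
    return out.sort_values("p_value", ignore_index=True)
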