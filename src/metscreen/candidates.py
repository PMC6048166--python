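"""Cross-species candidate gene triangulation.

Builds a driver-candidate list by combining differential expression from
mouse metastasis models (paired tumor/metastasis comparisons and a
metastatic-vs-nonmetastatic cell-line comparison) with recurrent somatic
copy-number amplification in human lung adenocarcinoma, plus a rescue
branch of amplified genes carrying validated missense mutations.

All expression tests operate on log2(x + 1)-transformed linear-scale
values. Fold-change filters are strict (``> threshold``); the
amplification recurrence filter is inclusive (``>=``) on both the
copy-ratio and the recurrent-fraction cut-offs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "gene_id",
    "fold_change",
    "log2_fold_change",
    "statistic",
    "p_value",
    "fdr_q",
    "direction",
    "zero_variance",
    "passes",
]


def log2_transform(values: np.ndarray | pd.DataFrame, offset: float = 1.0) -> np.ndarray:
    """log2(x + offset) transform used in front of every expression t-test."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression values must be non-negative on the linear scale")
    return np.log2(arr + offset)


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_ids in expression matrix: {dupes[:5]}")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")


def _finish_de_frame(
    gene_ids: Sequence[str],
    log2_fc: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    zero_var: np.ndarray,
    p_threshold: float,
    fc_threshold: float,
) -> pd.DataFrame:
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    fdr_q = multipletests(p, method="fdr_bh")[1]
    fc = 2.0 ** log2_fc
    passes = (p < p_threshold) & (np.abs(log2_fc) > np.log2(fc_threshold))
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "fold_change": fc,
            "log2_fold_change": log2_fc,
            "statistic": t,
            "p_value": p,
            "fdr_q": fdr_q,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "zero_variance": zero_var,
            "passes": passes,
        },
        columns=DE_COLUMNS,
    )


def paired_differential_expression(
    expr: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Two-sided paired t-test per gene on log2-transformed expression.

    Parameters
    ----------
    expr
        Genes x samples matrix of linear-scale expression (no negatives).
    pairs
        Sequence of ``(reference_sample, test_sample)`` column pairs. The
        reported fold change is the geometric-mean ratio test/reference.
    p_threshold, fc_threshold
        Passing rule: ``p < p_threshold`` and linear fold change strictly
        greater than ``fc_threshold`` in either direction. Defaults mirror
        the screen's selection filter (p < 0.01, FC > 1.5).

    Returns
    -------
    DataFrame with one row per gene: fold change, t statistic, p-value,
    BH q-value (informational; the passing rule uses raw p), direction,
    and a ``zero_variance`` QC flag (p forced to 1, never NaN).
    """
    _validate_expression(expr)
    if len(pairs) < 2:
        raise ValueError("paired design needs at least 2 complete pairs")
    ref = [a for a, _ in pairs]
    test = [b for _, b in pairs]
    if len(set(ref) | set(test)) != 2 * len(pairs):
        raise ValueError("pairing must be bijective: a sample may appear in only one pair")
    missing = [s for s in (*ref, *test) if s not in expr.columns]
    if missing:
        raise ValueError(f"samples not in expression matrix: {missing}")

    log = log2_transform(expr[list(ref) + list(test)].values, log_offset)
    n = len(pairs)
    diffs = log[:, n:] - log[:, :n]  # genes x pairs, test - reference
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    zero_var = sd_d == 0.0

    t = np.full(expr.shape[0], np.nan)
    p = np.ones(expr.shape[0])
    ok = ~zero_var
    t[ok] = mean_d[ok] / (sd_d[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return _finish_de_frame(expr.index, mean_d, t, p, zero_var, p_threshold, fc_threshold)


def unpaired_differential_expression(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group1: str,
    group2: str,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
    equal_variance: bool = True,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Two-sided homoscedastic (pooled-variance) t-test on log2 values.

    ``groups`` maps sample id -> group label; fold change is the
    geometric-mean ratio ``group2 / group1``. Welch's correction is
    available via ``equal_variance=False`` but the default matches the
    homoscedastic test used throughout this pipeline.
    """
    _validate_expression(expr)
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    s1 = [s for s in expr.columns if groups.get(s) == group1]
    s2 = [s for s in expr.columns if groups.get(s) == group2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(
            f"each group needs n >= 2 samples (got {group1}: {len(s1)}, {group2}: {len(s2)})"
        )
    x1 = log2_transform(expr[s1].values, log_offset)
    x2 = log2_transform(expr[s2].values, log_offset)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    mean_d = m2 - m1

    if equal_variance:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, 1.0)

    zero_var = se == 0.0
    t = np.full(expr.shape[0], np.nan)
    p = np.ones(expr.shape[0])
    ok = ~zero_var
    with np.errstate(invalid="ignore", divide="ignore"):
        t[ok] = mean_d[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=np.broadcast_to(df, se.shape)[ok])
    # degenerate: zero variance but unequal means = infinite evidence
    exact = zero_var & (mean_d != 0.0)
    t[exact] = np.sign(mean_d[exact]) * np.inf
    p[exact] = 0.0
    zero_var = zero_var & (mean_d == 0.0)
    return _finish_de_frame(expr.index, mean_d, t, p, zero_var, p_threshold, fc_threshold)


def passing_genes(de: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Gene ids passing the DE filter, optionally restricted to 'up' or 'down'."""
    sel = de["passes"]
    if direction is not None:
        sel = sel & (de["direction"] == direction)
    return set(de.loc[sel, "gene_id"])


def amplification_recurrence_filter(
    cna: pd.DataFrame,
    fold_threshold: float = 1.5,
    min_fraction: float = 0.05,
) -> set[str]:
    """Genes amplified (copy ratio >= fold_threshold) in >= min_fraction of samples.

    ``cna`` is a genes x samples matrix of linear copy-ratio values
    (1.0 = diploid-equivalent). Defaults reproduce the recurrence rule
    "1.5-fold amplification across >=5% of specimens".
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if cna.shape[1] == 0 or cna.shape[0] == 0:
        return set()
    if (cna.values <= 0).any():
        raise ValueError("copy-ratio values must be positive")
    frac = (cna.values >= fold_threshold).mean(axis=1)
    return set(cna.index[frac >= min_fraction])


def amplified_mutated_intersect(
    amplified: Iterable[str],
    mutations: pd.DataFrame,
) -> set[str]:
    """Amplified genes with at least one validated missense mutation record.

    ``mutations`` needs columns ``gene_id``, ``variant_class``, ``validated``.
    """
    amplified = set(amplified)
    if mutations.empty:
        return set()
    hit = mutations[(mutations["variant_class"] == "missense") & mutations["validated"]]
    return amplified & set(hit["gene_id"])


def map_orthologs(genes: Iterable[str], orthology: pd.DataFrame | None) -> set[str]:
    """Map gene ids through an (a_gene, b_gene) orthology table.

    One-to-many mappings expand to every target; genes without a mapping
    are dropped with a logged warning. ``orthology=None`` is the identity.
    """
    genes = set(genes)
    if orthology is None:
        return genes
    if orthology.duplicated().any():
        raise ValueError("orthology table contains duplicate pairs")
    a_col, b_col = orthology.columns[:2]
    lut: dict[str, set[str]] = {}
    for a, b in zip(orthology[a_col], orthology[b_col]):
        lut.setdefault(a, set()).add(b)
    unmapped = sorted(g for g in genes if g not in lut)
    if unmapped:
        logger.warning(
            "%d genes dropped for lack of an orthology mapping (e.g. %s)",
            len(unmapped),
            unmapped[:5],
        )
    mapped: set[str] = set()
    for g in genes:
        mapped |= lut.get(g, set())
    return mapped


def triangulate(
    de_up_a: Iterable[str],
    de_up_b: Iterable[str],
    amplified: Iterable[str],
    amplified_mutated: Iterable[str],
    orthology: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combine the evidence branches into the candidate gene table.

    candidates = (orth(de_up_a) & orth(de_up_b) & amplified) | amplified_mutated

    The two DE sets come from the mouse models and pass through the
    orthology map before intersection with the human amplification set.
    Returns a table with one row per candidate and boolean source flags
    recording which branch(es) contributed.
    """
    a = map_orthologs(de_up_a, orthology)
    b = map_orthologs(de_up_b, orthology)
    amplified = set(amplified)
    amplified_mutated = set(amplified_mutated)
    core = a & b & amplified
    candidates = sorted(core | amplified_mutated)
    rows = []
    for g in candidates:
        rows.append(
            {
                "gene_id": g,
                "de_up_a": g in a and g in core,
                "de_up_b": g in b and g in core,
                "amplified": g in amplified and g in core,
                "amplified_and_mutated": g in amplified_mutated,
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "de_up_a", "de_up_b", "amplified", "amplified_and_mutated"]
    )
    if not out.empty:
        assert out[["de_up_a", "de_up_b", "amplified", "amplified_and_mutated"]].any(axis=1).all()
    return out
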