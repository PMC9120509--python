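"""Rank-based functional enrichment of per-gene "heats".

A heat is any per-locus scalar evidence statistic (association LRT, effect
size, PBS, delta-PBS).  Variants are mapped onto genes within a window,
one heat per gene, and each functional category (e.g. a gene ontology) is
tested with a two-tailed Mann-Whitney U of member heats versus the rest:
categories whose genes rank significantly higher or lower than background
are enriched.  Effect size is the delta-rank (mean rank of members minus
mean rank of non-members); p-values are BH-FDR corrected across
categories.  Because only ranks enter, results are invariant to any
strictly monotone transform of the heats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "map_variants_to_genes",
    "mwu_enrichment",
    "category_heat_test",
    "combine_enrichments",
    "EnrichmentResult",
]

_EXACT_MAX_MEMBERS = 8


def map_variants_to_genes(
    variants: pd.DataFrame,
    gene_table: pd.DataFrame,
    window: int = 2500,
    agg: str = "max",
    heat_col: str = "heat",
) -> pd.Series:
    """Assign variant heats to genes within `window` bp and aggregate.

    `variants` needs columns chrom, pos, `heat_col`; `gene_table` needs
    chrom, start, end, gene_id with 0-based half-open intervals.  A variant
    lands on every gene whose interval, expanded by `window` on both sides,
    contains its position; the per-gene heat is the max (default) or mean
    over its variants.  Variants on chromosomes absent from the gene table
    are skipped with a warning.
    """
    if agg not in ("max", "mean"):
        raise ValueError("agg must be 'max' or 'mean'")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in gene_table.groupby("chrom"):
        tree = IntervalTree()
        for start, end, gid in zip(sub["start"], sub["end"], sub["gene_id"]):
            lo = max(int(start) - window, 0)
            hi = int(end) + window
            tree[lo:hi] = gid
        trees[chrom] = tree

    per_gene: dict[str, list[float]] = {}
    skipped = 0
    for chrom, pos, heat in zip(variants["chrom"], variants["pos"], variants[heat_col]):
        tree = trees.get(chrom)
        if tree is None:
            skipped += 1
            continue
        for iv in tree[int(pos)]:
            per_gene.setdefault(iv.data, []).append(float(heat))
    if skipped:
        warnings.warn(f"{skipped} variants on chromosomes absent from the gene table",
                      stacklevel=2)
    fn = max if agg == "max" else (lambda v: float(np.mean(v)))
    heats = pd.Series({g: fn(v) for g, v in per_gene.items()}, dtype=float)
    heats.index.name = "gene_id"
    heats.name = heat_col
    return heats.sort_index()


@dataclass
class EnrichmentResult:
    """Per-category delta-rank, MWU p and BH-adjusted p."""

    table: pd.DataFrame   # index: category; size, delta_rank, p, p_adj, direction
    n_genes: int

    def significant(self, alpha: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def _categories_as_sets(categories) -> dict[str, set]:
    if isinstance(categories, pd.DataFrame):
        cols = list(categories.columns)
        gene_col = "gene_id" if "gene_id" in cols else cols[0]
        cat_col = "go_id" if "go_id" in cols else cols[1]
        return {c: set(sub[gene_col]) for c, sub in categories.groupby(cat_col)}
    return {c: set(m) for c, m in dict(categories).items()}


def _mwu_pvalue(member_heats: np.ndarray, rest_heats: np.ndarray) -> float:
    """Two-tailed MWU p; exact enumeration for small untied member sets."""
    pooled = np.concatenate([member_heats, rest_heats])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(member_heats) <= _EXACT_MAX_MEMBERS and no_ties) else "asymptotic"
    res = mannwhitneyu(member_heats, rest_heats, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def mwu_enrichment(
    heats: pd.Series,
    categories,
    min_size: int = 15,
    alpha: float = 0.1,
) -> EnrichmentResult:
    """Two-tailed Mann-Whitney enrichment over gene categories.

    Heats are midranked ascending; for each category intersected with the
    heat index, delta_rank = mean(member ranks) - mean(rest ranks) and the
    two-sided MWU p is computed (exact enumeration when the category has
    <= 8 members and no ties, normal approximation with tie-corrected
    variance otherwise).  Categories smaller than `min_size` after
    intersection, or spanning the whole gene set, are dropped; duplicate
    membership sets are tested once.  BH FDR across the tested categories.
    """
    heats = heats.dropna()
    genes = set(heats.index)
    ranks = pd.Series(rankdata(heats.to_numpy()), index=heats.index)
    cat_sets = _categories_as_sets(categories)

    tested: dict[str, set] = {}
    seen: dict[frozenset, str] = {}
    for cat, members in sorted(cat_sets.items()):
        mem = frozenset(members & genes)
        if len(mem) < min_size or len(mem) == len(genes):
            continue
        if mem in seen:
            continue
        seen[mem] = cat
        tested[cat] = set(mem)
    if not tested:
        raise ValueError("no category passes min_size after intersecting with heats")

    rows = []
    heat_arr = heats.to_numpy()
    idx_of = {g: i for i, g in enumerate(heats.index)}
    for cat, members in tested.items():
        m_idx = np.fromiter((idx_of[g] for g in members), dtype=int)
        mask = np.zeros(len(heats), dtype=bool)
        mask[m_idx] = True
        delta = ranks.to_numpy()[mask].mean() - ranks.to_numpy()[~mask].mean()
        p = _mwu_pvalue(heat_arr[mask], heat_arr[~mask])
        rows.append({"category": cat, "size": int(mask.sum()),
                     "delta_rank": float(delta), "p": p,
                     "direction": "high" if delta > 0 else "low"})
    table = pd.DataFrame(rows).set_index("category")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values("p_adj")
    return EnrichmentResult(table=table, n_genes=len(genes))


def combine_enrichments(
    results: dict[str, EnrichmentResult],
    how: str = "union",
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Combine enrichment runs from different heat statistics.

    A category can be called enriched by the effect-size heats, by the
    test-statistic heats, or both.  `how="union"` (default) keeps every
    category significant in at least one run, reporting its best adjusted
    p and the runs that called it; `how="all"` returns the concatenated
    per-run tables for downstream filtering.
    """
    frames = []
    for name, res in results.items():
        t = res.table.copy()
        t["source"] = name
        frames.append(t.reset_index())
    combined = pd.concat(frames, ignore_index=True)
    if how == "all":
        return combined
    if how != "union":
        raise ValueError("how must be 'union' or 'all'")
    sig = combined[combined["p_adj"] < alpha]
    if sig.empty:
        return sig
    out = (sig.sort_values("p_adj")
              .groupby("category")
              .agg(best_p_adj=("p_adj", "min"),
                   delta_rank=("delta_rank", "first"),
                   size=("size", "first"),
                   sources=("source", lambda s: ";".join(sorted(set(s))))))
    return out.sort_values("best_p_adj")


def category_heat_test(heats: pd.Series, members) -> dict:
    """Rank-sum comparison of one category's heats against all the rest.

    Two-sided Wilcoxon rank-sum (exact for small untied member sets); also
    reports the percent difference of the member mean versus the rest.
    """
    heats = heats.dropna()
    members = set(members) & set(heats.index)
    if not members:
        raise ValueError("member set is empty after intersecting with heats")
    if len(members) == len(heats):
        raise ValueError("member set equals the full gene set")
    mask = heats.index.isin(members)
    mh, rh = heats.to_numpy()[mask], heats.to_numpy()[~mask]
    stat = mannwhitneyu(mh, rh, alternative="two-sided", method="asymptotic").statistic
    p = _mwu_pvalue(mh, rh)
    rest_mean = rh.mean()
    pct = float(100.0 * (mh.mean() - rest_mean) / abs(rest_mean)) if rest_mean != 0 else np.nan
    return {
        "n_members": int(mask.sum()),
        "statistic": float(stat),
        "p": p,
        "mean_members": float(mh.mean()),
        "mean_rest": float(rest_mean),
        "percent_difference": pct,
    }
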