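"""Pool-seq FST and the population-branch-statistic selection scan.

A select-and-resequence design: pooled larvae are sequenced before and
after a heat episode alongside an ambient control, and per-site FST between
the pools is folded into a population branch statistic (PBS) whose focal
branch is the heat-treated pool.  Large PBS values localize alleles whose
frequency moved specifically in the heat arm.

The FST estimator is a Hudson-type per-site estimator with a double
sampling correction: read sampling within a pool (depth d, factor
d/(d-1)) and gamete sampling into the pool (haploid pool size n, factor
n/(n-1)).  It is unbiased at zero differentiation (may go negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PoolCounts",
    "poolseq_fst",
    "pbs",
    "select_and_resequence_scan",
    "delta_pbs",
    "PbsTable",
]

ROLES = ("parental", "initial", "final_ambient", "final_heat")
_FST_CAP = 1.0 - 1e-6


@dataclass
class PoolCounts:
    """Per-site ref/alt read counts for one pool.

    size is the haploid pool size (number of chromosomes sampled into the
    pool); role is one of parental | initial | final_ambient | final_heat.
    """

    name: str
    role: str
    size: int
    sites: pd.DataFrame
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=int)
        self.alt = np.asarray(self.alt, dtype=int)
        if self.size < 2:
            raise ValueError("haploid pool size must be >= 2")
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ValueError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def freq(self) -> np.ndarray:
        """Alt-allele read frequency; NaN where depth is 0."""
        d = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt / np.maximum(d, 1), np.nan)

    def site_labels(self) -> pd.Index:
        return pd.Index(
            self.sites["chrom"].astype(str) + "_" + self.sites["pos"].astype(str),
            name="locus",
        )


def _within_het(p: np.ndarray, depth: np.ndarray, size: int) -> np.ndarray:
    """Depth- and pool-size-corrected within-pool heterozygosity."""
    d = depth.astype(float)
    corr = np.where(d > 1, d / np.maximum(d - 1.0, 1.0), np.nan)
    return corr * 2.0 * p * (1.0 - p) * size / (size - 1.0)


def poolseq_fst(a: PoolCounts, b: PoolCounts) -> np.ndarray:
    """Per-site Hudson-type FST between two pools.

    FST = (h_b - (h_a + h_b_within)/2) / h_b with
    h_i = [d_i/(d_i-1)] [n_i/(n_i-1)] 2 p_i (1 - p_i)  (within pool i)
    h_b = p_a (1 - p_b) + p_b (1 - p_a)                (between pools)

    Sites with depth < 2 in either pool, or monomorphic across both pools
    (h_b = 0), come back NaN.  Values are clamped to [-1, 1] and may be
    negative.
    """
    pa, pb = a.freq, b.freq
    da, db = a.depth, b.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        ha = _within_het(pa, da, a.size)
        hb = _within_het(pb, db, b.size)
        h_between = pa * (1.0 - pb) + pb * (1.0 - pa)
        fst = (h_between - 0.5 * (ha + hb)) / h_between
    fst = np.where((da >= 2) & (db >= 2) & (h_between > 0), fst, np.nan)
    return np.clip(fst, -1.0, 1.0)


def pbs(fst_ab, fst_ac, fst_bc):
    """Population branch statistic of branch A from three pairwise FSTs.

    Branch lengths T_xy = -log(1 - FST) with negative FST floored at 0 and
    FST capped just below 1; PBS_A = (T_AB + T_AC - T_BC) / 2.  Any missing
    FST propagates to a missing PBS.  Symmetric in the two outgroups B, C.
    """
    def t(f):
        f = np.clip(np.asarray(f, dtype=float), 0.0, _FST_CAP)
        return -np.log1p(-f)

    with np.errstate(invalid="ignore"):
        return (t(fst_ab) + t(fst_ac) - t(fst_bc)) / 2.0


@dataclass
class PbsTable:
    """Per-locus PBS results of one phenotype's scan."""

    table: pd.DataFrame       # index: locus; columns: fst_*, pbs
    n_input: int
    n_retained: int
    filter_counts: dict[str, int]

    @property
    def pbs(self) -> pd.Series:
        return self.table["pbs"]


def select_and_resequence_scan(
    pools: dict[str, PoolCounts],
    min_depth: int = 10,
    fst_parental_max: float = 0.05,
) -> PbsTable:
    """PBS scan of the heat-treated pool against initial and ambient pools.

    `pools` maps the four roles (parental, initial, final_ambient,
    final_heat) to their counts on a shared site index.  Loci are retained
    when (i) depth >= min_depth in every pool, (ii) both alleles are
    observed (>= 1 read each) in the parental and in the initial pool,
    and (iii) FST(initial, parental) < fst_parental_max — ruling out
    heterozygosity artifacts.  The focal branch A is final_heat; the
    outgroups are the initial pool and the final ambient pool.
    """
    missing = [r for r in ROLES if r not in pools]
    if missing:
        raise ValueError(
            f"missing pool roles {missing}; found {sorted(pools)}"
        )
    par, ini = pools["parental"], pools["initial"]
    amb, heat = pools["final_ambient"], pools["final_heat"]

    depth_ok = np.ones(len(par.ref), dtype=bool)
    for p in (par, ini, amb, heat):
        depth_ok &= p.depth >= min_depth
    biallelic = (par.ref >= 1) & (par.alt >= 1) & (ini.ref >= 1) & (ini.alt >= 1)
    fst_ip = poolseq_fst(ini, par)
    with np.errstate(invalid="ignore"):
        parental_ok = fst_ip < fst_parental_max
    parental_ok &= ~np.isnan(fst_ip)
    keep = depth_ok & biallelic & parental_ok

    fst_hi = poolseq_fst(heat, ini)
    fst_ha = poolseq_fst(heat, amb)
    fst_ia = poolseq_fst(ini, amb)
    pbs_a = pbs(fst_hi, fst_ha, fst_ia)

    table = pd.DataFrame(
        {
            "fst_heat_initial": fst_hi[keep],
            "fst_heat_ambient": fst_ha[keep],
            "fst_initial_ambient": fst_ia[keep],
            "fst_initial_parental": fst_ip[keep],
            "pbs": pbs_a[keep],
        },
        index=par.site_labels()[keep],
    )
    table = table.dropna(subset=["pbs"])
    return PbsTable(
        table=table,
        n_input=len(par.ref),
        n_retained=len(table),
        filter_counts={
            "depth": int((~depth_ok).sum()),
            "biallelic": int((depth_ok & ~biallelic).sum()),
            "parental_fst": int((depth_ok & biallelic & ~parental_ok).sum()),
        },
    )


def delta_pbs(nonbleached: PbsTable, cross: PbsTable) -> tuple[pd.DataFrame, dict]:
    """PBS difference (nonbleached - cross) on shared loci, plus summary.

    The summary reports the least-squares R^2 between the two PBS vectors
    and the ratio of their means — how much of the tolerant pool's
    selection signal is shared with the site-wide cross.
    """
    shared = nonbleached.table.index.intersection(cross.table.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared loci between the two PBS tables")
    a = nonbleached.table.loc[shared, "pbs"]
    b = cross.table.loc[shared, "pbs"]
    diff = pd.DataFrame(
        {"pbs_nonbleached": a, "pbs_cross": b, "delta_pbs": a - b}, index=shared
    )
    r = np.corrcoef(a, b)[0, 1]
    mean_b = b.mean()
    summary = {
        "n_shared": int(len(shared)),
        "r_squared": float(r**2),
        "mean_ratio": float(a.mean() / mean_b) if mean_b != 0 else np.nan,
        "mean_nonbleached": float(a.mean()),
        "mean_cross": float(mean_b),
    }
    return diff, summary
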