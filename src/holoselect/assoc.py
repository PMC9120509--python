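"""Locus association tests from genotype likelihoods and dosages.

Two tests mirror the two traits of interest:

* binary case-control: per locus, a likelihood-ratio test comparing
  separate HWE allele frequencies in the two phenotype groups against a
  pooled frequency, computed on the genotype-likelihood marginal
  likelihood (1 df);
* continuous: per locus, an LRT on the regression of the logit-transformed
  symbiont proportion on posterior dosage (beta = slope).

Genome-wide significance uses a max-statistic permutation null: trait
labels are permuted, the full per-locus scan recomputed, and the maximum
statistic of each permutation collected; the significance cutoff is an
upper empirical quantile (nearest rank) of those maxima, which controls
the family-wise error rate without assuming independence across loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._rng import child_rng
from .genolik import DosageMatrix, GenotypeLikelihoods, em_allele_frequency, gl_loglik

__all__ = [
    "AssociationResult",
    "PermutationNull",
    "binary_association",
    "continuous_association",
    "maxstat_threshold",
    "binary_lrt_statfn",
    "continuous_lrt_statfn",
    "compare_associations",
]

_LOGIT_CLAMP = 1e-3


@dataclass
class AssociationResult:
    """Per-locus association statistics plus filter flags.

    Flagged loci (ok == False) are excluded from thresholds and downstream
    heats; their LRT is still reported where computable.
    """

    loci: pd.Index
    lrt: np.ndarray
    p: np.ndarray
    beta: np.ndarray | None
    n_informative: np.ndarray
    flags: pd.DataFrame

    @property
    def ok(self) -> np.ndarray:
        return ~self.flags.any(axis=1).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"lrt": self.lrt, "p": self.p}, index=self.loci)
        if self.beta is not None:
            out["beta"] = self.beta
        out["n_informative"] = self.n_informative
        out = out.join(self.flags)
        out["ok"] = self.ok
        return out

    def significant(self, threshold: float) -> pd.Index:
        return self.loci[self.ok & (self.lrt > threshold)]


def _polymorphism_lrt(gl: np.ndarray, missing: np.ndarray, p_hat: np.ndarray) -> np.ndarray:
    """LRT of free allele frequency vs a monomorphic site (minor allele 0)."""
    ll_free = gl_loglik(gl, p_hat, missing)
    ll_mono = np.maximum(gl_loglik(gl, np.zeros_like(p_hat), missing),
                         gl_loglik(gl, np.ones_like(p_hat), missing))
    return np.maximum(2.0 * (ll_free - ll_mono), 0.0)


def binary_association(
    glt: GenotypeLikelihoods,
    labels: np.ndarray,
    min_samples: int = 5,
    maf_p: float = 2e-6,
) -> AssociationResult:
    """Case-control LRT per locus from genotype likelihoods.

    LRT = 2 [l(p_case) + l(p_control) - l(p_pooled)] where l is the
    GL-marginal log-likelihood under HWE and each frequency is the EM
    estimate within its group (1 df against chi-square).  Loci failing the
    polymorphism test (p >= maf_p on the monomorphic-vs-free LRT) or with
    fewer than `min_samples` informative samples in either group are
    flagged and excluded.  Symmetric under swapping the two labels.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {list(classes)}")
    case = labels == classes[1]
    gl, missing = glt.gl, glt.missing

    p_all = em_allele_frequency(gl, missing)
    p_case = em_allele_frequency(gl[:, case], missing[:, case])
    p_ctrl = em_allele_frequency(gl[:, ~case], missing[:, ~case])

    ll_all = gl_loglik(gl, p_all, missing)
    ll_case = gl_loglik(gl[:, case], p_case, missing[:, case])
    ll_ctrl = gl_loglik(gl[:, ~case], p_ctrl, missing[:, ~case])
    lrt = np.maximum(2.0 * (ll_case + ll_ctrl - ll_all), 0.0)
    pval = chi2.sf(lrt, df=1)

    poly_lrt = _polymorphism_lrt(gl, missing, p_all)
    poly_p = chi2.sf(poly_lrt, df=1)
    n_case = (~missing[:, case]).sum(axis=1)
    n_ctrl = (~missing[:, ~case]).sum(axis=1)
    flags = pd.DataFrame(
        {
            "flag_monomorphic": poly_p >= maf_p,
            "flag_low_n": (n_case < min_samples) | (n_ctrl < min_samples),
        },
        index=glt.site_labels(),
    )
    return AssociationResult(
        loci=glt.site_labels(),
        lrt=lrt,
        p=pval,
        beta=None,
        n_informative=(n_case + n_ctrl).astype(int),
        flags=flags,
    )


def _logit_trait(trait: np.ndarray) -> np.ndarray:
    trait = np.asarray(trait, dtype=float)
    if np.any((trait < 0) | (trait > 1)):
        raise ValueError("trait must be a proportion in [0, 1]")
    clamped = np.clip(trait, _LOGIT_CLAMP, 1.0 - _LOGIT_CLAMP)
    return np.log(clamped / (1.0 - clamped))


def _regression_lrt(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row slope + LRT of y ~ x[row]; x (L, n), y (n,)."""
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    syy = float((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), np.nan)
        rss1 = syy - np.where(sxx > 0, sxy**2 / np.maximum(sxx, 1e-300), 0.0)
        lrt = n * np.log(syy / np.maximum(rss1, 1e-12 * syy + 1e-300))
    return beta, np.maximum(lrt, 0.0)


def continuous_association(
    dm: DosageMatrix,
    trait: np.ndarray,
    min_high: int = 3,
    min_count: int = 3,
    high_dosage: float = 0.9,
) -> AssociationResult:
    """Symbiont-proportion association per locus from posterior dosages.

    The proportion trait is clamped to [1e-3, 1-1e-3], logit-transformed
    and regressed on dosage by least squares; LRT = n log(RSS0/RSS1)
    (1 df), beta = slope.  Loci with fewer than `min_high` samples whose
    dosage confidently departs from homozygous reference (dosage >=
    high_dosage) or with fewer than `min_count` minor-allele carriers are
    flagged and excluded.
    """
    y = _logit_trait(trait)
    if np.ptp(y) == 0:
        raise ValueError("constant trait: continuous association undefined")
    if len(y) < 4:
        raise ValueError("need >= 4 samples")
    x = dm.dosage
    beta, lrt = _regression_lrt(x, y)
    pval = chi2.sf(lrt, df=1)

    n_high = (x >= high_dosage).sum(axis=1)
    p_hat = x.mean(axis=1) / 2.0
    minor_is_alt = p_hat <= 0.5
    carriers = np.where(minor_is_alt, (x >= 0.5).sum(axis=1), (x <= 1.5).sum(axis=1))
    flags = pd.DataFrame(
        {
            "flag_min_high": n_high < min_high,
            "flag_min_count": carriers < min_count,
        },
        index=pd.Index(dm.sites["chrom"].astype(str) + "_" + dm.sites["pos"].astype(str),
                       name="marker"),
    )
    return AssociationResult(
        loci=flags.index,
        lrt=lrt,
        p=pval,
        beta=beta,
        n_informative=(~dm.missing).sum(axis=1).astype(int),
        flags=flags,
    )


@dataclass
class PermutationNull:
    """Max-statistic permutation null and its significance cutoff."""

    n_perm: int
    maxima: np.ndarray
    level: float
    threshold: float
    enumerated: bool = False

    def significant(self, result: AssociationResult) -> pd.Index:
        return result.significant(self.threshold)


def binary_lrt_statfn(glt: GenotypeLikelihoods, min_samples: int = 5,
                      maf_p: float = 2e-6, chunk: int = 64):
    """Batched per-locus binary LRT as a function of permuted label rows.

    Returns (stat_fn, keep) where keep marks loci passing the label-free
    filters (polymorphism, informative counts under balanced groups) and
    stat_fn maps a (P, n_samples) boolean case matrix to a (P, n_kept) LRT
    array.  The pooled likelihood term is label-invariant and precomputed.
    """
    gl, missing = glt.gl, glt.missing
    p_all = em_allele_frequency(gl, missing)
    ll_all = gl_loglik(gl, p_all, missing)
    poly_p = chi2.sf(_polymorphism_lrt(gl, missing, p_all), df=1)
    keep = (poly_p < maf_p) & ~np.isnan(p_all)
    glk = np.ascontiguousarray(gl[keep])
    mk = np.ascontiguousarray(missing[keep])
    ll_all_k = ll_all[keep]

    def stat_fn(case_matrix: np.ndarray) -> np.ndarray:
        case_matrix = np.asarray(case_matrix, dtype=bool)
        P = case_matrix.shape[0]
        L = glk.shape[0]
        out = np.empty((P, L))
        k_case = int(case_matrix[0].sum())
        for lo in range(0, P, chunk):
            cm = case_matrix[lo : lo + chunk]
            p = cm.shape[0]
            order = np.argsort(~cm, axis=1, kind="stable")   # cases first
            case_idx = order[:, :k_case]                     # (p, k)
            ctrl_idx = order[:, k_case:]
            ll_groups = np.zeros((p, L))
            low_n = np.zeros((p, L), dtype=bool)
            for idx, min_n in ((case_idx, min_samples), (ctrl_idx, min_samples)):
                sub_gl = glk[:, idx, :]                      # (L, p, k, 3)
                sub_gl = np.moveaxis(sub_gl, 0, 1)           # (p, L, k, 3)
                sub_m = np.moveaxis(mk[:, idx], 0, 1)        # (p, L, k)
                p_g = em_allele_frequency(sub_gl, sub_m)
                ll_groups += gl_loglik(sub_gl, p_g, sub_m)
                low_n |= (~sub_m).sum(axis=-1) < min_n
            lrt = np.maximum(2.0 * (ll_groups - ll_all_k[None, :]), 0.0)
            lrt[low_n] = np.nan
            out[lo : lo + p] = lrt
        return out

    return stat_fn, keep


def continuous_lrt_statfn(dm: DosageMatrix, trait: np.ndarray,
                          min_high: int = 3, min_count: int = 3,
                          high_dosage: float = 0.9):
    """Batched continuous LRT as a function of permuted trait orderings.

    stat_fn maps a (P, n_samples) integer matrix of sample permutations to
    a (P, n_kept) LRT array (the trait is permuted, the dosages stay put).
    """
    base = continuous_association(dm, trait, min_high, min_count, high_dosage)
    keep = base.ok
    x = dm.dosage[keep]
    y = _logit_trait(trait)

    def stat_fn(perm_matrix: np.ndarray) -> np.ndarray:
        perm_matrix = np.asarray(perm_matrix, dtype=int)
        out = np.empty((perm_matrix.shape[0], x.shape[0]))
        for i, perm in enumerate(perm_matrix):
            _, lrt = _regression_lrt(x, y[perm])
            out[i] = lrt
        return out

    return stat_fn, keep


def _distinct_binary_permutations(labels: np.ndarray) -> int:
    n = len(labels)
    k = int((labels == np.unique(labels)[1]).sum())
    return math.comb(n, k)


def maxstat_threshold(
    stat_fn,
    labels: np.ndarray,
    n_perm: int = 10_000,
    level: float = 0.9999,
    seed: int = 0,
    binary: bool = True,
    chunk: int = 256,
) -> PermutationNull:
    """Family-wise significance cutoff from a max-statistic permutation null.

    For each of `n_perm` label permutations the full per-locus scan is
    recomputed (via `stat_fn`, see binary_lrt_statfn /
    continuous_lrt_statfn) and its maximum statistic recorded; the
    threshold is the nearest-rank empirical quantile — order statistic
    ceil(level * n_perm) — of those maxima.  If `n_perm` exceeds the number
    of distinct binary label assignments, all assignments are enumerated
    instead (with a warning) and the quantile taken over the enumeration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    n = len(labels)
    enumerated = False
    if binary:
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("binary max-stat needs exactly 2 label classes")
        case = labels == classes[1]
        k = int(case.sum())
        distinct = math.comb(n, k)
        if n_perm > distinct:
            warnings.warn(
                f"n_perm={n_perm} exceeds the {distinct} distinct label "
                "assignments; enumerating all of them instead",
                stacklevel=2,
            )
            rows = np.zeros((distinct, n), dtype=bool)
            for i, combo in enumerate(combinations(range(n), k)):
                rows[i, list(combo)] = True
            enumerated = True
            perm_input = rows
        else:
            rng = child_rng(seed, "maxstat")
            rows = np.zeros((n_perm, n), dtype=bool)
            for i in range(n_perm):
                rows[i, rng.choice(n, size=k, replace=False)] = True
            perm_input = rows
    else:
        rng = child_rng(seed, "maxstat")
        perm_input = np.stack([rng.permutation(n) for _ in range(n_perm)])

    maxima_parts = []
    for lo in range(0, perm_input.shape[0], chunk):
        stats = stat_fn(perm_input[lo : lo + chunk])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            maxima_parts.append(np.nanmax(stats, axis=1))
    maxima = np.concatenate(maxima_parts)
    m = len(maxima)
    rank = min(max(int(np.ceil(level * m)), 1), m)
    threshold = float(np.sort(maxima)[rank - 1])
    return PermutationNull(
        n_perm=m, maxima=maxima, level=level, threshold=threshold, enumerated=enumerated
    )


def compare_associations(
    binary: AssociationResult,
    continuous: AssociationResult,
    binary_threshold: float,
    continuous_threshold: float,
) -> dict:
    """Overlay the two scans: Venn counts of significant loci plus the
    least-squares R^2 between the two LRT vectors on shared loci."""
    shared = binary.loci.intersection(continuous.loci)
    if len(shared) == 0:
        raise ValueError("no shared loci between the two association results")
    bin_df = binary.to_frame().loc[shared]
    con_df = continuous.to_frame().loc[shared]
    both_ok = bin_df["ok"].to_numpy() & con_df["ok"].to_numpy()
    bl = bin_df["lrt"].to_numpy()[both_ok]
    cl = con_df["lrt"].to_numpy()[both_ok]
    sig_b = set(shared[both_ok][bl > binary_threshold])
    sig_c = set(shared[both_ok][cl > continuous_threshold])
    r = np.corrcoef(bl, cl)[0, 1] if len(bl) > 1 else np.nan
    table = pd.DataFrame(
        {"lrt_binary": bl, "lrt_continuous": cl}, index=shared[both_ok]
    )
    table["sig_binary"] = table.index.isin(sig_b)
    table["sig_continuous"] = table.index.isin(sig_c)
    return {
        "table": table,
        "n_shared": int(both_ok.sum()),
        "only_binary": len(sig_b - sig_c),
        "only_continuous": len(sig_c - sig_b),
        "shared_significant": len(sig_b & sig_c),
        "r_squared": float(r**2),
    }
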