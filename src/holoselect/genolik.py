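"""Genotype-likelihood utilities.

Works directly on per-site likelihood triplets over the diploid genotypes
{homRef, het, homAlt} of a biallelic site, without ever calling hard
genotypes for the frequency/dosage machinery:

* allele-frequency estimation by EM under Hardy-Weinberg,
* posterior expected alternate-allele dosages,
* identity-by-state distances + hierarchical clustering (clonality check),
* PCA of dosages, including PC1 summaries of locus subsets (e.g. all loci
  annotated with one gene ontology) that are later used as genetic "traits".

Likelihood triplets are max-rescaled (each non-missing triplet has maximum
1); a missing triplet is flat, which makes it inert in every likelihood
sum below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "GenotypeLikelihoods",
    "DosageMatrix",
    "hwe_priors",
    "em_allele_frequency",
    "gl_loglik",
    "estimate_allele_frequency",
    "posterior_dosages",
    "call_genotypes",
    "ibs_distance",
    "IbsResult",
    "pca_dosages",
    "PcaResult",
]

_GENO_DOSAGE = np.array([0.0, 1.0, 2.0])


@dataclass
class GenotypeLikelihoods:
    """Max-rescaled genotype likelihoods for `n_sites x n_samples` triplets.

    sites:   DataFrame with columns chrom, pos, ref, alt
    samples: sample identifiers
    gl:      float array (n_sites, n_samples, 3), each non-missing triplet
             rescaled so its maximum is 1; missing triplets are flat ones
    missing: bool array (n_sites, n_samples)
    """

    sites: pd.DataFrame
    samples: list[str]
    gl: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must have shape (n_sites, n_samples, 3)")
        if self.missing is None:
            # flat triplets carry no information -> missing
            self.missing = np.ptp(self.gl, axis=2) == 0
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gl.shape[1]

    def site_labels(self) -> pd.Index:
        return pd.Index(
            self.sites["chrom"].astype(str) + "_" + self.sites["pos"].astype(str),
            name="marker",
        )


@dataclass
class DosageMatrix:
    """Posterior expected alt-allele counts (sites x samples), in [0, 2]."""

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray        # (n_sites, n_samples)
    freq: np.ndarray          # per-site EM allele frequency estimate
    missing: np.ndarray       # (n_sites, n_samples) True where no data

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]


def hwe_priors(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype priors [(1-p)^2, 2p(1-p), p^2], stacked last."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def em_allele_frequency(
    gl: np.ndarray,
    missing: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """EM estimate of the alt-allele frequency from genotype likelihoods.

    `gl` has shape (..., n_samples, 3); the estimate maximizes
    sum_samples log sum_g gl[g] * HWE(g | p) independently for every leading
    index. Iterates until max |delta p| < tol or `max_iter` sweeps.
    Sites with no informative sample come back as NaN.
    """
    gl = np.asarray(gl, dtype=float)
    if missing is None:
        missing = np.ptp(gl, axis=-1) == 0
    obs = ~missing
    n_obs = obs.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.full(gl.shape[:-2], 0.25, dtype=float)
        for _ in range(max_iter):
            w = hwe_priors(p)[..., None, :]          # (..., 1, 3)
            post = gl * w
            denom = post.sum(axis=-1)
            dos = (post[..., 1] + 2.0 * post[..., 2]) / denom
            num = np.where(obs, dos, 0.0).sum(axis=-1)
            p_new = num / (2.0 * n_obs)
            delta = np.abs(p_new - p)
            p = p_new
            if np.nanmax(delta, initial=0.0) < tol:
                break
    p = np.where(n_obs > 0, p, np.nan)
    return p


def gl_loglik(gl: np.ndarray, p: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Marginal log-likelihood sum_samples log sum_g gl[g]*HWE(g|p).

    `gl` (..., n_samples, 3); `p` broadcastable to the leading shape.
    Missing samples contribute 0.
    """
    gl = np.asarray(gl, dtype=float)
    if missing is None:
        missing = np.ptp(gl, axis=-1) == 0
    w = hwe_priors(np.asarray(p, dtype=float))[..., None, :]
    lik = (gl * w).sum(axis=-1)
    with np.errstate(divide="ignore"):
        ll = np.where(~missing, np.log(np.maximum(lik, 1e-300)), 0.0)
    return ll.sum(axis=-1)


def estimate_allele_frequency(glt: GenotypeLikelihoods, **kwargs) -> np.ndarray:
    """Per-site EM allele frequencies for a GenotypeLikelihoods container."""
    return em_allele_frequency(glt.gl, glt.missing, **kwargs)


def posterior_dosages(glt: GenotypeLikelihoods, freq: np.ndarray | None = None) -> DosageMatrix:
    """Posterior mean alt-allele dosage per site/sample.

    dosage = sum_g g * gl[g]*HWE(g|p) / sum_g gl[g]*HWE(g|p); a missing
    (flat) triplet collapses to the HWE prior mean 2p.
    """
    if freq is None:
        freq = estimate_allele_frequency(glt)
    freq = np.asarray(freq, dtype=float)
    w = hwe_priors(freq)[:, None, :]
    post = glt.gl * w
    denom = post.sum(axis=-1)
    dosage = (post * _GENO_DOSAGE).sum(axis=-1) / denom
    return DosageMatrix(
        sites=glt.sites,
        samples=list(glt.samples),
        dosage=dosage,
        freq=freq,
        missing=glt.missing.copy(),
    )


def call_genotypes(glt: GenotypeLikelihoods) -> np.ndarray:
    """Maximum-likelihood genotype calls in {0,1,2}; ties -> het; missing -> -1."""
    gl = glt.gl
    best = gl.max(axis=-1, keepdims=True)
    is_max = gl >= best - 1e-12
    calls = np.argmax(gl, axis=-1)
    tied = is_max.sum(axis=-1) > 1
    calls = np.where(tied, 1, calls)
    calls = np.where(glt.missing, -1, calls)
    return calls.astype(np.int8)


@dataclass
class IbsResult:
    """Pairwise identity-by-state distances plus an average-linkage tree."""

    samples: list[str]
    distance: np.ndarray      # symmetric (n, n), zero diagonal
    linkage: np.ndarray       # scipy linkage matrix (average)
    order: list[int]          # dendrogram leaf order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distance, index=self.samples, columns=self.samples)

    def to_newick(self) -> str:
        """Ultrametric newick; branch length = parent merge height - own height."""
        tree = to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            bl = parent_height - node.dist
            if node.is_leaf():
                return f"{self.samples[node.id]}:{bl:.6g}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            return f"({left},{right}):{bl:.6g}"

        left = rec(tree.get_left(), tree.dist)
        right = rec(tree.get_right(), tree.dist)
        return f"({left},{right});"


def ibs_distance(calls: np.ndarray, samples: list[str] | None = None) -> IbsResult:
    """Identity-by-state distance from hard genotype calls.

    `calls` is (n_sites, n_samples) in {0,1,2}, -1 = missing.  For each pair
    the distance is mean_{co-called sites} |g_i - g_j| / 2, i.e. the average
    allele-sharing deficit; 0 for clones/replicates, 1 for opposite
    homozygotes at every site.  Any pair without co-called sites is an error.
    """
    calls = np.asarray(calls)
    n = calls.shape[1]
    if n < 2:
        raise ValueError("ibs_distance needs at least 2 samples")
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    g = calls.astype(float)
    valid = calls >= 0
    g = np.where(valid, g, np.nan)
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[:, i : i + 1] - g[:, i + 1 :])  # (sites, n-i-1)
        co = (~np.isnan(diff)).sum(axis=0)
        if np.any(co == 0):
            bad = int(np.flatnonzero(co == 0)[0]) + i + 1
            raise ValueError(f"no co-called sites for pair ({samples[i]}, {samples[bad]})")
        d = np.nanmean(diff, axis=0) / 2.0
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    link = average(squareform(dist, checks=False))
    order = [int(i) for i in leaves_list(link)]
    return IbsResult(samples=list(samples), distance=dist, linkage=link, order=order)


@dataclass
class PcaResult:
    """Sample scores of a dosage PCA; PC1 sign fixed (loading sum >= 0)."""

    samples: list[str]
    scores: np.ndarray            # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray          # (n_loci_used, n_components)

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


def pca_dosages(
    dm: DosageMatrix,
    loci_subset: np.ndarray | None = None,
    scale: bool = False,
    n_components: int | None = None,
    subset_name: str = "subset",
) -> PcaResult:
    """PCA of posterior dosages (samples as observations, loci as variables).

    Missing dosages are already at their HWE prior mean 2p (see
    posterior_dosages), so no further imputation is needed; columns are
    centered, and optionally scaled by sqrt(p(1-p)).  PC1's sign is fixed so
    that the sum of its loadings is non-negative.
    """
    X = dm.dosage.T.copy()            # (samples, loci)
    freq = dm.freq
    if loci_subset is not None:
        loci_subset = np.asarray(loci_subset)
        X = X[:, loci_subset]
        freq = freq[loci_subset]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca_dosages needs >= 2 samples and >= 2 loci")
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = np.sqrt(np.clip(freq * (1.0 - freq), 1e-12, None))
        X = X / sd
    tot = float((X**2).sum())
    if tot <= 1e-12:
        raise ValueError(f"zero-variance locus subset '{subset_name}' in dosage PCA")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if n_components is None:
        n_components = min(X.shape) - 1 or 1
    n_components = min(n_components, len(S))
    scores = U[:, :n_components] * S[:n_components]
    load = Vt[:n_components].T
    evr = (S[:n_components] ** 2) / (S**2).sum()
    # deterministic orientation: each PC's loading sum >= 0
    sign = np.where(load.sum(axis=0) < 0, -1.0, 1.0)
    return PcaResult(
        samples=list(dm.samples),
        scores=scores * sign,
        explained_variance_ratio=evr,
        loadings=load * sign,
    )
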