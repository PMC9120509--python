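"""Synthetic holobiont data generator.

Emulates the study design every downstream stage assumes: a single
unstructured coral population with two historical bleaching phenotype
groups, maternally fixed symbiont (Durusdinium) proportions shifted by
host genotype at planted loci, pooled larval allele-frequency trajectories
with a single episode of heat-only viability selection, qPCR cycle
thresholds, planted metabolite co-abundance modules, and replicate-level
binomial survivorship.  Every emitted dataset carries its ground truth
(TruthSet) for parameter-recovery tests.

All randomness derives from one root seed via named child streams
(see _rng), so identical (config, seed) pairs reproduce every output
byte-for-byte and adding a stage never perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binom

from ._rng import child_rng
from .genolik import GenotypeLikelihoods
from .poolsel import PoolCounts

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_population",
    "gl_from_reads",
    "simulate_genotype_likelihoods",
    "simulate_pool_timeseries",
    "simulate_assays",
    "simulate_all",
]

#: survivorship probabilities per (phenotype, temperature); the high-arm
#: values mirror the strong phenotype effect of a heat-stress endpoint, the
#: ambient arm is phenotype-flat.
DEFAULT_SURVIVAL = {
    ("bleached", "ambient"): 0.37,
    ("nonbleached", "ambient"): 0.37,
    ("cross", "ambient"): 0.40,
    ("bleached", "high"): 0.05,
    ("nonbleached", "high"): 0.25,
    ("cross", "high"): 0.33,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic holobiont generator.

    Defaults describe the emulated design: 22 colonies in two phenotype
    groups of 11, biallelic unlinked sites, a handful of planted causal
    loci for phenotype and symbiont proportion, heat-only larval viability
    selection, and the assay layouts (qPCR duplicates on 3 branches,
    metabolite feature table, n = 15 survivorship replicates).
    """

    n_colonies: int = 22
    n_sites: int = 2000
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_causal_pheno: int = 5
    n_causal_sym: int = 5
    effect_pheno: float = 1.0      # liability shift per alt allele
    effect_sym: float = 2.0        # logit proportion-Durusdinium shift per alt allele
    sym_component_gap: float = 1.0  # +/- logit offset of the two maternal components
    sym_logit_sd: float = 0.5      # colony-level logit noise
    sym_liability_weight: float = 2.0
    s: float = 0.5                 # viability selection coefficient, heat arm only
    depth_mean: float = 30.0       # adult sequencing depth (Poisson mean)
    pool_depth_mean: float = 600.0  # pooled larval library depth (Poisson mean)
    err: float = 0.01              # per-base error probability
    pool_gametes: int = 5000       # gametes sampled into each larval pool
    n_go_terms: int = 20
    genes_per_term: int = 25
    gene_span: int = 2000          # gene length (bp) in the synthetic gene table
    n_metab_modules: int = 3
    module_size: int = 30
    n_metab_noise: int = 60
    noise_sd: float = 0.1          # metabolite within-module residual SD (log2)
    metab_missing_rate: float = 0.05
    ct_intercept: float = 22.0
    sigma_tech: float = 0.15       # qPCR technical-replicate CT noise (cycles)
    sigma_branch: float = 0.2      # branch-replicate logit noise on proportion
    n_surv_replicates: int = 15
    n_surv_start: int = 50         # larvae per survivorship replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_low < self.maf_high <= 0.5):
            raise ValueError("need 0 <= maf_low < maf_high <= 0.5")
        if not (0.0 <= self.err < 0.5):
            raise ValueError("err must be in [0, 0.5)")
        if self.s < 0:
            raise ValueError("selection coefficient s must be >= 0")
        for name in ("n_colonies", "n_sites", "pool_gametes", "n_go_terms",
                     "genes_per_term", "n_metab_modules", "module_size",
                     "n_surv_replicates", "n_surv_start"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_causal_pheno + self.n_causal_sym > self.n_sites:
            raise ValueError("more causal loci requested than sites")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset (for recovery tests)."""

    samples: list[str]
    sites: pd.DataFrame                  # chrom, pos, ref, alt
    site_freqs: np.ndarray               # population alt-allele frequencies
    genotypes: np.ndarray                # (n_colonies, n_sites) in {0,1,2}
    phenotype: np.ndarray                # per colony: "bleached"/"nonbleached"
    prop_durusdinium_true: np.ndarray    # per colony in [0,1]
    sym_logit_base: np.ndarray           # component intercept + colony noise
    causal_pheno_loci: np.ndarray
    causal_sym_loci: np.ndarray
    module_membership_true: np.ndarray | None = None
    h2_true: float | None = None
    gene_table: pd.DataFrame | None = None
    gene_go: pd.DataFrame | None = None

    def phenotype_mask(self, which: str = "nonbleached") -> np.ndarray:
        return self.phenotype == which


_BASES = np.array(list("ACGT"))


def _make_sites(n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
    """Unlinked biallelic sites spread over 14 chromosomes."""
    n_chrom = 14
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=n_sites))
    pos = np.zeros(n_sites, dtype=int)
    for c in range(1, n_chrom + 1):
        m = chrom == c
        pos[m] = np.sort(rng.choice(np.arange(1, 5_000_000), size=m.sum(), replace=False))
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    return pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
        }
    )


def _make_annotation(sites: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models near the simulated sites plus a gene->GO multi-map."""
    n_genes = config.n_go_terms * config.genes_per_term // 2
    idx = rng.choice(len(sites), size=min(n_genes, len(sites)), replace=False)
    idx.sort()
    rows = []
    for k, i in enumerate(idx):
        start = max(0, int(sites["pos"].iloc[i]) - rng.integers(0, config.gene_span))
        rows.append(
            {
                "chrom": sites["chrom"].iloc[i],
                "start": start,
                "end": start + config.gene_span,
                "gene_id": f"gene{k:05d}",
            }
        )
    gene_table = pd.DataFrame(rows)
    terms = [f"GO:{t:07d}" for t in range(config.n_go_terms)]
    assign = []
    for term in terms:
        members = rng.choice(gene_table["gene_id"], size=min(config.genes_per_term,
                                                             len(gene_table)), replace=False)
        assign.extend({"gene_id": g, "go_id": term} for g in members)
    gene_go = pd.DataFrame(assign).drop_duplicates().reset_index(drop=True)
    return gene_table, gene_go


def simulate_population(config: SimConfig) -> TruthSet:
    """Sample one admixture-free population with planted causal loci.

    Genotypes are HWE draws at uniform(maf_low, maf_high) frequencies.
    Proportion Durusdinium follows a two-component logit model: a maternal
    component intercept (+/- sym_component_gap) plus effect_sym times the
    centered alt-allele count over the symbiont-causal loci plus N(0,
    sym_logit_sd) colony noise, pushed through the inverse logit.  The
    binary phenotype thresholds a liability (phenotype-causal genotypes +
    weighted symbiont proportion + standard normal noise) at its median,
    giving two balanced groups.
    """
    rng_sites = child_rng(config.seed, "sites")
    rng_geno = child_rng(config.seed, "genotypes")
    rng_sym = child_rng(config.seed, "symbionts")
    rng_liab = child_rng(config.seed, "liability")
    rng_annot = child_rng(config.seed, "annotation")

    sites = _make_sites(config.n_sites, rng_sites)
    freqs = rng_sites.uniform(config.maf_low, config.maf_high, size=config.n_sites)
    genotypes = rng_geno.binomial(2, freqs[None, :], size=(config.n_colonies, config.n_sites))

    causal = rng_geno.choice(config.n_sites, size=config.n_causal_pheno + config.n_causal_sym,
                             replace=False)
    causal_pheno = np.sort(causal[: config.n_causal_pheno])
    causal_sym = np.sort(causal[config.n_causal_pheno:])

    component = rng_sym.integers(0, 2, size=config.n_colonies)  # maternal line
    base = np.where(component == 1, config.sym_component_gap, -config.sym_component_gap)
    base = base + rng_sym.normal(0.0, config.sym_logit_sd, size=config.n_colonies)
    if len(causal_sym):
        centered = (genotypes[:, causal_sym] - 2.0 * freqs[causal_sym]).sum(axis=1)
    else:
        centered = np.zeros(config.n_colonies)
    prop_d = expit(base + config.effect_sym * centered)

    if len(causal_pheno):
        g_term = (genotypes[:, causal_pheno] - 2.0 * freqs[causal_pheno]).sum(axis=1)
    else:
        g_term = np.zeros(config.n_colonies)
    liability = (config.effect_pheno * g_term
                 + config.sym_liability_weight * (prop_d - 0.5)
                 + rng_liab.normal(size=config.n_colonies))
    order = np.argsort(liability, kind="stable")
    phenotype = np.full(config.n_colonies, "bleached", dtype=object)
    phenotype[order[config.n_colonies // 2:]] = "nonbleached"

    gene_table, gene_go = _make_annotation(sites, config, rng_annot)
    samples = [f"colony{i + 1:02d}" for i in range(config.n_colonies)]
    return TruthSet(
        samples=samples,
        sites=sites,
        site_freqs=freqs,
        genotypes=genotypes,
        phenotype=np.asarray(phenotype),
        prop_durusdinium_true=prop_d,
        sym_logit_base=base,
        causal_pheno_loci=causal_pheno,
        causal_sym_loci=causal_sym,
        gene_table=gene_table,
        gene_go=gene_go,
    )


def gl_from_reads(alt_reads: np.ndarray, depth: np.ndarray, err: float) -> np.ndarray:
    """Likelihood triplet over {homRef, het, homAlt} given allele read counts.

    L(g) = Binomial(alt_reads; depth, p_g) with p_0 = err, p_1 = 1/2,
    p_2 = 1 - err, max-rescaled; depth 0 yields a flat triplet.
    """
    alt_reads = np.asarray(alt_reads)
    depth = np.asarray(depth)
    gl = np.stack(
        [binom.pmf(alt_reads, depth, p_g) for p_g in (err, 0.5, 1.0 - err)], axis=-1
    )
    gl = np.where((depth == 0)[..., None], 1.0, gl)
    return gl / gl.max(axis=-1, keepdims=True)


def simulate_genotype_likelihoods(
    truth: TruthSet,
    depth_mean: float,
    err: float,
    seed: int,
) -> GenotypeLikelihoods:
    """Read-sampling genotype likelihoods for the adult colonies.

    Per site/sample: depth ~ Poisson(depth_mean); alt reads ~ Binomial(depth,
    p_g) with p_0 = err, p_1 = 1/2, p_2 = 1 - err given the true genotype;
    the likelihood of genotype g is then Binomial(alt; depth, p_g),
    max-rescaled per triplet.  Depth 0 yields a flat triplet flagged missing.
    """
    if not (0.0 <= err < 0.5):
        raise ValueError("err must be in [0, 0.5)")
    rng = child_rng(seed, "genotype-likelihoods")
    g = truth.genotypes.T                      # (sites, samples)
    depth = rng.poisson(depth_mean, size=g.shape)
    p_read = np.array([err, 0.5, 1.0 - err])[g]
    alt_reads = rng.binomial(depth, p_read)
    gl = gl_from_reads(alt_reads, depth, err)
    missing = depth == 0
    return GenotypeLikelihoods(
        sites=truth.sites, samples=list(truth.samples), gl=gl, missing=missing
    )


def viability_selection(p: np.ndarray, s: float) -> np.ndarray:
    """One episode of genic viability selection: p' = p(1+s) / (1+sp)."""
    p = np.asarray(p, dtype=float)
    return p * (1.0 + s) / (1.0 + s * p)


def _pool_counts(freq: np.ndarray, depth_mean: float, err: float,
                 rng: np.random.Generator, name: str, role: str,
                 size: int, sites: pd.DataFrame) -> PoolCounts:
    depth = rng.poisson(depth_mean, size=freq.shape)
    p_read = freq * (1.0 - err) + (1.0 - freq) * err
    alt = rng.binomial(depth, p_read)
    return PoolCounts(
        name=name, role=role, size=size, sites=sites,
        ref=(depth - alt).astype(int), alt=alt.astype(int),
    )


def simulate_pool_timeseries(truth: TruthSet, config: SimConfig) -> dict[tuple[str, str], PoolCounts]:
    """Pooled allele-count trajectories for the larval selection experiment.

    For each phenotype pool ("cross" = all colonies, "nonbleached" = the
    tolerant half): parental frequency = mean alt frequency of the
    contributing colonies; initial larval frequency = binomial gamete sample
    of size pool_gametes; final_ambient resamples the initial frequencies
    (drift only); final_heat first applies one round of genic viability
    selection p' = p(1+s)/(1+sp) at the phenotype-causal loci, then
    resamples.  Read counts are Binomial(depth, pool frequency) with
    depth ~ Poisson(pool_depth_mean) and the per-base error folded into the
    read-level allele probability.
    """
    rng = child_rng(config.seed, "pools")
    out: dict[tuple[str, str], PoolCounts] = {}
    groups = {
        "cross": np.ones(len(truth.samples), dtype=bool),
        "nonbleached": truth.phenotype_mask("nonbleached"),
    }
    n = config.pool_gametes
    for pheno, mask in groups.items():
        if mask.sum() == 0:
            raise ValueError(f"no contributing colonies for pool '{pheno}'")
        hap = 2 * int(mask.sum())
        p_parent = truth.genotypes[mask].mean(axis=0) / 2.0
        f_init = rng.binomial(n, p_parent) / n
        f_amb = rng.binomial(n, f_init) / n
        f_sel = f_init.copy()
        if len(truth.causal_pheno_loci):
            f_sel[truth.causal_pheno_loci] = viability_selection(
                f_init[truth.causal_pheno_loci], config.s
            )
        f_heat = rng.binomial(n, f_sel) / n
        for role, f, size in (
            ("parental", p_parent, hap),
            ("initial", f_init, n),
            ("final_ambient", f_amb, n),
            ("final_heat", f_heat, n),
        ):
            out[(pheno, role)] = _pool_counts(
                f, config.pool_depth_mean, config.err, rng,
                name=f"{pheno}_{role}", role=role, size=size, sites=truth.sites,
            )
    return out


def simulate_assays(truth: TruthSet, config: SimConfig) -> dict[str, pd.DataFrame]:
    """qPCR CT table, metabolite feature table and survivorship table.

    qPCR: per colony x 3 branch replicates x 2 technical replicates for the
    Cladocopium and Durusdinium actin assays, CT = intercept - log2(copies)
    + N(0, sigma_tech), copies proportional to the branch-level symbiont
    proportion (branch proportions jitter the colony truth by
    N(0, sigma_branch) on the logit scale).  A genus below 1e-4 proportion
    does not amplify (empty CT).

    Metabolites: features x samples; module members load 1.0 on a module
    latent factor plus N(0, noise_sd) on the log2 scale around a per-feature
    baseline; noise features are pure baseline + noise; a molecular class
    label is enriched in each module by construction; entries drop out at
    metab_missing_rate.

    Survivorship: per phenotype x temperature x replicate, survivors ~
    Binomial(n_surv_start, pi) with pi from DEFAULT_SURVIVAL.
    """
    rng_q = child_rng(config.seed, "qpcr")
    rng_m = child_rng(config.seed, "metabolites")
    rng_s = child_rng(config.seed, "survivorship")

    # --- qPCR ---------------------------------------------------------
    rows = []
    for i, colony in enumerate(truth.samples):
        for branch in range(1, 4):
            jitter = rng_q.normal(0.0, config.sigma_branch)
            prop = float(expit(logit(np.clip(truth.prop_durusdinium_true[i], 1e-6, 1 - 1e-6))
                               + jitter))
            for assay, copies in (("C", 1.0 - prop), ("D", prop)):
                for rep in (1, 2):
                    if copies < 1e-4:
                        ct = np.nan
                    else:
                        ct = (config.ct_intercept - np.log2(copies)
                              + rng_q.normal(0.0, config.sigma_tech))
                    rows.append({"colony": colony, "branch": branch,
                                 "assay": assay, "tech_rep": rep, "ct": ct})
    qpcr = pd.DataFrame(rows)

    # --- metabolites --------------------------------------------------
    n_samp = len(truth.samples)
    n_mod = config.n_metab_modules
    n_feat = n_mod * config.module_size + config.n_metab_noise
    factors = rng_m.normal(size=(n_mod, n_samp))
    membership = np.zeros(n_feat, dtype=int)
    log2x = np.empty((n_feat, n_samp))
    baseline = rng_m.uniform(10.0, 20.0, size=n_feat)
    classes = np.empty(n_feat, dtype=object)
    class_pool = [f"class{k + 1}" for k in range(n_mod + 2)]
    for j in range(n_feat):
        if j < n_mod * config.module_size:
            m = j // config.module_size
            membership[j] = m + 1
            log2x[j] = baseline[j] + factors[m] + rng_m.normal(0.0, config.noise_sd, n_samp)
            classes[j] = (f"class{m + 1}" if rng_m.random() < 0.8
                          else rng_m.choice(class_pool))
        else:
            log2x[j] = baseline[j] + rng_m.normal(0.0, 1.0, n_samp)
            classes[j] = rng_m.choice(class_pool)
    abundance = np.power(2.0, log2x)
    # left-censored dropout: the lowest-intensity entries of each feature
    # fall below the detection limit (the regime min-imputation assumes)
    if config.metab_missing_rate > 0:
        thresh = np.quantile(abundance, config.metab_missing_rate, axis=1, keepdims=True)
        drop = abundance < thresh
        keep = np.argmax(abundance, axis=1)  # never censor the feature maximum
        drop[np.arange(n_feat), keep] = False
        abundance[drop] = np.nan
    metab = pd.DataFrame(abundance,
                         index=[f"feat{j + 1:04d}" for j in range(n_feat)],
                         columns=truth.samples)
    metab.insert(0, "molecular_class", classes)
    truth.module_membership_true = membership

    # --- survivorship -------------------------------------------------
    rows = []
    for (pheno, temp), pi in DEFAULT_SURVIVAL.items():
        for rep in range(1, config.n_surv_replicates + 1):
            surv = rng_s.binomial(config.n_surv_start, pi)
            rows.append({"phenotype": pheno, "temperature": temp, "replicate": rep,
                         "prop_surviving": surv / config.n_surv_start})
    surv_table = pd.DataFrame(rows)

    # analytic MS-ratio expectation at high temperature (excluding cross):
    # E[MS_b] ~ sigma2 + r tau2, E[MS_w] ~ sigma2 with r replicates
    pis = [DEFAULT_SURVIVAL[("bleached", "high")], DEFAULT_SURVIVAL[("nonbleached", "high")]]
    sigma2 = float(np.mean([p * (1 - p) / config.n_surv_start for p in pis]))
    tau2 = float(np.var(pis, ddof=1)) / 2.0 * 2.0  # two-group between variance
    r = config.n_surv_replicates
    truth.h2_true = (sigma2 + r * tau2) / (2.0 * sigma2 + r * tau2)

    return {"qpcr": qpcr, "metabolites": metab, "survivorship": surv_table}


def simulate_all(config: SimConfig) -> dict:
    """Run every stage; returns truth, gl, pools and assay tables."""
    truth = simulate_population(config)
    gl = simulate_genotype_likelihoods(truth, config.depth_mean, config.err, config.seed)
    pools = simulate_pool_timeseries(truth, config)
    assays = simulate_assays(truth, config)
    return {"truth": truth, "gl": gl, "pools": pools, **assays}
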