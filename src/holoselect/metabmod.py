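"""Metabolite co-abundance modules via a weighted correlation network.

The weighted-correlation-network workflow repurposed for metabolite
feature tables: minimum-value imputation and log2 transform, soft
thresholding of the unsigned correlation network (adjacency |cor|^beta
chosen by scale-free topology fit), topological-overlap clustering with a
static tree cut, eigen-feature (module PC1) extraction, kME filtering,
and merging of modules with highly correlated eigen-features.  Module
eigen-features are then correlated (Spearman) against per-sample traits
such as a per-ontology genotype PC1, and molecular-class composition of
each module is tested with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, spearmanr
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "merge_modules",
    "ModuleSet",
    "module_trait_correlation",
    "class_enrichment",
]


def preprocess(raw: pd.DataFrame) -> pd.DataFrame:
    """Impute missing abundances with the feature minimum, then log2.

    `raw` is features x samples with positive abundances and NaN for
    missing; features with no observed value at all are dropped with a
    warning.
    """
    values = raw.to_numpy(dtype=float)
    all_missing = np.all(np.isnan(values), axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing features",
                      stacklevel=2)
        raw = raw.loc[~all_missing]
        values = values[~all_missing]
    mins = np.nanmin(values, axis=1, keepdims=True)
    filled = np.where(np.isnan(values), mins, values)
    if np.any(filled <= 0):
        raise ValueError("abundances must be positive before log2")
    return pd.DataFrame(np.log2(filled), index=raw.index, columns=raw.columns)


def adjacency(data: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned adjacency |cor(i,j)|^power with zero diagonal."""
    corr = np.corrcoef(data.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    a = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) ~ log10 mean(k) over equal-occupancy bins.

    p(k) is the empirical density (bin count / (n * bin width)); with
    equal-occupancy bins the raw counts are flat by construction, so the
    width normalization carries the shape of the degree distribution.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    order = np.argsort(k)
    bins = np.array_split(k[order], n_bins)
    xs, ys = [], []
    for b in bins:
        width = b.max() - b.min() if len(b) else 0.0
        if len(b) == 0 or width <= 0:
            continue
        xs.append(np.log10(b.mean()))
        ys.append(np.log10(len(b) / (len(k) * width)))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(((ys - pred) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    data: pd.DataFrame,
    powers=range(1, 21),
    rsq_cut: float = 0.8,
    min_mean_k: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Scale-free-topology fit per candidate power; pick the elbow.

    For each power the unsigned adjacency is built, per-feature
    connectivity k_i = sum_j a_ij computed, and the fit is the signed R^2
    of the log-log regression of the binned degree distribution (negative
    when the slope is positive, i.e. not scale-free).  The chosen power is
    the smallest with fit >= rsq_cut among powers whose mean connectivity
    stays >= min_mean_k — without the connectivity floor, raising pure
    noise to a high power yields a sparse heavy-tailed network that looks
    deceptively scale-free.  If no such power exists the argmax fit is
    used with a warning.
    """
    data = data.loc[data.std(axis=1) > 0]
    if len(data) < 10:
        raise ValueError("need >= 10 non-constant features")
    rows = []
    for beta in powers:
        a = adjacency(data, beta)
        k = a.sum(axis=1)
        rows.append({"power": int(beta), "fit": _scale_free_fit(k),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    good = table[(table["fit"] >= rsq_cut) & (table["mean_k"] >= min_mean_k)]
    if len(good):
        chosen = int(good["power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "power"])
        warnings.warn(
            f"no power reaches scale-free fit {rsq_cut} at mean connectivity "
            f">= {min_mean_k}; falling back to the argmax (power {chosen})",
            stacklevel=2,
        )
    return table, chosen


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    Diagonal treated as 1; values lie in [0, 1] for adjacency in [0, 1].
    """
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleSet:
    """Module assignment (0 = unassigned) with eigen-features and kME."""

    features: pd.Index
    labels: np.ndarray                      # per-feature module label
    eigenfeatures: pd.DataFrame             # samples x modules ("M1", ...)
    kme: np.ndarray                         # per-feature kME to own module (NaN if unassigned)
    power: float

    def module_sizes(self) -> pd.Series:
        lab = pd.Series(self.labels)
        return lab[lab > 0].value_counts().sort_index()

    def partition(self) -> dict[int, frozenset]:
        out: dict[int, set] = {}
        for f, l in zip(self.features, self.labels):
            out.setdefault(int(l), set()).add(f)
        return {k: frozenset(v) for k, v in out.items()}


def _eigenfeature(data: np.ndarray) -> np.ndarray:
    """PC1 score vector (over samples) of standardized member abundances,
    oriented so the mean member correlation with it is positive."""
    X = data - data.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    e = Vt[0]
    kme = _row_cor(X, e)
    if np.nanmean(kme) < 0:
        e = -e
    return e


def _row_cor(data: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of data with vec."""
    xc = data - data.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, xc @ vc / np.maximum(denom, 1e-300), 0.0)


def _recompute_eigen(data: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {
        m: _eigenfeature(data[labels == m])
        for m in sorted(set(labels[labels > 0]))
    }


def merge_modules(
    data: np.ndarray,
    labels: np.ndarray,
    merge_height: float,
) -> np.ndarray:
    """Iteratively merge modules whose eigen-feature correlation
    dissimilarity (1 - cor) falls below `merge_height`, until stable."""
    labels = labels.copy()
    while True:
        eigen = _recompute_eigen(data, labels)
        mods = sorted(eigen)
        if len(mods) < 2:
            break
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                d = 1.0 - float(np.corrcoef(eigen[mods[i]], eigen[mods[j]])[0, 1])
                if d < merge_height and (best is None or d < best[0]):
                    best = (d, mods[i], mods[j])
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
    # relabel 1..m by size (desc) for stable output
    sizes = {m: int((labels == m).sum()) for m in set(labels[labels > 0])}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    return np.array([remap.get(l, 0) for l in labels])


def detect_modules(
    data: pd.DataFrame,
    power: float,
    min_size: int = 25,
    min_kme: float = 0.8,
    merge_height: float = 0.15,
    cut_height: float = 0.97,
) -> ModuleSet:
    """Detect co-abundance modules from a preprocessed feature table.

    Pipeline: unsigned adjacency at `power` -> TOM similarity -> average-
    linkage clustering of 1 - TOM -> static cut at `cut_height` -> clusters
    below `min_size` unassigned -> eigen-features -> features with kME <
    `min_kme` unassigned (modules rechecked against `min_size`) -> modules
    with eigen-feature dissimilarity < `merge_height` merged iteratively.
    Constant features are always unassigned.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    X = data.to_numpy(dtype=float)
    n = len(data)
    variable = X.std(axis=1) > 0
    labels = np.zeros(n, dtype=int)
    if variable.sum() < min_size:
        warnings.warn("fewer variable features than min_size; all unassigned",
                      stacklevel=2)
        return ModuleSet(features=data.index, labels=labels,
                         eigenfeatures=pd.DataFrame(index=data.columns),
                         kme=np.full(n, np.nan), power=power)

    Xv = X[variable]
    a = adjacency(pd.DataFrame(Xv), power)
    tom = tom_similarity(a)
    dist = 1.0 - tom
    link = average(squareform(dist, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    lab_v = np.zeros(len(Xv), dtype=int)
    next_id = 1
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= min_size:
            lab_v[members] = next_id
            next_id += 1

    # kME filter, then re-apply the size floor
    for _ in range(2):
        eigen = _recompute_eigen(Xv, lab_v)
        for m, e in eigen.items():
            members = lab_v == m
            kme_m = _row_cor(Xv[members], e)
            drop = np.flatnonzero(members)[kme_m < min_kme]
            lab_v[drop] = 0
        for m in list(np.unique(lab_v[lab_v > 0])):
            if (lab_v == m).sum() < min_size:
                lab_v[lab_v == m] = 0

    lab_v = merge_modules(Xv, lab_v, merge_height)

    labels[variable] = lab_v
    eigen = _recompute_eigen(Xv, lab_v)
    kme = np.full(n, np.nan)
    idx_v = np.flatnonzero(variable)
    for m, e in eigen.items():
        members = lab_v == m
        kme[idx_v[members]] = _row_cor(Xv[members], e)
    eig_df = pd.DataFrame(
        {f"M{m}": e for m, e in eigen.items()}, index=data.columns
    )
    return ModuleSet(features=data.index, labels=labels, eigenfeatures=eig_df,
                     kme=kme, power=power)


def module_trait_correlation(
    modules: ModuleSet,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of each module eigen-feature with each trait.

    `traits` is samples x traits, aligned on the eigen-feature sample index
    (>= 4 shared samples required).  BH FDR across the full matrix.
    """
    shared = modules.eigenfeatures.index.intersection(traits.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples between modules and traits")
    eig = modules.eigenfeatures.loc[shared]
    tr = traits.loc[shared]
    rows = []
    for mod in eig.columns:
        for trait in tr.columns:
            r, p = spearmanr(eig[mod], tr[trait])
            rows.append({"module": mod, "trait": trait, "rho": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def class_enrichment(
    modules: ModuleSet,
    class_labels: pd.Series,
) -> pd.DataFrame:
    """Fisher-exact molecular-class enrichment per (module, class).

    For each assigned module and each class with labeled features, builds
    the 2x2 table (in-module & in-class vs complements over labeled
    features), reports the sample odds ratio, the conditional-MLE odds
    ratio, the two-sided Fisher exact p, and BH-adjusted p over all tested
    pairs.
    """
    lab = pd.Series(modules.labels, index=modules.features)
    classes = class_labels.reindex(modules.features).dropna()
    if classes.empty:
        raise ValueError("no labeled features")
    rows = []
    for m in sorted(set(modules.labels[modules.labels > 0])):
        in_mod = lab.loc[classes.index] == m
        for cls in sorted(classes.unique()):
            in_cls = classes == cls
            n11 = int((in_mod & in_cls).sum())
            n12 = int((in_mod & ~in_cls).sum())
            n21 = int((~in_mod & in_cls).sum())
            n22 = int((~in_mod & ~in_cls).sum())
            table = [[n11, n12], [n21, n22]]
            _, p = fisher_exact(table, alternative="two-sided")
            with np.errstate(divide="ignore", invalid="ignore"):
                sample_or = (n11 * n22) / (n12 * n21) if n12 * n21 > 0 else np.inf
            cond_or = float(odds_ratio(table, kind="conditional").statistic)
            rows.append({"module": f"M{m}", "class": cls, "n_in_both": n11,
                         "odds_ratio": float(sample_or),
                         "odds_ratio_cmle": cond_or, "p": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p_adj").reset_index(drop=True)
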