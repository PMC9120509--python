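"""Metabolite preprocessing, network modules, trait correlation, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from holoselect.metabmod import (
    adjacency,
    class_enrichment,
    detect_modules,
    merge_modules,
    module_trait_correlation,
    pick_soft_threshold,
    preprocess,
    tom_similarity,
)
from holoselect.simulate import SimConfig, simulate_all


def planted_table(n_modules=3, size=30, n_noise=60, n_samples=22,
                  loading=1.0, noise_sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_modules, n_samples))
    rows, truth = [], []
    for m in range(n_modules):
        for _ in range(size):
            rows.append(loading * factors[m] + rng.normal(0, noise_sd, n_samples))
            truth.append(m + 1)
    for _ in range(n_noise):
        rows.append(rng.normal(0, 1.0, n_samples))
        truth.append(0)
    data = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                        columns=[f"s{i}" for i in range(n_samples)])
    return data, np.array(truth), factors


class TestPreprocess:
    def test_impute_then_log2(self):
        raw = pd.DataFrame([[4.0, np.nan, 16.0]], index=["f1"], columns=list("abc"))
        out = preprocess(raw)
        np.testing.assert_allclose(out.loc["f1"], [2.0, 2.0, 4.0])

    def test_no_missing_is_pure_log2(self):
        raw = pd.DataFrame([[2.0, 8.0], [1.0, 4.0]], columns=list("ab"))
        np.testing.assert_allclose(preprocess(raw), np.log2(raw))

    def test_all_missing_feature_dropped(self):
        raw = pd.DataFrame([[np.nan, np.nan], [2.0, 4.0]], index=["f1", "f2"],
                           columns=list("ab"))
        with pytest.warns(UserWarning, match="all-missing"):
            out = preprocess(raw)
        assert list(out.index) == ["f2"]


class TestSoftThreshold:
    def test_planted_structure_reaches_cut(self):
        data, _, _ = planted_table(seed=1)
        table, power = pick_soft_threshold(data)
        assert table["fit"].max() >= 0.8
        assert 1 <= power <= 20

    def test_fit_matches_from_scratch_recomputation(self):
        """The tabulated fit at one power equals an independent binning and
        log-log regression of the degree distribution."""
        data, _, _ = planted_table(seed=2)
        table, _ = pick_soft_threshold(data, powers=[6])
        a = np.abs(np.corrcoef(data.to_numpy())) ** 6
        np.fill_diagonal(a, 0.0)
        k = np.sort(a.sum(axis=1))
        bins = np.array_split(k, 10)
        xs = np.array([np.log10(b.mean()) for b in bins])
        ys = np.array([np.log10(len(b) / (len(k) * (b.max() - b.min()))) for b in bins])
        slope, intercept = np.polyfit(xs, ys, 1)
        ss_res = ((ys - (slope * xs + intercept)) ** 2).sum()
        r2 = 1 - ss_res / ((ys - ys.mean()) ** 2).sum()
        expected = -r2 if slope > 0 else r2
        assert table["fit"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(80, 12)))
        with pytest.warns(UserWarning, match="falling back"):
            _, power = pick_soft_threshold(data)
        assert 1 <= power <= 20


class TestTom:
    def test_range_symmetry_diagonal(self):
        data, _, _ = planted_table(seed=3)
        tom = tom_similarity(adjacency(data, 6))
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestDetectModules:
    def test_planted_modules_recovered(self):
        data, truth, _ = planted_table(seed=4)
        mods = detect_modules(data, power=6)
        assert adjusted_rand_score(truth, mods.labels) >= 0.9
        noise = truth == 0
        assert (mods.labels[noise] == 0).mean() >= 0.95

    def test_same_latent_factor_modules_merge(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(size=22)
        rows = [factor + rng.normal(0, 0.1, 22) for _ in range(60)]
        rows += [rng.normal(0, 1, 22) for _ in range(40)]
        data = pd.DataFrame(rows)
        mods = detect_modules(data, power=6)
        labels = mods.labels[:60]
        assigned = labels[labels > 0]
        assert len(np.unique(assigned)) == 1

    def test_iid_noise_mostly_unassigned(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(150, 22)))
        mods = detect_modules(data, power=6)
        assert (mods.labels == 0).mean() >= 0.95

    def test_merge_idempotent(self):
        data, _, _ = planted_table(seed=8)
        mods = detect_modules(data, power=6)
        X = data.to_numpy()
        again = merge_modules(X, mods.labels.copy(), merge_height=0.15)
        assert adjusted_rand_score(mods.labels, again) == 1.0

    def test_partition_invariant_to_feature_order(self):
        data, _, _ = planted_table(seed=9)
        mods1 = detect_modules(data, power=6)
        rng = np.random.default_rng(1)
        order = rng.permutation(len(data))
        mods2 = detect_modules(data.iloc[order], power=6)
        back = np.empty(len(data), dtype=int)
        back[order] = mods2.labels
        assert adjusted_rand_score(mods1.labels, back) == 1.0

    def test_assigned_features_meet_kme_floor(self):
        data, _, _ = planted_table(seed=10)
        mods = detect_modules(data, power=6, min_kme=0.8)
        assert np.all(mods.kme[mods.labels > 0] >= 0.8)
        assert (mods.module_sizes() >= 25).all()


class TestModuleTraitCorrelation:
    def test_eigenfeature_self_correlation(self):
        data, _, _ = planted_table(seed=11)
        mods = detect_modules(data, power=6)
        traits = mods.eigenfeatures.iloc[:, [0]].rename(columns={"M1": "t"})
        out = module_trait_correlation(mods, traits)
        row = out[(out["module"] == "M1") & (out["trait"] == "t")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_matches_rank_arithmetic_oracle(self):
        """Spearman rho on an 8-sample set equals the rank-Pearson formula
        computed from scratch."""
        data, _, _ = planted_table(n_samples=8, seed=12)
        mods = detect_modules(data, power=6)
        rng = np.random.default_rng(0)
        trait = pd.DataFrame({"t": rng.normal(size=8)}, index=data.columns)
        out = module_trait_correlation(mods, trait)
        e = mods.eigenfeatures["M1"].to_numpy()
        rx = pd.Series(e).rank().to_numpy()
        ry = trait["t"].rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        got = out[(out["module"] == "M1")]["rho"].iloc[0]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_permuted_traits_rarely_significant(self):
        hits = 0
        for seed in range(10):
            data, _, _ = planted_table(seed=100 + seed)
            mods = detect_modules(data, power=6)
            rng = np.random.default_rng(seed)
            traits = pd.DataFrame(
                rng.normal(size=(22, 5)), index=data.columns,
                columns=[f"t{i}" for i in range(5)],
            )
            out = module_trait_correlation(mods, traits)
            hits += (out["p_adj"] < 0.1).any()
        assert hits <= 1

    def test_too_few_shared_samples_raises(self):
        data, _, _ = planted_table(seed=13)
        mods = detect_modules(data, power=6)
        traits = pd.DataFrame({"t": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="shared samples"):
            module_trait_correlation(mods, traits)


class TestClassEnrichment:
    def test_worked_table_odds_ratio_and_p(self):
        """[[10,15],[5,70]]: sample OR = 700/75 = 9.33 and the two-sided
        Fisher p equals a from-scratch hypergeometric pmf summation."""
        labels = (["inA"] * 10 + ["other"] * 15) + (["inA"] * 5 + ["other"] * 70)
        features = pd.Index([f"f{i}" for i in range(100)])
        from holoselect.metabmod import ModuleSet

        module_labels = np.array([1] * 25 + [0] * 75)
        mods = ModuleSet(features=features, labels=module_labels,
                         eigenfeatures=pd.DataFrame(index=[f"s{i}" for i in range(5)]),
                         kme=np.full(100, np.nan), power=6)
        out = class_enrichment(mods, pd.Series(labels, index=features))
        row = out[(out["module"] == "M1") & (out["class"] == "inA")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(700.0 / 75.0, abs=1e-9)

        # hypergeometric tail oracle: sum pmf over tables as or more extreme
        M, n, N = 100, 15, 25   # total, class size, module size
        pmf_obs = hypergeom.pmf(10, M, n, N)
        p_oracle = sum(
            hypergeom.pmf(k, M, n, N)
            for k in range(0, min(n, N) + 1)
            if hypergeom.pmf(k, M, n, N) <= pmf_obs * (1 + 1e-9)
        )
        assert row["p"] == pytest.approx(p_oracle, rel=1e-6)

    def test_uniform_class_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            from holoselect.metabmod import ModuleSet

            n = 200
            features = pd.Index([f"f{i}" for i in range(n)])
            labels = rng.choice([0, 1, 2], size=n, p=[0.4, 0.3, 0.3])
            classes = pd.Series(rng.choice(["x", "y", "z"], size=n), index=features)
            mods = ModuleSet(features=features, labels=labels,
                             eigenfeatures=pd.DataFrame(), kme=np.full(n, np.nan),
                             power=6)
            out = class_enrichment(mods, classes)
            hits += (out["p_adj"] < 0.1).any()
        assert hits <= 1

    def test_pure_class_module_minimal_p(self):
        from holoselect.metabmod import ModuleSet

        n = 120
        features = pd.Index([f"f{i}" for i in range(n)])
        labels = np.array([1] * 30 + [0] * 90)
        classes = pd.Series(["hit"] * 30 + ["bg1"] * 45 + ["bg2"] * 45,
                            index=features)
        mods = ModuleSet(features=features, labels=labels,
                         eigenfeatures=pd.DataFrame(), kme=np.full(n, np.nan),
                         power=6)
        out = class_enrichment(mods, classes)
        target = out[(out["module"] == "M1") & (out["class"] == "hit")]["p"].iloc[0]
        assert target == out["p"].min()


class TestEndToEndWithGenerator:
    def test_generator_modules_recovered_and_classes_enriched(self):
        data_all = simulate_all(SimConfig(n_sites=50, seed=3))
        truth = data_all["truth"]
        metab = data_all["metabolites"]
        classes = metab["molecular_class"]
        data = preprocess(metab.drop(columns="molecular_class"))
        mods = detect_modules(data, power=6)
        assert adjusted_rand_score(truth.module_membership_true, mods.labels) >= 0.9
        enr = class_enrichment(mods, classes)
        assert (enr["p_adj"] < 0.05).any()
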