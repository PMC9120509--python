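"""Association tests and the max-statistic permutation threshold."""

import itertools

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2

from holoselect import assoc, genolik
from holoselect.assoc import (
    binary_association,
    binary_lrt_statfn,
    compare_associations,
    continuous_association,
    maxstat_threshold,
)
from holoselect.simulate import SimConfig, simulate_genotype_likelihoods, simulate_population

from conftest import make_gl


def _certain(genotype):
    t = [0.0, 0.0, 0.0]
    t[genotype] = 1.0
    return t


class TestBinaryAssociation:
    def test_closed_form_perfect_separation(self):
        """10 certain homAlt cases vs 10 certain homRef controls:
        LRT = 2[0 + 0 - l(pooled 0.5)] = -40 log(0.25)."""
        gl = [[_certain(2)] * 10 + [_certain(0)] * 10]
        glt = make_gl(gl)
        labels = np.array(["case"] * 10 + ["ctrl"] * 10)
        res = binary_association(glt, labels)
        expected = -2.0 * 20 * np.log(0.25)
        assert res.lrt[0] == pytest.approx(expected, rel=1e-6)
        assert res.ok[0]

    def test_label_swap_invariance(self, small_dataset, small_truth):
        glt = small_dataset["gl"]
        res1 = binary_association(glt, small_truth.phenotype)
        flipped = np.where(small_truth.phenotype == "bleached", "nonbleached", "bleached")
        res2 = binary_association(glt, flipped)
        np.testing.assert_allclose(res1.lrt, res2.lrt, atol=1e-8)

    def test_monomorphic_locus_flagged(self):
        gl = [[_certain(0)] * 12, [_certain(0)] * 6 + [_certain(1)] * 6]
        glt = make_gl(gl)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = binary_association(glt, labels)
        assert res.flags["flag_monomorphic"].iloc[0]
        assert not res.flags["flag_monomorphic"].iloc[1]

    def test_single_class_raises(self, small_dataset):
        with pytest.raises(ValueError, match="2 label classes"):
            binary_association(small_dataset["gl"], np.array(["x"] * 22))

    def test_null_median_matches_chisq(self):
        """Permuted labels leave group frequencies identical in expectation:
        the LRT median should sit at the chi-square(1) median 0.455."""
        cfg = SimConfig(n_sites=2500, n_causal_pheno=0, n_causal_sym=0, seed=31)
        truth = simulate_population(cfg)
        glt = simulate_genotype_likelihoods(truth, 30, 0.01, 31)
        rng = np.random.default_rng(99)
        labels = rng.permutation(truth.phenotype)
        res = binary_association(glt, labels)
        med = np.median(res.lrt[res.ok])
        assert med == pytest.approx(chi2.median(1), abs=0.1)


class TestContinuousAssociation:
    def _dm(self, dosage):
        import pandas as pd

        n_sites, n = dosage.shape
        sites = pd.DataFrame({"chrom": ["chr1"] * n_sites, "pos": range(n_sites),
                              "ref": ["A"] * n_sites, "alt": ["C"] * n_sites})
        return genolik.DosageMatrix(
            sites=sites, samples=[f"s{i}" for i in range(n)], dosage=dosage,
            freq=dosage.mean(axis=1) / 2, missing=np.zeros_like(dosage, dtype=bool),
        )

    def test_exact_linear_logit_recovers_slope(self):
        dosage = np.tile(np.linspace(0, 2, 12), (1, 1))
        trait = expit(0.5 * dosage[0])
        res = continuous_association(self._dm(dosage), trait)
        assert res.beta[0] == pytest.approx(0.5, abs=1e-6)
        assert res.lrt[0] > 50

    def test_permuted_trait_null_qq_slope(self):
        cfg = SimConfig(n_sites=2000, n_causal_pheno=0, n_causal_sym=0, seed=23)
        truth = simulate_population(cfg)
        glt = simulate_genotype_likelihoods(truth, 30, 0.01, 23)
        dm = genolik.posterior_dosages(glt)
        rng = np.random.default_rng(7)
        trait = rng.permutation(truth.prop_durusdinium_true)
        res = continuous_association(dm, trait)
        lrt = np.sort(res.lrt[res.ok])
        qs = np.linspace(0.05, 0.95, 19)
        theo = chi2.ppf(qs, 1)
        emp = np.quantile(lrt, qs)
        slope = np.polyfit(theo, emp, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_min_count_filter(self):
        dosage = np.zeros((1, 12))
        dosage[0, :2] = 1.0          # only 2 minor-allele carriers
        trait = np.linspace(0.2, 0.8, 12)
        res = continuous_association(self._dm(dosage), trait, min_count=3)
        assert res.flags["flag_min_count"].iloc[0]
        assert not res.ok[0]

    def test_constant_trait_raises(self):
        dosage = np.random.default_rng(0).uniform(0, 2, (3, 8))
        with pytest.raises(ValueError, match="constant trait"):
            continuous_association(self._dm(dosage), np.full(8, 0.4))

    def test_causal_loci_rank_high(self):
        """Planted symbiont loci are strongly enriched in the upper LRT tail
        (a calibrated power bound lives in the acceptance suite)."""
        cfg = SimConfig(n_sites=1000, n_causal_pheno=0, n_causal_sym=5,
                        effect_sym=2.0, seed=2)
        truth = simulate_population(cfg)
        glt = simulate_genotype_likelihoods(truth, 30, 0.01, 2)
        dm = genolik.posterior_dosages(glt)
        res = continuous_association(dm, truth.prop_durusdinium_true)
        pct = np.array([
            (res.lrt < res.lrt[i]).mean() for i in truth.causal_sym_loci
        ])
        assert np.median(pct) > 0.8


class TestMaxstatThreshold:
    def test_nearest_rank_small_n_perm(self):
        """With n_perm = 10 at level 0.9999 the cutoff is the largest of the
        10 maxima (nearest-rank order statistic 10)."""
        vals = np.arange(10.0)

        def stat_fn(rows):
            return vals[: len(rows), None] * np.ones((1, 3))

        labels = np.array([0] * 6 + [1] * 6)
        null = maxstat_threshold(stat_fn, labels, n_perm=10, level=0.9999, seed=0)
        assert null.threshold == vals.max()

    def test_enumeration_matches_bruteforce(self):
        """Tiny sample: the enumerated null equals looping over all distinct
        case assignments by hand."""
        rng = np.random.default_rng(12)
        gl = rng.dirichlet([1, 1, 1], size=(3, 6))
        gl = gl / gl.max(axis=-1, keepdims=True)
        glt = make_gl(gl)
        labels = np.array([0, 0, 0, 0, 1, 1])
        stat_fn, keep = binary_lrt_statfn(glt, min_samples=1, maf_p=1.1)
        with pytest.warns(UserWarning, match="enumerating"):
            null = maxstat_threshold(stat_fn, labels, n_perm=100, level=0.95, seed=0)
        assert null.enumerated and null.n_perm == 15

        maxima = []
        for combo in itertools.combinations(range(6), 2):
            lab = np.array(["ctrl"] * 6, dtype=object)
            for c in combo:
                lab[c] = "case"
            res = binary_association(glt, lab, min_samples=1, maf_p=1.1)
            maxima.append(res.lrt.max())
        expected = np.sort(maxima)[int(np.ceil(0.95 * 15)) - 1]
        assert null.threshold == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_locus_order_and_label_encoding(self, small_dataset, small_truth):
        glt = small_dataset["gl"]
        stat_fn, _ = binary_lrt_statfn(glt)
        t1 = maxstat_threshold(stat_fn, small_truth.phenotype, n_perm=50, seed=5)

        order = np.random.default_rng(0).permutation(glt.n_sites)
        glt2 = genolik.GenotypeLikelihoods(
            sites=glt.sites.iloc[order].reset_index(drop=True),
            samples=glt.samples, gl=glt.gl[order], missing=glt.missing[order],
        )
        stat_fn2, _ = binary_lrt_statfn(glt2)
        t2 = maxstat_threshold(stat_fn2, small_truth.phenotype, n_perm=50, seed=5)
        assert t1.threshold == pytest.approx(t2.threshold, abs=1e-10)

        coded = np.where(small_truth.phenotype == "nonbleached", 1, 0)
        t3 = maxstat_threshold(stat_fn, coded, n_perm=50, seed=5)
        assert t1.threshold == pytest.approx(t3.threshold, abs=1e-10)

    def test_batched_statfn_matches_direct(self, small_dataset, small_truth):
        """The vectorized permutation path reproduces binary_association."""
        glt = small_dataset["gl"]
        stat_fn, keep = binary_lrt_statfn(glt)
        case = (small_truth.phenotype == "nonbleached")[None, :]
        batched = stat_fn(case)[0]
        direct = binary_association(glt, small_truth.phenotype)
        np.testing.assert_allclose(
            batched[~np.isnan(batched)],
            direct.lrt[keep][~np.isnan(batched)],
            atol=1e-6,
        )


class TestCompareAssociations:
    def _result(self, loci, lrt, ok=None):
        import pandas as pd

        n = len(lrt)
        flags = pd.DataFrame({"flag": [False] * n}, index=loci)
        if ok is not None:
            flags["flag"] = ~np.asarray(ok)
        return assoc.AssociationResult(
            loci=loci, lrt=np.asarray(lrt, float),
            p=chi2.sf(np.asarray(lrt, float), 1), beta=None,
            n_informative=np.full(n, 22), flags=flags,
        )

    def test_identical_results_fully_shared(self):
        import pandas as pd

        loci = pd.Index([f"l{i}" for i in range(6)])
        res = self._result(loci, [1, 2, 3, 10, 20, 30])
        cmp = compare_associations(res, res, 5.0, 5.0)
        assert cmp["shared_significant"] == 3
        assert cmp["only_binary"] == cmp["only_continuous"] == 0
        assert cmp["r_squared"] == pytest.approx(1.0)

    def test_disjoint_significant_sets(self):
        import pandas as pd

        loci = pd.Index([f"l{i}" for i in range(4)])
        a = self._result(loci, [10, 10, 0, 0])
        b = self._result(loci, [0, 0, 10, 10])
        cmp = compare_associations(a, b, 5.0, 5.0)
        assert cmp["shared_significant"] == 0
        assert cmp["only_binary"] == 2 and cmp["only_continuous"] == 2

    def test_shared_counts_match_set_arithmetic(self, small_dataset, small_truth):
        glt = small_dataset["gl"]
        dm = genolik.posterior_dosages(glt)
        rb = binary_association(glt, small_truth.phenotype)
        rc = continuous_association(dm, small_truth.prop_durusdinium_true)
        cmp = compare_associations(rb, rc, 3.0, 3.0)
        sig_b = set(rb.significant(3.0)) & set(cmp["table"].index)
        sig_c = set(rc.significant(3.0)) & set(cmp["table"].index)
        assert cmp["shared_significant"] == len(sig_b & sig_c)

    def test_empty_intersection_raises(self):
        import pandas as pd

        a = self._result(pd.Index(["x"]), [1.0])
        b = self._result(pd.Index(["y"]), [1.0])
        with pytest.raises(ValueError, match="shared"):
            compare_associations(a, b, 1, 1)
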