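"""Stratified mtSNP scan, dummy thresholds, haplotypes, ANOVA, and Cox."""

import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtcnkit import mito
from mtcnkit.finemap import CredibleSet
from mtcnkit.synthdata import SimulationConfig, simulate_cohort


def _cov(rng, n):
    return pd.DataFrame({"age": rng.uniform(40, 70, n),
                         "sex": rng.integers(0, 2, n).astype(float)})


def _hap_table(labels: pd.Series) -> mito.HaplotypeTable:
    freq = labels.value_counts(normalize=True)
    return mito.HaplotypeTable(labels=labels, frequencies=freq,
                               reference=freq.idxmax(), snps=[], n_masked=0)


class TestWithAgeSquared:
    def test_adds_centered_square_keeps_age(self, rng):
        cov = _cov(rng, 50)
        out = mito.with_age_squared(cov)
        assert list(out.columns) == ["age", "sex", "age_sq"]
        pd.testing.assert_series_equal(out["age"], cov["age"])
        centered = cov["age"] - cov["age"].mean()
        np.testing.assert_allclose(out["age_sq"], centered ** 2)


class TestMtsnpScan:
    @staticmethod
    def _two_strata(rng, n=3000, m=8):
        G = pd.DataFrame(rng.binomial(1, 0.3, (n, m)).astype(float),
                         columns=[f"mt{j}" for j in range(m)])
        strata = pd.Series(np.where(np.arange(n) < n // 2, "A", "B"),
                           index=G.index)
        return G, strata

    def test_planted_effect_recovered_across_strata(self, rng):
        G, strata = self._two_strata(rng)
        cov = _cov(rng, len(G))
        traits = pd.DataFrame({
            "y": 0.4 * G["mt0"] + rng.standard_normal(len(G))})
        res = mito.mtsnp_scan(G, traits, cov, strata)
        row = res.set_index("snp").loc["mt0"]
        assert row["n_strata"] == 2
        assert abs(row["beta"] - 0.4) < 3 * row["se"]
        assert row["p"] < 1e-10

    def test_rare_snp_excluded_by_maf_filter(self, rng):
        G, strata = self._two_strata(rng, n=4000)
        G["rare"] = 0.0
        half = len(G) // 2
        j = G.columns.get_loc("rare")
        G.iloc[:6, j] = 1.0                  # MAF 0.003 in stratum A
        G.iloc[half:half + 6, j] = 1.0       # MAF 0.003 in stratum B
        traits = pd.DataFrame({"y": rng.standard_normal(len(G))})
        res = mito.mtsnp_scan(G, traits, _cov(rng, len(G)), strata)
        assert "rare" not in set(res["snp"])
        assert "mt0" in set(res["snp"])

    def test_single_stratum_pass_gives_n_strata_one(self, rng):
        G, strata = self._two_strata(rng, n=4000)
        # common in stratum A, far below the MAF floor in stratum B
        half = len(G) // 2
        col = np.zeros(len(G))
        col[:half] = rng.binomial(1, 0.3, half)
        G["aonly"] = col
        traits = pd.DataFrame({"y": rng.standard_normal(len(G))})
        res = mito.mtsnp_scan(G, traits, _cov(rng, len(G)), strata)
        assert res.set_index("snp").loc["aonly", "n_strata"] == 1

    def test_low_info_snp_excluded(self, rng):
        G, strata = self._two_strata(rng, n=1000)
        traits = pd.DataFrame({"y": rng.standard_normal(len(G))})
        info = pd.DataFrame(1.0, index=["A", "B"], columns=G.columns)
        info.loc["A", "mt0"] = 0.5
        info.loc["B", "mt0"] = 0.5
        res = mito.mtsnp_scan(G, traits, _cov(rng, len(G)), strata, info=info)
        assert "mt0" not in set(res["snp"])

    def test_collinear_age_squared_dropped_with_warning(self, rng, caplog):
        G, strata = self._two_strata(rng, n=600)
        cov = _cov(rng, len(G))
        cov["age"] = np.where(np.arange(len(G)) % 2 == 0, 45.0, 65.0)
        cov = mito.with_age_squared(cov)  # two-valued age: age_sq is linear in age
        traits = pd.DataFrame({"y": rng.standard_normal(len(G))})
        with caplog.at_level("WARNING"):
            res = mito.mtsnp_scan(G, traits, cov, strata)
        assert "collinear" in caplog.text
        assert len(res) == G.shape[1]

    def test_meta_matches_manual_ivw_of_per_stratum_fits(self, rng):
        from mtcnkit.assoc import single_variant_assoc
        G, strata = self._two_strata(rng, n=2000, m=3)
        cov = _cov(rng, len(G))
        traits = pd.DataFrame({
            "y": 0.2 * G["mt1"] + rng.standard_normal(len(G))})
        res = mito.mtsnp_scan(G, traits, cov, strata).set_index("snp")
        betas, ws = [], []
        for s in ("A", "B"):
            rows = strata.index[strata == s]
            fit = single_variant_assoc(G.loc[rows], traits["y"].loc[rows],
                                       cov.loc[rows]).set_index("id")
            betas.append(fit.loc["mt1", "beta"])
            ws.append(1.0 / fit.loc["mt1", "se"] ** 2)
        expected = np.average(betas, weights=ws)
        assert res.loc["mt1", "beta"] == pytest.approx(expected, abs=1e-10)
        assert res.loc["mt1", "se"] == pytest.approx(
            1.0 / np.sqrt(sum(ws)), abs=1e-10)


class TestDummyTraitThreshold:
    def test_threshold_is_rank_th_minimum_over_n_traits(self, rng):
        n = 400
        G = pd.DataFrame(rng.binomial(1, 0.3, (n, 10)).astype(float),
                         columns=[f"mt{j}" for j in range(10)])
        strata = pd.Series(["A"] * n, index=G.index)
        cov = _cov(rng, n)
        thr, minima = mito.dummy_trait_threshold(
            G, cov, strata, n_dummy=40, rank=3, n_traits=42,
            rng=np.random.default_rng(3))
        assert len(minima) == 40
        assert thr == pytest.approx(np.sort(minima)[2] / 42)

    def test_threshold_scales_inversely_with_n_traits(self, rng):
        n = 300
        G = pd.DataFrame(rng.binomial(1, 0.4, (n, 6)).astype(float),
                         columns=[f"mt{j}" for j in range(6)])
        strata = pd.Series(["A"] * n, index=G.index)
        cov = _cov(rng, n)
        thr_1, _ = mito.dummy_trait_threshold(
            G, cov, strata, n_dummy=20, rank=2, n_traits=1,
            rng=np.random.default_rng(9))
        thr_42, _ = mito.dummy_trait_threshold(
            G, cov, strata, n_dummy=20, rank=2, n_traits=42,
            rng=np.random.default_rng(9))
        assert thr_1 == pytest.approx(42.0 * thr_42)

    def test_defaults_match_study_design(self):
        sig = inspect.signature(mito.dummy_trait_threshold)
        assert sig.parameters["n_dummy"].default == 300
        assert sig.parameters["rank"].default == 15
        assert sig.parameters["n_traits"].default == 42

    def test_rank_exceeding_n_dummy_rejected(self, rng):
        G = pd.DataFrame(rng.binomial(1, 0.3, (50, 2)).astype(float))
        strata = pd.Series(["A"] * 50, index=G.index)
        with pytest.raises(ValueError):
            mito.dummy_trait_threshold(G, _cov(rng, 50), strata,
                                       n_dummy=5, rank=10)

    def test_minima_match_min_of_m_uniforms_law(self):
        """With independent SNPs each per-trait minimum p is the smallest of
        m near-uniform p-values, i.e. Beta(1, m)."""
        rng = np.random.default_rng(14)
        n, m = 500, 12
        G = pd.DataFrame(rng.binomial(1, 0.3, (n, m)).astype(float),
                         columns=[f"mt{j}" for j in range(m)])
        strata = pd.Series(["A"] * n, index=G.index)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float)},
                           index=G.index)
        _, minima = mito.dummy_trait_threshold(
            G, cov, strata, n_dummy=150, rank=8,
            rng=np.random.default_rng(15))
        ks = sps.kstest(minima, sps.beta(1, m).cdf)
        assert ks.pvalue > 0.01


class TestBuildHaplotypes:
    @staticmethod
    def _sets(variant_lists):
        return [CredibleSet(f"L{j}", vs, list(np.linspace(0.9, 0.1, len(vs))))
                for j, vs in enumerate(variant_lists)]

    def test_frequencies_sum_to_one_and_reference_most_common(self, rng):
        n = 2000
        G = pd.DataFrame({"a": rng.binomial(1, 0.4, n),
                          "b": rng.binomial(1, 0.3, n)})
        mask = pd.Series(True, index=["a", "b"])
        tab = mito.build_haplotypes(G, self._sets([["a"], ["b"]]), mask)
        assert tab.frequencies.sum() == pytest.approx(1.0)
        assert tab.reference == tab.frequencies.idxmax()
        assert tab.snps == ["a", "b"]
        assert len(tab.frequencies) <= 4

    def test_backbone_recovery(self):
        """One tagging SNP per backbone reconstructs the eight backbones."""
        cfg = SimulationConfig(n_individuals=3000, n_snps=10, n_mtsnps=40,
                               n_traits=9, backbone_mutation_rate=0.0, seed=31)
        cohort = simulate_cohort(cfg)
        G = cohort.mito_genotypes
        # pick SNPs until every backbone has a distinct allele string
        chosen: list[str] = []
        bb = pd.Series(cohort.mito_backbone, index=G.index)
        for c in G.columns:
            chosen.append(c)
            per_bb = G[chosen].groupby(bb).first()
            labels = G[chosen].astype(int).astype(str).agg("".join, axis=1)
            if per_bb.drop_duplicates().shape[0] == per_bb.shape[0]:
                break
        sets = self._sets([[c] for c in chosen])
        mask = pd.Series(True, index=G.columns)
        tab = mito.build_haplotypes(G, sets, mask, maf_floor=0.0)
        # without mutation, haplotype label is a function of the backbone
        table = pd.crosstab(bb, tab.labels)
        assert ((table > 0).sum(axis=1) == 1).all()

    def test_substitution_down_pip_order(self, rng, caplog):
        n = 500
        G = pd.DataFrame({"top": rng.binomial(1, 0.4, n),
                          "second": rng.binomial(1, 0.4, n)})
        cs = CredibleSet("L0", ["top", "second"], [0.8, 0.2])
        mask = pd.Series({"top": False, "second": True})
        with caplog.at_level("INFO"):
            tab = mito.build_haplotypes(G, [cs], mask)
        assert tab.snps == ["second"]
        assert "substituted" in caplog.text

    def test_no_dual_array_member_raises_naming_set(self, rng):
        G = pd.DataFrame({"x": rng.binomial(1, 0.4, 100)})
        cs = CredibleSet("locus_7", ["x"], [1.0])
        mask = pd.Series({"x": False})
        with pytest.raises(ValueError, match="locus_7"):
            mito.build_haplotypes(G, [cs], mask)

    def test_rare_haplotypes_masked(self, rng):
        n = 3000
        a = rng.binomial(1, 0.5, n)
        b = a.copy()
        flip = rng.choice(n, 6, replace=False)  # 6/3000 = 0.002 < 0.005
        b[flip] = 1 - b[flip]
        G = pd.DataFrame({"a": a, "b": b})
        mask = pd.Series(True, index=["a", "b"])
        tab = mito.build_haplotypes(G, self._sets([["a"], ["b"]]), mask)
        assert tab.n_masked == 6
        assert tab.labels.isna().sum() == 6
        assert set(tab.frequencies.index) <= {"00", "11"}
        assert tab.frequencies.sum() == pytest.approx(1.0)


class TestHaplotypeAnova:
    def test_planted_effect_detected_and_recovered(self):
        rng = np.random.default_rng(8)
        n = 5000
        labels = pd.Series(rng.choice(["00", "01", "11"], n, p=[0.5, 0.3, 0.2]),
                           index=pd.RangeIndex(n))
        cov = _cov(rng, n)
        y = pd.Series(0.3 * (labels == "11") + 0.01 * cov["age"]
                      + rng.standard_normal(n))
        p, effects = mito.haplotype_anova(y, _hap_table(labels), cov)
        assert p < 1e-4
        row = effects.set_index("haplotype").loc["11"]
        assert abs(row["beta"] - 0.3) < 3 * row["se"]

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        n, reps = 400, 200
        cov = _cov(rng, n)
        ps = []
        for _ in range(reps):
            labels = pd.Series(rng.choice(["00", "01", "11"], n),
                               index=pd.RangeIndex(n))
            y = pd.Series(rng.standard_normal(n))
            p, _ = mito.haplotype_anova(y, _hap_table(labels), cov)
            ps.append(p)
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_single_level_rejected(self, rng):
        labels = pd.Series(["00"] * 100)
        y = pd.Series(rng.standard_normal(100))
        with pytest.raises(ValueError, match="reference"):
            mito.haplotype_anova(y, _hap_table(labels), _cov(rng, 100))

    def test_lone_carrier_level_merged_to_missing(self, rng, caplog):
        labels = pd.Series(["00"] * 60 + ["11"] * 39 + ["01"])
        y = pd.Series(rng.standard_normal(100))
        with caplog.at_level("WARNING"):
            p, effects = mito.haplotype_anova(y, _hap_table(labels),
                                              _cov(rng, 100))
        assert "carriers" in caplog.text
        assert list(effects["haplotype"]) == ["11"]


class TestCoxMortality:
    @staticmethod
    def _cohort(**kw):
        cfg = SimulationConfig(n_individuals=kw.pop("n", 10_000), n_snps=10,
                               n_mtsnps=10, n_traits=9,
                               baseline_hazard=6e-5, **kw)
        return simulate_cohort(cfg)

    @staticmethod
    def _backbone_haps(cohort):
        labels = pd.Series(
            np.where(cohort.mito_backbone == 1, "1", "0"),
            index=cohort.individuals)
        return _hap_table(labels)

    def test_unknown_mode_rejected(self, rng):
        cohort = self._cohort(n=500, seed=1)
        with pytest.raises(ValueError, match="mode"):
            mito.cox_mortality(self._backbone_haps(cohort), cohort.survival,
                               cohort.covariates[["age", "sex"]],
                               mode="accidental")

    def test_all_external_deaths_rejected(self, rng):
        cohort = self._cohort(n=500, seed=2)
        surv = cohort.survival.copy()
        surv.loc[surv["event"] == 1, "cause"] = "external"
        with pytest.raises(ValueError, match="no events"):
            mito.cox_mortality(self._backbone_haps(cohort), surv,
                               cohort.covariates[["age", "sex"]])

    def test_planted_log_hr_recovered(self):
        cohort = self._cohort(hap_log_hr=0.5, seed=5)
        haps = self._backbone_haps(cohort)
        res = mito.cox_mortality(haps, cohort.survival,
                                 cohort.covariates[["age", "sex"]])
        est = float(res["log_hr"].iloc[0])
        se = float(res["se"].iloc[0])
        assert abs(est - 0.5) < 3 * se
        assert res["global_p"] < 1e-3
        assert float(res["hazard_ratios"].iloc[0]) == pytest.approx(
            np.exp(est))

    def test_event_counts_partition_by_cause(self):
        cohort = self._cohort(n=4000, seed=6)
        haps = self._backbone_haps(cohort)
        cov = cohort.covariates[["age", "sex"]]
        counts = {m: mito.cox_mortality(haps, cohort.survival, cov,
                                        mode=m)["n_events"]
                  for m in ("all", "cancer", "non_cancer")}
        surv = cohort.survival
        by_cause = surv.loc[surv["event"] == 1, "cause"].value_counts()
        assert counts["cancer"] == by_cause.get("cancer", 0)
        assert counts["non_cancer"] == by_cause.get("non_cancer", 0)
        assert counts["all"] == counts["cancer"] + counts["non_cancer"]
        # external deaths are censored in every mode
        assert counts["all"] == int(surv["event"].sum()) - by_cause.get(
            "external", 0)

    def test_null_loglik_matches_lifelines_lr_decomposition(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(30)
        n = 400
        time = rng.exponential(100.0, n)  # continuous: no ties
        event = rng.integers(0, 2, n)
        x = rng.standard_normal(n)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        lrt = cph.log_likelihood_ratio_test()
        ll_null = cph.log_likelihood_ - lrt.test_statistic / 2.0
        ours = mito._null_cox_loglik(time, event)
        assert ours == pytest.approx(ll_null, rel=1e-8)


class TestPruneIndependentSnps:
    def test_redundant_copy_removed_causal_kept(self, rng):
        n = 2000
        v0 = rng.binomial(2, 0.3, n).astype(float)
        v1 = v0 + 0.1 * rng.standard_normal(n)  # near-duplicate of v0
        v2 = rng.binomial(2, 0.3, n).astype(float)
        G = pd.DataFrame({"v0": v0, "v1": v1, "v2": v2})
        traits = pd.DataFrame({"y": 0.5 * v0 + rng.standard_normal(n)})
        kept = mito.prune_independent_snps(G, traits, ["v0", "v1", "v2"])
        assert "v0" in kept
        assert "v2" not in kept

    def test_two_independent_effects_both_kept(self, rng):
        n = 2000
        G = pd.DataFrame(rng.binomial(2, 0.3, (n, 3)).astype(float),
                         columns=["a", "b", "c"])
        traits = pd.DataFrame({
            "y": 0.4 * G["a"] + 0.4 * G["b"] + rng.standard_normal(n)})
        kept = mito.prune_independent_snps(G, traits, ["a", "b", "c"])
        assert set(kept) >= {"a", "b"}
        assert "c" not in kept

    def test_all_null_empties_list(self, rng):
        n = 1000
        G = pd.DataFrame(rng.binomial(2, 0.3, (n, 3)).astype(float),
                         columns=["a", "b", "c"])
        traits = pd.DataFrame({"y": rng.standard_normal(n)})
        assert mito.prune_independent_snps(G, traits, ["a", "b", "c"]) == []
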