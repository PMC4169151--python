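"""Scan statistics, permutation thresholds and forward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isoqtl as q
from isoqtl.encode import GwasDataset, LinkageDataset
from isoqtl.mapping import (MappingError, _permuted_phenotypes, align,
                            empirical_threshold)


def _toy_dataset(n_per_family=40, n_snps=30, families=("A", "B"), seed=0,
                 kind="gwas"):
    """Random 0/1/2 genotypes segregating in every family."""
    rng = np.random.default_rng(seed)
    n = n_per_family * len(families)
    while True:
        codes = rng.choice([0.0, 1.0, 2.0], size=(n, n_snps), p=[0.25, 0.5, 0.25])
        ok = all(
            np.ptp(codes[i * n_per_family:(i + 1) * n_per_family], axis=0).min() > 0
            for i in range(len(families))
        )
        if ok:
            break
    fam = np.repeat(list(families), n_per_family).astype(object)
    lid = np.array([f"l{i}" for i in range(n)], dtype=object)
    smap = q.SnpMap.from_positions({"1": (np.arange(n_snps) + 1) * 1000})
    gm = q.GenotypeMatrix(codes, lid, fam, smap, "gwas" if kind == "gwas" else "linkage")
    if kind == "gwas":
        return GwasDataset(gm)
    seg = {f: np.ones(n_snps, dtype=bool) for f in families}
    return LinkageDataset(gm, seg, [], {})


def _pheno(dataset, y, trait="Y"):
    gm = dataset.matrix
    return pd.DataFrame({"line_id": gm.line_id, "family": gm.family, trait: y})


class TestFitLinear:
    def test_exact_fit_recovers_slope_with_zero_rss(self):
        x = np.arange(10.0)
        fit = q.fit_linear(2.0 * x, x[:, None])
        assert fit.beta[0] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_fits_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = q.fit_linear(y, np.ones((3, 1)))
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        fit = q.fit_linear(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-8)
        np.testing.assert_allclose(fit.rss, ref.ssr, rtol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-6)

    def test_dependent_column_dropped_deterministically(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, x])
        fit = q.fit_linear(x * 3.0, X)
        assert fit.kept.tolist() == [True, True, False]
        assert np.isnan(fit.beta[2])

    def test_zero_residual_df_raises(self):
        with pytest.raises(MappingError):
            q.fit_linear(np.array([1.0, 2.0]), np.eye(2))


class TestAdjustedR2:
    def test_limits_and_hand_computed_case(self):
        assert q.adjusted_r2(1.0, 30, 3) == pytest.approx(1.0)
        assert q.adjusted_r2(0.0, 30, 0) == pytest.approx(0.0)
        # 3-point regression: r2=0.75, n=3, p=1 -> 1 - 0.25*2/1 = 0.5
        assert q.adjusted_r2(0.75, 3, 1) == pytest.approx(0.5)

    def test_undefined_when_saturated(self):
        with pytest.raises(MappingError):
            q.adjusted_r2(0.9, 4, 3)


class TestCandidateTerms:
    def test_gwas_yields_single_column(self):
        ds = _toy_dataset()
        model = q.ModelSpec("gwas", ("A", "B"), "Y", n_perm=50, alpha=0.5)
        data = align(ds, _pheno(ds, np.zeros(80)), model)
        cols, fams = q.candidate_term(0, model, data)
        assert cols.shape == (80, 1) and fams == ("combined",)

    def test_nested_yields_one_column_per_segregating_family(self):
        ds = _toy_dataset(kind="linkage")
        ds.seg["B"][0] = False
        model = q.ModelSpec("joint_linkage", ("A", "B"), "Y", n_perm=50, alpha=0.5)
        data = align(ds, _pheno(ds, np.zeros(80)), model)
        cols, fams = q.candidate_term(0, model, data)
        assert fams == ("A",)
        assert (cols[data.family == "B"] == 0).all()
        cols2, fams2 = q.candidate_term(1, model, data)
        assert fams2 == ("A", "B") and cols2.shape == (80, 2)

    def test_fully_masked_snp_rejected(self):
        ds = _toy_dataset(kind="linkage")
        ds.seg["A"][0] = ds.seg["B"][0] = False
        model = q.ModelSpec("joint_linkage", ("A", "B"), "Y", n_perm=50, alpha=0.5)
        data = align(ds, _pheno(ds, np.zeros(80)), model)
        with pytest.raises(MappingError):
            q.candidate_term(0, model, data)


class TestScan:
    def test_null_pvalues_are_uniform(self):
        ds = _toy_dataset(n_per_family=60, n_snps=400, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=120)
        model = q.ModelSpec("gwas", ("A", "B"), "Y")
        data = align(ds, _pheno(ds, y), model)
        sc = q.scan(data, model)
        ks = stats.kstest(sc.pvalue[sc.tested], "uniform")
        assert ks.pvalue > 0.001

    def test_exact_linear_phenotype_maximizes_causal_statistic(self):
        ds = _toy_dataset(seed=5)
        y = 3.0 * ds.matrix.codes[:, 7]
        model = q.ModelSpec("gwas", ("A", "B"), "Y")
        data = align(ds, _pheno(ds, y), model)
        sc = q.scan(data, model)
        assert np.nanargmax(sc.fstat) == 7

    def test_conditioning_on_causal_snp_removes_linked_signal(self):
        ds = _toy_dataset(seed=6)
        rng = np.random.default_rng(7)
        # SNP 8 is a noisy copy of the causal SNP 7 (tight linkage)
        ds.matrix.codes[:, 8] = ds.matrix.codes[:, 7]
        flip = rng.choice(80, 6, replace=False)
        ds.matrix.codes[flip, 8] = rng.choice([0.0, 1.0, 2.0], size=6)
        y = 2.0 * ds.matrix.codes[:, 7] + rng.normal(size=80)
        model = q.ModelSpec("gwas", ("A", "B"), "Y")
        data = align(ds, _pheno(ds, y), model)
        before = q.scan(data, model)
        cols, _ = q.candidate_term(7, model, data)
        after = q.scan(data, model, [(cols, ("combined",))], exclude=[7])
        assert after.fstat[8] < before.fstat[8]


class TestPermutationNull:
    def test_alpha_one_threshold_is_minimum(self):
        stats_ = np.array([5.0, 1.0, 3.0, 4.0])
        assert empirical_threshold(stats_, 1.0) == 1.0

    def test_threshold_monotone_in_alpha(self):
        ds = _toy_dataset(seed=8)
        rng = np.random.default_rng(9)
        y = rng.normal(size=80)
        thresholds = []
        for alpha in (0.5, 0.1, 0.05, 0.01):
            model = q.ModelSpec("gwas", ("A", "B"), "Y", alpha=alpha,
                                n_perm=400, seed=10)
            data = align(ds, _pheno(ds, y), model)
            null = q.permutation_threshold(data, model)
            thresholds.append(null.threshold)
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))

    def test_permutation_preserves_family_means(self):
        ds = _toy_dataset(seed=11)
        rng = np.random.default_rng(12)
        y = rng.normal(size=80) + np.where(ds.matrix.family == "A", 0.0, 5.0)
        model = q.ModelSpec("gwas", ("A", "B"), "Y", n_perm=50, alpha=0.5, seed=13)
        data = align(ds, _pheno(ds, y), model)
        Y = _permuted_phenotypes(data, 50, model.seed)
        for fam in ("A", "B"):
            rows = data.family_rows(fam)
            np.testing.assert_allclose(Y[rows].mean(axis=0), data.y[rows].mean())

    def test_order_statistic_quantile_rule(self):
        # 1000 permutations at alpha=0.01 -> the 991st order statistic,
        # i.e. the 10th largest maximum
        stats_ = np.random.default_rng(0).permutation(1000).astype(float)
        assert empirical_threshold(stats_, 0.01) == 990.0

    def test_permutation_substreams_are_replayable(self):
        ds = _toy_dataset(seed=30)
        model = q.ModelSpec("gwas", ("A", "B"), "Y", seed=31)
        data = align(ds, _pheno(ds, np.random.default_rng(1).normal(size=80)),
                     model)
        short = _permuted_phenotypes(data, 10, model.seed)
        long = _permuted_phenotypes(data, 25, model.seed)
        np.testing.assert_array_equal(short, long[:, :10])

    def test_small_n_perm_warns(self):
        ds = _toy_dataset(seed=14)
        model = q.ModelSpec("gwas", ("A", "B"), "Y", n_perm=100, alpha=0.01)
        data = align(ds, _pheno(ds, np.random.default_rng(0).normal(size=80)), model)
        with pytest.warns(UserWarning, match="unstable"):
            q.permutation_threshold(data, model)

    def test_independent_of_thread_count(self):
        ds = _toy_dataset(n_per_family=50, n_snps=100, seed=15)
        rng = np.random.default_rng(16)
        y = rng.normal(size=100)
        model = q.ModelSpec("gwas", ("A", "B"), "Y", n_perm=600, seed=17)
        data = align(ds, _pheno(ds, y), model)
        n1 = q.permutation_threshold(data, model, threads=1)
        n3 = q.permutation_threshold(data, model, threads=3)
        np.testing.assert_array_equal(n1.max_stats, n3.max_stats)


class TestForwardSelect:
    def test_infinite_threshold_selects_nothing(self, small_study):
        model = q.ModelSpec("gwas", ("A", "B"), "Y")
        res = q.forward_select(small_study["gwas"], small_study["pheno"], model,
                               threshold=np.inf)
        assert res.n_qtl == 0
        assert set(res.family_coefs) == {"A", "B"}

    def test_noise_free_single_qtl_recovered_exactly(self):
        ds = _toy_dataset(seed=18)
        y = 4.0 * ds.matrix.codes[:, 3] + np.where(ds.matrix.family == "A", 0, 2.0)
        model = q.ModelSpec("gwas", ("A", "B"), "Y", max_steps=3)
        res = q.forward_select(ds, _pheno(ds, y), model, threshold=1e6)
        assert [s.snp_index for s in res.selected] == [3]
        assert res.selected[0].effects["combined"] == pytest.approx(4.0)
        assert res.r2 == pytest.approx(1.0)

    def test_tie_broken_toward_smaller_position(self):
        rng = np.random.default_rng(19)
        col = rng.choice([0.0, 1.0, 2.0], size=40)
        other = rng.choice([0.0, 1.0, 2.0], size=40)
        codes = np.column_stack([other, col, col])
        smap = q.SnpMap.from_positions({"1": [1000, 2000, 3000]})
        gm = q.GenotypeMatrix(codes, np.array([f"l{i}" for i in range(40)], dtype=object),
                              np.array(["A"] * 40, dtype=object), smap, "gwas")
        ds = GwasDataset(gm)
        y = col + rng.normal(size=40) * 0.1
        model = q.ModelSpec("gwas", ("A",), "Y", max_steps=1)
        res = q.forward_select(ds, _pheno(ds, y), model, threshold=-np.inf)
        assert res.selected[0].pos_bp == 2000

    def test_single_family_joint_linkage_equals_biparental(self, small_study):
        jl = q.ModelSpec("joint_linkage", ("B",), "Y", n_perm=100, alpha=0.05,
                         seed=20)
        bp = q.ModelSpec("biparental", ("B",), "Y", n_perm=100, alpha=0.05,
                         seed=20)
        r1 = q.forward_select(small_study["linkage"], small_study["pheno"], jl)
        r2 = q.forward_select(small_study["linkage"], small_study["pheno"], bp)
        assert [s.snp_id for s in r1.selected] == [s.snp_id for s in r2.selected]
        assert r1.r2_adj == r2.r2_adj
        for s1, s2 in zip(r1.selected, r2.selected):
            assert s1.effects == s2.effects

    def test_nested_model_fits_at_least_as_well_as_combined(self, small_study):
        """Handing the GWAS-selected SNPs to the nested parameterization
        cannot fit worse (raw R^2)."""
        model = q.ModelSpec("gwas", ("A", "B"), "Y", n_perm=100, alpha=0.05,
                            seed=21)
        gres = q.forward_select(small_study["gwas"], small_study["pheno"], model)
        assert gres.n_qtl >= 1
        data = align(small_study["gwas"], small_study["pheno"], model)
        base = [np.ones(data.n_lines), (data.family == "B").astype(float)]
        gwas_cols = [data.codes[:, s.snp_index] for s in gres.selected]
        nested_cols = []
        for s in gres.selected:
            for fam in ("A", "B"):
                nested_cols.append(np.where(data.family == fam,
                                            data.codes[:, s.snp_index], 0.0))
        tss = np.sum((data.y - data.y.mean()) ** 2)
        r2_g = 1 - q.fit_linear(data.y, np.column_stack(base + gwas_cols)).rss / tss
        r2_n = 1 - q.fit_linear(data.y, np.column_stack(base + nested_cols)).rss / tss
        assert r2_n >= r2_g - 1e-12

    def test_allelic_series_needs_two_gwas_steps_but_one_nested_step(self):
        """Two family groups with effects 5.3 vs 19.3 at one locus and no
        marker segregating in both groups: the single-effect model needs
        two SNPs, the family-nested model one (fixed seed)."""
        from isoqtl.evaluate import _index_of
        from isoqtl.simulate import allelic_series_scenario, simulate_scenario
        truth, gm, ph = simulate_scenario(allelic_series_scenario(), 21)
        trimmed, _ = q.trim_snps(gm)
        keep = _index_of(gm.snp_map, trimmed.snp_map)
        parents = {f.name: tuple(v[keep] for v in truth.parent_genotypes(f.name))
                   for f in truth.families}
        gwas_ds = q.build_gwas_dataset(trimmed)
        linkage_ds = q.build_linkage_dataset(trimmed, parents)
        fams = tuple("ABCDE")
        jl = q.forward_select(linkage_ds, ph,
                              q.ModelSpec("joint_linkage", fams, "FL",
                                          n_perm=500, seed=21))
        gw = q.forward_select(gwas_ds, ph,
                              q.ModelSpec("gwas", fams, "FL", n_perm=500, seed=21))
        assert jl.n_qtl == 1
        assert gw.n_qtl >= 2
        series = jl.selected[0].effects
        small = np.mean([series["A"], series["B"]])
        large = np.mean([series["C"], series["D"]])
        assert small == pytest.approx(5.3, abs=2.0)
        assert large == pytest.approx(19.3, abs=2.0)


class TestEffectTable:
    def test_gwas_rows_carry_combined_effect_and_state_codes(self, demo_abcde):
        res = demo_abcde.results[("FL", "ABCDE", "gwas")]
        df = q.estimate_effects(res)
        assert {"combined", "state_A", "state_E"} <= set(df.columns)
        assert set(df["step"]) == set(range(1, res.n_qtl + 1))

    def test_nested_rows_mark_nonsegregating_families_ns(self, small_study):
        model = q.ModelSpec("joint_linkage", ("A", "B"), "Y", n_perm=100,
                            alpha=0.05, seed=22)
        res = q.forward_select(small_study["linkage"], small_study["pheno"], model)
        df = q.estimate_effects(res)
        assert res.n_qtl >= 1
        # family A segregates only inside its chr1 introgression: any QTL
        # selected outside it must be NS for A
        for _, row in df.iterrows():
            if row["chrom"] != "1":
                assert row["A"] == "NS"
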