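import numpy as np
import pandas as pd
import pytest

from reductomir import diffexpr
from reductomir.synthetic_data import SimulationConfig, simulate_counts

from conftest import make_count_matrix, make_design


def _fit(cm):
    sf = diffexpr.estimate_size_factors(cm)
    disp = diffexpr.estimate_dispersions(cm, sf)
    return sf, disp


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        design = make_design({"A": 2})
        cm = make_count_matrix([[10, 20], [100, 200], [1, 2]], design)
        sf = diffexpr.estimate_size_factors(cm)
        assert sf.factors.iloc[1] / sf.factors.iloc[0] == pytest.approx(2.0)

    def test_identical_columns_give_equal_factors(self):
        design = make_design({"A": 3})
        cm = make_count_matrix([[5, 5, 5], [9, 9, 9]], design)
        sf = diffexpr.estimate_size_factors(cm)
        assert np.allclose(sf.values, sf.values[0])

    def test_no_always_positive_feature_is_an_error(self):
        design = make_design({"A": 2})
        cm = make_count_matrix([[0, 5], [7, 0]], design)
        with pytest.raises(ValueError, match="nonzero"):
            diffexpr.estimate_size_factors(cm)


class TestDispersions:
    def test_recovers_constant_dispersion(self, rng):
        # 500 features, alpha = 0.1, n = 4/group
        alpha, F = 0.1, 500
        design = make_design({"A": 4, "B": 4})
        mu = rng.lognormal(5.5, 1.0, F)
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (F, 8))
        cm = make_count_matrix(counts, design)
        _, disp = _fit(cm)
        assert 0.07 <= float(disp.final.median()) <= 0.14

    def test_poisson_data_yields_near_zero_dispersion(self, rng):
        design = make_design({"A": 4, "B": 4})
        mu = rng.lognormal(6.0, 0.8, 400)
        counts = rng.poisson(mu[:, None], (400, 8))
        cm = make_count_matrix(counts, design)
        _, disp = _fit(cm)
        assert float(disp.final.median()) <= 0.02

    def test_single_feature_falls_back_to_mle(self, rng):
        design = make_design({"A": 4, "B": 4})
        cm = make_count_matrix(rng.poisson(100, (1, 8)), design)
        sf = diffexpr.estimate_size_factors(cm)
        with pytest.warns(UserWarning, match="single feature"):
            disp = diffexpr.estimate_dispersions(cm, sf)
        assert disp.final.iloc[0] == disp.genewise.iloc[0]


class TestWald:
    def test_null_feature_has_no_signal(self, rng):
        design = make_design({"A": 4, "B": 4})
        counts = np.vstack(
            [rng.poisson(200, (60, 8)), [[150] * 8]]  # constant row: exact null
        )
        cm = make_count_matrix(counts, design)
        sf, disp = _fit(cm)
        res = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))
        last = res.iloc[-1]
        assert abs(last["log2FC"]) < 0.05
        assert last["pvalue"] > 0.5

    def test_consistency_on_large_groups(self, rng):
        # true 4x ratio, n = 50/group, equal library sizes -> the estimator
        # converges to 2 log2 units
        design = make_design({"A": 50, "B": 50})
        F = 60
        base = rng.lognormal(5.5, 0.5, F)
        mu = np.concatenate(
            [np.tile(base, (50, 1)).T, np.tile(4 * base, (50, 1)).T], axis=1
        )
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        cm = make_count_matrix(counts, design)
        sf = diffexpr.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        disp = diffexpr.estimate_dispersions(cm, sf)
        res = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))
        assert float(res["log2FC"].mean()) == pytest.approx(2.0, abs=0.1)

    def test_contrast_antisymmetry(self, rng):
        design = make_design({"A": 3, "B": 3})
        cm = make_count_matrix(rng.poisson(100, (50, 6)), design)
        sf, disp = _fit(cm)
        ab = diffexpr.wald_test(cm, sf, disp, contrast=("A", "B"))
        ba = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))
        np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"], atol=1e-9)
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"], atol=1e-12)

    def test_scale_invariance_of_one_sample(self, rng):
        design = make_design({"A": 3, "B": 3})
        counts = rng.poisson(100, (80, 6))
        cm = make_count_matrix(counts, design)
        scaled = counts.copy()
        scaled[:, 0] *= 3
        cm2 = make_count_matrix(scaled, design)
        sf1, disp1 = _fit(cm)
        sf2 = diffexpr.estimate_size_factors(cm2)
        # the scaled sample's factor grows 3x relative to any other sample
        # (absolute factors shift by the geometric-mean convention)
        r_before = sf1.values[0] / sf1.values[1]
        r_after = sf2.values[0] / sf2.values[1]
        assert r_after / r_before == pytest.approx(3.0, rel=1e-6)
        # normalized counts for the scaled sample are exactly restored
        n1 = diffexpr.normalized_counts(cm, sf1)
        n2 = diffexpr.normalized_counts(cm2, sf2)
        np.testing.assert_allclose(
            n2.iloc[:, 0] / n2.iloc[:, 1], n1.iloc[:, 0] / n1.iloc[:, 1], rtol=1e-9
        )
        # the contrast estimate is only approximately invariant: a count-level
        # ML fit necessarily gives the 3x sample more likelihood weight
        r1 = diffexpr.wald_test(cm, sf1, disp1, contrast=("B", "A"))
        r2 = diffexpr.wald_test(cm2, sf2, disp1, contrast=("B", "A"))
        np.testing.assert_allclose(r1["log2FC"], r2["log2FC"], atol=0.05)

    def test_bonferroni_dominates_p(self, rng):
        design = make_design({"A": 3, "B": 3})
        cm = make_count_matrix(rng.poisson(50, (100, 6)), design)
        sf, disp = _fit(cm)
        res = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A")).dropna(
            subset=["pvalue"]
        )
        assert (res["qvalue_bonferroni"] >= res["pvalue"] - 1e-15).all()
        assert (res["qvalue_bonferroni"] <= 1.0).all()

    def test_separated_feature_is_clamped_not_fatal(self, rng):
        design = make_design({"A": 3, "B": 3})
        counts = rng.poisson(100, (30, 6))
        counts[0, :3] = 0  # group A all zero
        counts[0, 3:] = 500
        cm = make_count_matrix(counts, design)
        sf, disp = _fit(cm)
        res = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))
        row = res.iloc[0]
        assert row["lfc_clamped"]
        assert row["log2FC"] == pytest.approx(10.0)

    def test_all_zero_rows_excluded_from_family(self, rng):
        design = make_design({"A": 3, "B": 3})
        counts = rng.poisson(100, (20, 6))
        counts[5] = 0
        cm = make_count_matrix(counts, design)
        sf, disp = _fit(cm)
        res = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))
        assert np.isnan(res.loc[5, "pvalue"])
        tested = res["pvalue"].notna().sum()
        assert tested == 19
        # Q uses the reduced family size
        ok = res.dropna(subset=["pvalue"])
        np.testing.assert_allclose(
            ok["qvalue_bonferroni"], np.minimum(ok["pvalue"] * 19, 1.0)
        )


class TestAgainstDESeq2:
    def test_log2fc_agrees_with_reference_implementation(self, rng):
        """Cross-check the NB Wald estimates against DESeq2 (via pydeseq2)."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        design = make_design({"A": 4, "B": 4})
        F = 150
        base = rng.lognormal(5.0, 1.0, F)
        fc = 2.0 ** rng.choice([0.0, 1.5, -1.5], F, p=[0.7, 0.15, 0.15])
        mu = np.concatenate(
            [np.tile(base, (4, 1)).T, np.tile(base * fc, (4, 1)).T], axis=1
        )
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        cm = make_count_matrix(counts, design)
        sf, disp = _fit(cm)
        mine = diffexpr.wald_test(cm, sf, disp, contrast=("B", "A"))

        dds = DeseqDataSet(
            counts=pd.DataFrame(
                counts.T, index=design.sample_ids, columns=cm.feature_ids
            ),
            metadata=pd.DataFrame(
                {"condition": ["A"] * 4 + ["B"] * 4}, index=design.sample_ids
            ),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        theirs = ds.results_df

        diff = mine.set_index("feature_id")["log2FC"] - theirs["log2FoldChange"]
        assert float(diff.abs().median()) < 0.05
        corr = np.corrcoef(
            mine.set_index("feature_id")["log2FC"], theirs["log2FoldChange"]
        )[0, 1]
        assert corr > 0.99


class TestFilters:
    def _row(self, q, lfc, csum):
        return pd.DataFrame(
            {
                "feature_id": ["f"],
                "log2FC": [lfc],
                "qvalue_bonferroni": [q],
                "count_sum": [csum],
                "contrast": ["c"],
            }
        )

    @pytest.mark.parametrize(
        "q,lfc,csum,sig,bio",
        [
            (0.01, 1.5, 100.0, True, True),
            (0.01, 0.5, 100.0, True, False),
            (0.20, 1.5, 0.8, False, False),
        ],
    )
    def test_flag_rules(self, q, lfc, csum, sig, bio):
        out = diffexpr.apply_de_filters(self._row(q, lfc, csum), return_all=True)
        assert bool(out["sig_candidate"][0]) is sig
        assert bool(out["bio_flag"][0]) is bio


class TestPCA:
    def test_rank_one_matrix_loads_on_pc1(self):
        # log2(count + 1) is exactly additive: a_i + b_j with integer counts
        design = make_design({"A": 2, "B": 2})
        a, b = np.array([0, 1, 2]), np.array([3, 3, 5, 5])
        counts = (2.0 ** (a[:, None] + b[None, :]) - 1).astype(int)
        cm = make_count_matrix(counts, design)
        sf = diffexpr.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        res = diffexpr.pca_summary(cm, sf)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        design = make_design({"A": 3, "B": 3})
        cm = make_count_matrix(rng.poisson(50, (40, 6)), design)
        sf = diffexpr.estimate_size_factors(cm)
        res = diffexpr.pca_summary(cm, sf)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_groups_separate_on_first_pcs(self):
        cfg = SimulationConfig(
            n_mirna=300,
            n_mrna=50,
            mirna_group_sizes={"NTg": 4, "TgL": 4, "TgH": 4},
            frac_transgene_only=0.2,
            frac_transgene_dose=0.1,
            frac_dose_only=0.1,
            n_are_bearing=0,
            n_reductomir=0,
            n_effector=0,
            n_suppressed_targets=0,
            seed=3,
        )
        cm, _, _ = simulate_counts(cfg)
        sf = diffexpr.estimate_size_factors(cm)
        res = diffexpr.pca_summary(cm, sf, n_components=3)
        groups = cm.design.groups.reindex(res.scores.index)
        centroids = res.scores.groupby(groups.to_numpy()).mean()
        for sid, score in res.scores.iterrows():
            d = ((centroids - score) ** 2).sum(axis=1)
            assert d.idxmin() == groups[sid]


class TestDdct:
    def test_fold_change_rules(self):
        groups = pd.Series({"c1": "ctl", "c2": "ctl", "t1": "trt"})
        ct_ref = pd.Series({"c1": 15.0, "c2": 15.0, "t1": 15.0})
        # control dCt {5, 5}; sample dCt 3 -> ddCt = -2 -> fold 4
        ct_tgt = pd.Series({"c1": 20.0, "c2": 20.0, "t1": 18.0})
        fold = diffexpr.ddct_fold_change(ct_tgt, ct_ref, groups, "ctl")
        assert fold["c1"] == pytest.approx(1.0)  # ddCt = 0
        assert fold["t1"] == pytest.approx(4.0)
        # ddCt = -1 -> fold 2
        fold2 = diffexpr.ddct_fold_change(
            pd.Series({"c1": 20.0, "c2": 20.0, "t1": 19.0}), ct_ref, groups, "ctl"
        )
        assert fold2["t1"] == pytest.approx(2.0)

    def test_missing_control_group_is_an_error(self):
        groups = pd.Series({"t1": "trt"})
        with pytest.raises(ValueError, match="control group"):
            diffexpr.ddct_fold_change(
                pd.Series({"t1": 20.0}), pd.Series({"t1": 15.0}), groups, "ctl"
            )
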