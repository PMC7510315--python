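"""Immune phenotyping, deconvolution, fraction contrasts, eTMB."""

import numpy as np
import pandas as pd
import pytest

import ccrcckit as ck
from ccrcckit import ExpressionMatrix


class TestAssignPhenotypes:
    def test_tier_recovery_and_normal_coclustering(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = ck.SimulationConfig(seed=1)
        X, meta, truth = ck.generate_expression_cohort(cfg)
        phen = ck.assign_immune_phenotypes(X, ck.MARKER_GENES, meta["tissue"].eq("tumor"))
        ari = adjusted_rand_score(truth.immune_tier, phen.labels.loc[truth.immune_tier.index])
        assert ari >= 0.8
        assert (phen.labels[meta["tissue"] == "normal"] == "normal").all()

    def test_score_ordering_definitional(self):
        cfg = ck.SimulationConfig(seed=2)
        X, meta, _ = ck.generate_expression_cohort(cfg)
        phen = ck.assign_immune_phenotypes(X, ck.MARKER_GENES, meta["tissue"].eq("tumor"))
        gm = phen.group_mean_z
        if {"active", "tolerant"} <= set(gm.index):
            assert gm["active"] > gm["tolerant"]
        if {"tolerant", "inactive"} <= set(gm.index):
            assert gm["tolerant"] > gm["inactive"]

    def test_no_normals_fallback_warns(self):
        cfg = ck.SimulationConfig(n_normal=1, seed=3)  # minimum normals
        X, meta, _ = ck.generate_expression_cohort(cfg)
        tumors_only = ExpressionMatrix(X.data[meta.index[meta["tissue"] == "tumor"]])
        flags = pd.Series(True, index=tumors_only.samples)
        with pytest.warns(UserWarning, match="no normal samples"):
            phen = ck.assign_immune_phenotypes(tumors_only, ck.MARKER_GENES, flags)
        assert set(phen.labels.unique()) <= {"active", "tolerant", "inactive"}

    def test_missing_markers_rejected(self, small_config):
        X, meta, _ = ck.generate_expression_cohort(small_config)
        with pytest.raises(ValueError, match="marker"):
            ck.assign_immune_phenotypes(
                X, [f"NOPE{i}" for i in range(66)], meta["tissue"].eq("tumor")
            )

    def test_sample_order_and_scale_invariance(self):
        cfg = ck.SimulationConfig(seed=4)
        X, meta, _ = ck.generate_expression_cohort(cfg)
        flags = meta["tissue"].eq("tumor")
        base = ck.assign_immune_phenotypes(X, ck.MARKER_GENES, flags)
        perm = np.random.default_rng(0).permutation(X.data.shape[1])
        Xp = ExpressionMatrix(X.data.iloc[:, perm])
        permed = ck.assign_immune_phenotypes(Xp, ck.MARKER_GENES, flags.iloc[perm])
        pd.testing.assert_series_equal(
            base.labels.sort_index(), permed.labels.sort_index()
        )
        scaled = ck.assign_immune_phenotypes(
            ExpressionMatrix(X.data * 7.0), ck.MARKER_GENES, flags
        )
        pd.testing.assert_series_equal(base.labels, scaled.labels)


class TestDeconvolution:
    def test_pure_reference_column(self):
        ref = ck.default_reference_profiles(seed=0)
        sample = ExpressionMatrix(ref.data.iloc[:, [2]].rename(columns=lambda c: "S"))
        est = ck.deconvolve_fractions(sample, ref)
        assert est.iloc[0][ref.data.columns[2]] == pytest.approx(1.0, abs=1e-8)
        assert est.iloc[0].drop(ref.data.columns[2]).abs().max() < 1e-8

    def test_noiseless_exact_recovery(self):
        ref = ck.default_reference_profiles(seed=0)
        rng = np.random.default_rng(1)
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(ref.data.shape[1] + 1), size=40)[:, :-1],
            index=[f"S{i}" for i in range(40)], columns=ref.data.columns,
        )
        mix = ck.generate_mixture_profiles(ref, fr, noise_sd=0.0)
        est = ck.deconvolve_fractions(mix, ref)
        assert np.abs(est[fr.columns].to_numpy() - fr.to_numpy()).max() <= 1e-6

    def test_fractions_simplex_invariant(self):
        ref = ck.default_reference_profiles(seed=0)
        rng = np.random.default_rng(2)
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(ref.data.shape[1] + 1), size=20)[:, :-1],
            index=[f"S{i}" for i in range(20)], columns=ref.data.columns,
        )
        sig = ref.values[ref.values > 1].mean()
        mix = ck.generate_mixture_profiles(ref, fr, noise_sd=0.2 * sig, seed=3)
        est = ck.deconvolve_fractions(mix, ref)
        assert (est.to_numpy() >= 0).all()
        assert np.allclose(est.sum(axis=1), 1.0)

    def test_collinear_reference_named(self):
        ref = ck.default_reference_profiles(seed=0)
        dup = ref.data.copy()
        dup["CAFs"] = dup["Macrophages"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ck.deconvolve_fractions(
                ExpressionMatrix(ref.data.iloc[:, [0]].rename(columns=lambda c: "S")),
                ExpressionMatrix(dup),
            )

    def test_insufficient_shared_genes(self):
        ref = ck.default_reference_profiles(seed=0)
        sample = ExpressionMatrix(
            ref.data.iloc[:10, [0]].rename(columns=lambda c: "S")
        )
        with pytest.raises(ValueError, match="shared"):
            ck.deconvolve_fractions(sample, ref)


class TestCompareFractions:
    def _fracs(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        cols = list(ck.DEFAULT_CELL_TYPES) + ["other"]
        vals = rng.dirichlet(np.ones(len(cols)), size=n)
        return pd.DataFrame(vals, index=[f"S{i}" for i in range(n)], columns=cols)

    def test_identical_groups_zero_logratio(self):
        fr = self._fracs()
        dup = pd.concat([fr, fr.rename(index=lambda s: s + "_dup")])
        comp = ck.compare_fractions(
            dup, list(fr.index), [s + "_dup" for s in fr.index]
        )
        assert np.allclose(comp.table["log10_ratio"], 0.0)
        assert (comp.table["flag"] == "ns").all()

    def test_planted_elevation_flagged(self):
        fr = self._fracs(seed=1)
        fr2 = fr.copy()
        boosted = fr2.loc[: "S19", "Macrophages"] * 2.5
        fr2.loc[: "S19", "Macrophages"] = boosted
        comp = ck.compare_fractions(fr2, [f"S{i}" for i in range(20)],
                                    [f"S{i}" for i in range(20, 40)])
        row = comp.table.loc["Macrophages"]
        assert row["flag"] == "elevated" and row["log10_ratio"] > 0

    def test_overlapping_groups_rejected(self):
        fr = self._fracs()
        with pytest.raises(ValueError, match="disjoint"):
            ck.compare_fractions(fr, ["S0", "S1"], ["S1", "S2"])

    def test_zero_mean_warns(self):
        fr = self._fracs()
        fr.loc[:, "NKcells"] = 0.0
        with pytest.warns(UserWarning, match="zero group mean"):
            comp = ck.compare_fractions(fr, [f"S{i}" for i in range(20)],
                                        [f"S{i}" for i in range(20, 40)])
        assert np.isnan(comp.table.loc["NKcells", "log10_ratio"])


class TestEtmb:
    def test_self_correlation(self):
        etmb = pd.Series([3, 10, 54, 20, 7], index=[f"S{i}" for i in range(5)])
        fr = pd.DataFrame({"CD8_Tcells": etmb / 100.0})
        r = ck.correlate_etmb(etmb, fr)
        assert r["CD8_Tcells"] == pytest.approx(1.0)

    def test_too_few_samples_refused(self):
        etmb = pd.Series([1, 2], index=["a", "b"])
        fr = pd.DataFrame({"x": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            ck.correlate_etmb(etmb, fr)

    def test_constant_etmb_refused(self):
        etmb = pd.Series([0, 0, 0], index=["a", "b", "c"])
        fr = pd.DataFrame({"x": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            ck.correlate_etmb(etmb, fr)

    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(3)
        n = 50
        load = rng.poisson(50, size=n).astype(float)
        frac = 0.002 * load + rng.normal(scale=0.03, size=n)
        target = np.corrcoef(load, frac)[0, 1]
        etmb = pd.Series(load, index=[f"S{i}" for i in range(n)])
        fr = pd.DataFrame({"CD8_Tcells": frac}, index=etmb.index)
        r = ck.correlate_etmb(etmb, fr)["CD8_Tcells"]
        assert abs(r - target) < 1e-12

    def test_counts_from_matched_normal_filtering(self, make_record):
        tumor = [make_record(sample_id="T1", pos=p) for p in (1, 2, 3)]
        normals = {"T1": [make_record(sample_id="T1N", pos=2)]}
        kept, _ = ck.run_filter_cascade(tumor, ["VHL"], normals)
        etmb = ck.estimate_etmb(kept, ["T1"])
        assert etmb["T1"] == 2
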