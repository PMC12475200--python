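import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from ecostate import deconvolution as dc
from ecostate import simulate


def constrained_ls_fractions(bulk, sig):
    """Independent oracle: per-sample non-negative least squares on the
    signature, normalized to a simplex."""
    shared = [g for g in sig.index if g in bulk.index]
    A = sig.loc[shared].to_numpy()
    out = []
    for s in bulk.columns:
        beta, _ = nnls(A, bulk.loc[shared, s].to_numpy())
        out.append(beta / beta.sum())
    return pd.DataFrame(out, index=bulk.columns, columns=sig.columns)


class TestSignatureMatrix:
    def test_marker_fold_changes_recomputed(self, panel, signature):
        vals = signature.values
        for t, markers in signature.markers_by_type.items():
            sub = panel.base_profiles.loc[markers]
            fold = sub[t] / sub.drop(columns=[t]).max(axis=1)
            assert fold.iloc[0] >= 8.0
            assert (fold > 1.0).all()
            assert len(markers) >= 10

    def test_each_type_is_row_max_on_its_markers(self, signature):
        for t, markers in signature.markers_by_type.items():
            assert (signature.values.loc[markers].idxmax(axis=1) == t).all()

    def test_identical_types_rejected(self, panel):
        prof = panel.base_profiles[["B", "CD4T"]].copy()
        prof["B2"] = prof["B"]
        with pytest.raises(ValueError, match="B"):
            dc.build_signature_matrix(prof)

    def test_deterministic(self, panel):
        a = dc.build_signature_matrix(panel.base_profiles)
        b = dc.build_signature_matrix(panel.base_profiles)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestSvrDeconvolve:
    def test_two_type_mixture_matches_ls_oracle(self, panel, signature):
        sig = signature.values
        mix = 0.3 * sig["B"] + 0.7 * sig["CD8T"]
        bulk = pd.DataFrame({"m1": mix / mix.sum() * 1e6}, index=sig.index)
        est = dc.svr_deconvolve(bulk, signature)
        oracle = constrained_ls_fractions(bulk, sig)
        assert abs(est.loc["m1", "B"] - 0.3) <= 0.01
        assert abs(est.loc["m1", "CD8T"] - 0.7) <= 0.01
        assert np.abs(est.to_numpy() - oracle.to_numpy()).mean() <= 0.01

    def test_pure_sample_recovered(self, panel, signature):
        bulk = pd.DataFrame({"pure": panel.base_profiles["Treg"]})
        est = dc.svr_deconvolve(bulk, signature)
        assert est.loc["pure", "Treg"] >= 0.99
        assert est.drop(columns=["Treg"]).loc["pure"].max() <= 0.01

    def test_benign_mixture_has_no_lp_signal(self, panel, signature):
        benign = simulate.generate_benign_cohort(panel, 10, seed=21)
        est = dc.svr_deconvolve(benign, signature)
        assert (est["LP"] < 0.005).all()

    def test_invariant_to_tpm_rescaling(self, noiseless_cohort, signature):
        expr, _ = noiseless_cohort
        sub = expr.iloc[:, :5]
        a = dc.svr_deconvolve(sub, signature)
        b = dc.svr_deconvolve(sub * 3.7, signature)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_rows_are_simplexes(self, noiseless_cohort, signature):
        expr, _ = noiseless_cohort
        est = dc.svr_deconvolve(expr.iloc[:, :8], signature)
        assert np.allclose(est.sum(axis=1), 1.0, atol=1e-9)
        assert (est.to_numpy() >= 0).all()

    def test_low_gene_overlap_rejected(self, noiseless_cohort, signature):
        expr, _ = noiseless_cohort
        few = expr.iloc[: len(expr) // 20]
        with pytest.raises(ValueError, match="50%"):
            dc.svr_deconvolve(few, signature)

    def test_all_zero_sample_rejected(self, signature):
        bulk = pd.DataFrame({"z": np.zeros(len(signature.values))}, index=signature.values.index)
        with pytest.raises(ValueError, match="zero"):
            dc.svr_deconvolve(bulk, signature)


class TestComposeTwoTier:
    def test_worked_example(self):
        fine = pd.DataFrame({"B": [0.6], "T": [0.4]}, index=["s1"])
        coarse = pd.DataFrame(
            {"immune": [0.5], "endothelial": [0.2], "fibroblast": [0.3]}, index=["s1"]
        )
        out = dc.compose_two_tier(fine, coarse)
        assert out.loc["s1"].to_dict() == pytest.approx(
            {"B": 0.3, "T": 0.2, "endothelial": 0.2, "fibroblast": 0.3}
        )
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("immune", [1.0, 0.0])
    def test_degenerate_immune_fraction(self, immune):
        fine = pd.DataFrame({"B": [0.6], "T": [0.4]}, index=["s1"])
        coarse = pd.DataFrame({"immune": [immune], "fibroblast": [1 - immune]}, index=["s1"])
        out = dc.compose_two_tier(fine, coarse)
        assert out.loc["s1", "B"] == pytest.approx(0.6 * immune)
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_row_sums_preserved_on_random_simplexes(self):
        rng = np.random.default_rng(0)
        fine = pd.DataFrame(rng.dirichlet(np.ones(5), size=20))
        coarse = pd.DataFrame(
            rng.dirichlet(np.ones(3), size=20), columns=["immune", "fibroblast", "endothelial"]
        )
        out = dc.compose_two_tier(fine, coarse)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_sample_mismatch_rejected(self):
        fine = pd.DataFrame({"B": [1.0]}, index=["s1"])
        coarse = pd.DataFrame({"immune": [1.0]}, index=["s2"])
        with pytest.raises(ValueError):
            dc.compose_two_tier(fine, coarse)


class TestPoolLineages:
    def test_members_summed(self):
        frac = pd.DataFrame({"CD4 naive": [0.1], "CD4 memory": [0.2], "B": [0.7]})
        out = dc.pool_lineages(frac, {"CD4 naive": "CD4T", "CD4 memory": "CD4T", "B": "B"})
        assert out.loc[0, "CD4T"] == pytest.approx(0.3)
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_identity_map_unchanged(self, noiseless_cohort, signature):
        frac = pd.DataFrame({"B": [0.4], "LP": [0.6]})
        out = dc.pool_lineages(frac, {"B": "B", "LP": "LP"})
        pd.testing.assert_frame_equal(out[frac.columns], frac)

    def test_missing_mapping_rejected(self):
        with pytest.raises(ValueError, match="B"):
            dc.pool_lineages(pd.DataFrame({"B": [1.0]}), {})


class TestFilterVariants:
    @pytest.mark.parametrize(
        "row,kept",
        [
            (("tumor", 4, 0.031, False), True),
            (("tumor", 3, 0.5, False), False),
            (("tumor", 10, 0.03, False), False),
            (("plasma", 10, 0.002, False), False),
            (("plasma", 10, 0.002, True), True),
            (("plasma", 4, 0.0009, True), False),
        ],
    )
    def test_read_and_vaf_rules(self, row, kept):
        comp, reads, vaf, duplex = row
        gt = pd.DataFrame(
            {
                "sample_id": ["s"],
                "variant_id": ["v"],
                "vaf": [vaf],
                "supporting_reads": [reads],
                "duplex_support": [duplex],
                "compartment": [comp],
            }
        )
        assert (len(dc.filter_variants(gt)) == 1) is kept


class TestGenotypeAnchor:
    @staticmethod
    def _frac_and_gt(ratio, n=6):
        rng = np.random.default_rng(0)
        cf = rng.uniform(0.005, 0.02, size=n)
        lp_est = ratio * cf
        frac = pd.DataFrame(
            {"LP": lp_est, "B": (1 - lp_est) * 0.6, "CD4T": (1 - lp_est) * 0.4},
            index=[f"s{i}" for i in range(n)],
        )
        gt = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "variant_id": [f"v{i}" for i in range(n)],
                "vaf": cf / 2.0,
                "supporting_reads": 10,
                "duplex_support": True,
                "compartment": "plasma",
            }
        )
        return frac, gt

    def test_constructed_16_67_ratio_recovered_exactly(self):
        frac, gt = self._frac_and_gt(16.67)
        scaled, fit = dc.genotype_anchor_scale(frac, gt)
        assert fit.scale_factor == pytest.approx(16.67, rel=1e-9)
        assert fit.scale_factor * fit.slope == pytest.approx(1.0)

    def test_unit_slope_leaves_lp_unchanged(self):
        frac, gt = self._frac_and_gt(1.0)
        scaled, fit = dc.genotype_anchor_scale(frac, gt)
        assert fit.scale_factor == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(scaled["LP"], frac["LP"], atol=1e-12)

    def test_idempotent_after_one_application(self):
        frac, gt = self._frac_and_gt(16.67)
        scaled, _ = dc.genotype_anchor_scale(frac, gt)
        _, fit2 = dc.genotype_anchor_scale(scaled, gt)
        assert fit2.slope == pytest.approx(1.0, rel=1e-9)

    def test_rows_stay_simplexes(self):
        frac, gt = self._frac_and_gt(16.67)
        scaled, _ = dc.genotype_anchor_scale(frac, gt)
        assert np.allclose(scaled.sum(axis=1), 1.0, atol=1e-12)

    def test_too_few_pairs_rejected(self):
        frac, gt = self._frac_and_gt(16.67, n=2)
        with pytest.raises(ValueError, match="pairs"):
            dc.genotype_anchor_scale(frac, gt)

    def test_recovers_planted_inflation_on_synthetic_cohort(
        self, panel, noiseless_cohort, signature
    ):
        expr, truth = noiseless_cohort
        frac = dc.svr_deconvolve(expr, signature)
        gt = dc.filter_variants(
            simulate.generate_genotype_table(truth, vaf_noise_sd=0.0, seed=3)
        )
        scaled, fit = dc.genotype_anchor_scale(frac, gt)
        assert abs(fit.scale_factor - truth.inflation_factor) / truth.inflation_factor <= 0.05


class TestImputeCellTypeGeps:
    def test_exact_linear_mixture_recovers_profiles(self):
        rng = np.random.default_rng(1)
        n_s, n_g, n_t = 30, 60, 3
        F = rng.dirichlet(np.ones(n_t), size=n_s)
        G = rng.uniform(1, 50, size=(n_g, n_t))
        bulk = pd.DataFrame(
            (F @ G.T).T, index=[f"g{i}" for i in range(n_g)], columns=[f"s{i}" for i in range(n_s)]
        )
        frac = pd.DataFrame(F, index=bulk.columns, columns=["A", "B", "C"])
        res = dc.impute_celltype_geps(bulk, frac, min_genes=10)
        for j, t in enumerate(["A", "B", "C"]):
            got = res.geps[t]
            want = G[[int(g[1:]) for g in got.index], j][:, None]
            assert np.allclose(got.to_numpy(), np.broadcast_to(want, got.shape), rtol=1e-6)

    def test_absent_type_excluded(self):
        rng = np.random.default_rng(2)
        F = rng.dirichlet(np.ones(2), size=20)
        F = np.column_stack([F, np.zeros(20)])
        G = rng.uniform(1, 50, size=(80, 3))
        bulk = pd.DataFrame(
            (F @ G.T).T, index=[f"g{i}" for i in range(80)], columns=[f"s{i}" for i in range(20)]
        )
        frac = pd.DataFrame(F, index=bulk.columns, columns=["A", "B", "absent"])
        res = dc.impute_celltype_geps(bulk, frac)
        assert "absent" in res.excluded_types

    def test_constant_gene_gets_group_estimate_everywhere(self):
        rng = np.random.default_rng(3)
        F = rng.dirichlet(np.ones(2), size=15)
        bulk = pd.DataFrame(
            np.vstack([np.full(15, 7.0), rng.uniform(1, 9, size=(60, 15))]),
            index=[f"g{i}" for i in range(61)],
            columns=[f"s{i}" for i in range(15)],
        )
        frac = pd.DataFrame(F, index=bulk.columns, columns=["A", "B"])
        res = dc.impute_celltype_geps(bulk, frac, min_genes=5)
        for t in res.geps:
            if "g0" in res.geps[t].index:
                row = res.geps[t].loc["g0"]
                assert row.std() == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_fractions_rejected(self):
        F = np.tile([0.5, 0.5], (10, 1))
        bulk = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 9, size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(10)],
        )
        frac = pd.DataFrame(F, index=bulk.columns, columns=["A", "B"])
        with pytest.raises(ValueError, match="rank"):
            dc.impute_celltype_geps(bulk, frac)
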