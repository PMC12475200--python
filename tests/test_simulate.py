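import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from ecostate import simulate
from ecostate.simulate import CellTypeSpec


class TestReferencePanel:
    def test_deterministic_under_fixed_seed(self, panel):
        again = simulate.generate_reference_panel(
            1200, simulate.default_cell_type_spec(), seed=7
        )
        pd.testing.assert_frame_equal(panel.base_profiles, again.base_profiles)
        for t in panel.cell_types:
            pd.testing.assert_frame_equal(panel.state_programs[t], again.state_programs[t])

    def test_marker_genes_exceed_other_types_by_requested_fold(self, panel):
        bp = panel.base_profiles
        for t in panel.cell_types:
            sub = bp.loc[panel.marker_genes[t]]
            fold = sub[t] / sub.drop(columns=[t]).max(axis=1)
            assert len(sub) >= 20
            assert (fold >= 8.0).all()

    def test_marker_submatrix_condition_number_finite(self, panel):
        genes = [g for t in panel.cell_types for g in panel.marker_genes[t]]
        cond = np.linalg.cond(panel.base_profiles.loc[genes].to_numpy())
        assert np.isfinite(cond)

    def test_state_programs_have_unit_geometric_mean(self, panel):
        for t in panel.cell_types:
            for col in panel.state_programs[t]:
                assert gmean(panel.state_programs[t][col]) == pytest.approx(1.0, abs=1e-9)

    def test_state_programs_distinguishable_on_program_genes(self, panel):
        for t in panel.cell_types:
            progs = panel.state_programs[t]
            genes = sorted({g for bl in panel.program_genes[t] for g in bl})
            sub = progs.loc[genes]
            corr = sub.corr()
            off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
            assert (off < 0.5).all()

    @pytest.mark.parametrize(
        "spec_err",
        [
            [("A", 5, 1.0), ("LP", 3, 16.67)],
            [("A", 1, 1.0), ("LP", 3, 16.67)],
            [("A", 2, 1.0), ("A", 2, 1.0), ("LP", 3, 16.67)],
            [("A", 2, 1.0), ("B", 2, 1.0)],
        ],
        ids=["k_too_high", "k_too_low", "duplicate_names", "no_lp"],
    )
    def test_invalid_specs_rejected(self, spec_err):
        with pytest.raises(ValueError):
            simulate.generate_reference_panel(1000, spec_err, seed=0)

    def test_small_gene_count_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_reference_panel(
                199, [CellTypeSpec("A", 2), CellTypeSpec("LP", 3, 16.67)], seed=0
            )


class TestBulkCohort:
    def test_fraction_rows_are_simplexes(self, noiseless_cohort):
        _, truth = noiseless_cohort
        assert np.allclose(truth.cell_fractions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(truth.expression_fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (truth.cell_fractions.to_numpy() >= 0).all()

    def test_columns_tpm_normalized(self, noiseless_cohort):
        expr, _ = noiseless_cohort
        assert np.allclose(expr.sum(axis=0), 1e6, atol=1.0)

    def test_expression_fraction_identity(self, panel, noiseless_cohort):
        _, truth = noiseless_cohort
        rna = panel.rna_content.reindex(truth.cell_fractions.columns).to_numpy()
        num = truth.cell_fractions.to_numpy() * rna
        expected = num / num.sum(axis=1, keepdims=True)
        assert np.allclose(truth.expression_fractions.to_numpy(), expected, atol=1e-12)

    def test_noiseless_mixture_is_exactly_linear(self, panel, eco_map):
        expr, truth = simulate.generate_bulk_cohort(
            panel, 3, 3, eco_map, noise_model=None, seed=5
        )
        s = expr.columns[0]
        ef = truth.expression_fractions.loc[s]
        manual = np.zeros(len(panel.gene_ids))
        for t in panel.cell_types:
            st = truth.state_labels.loc[s, t]
            manual += ef[t] * (
                panel.base_profiles[t].to_numpy()
                * panel.state_programs[t].to_numpy()[:, st]
            )
        manual = manual / manual.sum() * 1e6
        assert np.allclose(expr[s].to_numpy(), manual, rtol=1e-12)

    def test_lp_inflation_matches_closed_form(self, panel, eco_map):
        # expression fraction = r*cf / (1 + (r-1)*cf) when other types have
        # unit RNA content
        _, truth = simulate.generate_bulk_cohort(
            panel, 20, 3, eco_map, noise_model=None, seed=9
        )
        r = panel.rna_content["LP"]
        cf = truth.cell_fractions["LP"].to_numpy()
        expected = r * cf / (1.0 + (r - 1.0) * cf)
        assert np.allclose(truth.expression_fractions["LP"].to_numpy(), expected, atol=1e-12)

    def test_same_seed_bit_identical(self, panel, eco_map):
        a = simulate.generate_bulk_cohort(panel, 10, 3, eco_map, seed=3)
        b = simulate.generate_bulk_cohort(panel, 10, 3, eco_map, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1].state_labels, b[1].state_labels)

    def test_preconditions(self, panel, eco_map):
        with pytest.raises(ValueError):
            simulate.generate_bulk_cohort(panel, 10, 1, eco_map, seed=0)
        with pytest.raises(ValueError):
            simulate.generate_bulk_cohort(
                panel, 10, 3, eco_map, lp_cell_fraction_range=(0.05, 0.2), seed=0
            )
        bad_map = {1: {"CD4T": 9}, 2: {"CD4T": 0}}
        with pytest.raises(ValueError):
            simulate.generate_bulk_cohort(panel, 10, 2, bad_map, seed=0)


class TestGenotypes:
    def test_noise_free_vafs_are_half_lp_fraction(self, noiseless_cohort):
        _, truth = noiseless_cohort
        gt = simulate.generate_genotype_table(truth, vaf_noise_sd=0.0, seed=3)
        real = gt[gt["variant_id"].str.contains("_var")]
        med = real.groupby("sample_id")["vaf"].median()
        for s, cf in truth.cell_fractions["LP"].items():
            assert 2.0 * med[s] == pytest.approx(cf, rel=1e-12)

    def test_reproducible(self, noiseless_cohort):
        _, truth = noiseless_cohort
        a = simulate.generate_genotype_table(truth, seed=11)
        b = simulate.generate_genotype_table(truth, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_noise_rejected(self, noiseless_cohort):
        with pytest.raises(ValueError):
            simulate.generate_genotype_table(noiseless_cohort[1], vaf_noise_sd=-0.1)


class TestSpatialGrid:
    def test_reproducible_and_shapes(self, panel, eco_map):
        regions = np.ones((6, 6), dtype=int)
        regions[:, 3:] = 2
        a = simulate.generate_spatial_grid(panel, (6, 6), regions, eco_map, seed=4)
        b = simulate.generate_spatial_grid(panel, (6, 6), regions, eco_map, seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.counts.shape == (36, 1200)
        assert not a.coordinates.duplicated().any()
        assert (a.counts.to_numpy() >= 0).all()

    def test_unlabeled_cell_rejected(self, panel, eco_map):
        regions = np.ones((4, 4), dtype=int)
        regions[0, 0] = 0
        with pytest.raises(ValueError):
            simulate.generate_spatial_grid(panel, (4, 4), regions, eco_map, seed=0)


class TestClonotypes:
    def test_zero_entropy_gives_single_clonotype(self):
        t = simulate.generate_clonotype_tables(2, ["g", "g"], {"g": 0.0}, 500, seed=1)
        assert (t.groupby("sample_id").size() == 1).all()

    def test_max_entropy_gives_uniform_counts(self):
        K = 200
        t = simulate.generate_clonotype_tables(
            1, ["g"], {"g": math.log(K)}, K, entropy_jitter_sd=0.0, seed=1
        )
        counts = t["count"].to_numpy()
        assert len(counts) == K
        assert counts.max() - counts.min() <= 1

    def test_realized_entropy_hits_target(self):
        from ecostate.repertoire import shannon_entropy

        t = simulate.generate_clonotype_tables(
            4, ["g"] * 4, {"g": 2.0}, 1000, seed=2
        )
        for _, grp in t.groupby("sample_id"):
            assert abs(shannon_entropy(grp["count"]) - 2.0) <= 0.1

    def test_target_outside_feasible_range_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_clonotype_tables(1, ["g"], {"g": 10.0}, 100, seed=0)


class TestSurvival:
    def test_high_risk_ecotype_shortens_survival(self, noisy_cohort):
        _, truth = noisy_cohort
        surv = simulate.generate_survival(
            truth, baseline_hazard=0.02, log_hr_per_unit_ecotype3=2.5,
            censor_rate=0.0, seed=8,
        )
        hi = surv[surv["LPE3"] > 0.5]["time_months"]
        lo = surv[surv["LPE3"] < 0.2]["time_months"]
        assert hi.median() < lo.median()

    def test_abundances_are_simplex_and_reproducible(self, noisy_cohort):
        _, truth = noisy_cohort
        a = simulate.generate_survival(truth, seed=5)
        b = simulate.generate_survival(truth, seed=5)
        pd.testing.assert_frame_equal(a, b)
        cols = [c for c in a.columns if c.startswith("LPE")]
        assert np.allclose(a[cols].sum(axis=1), 1.0, atol=1e-9)
        assert (a["time_months"] > 0).all()

    def test_censor_rate_precondition(self, noisy_cohort):
        with pytest.raises(ValueError):
            simulate.generate_survival(noisy_cohort[1], censor_rate=1.0)
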