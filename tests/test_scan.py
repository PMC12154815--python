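"""Association scan: OLS oracle equivalence, thresholds, leads, locations,
fold change, additive SV model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from guqtl import (
    PlantedEffect,
    SimulationTruth,
    additive_sv_check,
    classify_location,
    fit_association,
    fold_change,
    make_annotation,
    run_scan,
    select_lead,
    simulate_genotypes,
    two_haplotype_block,
)
from guqtl.simulate import BlockSpec, gene_feature_position, simulate_usage_matrix


class TestFitAssociation:
    def test_closed_form_slope(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0.10, 0.12, 0.20, 0.22, 0.30, 0.32])
        res = fit_association(y, x)
        assert res.beta == pytest.approx(0.100, abs=1e-12)

    def test_constant_usage_row(self):
        res = fit_association(np.full(6, 0.2), np.array([0, 1, 2, 0, 1, 2.0]))
        assert res.beta == 0.0
        assert res.adj_r2 == 0.0
        assert res.p == 1.0

    def test_constant_dosage_flagged_untestable(self):
        res = fit_association(np.array([0.1, 0.2, 0.3]), np.ones(3))
        assert not res.testable

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            fit_association(np.array([0.1, 0.2]), np.array([0.0, 1.0]))

    def test_matches_statsmodels_oracle_on_random_fixtures(self):
        """Closed-form OLS agrees with the normal-equations solver in
        statsmodels to 1e-12 on beta, SE, t, P and adjusted R2."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(x) == 0:
                x[0] += 1
            y = 0.2 + rng.normal(0, 0.05, n) + rng.normal() * 0.03 * x
            res = fit_association(y, x)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert res.beta == pytest.approx(fit.params[1], abs=1e-12)
            assert res.se == pytest.approx(fit.bse[1], abs=1e-12)
            assert res.t == pytest.approx(fit.tvalues[1], abs=1e-9)
            assert res.p == pytest.approx(fit.pvalues[1], abs=1e-12)
            assert res.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-12)


class TestAdjustedAndTransformed:
    def test_covariate_adjustment_matches_statsmodels(self):
        rng = np.random.default_rng(55)
        n = 80
        x = rng.integers(0, 3, size=n).astype(float)
        z = rng.normal(size=(n, 2))
        y = 0.1 + 0.02 * x + 0.05 * z[:, 0] + rng.normal(0, 0.03, n)
        res = fit_association(y, x, covariates=z)
        design = sm.add_constant(np.column_stack([x, z]))
        fit = sm.OLS(y, design).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_transforms_are_monotone_and_default_off(self):
        from guqtl.scan import transform_usage

        y = np.array([[0.1, 0.2, 0.05, 0.4]])
        assert transform_usage(y, None) is y
        logit = transform_usage(y, "logit")
        rank = transform_usage(y, "rankint")
        order = np.argsort(y[0])
        assert (np.argsort(logit[0]) == order).all()
        assert (np.argsort(rank[0]) == order).all()
        with pytest.raises(ValueError):
            transform_usage(y, "sqrt")


class TestRunScan:
    def test_threshold_from_effective_tests(self, planted_cohort):
        blocks, truth = planted_cohort
        gt = simulate_genotypes(blocks[:4], None, 50, seed=1)
        usage = simulate_usage_matrix(gt, SimulationTruth(
            genes=["A", "B"], mu={"A": 0.0, "B": 0.0}, sigma=0.1), seed=1)
        ld_groups = [["g1"], ["g2"], ["g3"], ["g4"]]
        scan = run_scan(usage, gt, ld_groups=ld_groups)
        assert scan.threshold == pytest.approx(0.05 / 4)
        assert scan.n_effective_tests == 4

    def test_threshold_invariant_to_duplicated_variant(self):
        """Adding a variant in perfect LD with an existing one does not
        change the Bonferroni denominator."""
        gt1 = simulate_genotypes([two_haplotype_block("b", [100])], None, 80, seed=2)
        gt2 = simulate_genotypes([two_haplotype_block("b", [100, 105])], None, 80, seed=2)
        genes = ["A", "B"]
        truth = SimulationTruth(genes=genes, mu={g: 0.0 for g in genes}, sigma=0.1)
        u1 = simulate_usage_matrix(gt1, truth, seed=3)
        u2 = simulate_usage_matrix(gt2, truth, seed=3)
        s1 = run_scan(u1, gt1)
        s2 = run_scan(u2, gt2)
        assert s1.threshold == s2.threshold

    def test_results_invariant_to_sample_and_variant_order(self, planted_cohort):
        blocks, truth = planted_cohort
        gt = simulate_genotypes(blocks, None, 100, seed=5)
        usage = simulate_usage_matrix(gt, truth, seed=5)
        scan = run_scan(usage, gt)
        perm = list(np.random.default_rng(0).permutation(gt.individuals))
        gt_p = gt.subset_individuals(perm)
        usage_p = type(usage)(
            frequencies=usage.frequencies[perm],
            counts=usage.counts[perm],
            sample_totals=usage.sample_totals[perm],
        )
        scan_p = run_scan(usage_p, gt_p)
        a = scan.results.set_index(["gene", "variant_id"])["p"]
        b = scan_p.results.set_index(["gene", "variant_id"])["p"]
        pd.testing.assert_series_equal(a, b.reindex(a.index), atol=1e-12, rtol=0)

    def test_planted_effect_recovered_with_correct_sign(self, planted_cohort):
        blocks, truth = planted_cohort
        gt = simulate_genotypes(blocks, None, 200, seed=8)
        usage = simulate_usage_matrix(gt, truth, seed=8)
        scan = run_scan(usage, gt)
        for i, gene in enumerate(truth.genes):
            res = scan.gene_results(gene)
            best = res.loc[res["p"].idxmin()]
            assert best["variant_id"] == f"v{i:02d}_v1"
            assert best["beta"] > 0


class TestSelectLead:
    def _results(self, rows):
        return pd.DataFrame(
            [
                {"gene": "g", "variant_id": v, "n": 50, "beta": b, "se": 0.1,
                 "t": 1.0, "p": p, "adj_r2": 0.1, "partition": "unmutated",
                 "testable": True}
                for v, b, p in rows
            ]
        )

    def test_unique_minimum(self):
        lead = select_lead(self._results([("v1", 0.1, 1e-8), ("v2", 0.1, 1e-4)]), 0.01)
        assert lead.variants == ["v1"]
        assert lead.significant

    def test_perfect_ld_ties_all_reported(self):
        lead = select_lead(self._results([("v1", 0.1, 1e-8), ("v2", 0.1, 1e-8)]), 0.01)
        assert lead.variants == ["v1", "v2"]

    def test_no_significant_results_flagged(self):
        lead = select_lead(self._results([("v1", 0.1, 0.5)]), 0.01)
        assert not lead.significant
        assert lead.variants == []


@pytest.fixture(scope="module")
def location_setup():
    genes = ["gA", "gB"]
    ann = make_annotation(genes)
    positions = {
        "coding": gene_feature_position(ann, "gA", "V-exon", 10),
        "RSS_spacer": gene_feature_position(ann, "gA", "RSS_spacer", 3),
        "intron": gene_feature_position(ann, "gB", "intron", 0),
        "L-Part1": gene_feature_position(ann, "gB", "L-Part1", 5),
        "intergenic": gene_feature_position(ann, "gB", "gene_body", 600),
    }
    blocks = [BlockSpec("m", sorted(positions.values()), [((0,) * 5, 0.5), ((1,) * 5, 0.5)])]
    gt = simulate_genotypes(blocks, None, 10, seed=0)
    vid_by_pos = dict(zip(gt.variants["pos"], gt.variants["variant_id"]))
    return gt, ann, {lbl: vid_by_pos[pos] for lbl, pos in positions.items()}


class TestClassifyLocation:
    @pytest.mark.parametrize("label", ["coding", "RSS_spacer", "intron", "L-Part1", "intergenic"])
    def test_feature_classes(self, location_setup, label):
        gt, ann, vids = location_setup
        assert classify_location(vids[label], gt, ann) == label

    def test_outside_locus_errors(self, location_setup):
        gt, ann, _ = location_setup
        gt2 = gt.subset_variants([0])
        gt2.variants.loc[0, "pos"] = 10**9
        with pytest.raises(ValueError, match="outside locus"):
            classify_location(gt2.variant_ids[0], gt2, ann)


class TestFoldChange:
    def test_homozygote_ratio(self):
        x = np.array([0, 0, 2, 2, 1, 1], dtype=float)
        y = np.array([0.11, 0.11, 0.31, 0.31, 0.2, 0.2])
        fc, flag = fold_change(y, x)
        assert fc == pytest.approx(0.31 / 0.11)
        assert flag == "homozygote_ratio"

    def test_equal_means_is_one(self):
        fc, _ = fold_change(np.array([0.2, 0.2, 0.2, 0.2]), np.array([0, 0, 2, 2.0]))
        assert fc == pytest.approx(1.0)

    def test_zero_minimum_undefined(self):
        fc, flag = fold_change(np.array([0.0, 0.0, 0.3, 0.3]), np.array([0, 0, 2, 2.0]))
        assert fc is None
        assert flag == "zero_minimum"

    def test_missing_homozygote_falls_back(self):
        fc, flag = fold_change(np.array([0.1, 0.1, 0.2, 0.2]), np.array([0, 0, 1, 1.0]))
        assert fc == pytest.approx(2.0)
        assert flag == "present_class_ratio"

    def test_single_genotype_class_undefined(self):
        fc, flag = fold_change(np.array([0.1, 0.2]), np.array([1.0, 1.0]))
        assert fc is None
        assert flag == "single_genotype_class"


class TestAdditiveSV:
    def test_copy_number_means_monotone_by_construction(self):
        from guqtl.simulate import SVSpec, simulate_usage_and_repertoires
        from guqtl.usage import compute_usage

        genes = ["G0", "G1", "G2"]
        truth = SimulationTruth(
            genes=genes,
            mu={g: 0.0 for g in genes},
            effects=[PlantedEffect("G0", "sv1", 0.0, "sv_copy_number")],
            sigma=0.0,
            pi_mut=0.0,
            seq_count_range=(2000, 2000),
        )
        gt = simulate_genotypes(
            [two_haplotype_block("b", [100])], [SVSpec("sv1", 500, 0.4, ["G0"])], 120, seed=13
        )
        out = simulate_usage_and_repertoires(gt, truth, seed=13)
        usage = compute_usage(out.repertoire)
        cn = 2 - np.asarray(gt.dosage_of("sv1"))
        report = additive_sv_check(usage.frequencies.loc["G0", gt.individuals], cn)
        assert report["monotone_nondecreasing"].all()
        means = report.set_index("copy_number")["mean_usage"]
        assert means.loc[0] == 0.0
        assert means.is_monotonic_increasing

    def test_single_class_trivially_monotone(self):
        report = additive_sv_check(np.array([0.1, 0.2]), np.array([2, 2]))
        assert len(report) == 1
        assert report["monotone_nondecreasing"].all()
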