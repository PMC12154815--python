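"""Generator behaviour: haplotype sampling, planted effects, round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guqtl import (
    BlockSpec,
    PlantedEffect,
    SimulationTruth,
    SVSpec,
    make_annotation,
    read_fixture_bundle,
    simulate_genotypes,
    simulate_usage_and_repertoires,
    two_haplotype_block,
    write_fixture_bundle,
)
from guqtl.ld import genotype_r2
from guqtl.repertoire import gene_of


def test_block_pool_validation():
    with pytest.raises(ValueError, match="empty"):
        BlockSpec("b", [1], [])
    with pytest.raises(ValueError, match="sum"):
        BlockSpec("b", [1], [((0,), 0.4), ((1,), 0.4)])
    with pytest.raises(ValueError, match="increasing"):
        BlockSpec("b", [5, 5], [((0, 0), 1.0)])


def test_single_haplotype_pool_is_monomorphic():
    block = BlockSpec("b", [10, 20], [((1, 0), 1.0)])
    gt = simulate_genotypes([block], None, 10, seed=0)
    assert np.all(gt.maf() == 0.0)
    assert np.all(np.var(gt.dosages, axis=1) == 0.0)


def test_complementary_haplotypes_are_in_perfect_ld(single_block_genotypes):
    d = single_block_genotypes.dosages
    for i in range(d.shape[0]):
        for j in range(i + 1, d.shape[0]):
            assert genotype_r2(d[i], d[j]) == pytest.approx(1.0, abs=1e-12)


def test_cross_block_r2_is_near_zero():
    """Independent assortment between blocks forces E[r2] ~ 1/(2n)."""
    vals = []
    for seed in range(5):
        gt = simulate_genotypes(
            [two_haplotype_block("a", [100, 200]), two_haplotype_block("b", [900, 950])],
            None,
            500,
            seed=seed,
        )
        d = gt.dosages
        for i in (0, 1):
            for j in (2, 3):
                vals.append(genotype_r2(d[i], d[j]))
    assert np.mean(vals) < 0.05


def test_dosage_equals_haplotype_sum(two_block_genotypes):
    gt = two_block_genotypes
    assert np.array_equal(gt.dosages, gt.haplotypes[:, :, 0] + gt.haplotypes[:, :, 1])


def test_empirical_maf_tracks_pool_maf():
    block = BlockSpec("b", [1, 2], [((1, 1), 0.3), ((0, 0), 0.7)])
    gt = simulate_genotypes([block], None, 400, seed=5)
    se = np.sqrt(0.3 * 0.7 / 800)
    assert np.all(np.abs(gt.maf() - 0.3) < 3 * se)


def _flat_truth(genes, **kw):
    return SimulationTruth(genes=genes, mu={g: 0.0 for g in genes}, **kw)


def test_zero_beta_zero_sigma_usage_matches_softmax():
    genes = ["A", "B", "C"]
    mu = {"A": 0.0, "B": 1.0, "C": -1.0}
    truth = SimulationTruth(
        genes=genes, mu=mu, sigma=0.0, pi_mut=0.0, seq_count_range=(10000, 10000)
    )
    gt = simulate_genotypes([two_haplotype_block("b", [100])], None, 10, seed=2)
    out = simulate_usage_and_repertoires(gt, truth, seed=2)
    expect = np.exp([mu[g] for g in genes])
    expect = expect / expect.sum()
    counts = out.repertoire.assign(gene=out.repertoire["v_call"].map(gene_of))
    for s, grp in counts.groupby("sample_id"):
        freq = grp["gene"].value_counts(normalize=True).reindex(genes).fillna(0).to_numpy()
        se = np.sqrt(expect * (1 - expect) / 10000)
        assert np.all(np.abs(freq - expect) <= 3 * se + 1e-12)


def test_planted_effect_shifts_usage_with_dosage():
    genes = [f"G{i}" for i in range(5)]
    truth = _flat_truth(
        genes,
        effects=[PlantedEffect("G0", "b_v1", 1.0)],
        sigma=0.1,
        pi_mut=0.0,
        seq_count_range=(500, 500),
    )
    gt = simulate_genotypes([two_haplotype_block("b", [100])], None, 200, seed=3)
    out = simulate_usage_and_repertoires(gt, truth, seed=3)
    counts = out.repertoire.assign(gene=out.repertoire["v_call"].map(gene_of))
    usage = (
        counts.groupby("sample_id")["gene"]
        .apply(lambda s: (s == "G0").mean())
        .reindex(gt.individuals)
    )
    rho = stats.spearmanr(gt.dosage_of("b_v1"), usage).statistic
    assert rho > 0


def test_zero_copy_number_silences_gene():
    genes = ["G0", "G1"]
    truth = _flat_truth(
        genes,
        effects=[PlantedEffect("G0", "sv1", 0.0, "sv_copy_number")],
        sigma=0.0,
        pi_mut=0.0,
        seq_count_range=(200, 200),
    )
    blocks = [two_haplotype_block("b", [100])]
    svs = [SVSpec("sv1", 500, 0.7, ["G0"])]
    gt = simulate_genotypes(blocks, svs, 60, seed=4)
    out = simulate_usage_and_repertoires(gt, truth, seed=4)
    zero_cn = np.asarray(gt.dosage_of("sv1")) == 2  # both copies deleted
    assert zero_cn.any()
    counts = out.repertoire.assign(gene=out.repertoire["v_call"].map(gene_of))
    per_sample = counts.groupby("sample_id")["gene"].apply(lambda s: (s == "G0").sum())
    for ind, has_zero in zip(gt.individuals, zero_cn):
        if has_zero:
            assert per_sample.get(ind, 0) == 0


def test_all_deleted_propensity_errors():
    genes = ["G0"]
    truth = _flat_truth(
        genes, effects=[PlantedEffect("G0", "sv1", 0.0, "sv_copy_number")], sigma=0.0
    )
    gt = simulate_genotypes([two_haplotype_block("b", [100])], [SVSpec("sv1", 500, 0.9, ["G0"])], 30, seed=0)
    # force a homozygous deletion for individual 0
    gt.haplotypes[gt.index_of("sv1"), 0, :] = 1
    with pytest.raises(ValueError, match="all-zero"):
        simulate_usage_and_repertoires(gt, truth, seed=0)


@pytest.fixture(scope="module")
def small_bundle(tmp_path_factory):
    genes = ["G0", "G1", "G2"]
    truth = SimulationTruth(
        genes=genes,
        mu={g: 0.0 for g in genes},
        effects=[PlantedEffect("G0", "b_v1", 0.5)],
        sigma=0.1,
        pi_mut=0.3,
        seq_count_range=(150, 300),
    )
    gt = simulate_genotypes([two_haplotype_block("b", [100, 200])], None, 12, seed=9)
    out = simulate_usage_and_repertoires(gt, truth, seed=9)
    ann = make_annotation(genes)
    d1 = tmp_path_factory.mktemp("bundle1")
    write_fixture_bundle(str(d1), gt, out.repertoire, out.germline_sets, ann, truth)
    return gt, out, ann, truth, str(d1)


def test_bundle_round_trip_preserves_dosages_and_counts(small_bundle):
    gt, out, ann, truth, d1 = small_bundle
    gt2, rep2, gs2, ann2 = read_fixture_bundle(d1)
    assert np.array_equal(gt.dosages, gt2.dosages)
    assert np.array_equal(gt.haplotypes, gt2.haplotypes)
    got = rep2.groupby("sample_id").size()
    want = out.repertoire.groupby("sample_id").size()
    pd.testing.assert_series_equal(got, want)
    for ind in gs2:
        assert gs2[ind].chrom_alleles == out.germline_sets[ind].chrom_alleles
        assert gs2[ind].alleles == out.germline_sets[ind].alleles
    pd.testing.assert_frame_equal(ann.features, ann2.features)


def test_bundle_byte_identical_across_runs(tmp_path, small_bundle):
    import filecmp
    import os

    genes = ["G0", "G1", "G2"]
    truth = SimulationTruth(
        genes=genes,
        mu={g: 0.0 for g in genes},
        effects=[PlantedEffect("G0", "b_v1", 0.5)],
        sigma=0.1,
        pi_mut=0.3,
        seq_count_range=(150, 300),
    )
    dirs = []
    for k in (1, 2):
        rng = np.random.default_rng(9)
        gt = simulate_genotypes([two_haplotype_block("b", [100, 200])], None, 12, rng)
        out = simulate_usage_and_repertoires(gt, truth, rng)
        d = tmp_path / f"run{k}"
        write_fixture_bundle(str(d), gt, out.repertoire, out.germline_sets, make_annotation(genes), truth)
        dirs.append(d)
    for root, _, files in os.walk(dirs[0]):
        rel = os.path.relpath(root, dirs[0])
        for f in files:
            a = os.path.join(root, f)
            b = os.path.join(dirs[1], rel, f)
            assert filecmp.cmp(a, b, shallow=False), f"{rel}/{f} differs between runs"


def test_truth_json_lists_each_planted_effect_once(small_bundle):
    import json
    import os

    *_, truth, d1 = small_bundle
    with open(os.path.join(d1, "truth.json")) as fh:
        payload = json.load(fh)
    effects = payload["effects"]
    keys = [(e["gene"], e["variant_id"]) for e in effects]
    assert sorted(keys) == sorted({(e.gene, e.variant_id) for e in truth.effects})
    assert len(keys) == len(truth.effects)
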