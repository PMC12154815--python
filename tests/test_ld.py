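"""LD statistics: genotype r2, haplotype frequencies/EM, D' CIs, Gabriel
blocks, perfect-LD collapsing, block-gene overlap."""

import numpy as np
import pandas as pd
import pytest

from guqtl import (
    GabrielThresholds,
    collapse_perfect_ld,
    dprime_ci,
    gabriel_blocks,
    genotype_r2,
    haplotype_frequencies,
    make_annotation,
    simulate_genotypes,
    two_haplotype_block,
)
from guqtl.annotation import LocusAnnotation
from guqtl.genotypes import GenotypeTable
from guqtl.ld import (
    LDBlock,
    _em_haplotype_frequencies,
    blocks_overlap_genes,
    dprime_point,
)


class TestGenotypeR2:
    def test_self_correlation_is_one(self):
        a = np.array([0, 1, 2, 0, 1, 2])
        assert genotype_r2(a, a) == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert genotype_r2(a, 2 - a) == pytest.approx(1.0)

    def test_constant_vector_is_missing(self):
        assert genotype_r2(np.array([0, 1, 2, 1]), np.array([1, 1, 1, 1])) is None

    def test_missing_handled_pairwise(self):
        a = np.array([0.0, 1.0, 2.0, np.nan, 2.0])
        b = np.array([0.0, 1.0, 2.0, 1.0, 2.0])
        assert genotype_r2(a, b) == pytest.approx(1.0)


def _table_from_haplotypes(haps, n_each):
    """GenotypeTable with explicit phased haplotypes for 2 variants."""
    hlist = []
    for h, c in zip(haps, n_each):
        hlist += [h] * c
    # pair consecutive haplotypes into individuals
    arr = np.array(hlist, dtype=np.int8)  # (2n, 2 variants)
    n = arr.shape[0] // 2
    hap = np.stack([arr[0::2].T, arr[1::2].T], axis=2)  # (variants, n, 2)
    variants = pd.DataFrame(
        {
            "variant_id": ["va", "vb"],
            "chrom": "c",
            "pos": [10, 20],
            "ref": "A",
            "alt": "G",
            "kind": "SNV",
        }
    )
    return GenotypeTable(variants, hap, [f"i{k}" for k in range(n)])


class TestHaplotypeFrequencies:
    def test_phased_direct_count(self):
        gt = _table_from_haplotypes([(0, 0), (1, 1)], [50, 50])
        freqs = haplotype_frequencies(gt, "va", "vb")
        assert freqs[0, 0] == pytest.approx(0.5)
        assert freqs[1, 1] == pytest.approx(0.5)
        assert freqs[0, 1] == freqs[1, 0] == 0.0

    def test_em_equals_direct_count_without_double_heterozygotes(self):
        gt = _table_from_haplotypes([(0, 0), (1, 0), (1, 1)], [40, 30, 30])
        direct = haplotype_frequencies(gt, "va", "vb", phased=True)
        d = gt.dosages
        # no double heterozygote individuals in this construction?
        # filter to individuals that are not double-het to guarantee it
        mask = ~((d[0] == 1) & (d[1] == 1))
        em = _em_haplotype_frequencies(d[0][mask], d[1][mask])
        ha = gt.haplotypes[0][mask]
        hb = gt.haplotypes[1][mask]
        table = np.zeros((2, 2))
        for c in (0, 1):
            np.add.at(table, (ha[:, c], hb[:, c]), 1.0)
        np.testing.assert_allclose(em, table / table.sum(), atol=1e-7)

    def test_em_invariant_to_initialization(self):
        rng = np.random.default_rng(12)
        ga = rng.integers(0, 3, size=20)
        gb = rng.integers(0, 3, size=20)
        base = _em_haplotype_frequencies(ga, gb)
        for _ in range(10):
            init = rng.dirichlet(np.ones(4)).reshape(2, 2)
            alt = _em_haplotype_frequencies(ga, gb, init=init)
            np.testing.assert_allclose(alt, base, atol=1e-6)


class TestDprime:
    def test_perfect_coupling_closed_form(self):
        # AB=50, ab=50 haplotypes: D = 0.5 - 0.25 = 0.25, D' = 1
        freqs = np.array([[0.5, 0.0], [0.0, 0.5]])
        d, dp = dprime_point(freqs)
        assert d == pytest.approx(0.25)
        assert dp == pytest.approx(1.0)
        dp_hat, lo, hi = dprime_ci(freqs, 100)
        assert dp_hat == pytest.approx(1.0)
        assert hi >= 0.998  # upper bound at grid resolution
        assert lo > 0.9

    def test_independent_sites_have_zero_dprime(self):
        p_a, p_b = 0.4, 0.3
        freqs = np.array(
            [[p_a * p_b, p_a * (1 - p_b)], [(1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]]
        )
        _, dp = dprime_point(freqs)
        assert dp == pytest.approx(0.0, abs=1e-12)

    def test_ci_tightens_with_sample_size(self):
        freqs = np.array([[0.45, 0.05], [0.05, 0.45]])
        widths = []
        for n in (50, 100, 200, 400, 800):
            _, lo, hi = dprime_ci(freqs, n)
            widths.append(hi - lo)
        assert all(w2 <= w1 + 1e-9 for w1, w2 in zip(widths, widths[1:]))

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError):
            dprime_ci(np.array([[0.5, 0.5], [0.0, 0.0]]), 100)


class TestGabrielBlocks:
    def test_single_pair_pool_yields_one_block(self, single_block_genotypes):
        blocks = gabriel_blocks(single_block_genotypes)
        assert len(blocks) == 1
        assert blocks[0].members == [f"blk_v{k}" for k in range(1, 6)]
        assert (blocks[0].start, blocks[0].end) == (10, 50)
        assert blocks[0].length == 41
        assert blocks[0].n_snvs == 5

    def test_single_variant_no_blocks(self):
        gt = simulate_genotypes([two_haplotype_block("b", [100])], None, 50, seed=0)
        assert gabriel_blocks(gt) == []

    def test_two_planted_blocks_recovered(self, two_block_genotypes):
        blocks = gabriel_blocks(two_block_genotypes)
        assert len(blocks) == 2
        assert blocks[0].members == [f"b1_v{k}" for k in range(1, 5)]
        assert blocks[1].members == [f"b2_v{k}" for k in range(1, 5)]

    def test_invariant_to_variant_id_relabeling(self, two_block_genotypes):
        gt = two_block_genotypes
        renamed = GenotypeTable(
            gt.variants.assign(variant_id=[f"x{k}" for k in range(gt.n_variants)]),
            gt.haplotypes,
            gt.individuals,
        )
        a = [(b.start, b.end) for b in gabriel_blocks(gt)]
        b = [(b.start, b.end) for b in gabriel_blocks(renamed)]
        assert a == b


class TestCollapsePerfectLD:
    def test_duplicates_and_mirrors_group_together(self):
        variants = pd.DataFrame(
            {
                "variant_id": ["a", "b", "c", "d"],
                "chrom": "c",
                "pos": [1, 2, 3, 4],
                "ref": "A",
                "alt": "G",
                "kind": "SNV",
            }
        )
        base = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        other = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        dosages = np.stack([base, base, 2 - base, other])
        hap = np.stack([dosages // 2 + dosages % 2, dosages // 2], axis=2).astype(np.int8)
        gt = GenotypeTable(variants, hap, [f"i{k}" for k in range(6)])
        groups = collapse_perfect_ld(gt)
        as_sets = sorted(sorted(g) for g in groups)
        assert as_sets == [["a", "b", "c"], ["d"]]

    def test_partition_property(self, two_block_genotypes):
        groups = collapse_perfect_ld(two_block_genotypes)
        flat = [v for g in groups for v in g]
        assert sorted(flat) == sorted(two_block_genotypes.variant_ids)

    def test_four_patterns_give_four_effective_tests(self):
        rng = np.random.default_rng(3)
        patterns = rng.integers(0, 3, size=(4, 40)).astype(np.int8)
        rows = np.vstack([patterns[[0, 1, 2, 3]], patterns[[0, 1, 2]], patterns[[0, 1, 2]]])
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{k}" for k in range(10)],
                "chrom": "c",
                "pos": np.arange(10) + 1,
                "ref": "A",
                "alt": "G",
                "kind": "SNV",
            }
        )
        hap = np.stack([np.clip(rows, 0, 1), np.clip(rows - 1, 0, 1)], axis=2).astype(np.int8)
        gt = GenotypeTable(variants, hap, [f"i{k}" for k in range(40)])
        assert len(collapse_perfect_ld(gt)) == 4


class TestBlockGeneOverlap:
    def test_overlap_and_boundary(self):
        ann = LocusAnnotation(
            pd.DataFrame(
                [
                    {"chrom": "c", "start": 100, "end": 200, "gene": "gA", "feature": "gene_body"},
                    {"chrom": "c", "start": 300, "end": 400, "gene": "gB", "feature": "gene_body"},
                ]
            )
        )
        blocks = [LDBlock("c", 150, 299, ["v1", "v2"])]
        hits = blocks_overlap_genes(blocks, ann)
        assert hits["gene"].tolist() == ["gA"]  # gB starts 1 bp after block end
        assert blocks[0].genes == ["gA"]

    def test_disjoint_means_no_assignment(self):
        ann = make_annotation(["gX"])
        blocks = [LDBlock("chrS", 1, 5, ["v"])]
        assert len(blocks_overlap_genes(blocks, ann)) == 0
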