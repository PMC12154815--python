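import numpy as np
import pandas as pd
import pytest

from guqtl import (
    BlockSpec,
    PersonalizedGermlineSet,
    PlantedEffect,
    SimulationTruth,
    simulate_genotypes,
    two_haplotype_block,
)


@pytest.fixture(scope="session")
def two_block_genotypes():
    """Two internally perfect LD blocks assorting independently, n=500."""
    blocks = [
        two_haplotype_block("b1", [100, 200, 300, 400]),
        two_haplotype_block("b2", [5100, 5200, 5300, 5400]),
    ]
    return simulate_genotypes(blocks, None, 500, seed=11)


@pytest.fixture(scope="session")
def single_block_genotypes():
    """One 5-variant block with a complementary haplotype pair, n=100
    (200 haplotypes)."""
    return simulate_genotypes(
        [two_haplotype_block("blk", [10, 20, 30, 40, 50])], None, 100, seed=7
    )


def make_repertoire(rows):
    """Build an AIRR table from (sample, v_call, j_call, v_id, j_id, junction) tuples."""
    recs = []
    for k, (sample, v, j, vid, jid, junc) in enumerate(rows):
        recs.append(
            {
                "sequence_id": f"{sample}_s{k}",
                "sample_id": sample,
                "v_call": v,
                "j_call": j,
                "v_identity": vid,
                "j_identity": jid,
                "junction_aa": junc,
                "duplicate_count": 1,
            }
        )
    columns = [
        "sequence_id", "sample_id", "v_call", "j_call",
        "v_identity", "j_identity", "junction_aa", "duplicate_count",
    ]
    return pd.DataFrame(recs, columns=columns)


@pytest.fixture
def simple_germline():
    """Two individuals; I2's paralog pair shares a sequence (not disambiguatable)."""
    def gs(ind, prox_seqs, dist_seqs):
        alleles = {
            "IGKV1-12": dict(prox_seqs),
            "IGKV1D-12": dict(dist_seqs),
            "IGKV1-39": {"01": "MMMM"},
            "IGKV5-2": {"01": "PPPP"},
            "IGLJ1": {"01": "QV"},
            "IGLJ3-2": {"01": "WV"},
        }
        return PersonalizedGermlineSet(ind, alleles, {})

    return {
        "I1": gs("I1", {"01": "AAAA", "02": "AAAB"}, {"01": "CCCC"}),
        "I2": gs("I2", {"01": "AAAA"}, {"01": "AAAA", "02": "DDDD"}),
    }


@pytest.fixture(scope="session")
def planted_cohort():
    """20 genes, one planted intergenic guQTL each (MAF 0.3, beta 1), n=200."""
    genes = [f"G{i:02d}" for i in range(20)]
    blocks = [
        BlockSpec(f"v{i:02d}", [1000 * (i + 1)], [((0,), 0.7), ((1,), 0.3)])
        for i in range(20)
    ]
    effects = [PlantedEffect(genes[i], f"v{i:02d}_v1", 1.0, "intergenic") for i in range(20)]
    truth = SimulationTruth(
        genes=genes, mu={g: 0.0 for g in genes}, effects=effects, sigma=0.2
    )
    return blocks, truth
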