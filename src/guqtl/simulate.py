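"""Synthetic cohort generator with planted, recoverable structure.

Emulates the inputs of a light-chain gene-usage QTL study: block-structured
diploid haplotypes (no recombination within a block, free recombination
between blocks), SV deletions changing diploid gene copy number, per-gene
usage with additive *cis* effects on a log-propensity scale, an
unmutated/mutated sequence split, per-chromosome germline allele
assignments, and junction amino acids carrying germline-derived V/J
residues. Every planted effect is recorded in a :class:`SimulationTruth`
so downstream stages can be tested against ground truth.

The generative model: for gene g in individual i,

    w_gi = exp(mu_g + sum_v beta_gv * x_iv + eps_gi) * prod_sv (cn_gi / 2)

with eps_gi ~ Normal(0, sigma_g^2) and cn the diploid copy number under SV
deletions (cn = 0 forces w = 0). Usage p_gi = w_gi / sum_g w_gi, and each of
the N_i unique sequences draws its V gene from Categorical(p_i).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import LocusAnnotation
from .genotypes import GenotypeTable, VARIANT_COLUMNS
from .repertoire import AIRR_COLUMNS, PersonalizedGermlineSet, write_airr

#: amino-acid alphabet for random germline/junction residues; C is excluded
#: so random inserts never collide with the conserved junction cysteine
AA_NO_C = list("ADEFGHIKLMNPQRSTVWY")
AA_NO_C_NO_AROMATIC = list("ADEGIKLMNPQRSTV")

MECHANISMS = {"intergenic", "RSS", "coding_missense", "coding_stop", "sv_copy_number"}


@dataclass
class BlockSpec:
    """One LD block: a pool of haplotypes over its variant positions.

    Within a block haplotypes are drawn whole (no recombination); blocks
    assort independently of one another, which is what creates
    between-block recombination in the cohort.
    """

    block_id: str
    variant_positions: list[int]
    haplotype_pool: list[tuple[tuple[int, ...], float]]
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if not self.haplotype_pool:
            raise ValueError(f"block {self.block_id}: empty haplotype pool")
        total = sum(f for _, f in self.haplotype_pool)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"block {self.block_id}: pool frequencies sum to {total}, not 1")
        for hap, _ in self.haplotype_pool:
            if len(hap) != len(self.variant_positions):
                raise ValueError(f"block {self.block_id}: haplotype length mismatch")
        if any(b <= a for a, b in zip(self.variant_positions, self.variant_positions[1:])):
            raise ValueError(f"block {self.block_id}: positions must be strictly increasing")


@dataclass
class SVSpec:
    """An SV deletion segregating in the cohort, removing whole gene copies."""

    variant_id: str
    pos: int
    deletion_freq: float
    genes: list[str]
    chrom: str = "chrS"


@dataclass
class PlantedEffect:
    """A planted cis effect of one variant on one gene's usage."""

    gene: str
    variant_id: str
    beta: float
    mechanism: str = "intergenic"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class SimulationTruth:
    """Ground truth and generative parameters for one synthetic cohort."""

    genes: list[str]
    mu: dict[str, float]
    effects: list[PlantedEffect] = field(default_factory=list)
    sigma: float | dict[str, float] = 0.2
    pi_mut: float = 0.5
    seq_count_range: tuple[int, int] = (1000, 5000)
    j_genes: list[str] = field(default_factory=lambda: ["IGLJ1", "IGLJ2", "IGLJ3"])
    #: per-gene override of the 3 germline V residues entering the junction
    gene_suffix: dict[str, str] = field(default_factory=dict)
    #: groups of genes sharing their *01 allele sequence (paralog ambiguity)
    shared_first_allele: list[list[str]] = field(default_factory=list)
    #: genes given a second allele linked to a (non-coding) variant:
    #: gene -> variant_id; coding-effect genes get this automatically
    allele_linkage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sig = self.sigma.values() if isinstance(self.sigma, dict) else [self.sigma]
        if any(s < 0 for s in sig):
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.pi_mut <= 1.0:
            raise ValueError("pi_mut must lie in [0, 1]")

    def sigma_of(self, gene: str) -> float:
        if isinstance(self.sigma, dict):
            return self.sigma.get(gene, 0.0)
        return self.sigma

    def expected_usage(self, genotypes: GenotypeTable) -> pd.DataFrame:
        """Noise-free usage implied by mu and the planted effects."""
        w = _propensity(genotypes, self, eps=None)
        return pd.DataFrame(
            w / w.sum(axis=0, keepdims=True), index=self.genes, columns=genotypes.individuals
        )


@dataclass
class SimulationOutput:
    """Everything the generator produced for one cohort."""

    repertoire: pd.DataFrame
    germline_sets: dict[str, PersonalizedGermlineSet]
    expected_usage: pd.DataFrame
    #: per-sample bookkeeping: unmutated / mutated / total unique sequences
    sample_log: pd.DataFrame
    #: realized per-gene unmutated counts (genes x samples)
    unmutated_counts: pd.DataFrame


# ----------------------------------------------------------------- genotypes

def simulate_genotypes(
    blocks: list[BlockSpec],
    sv_specs: list[SVSpec] | None,
    n_individuals: int,
    seed: int | np.random.Generator,
) -> GenotypeTable:
    """Draw a phased diploid cohort from block haplotype pools.

    Each individual receives two haplotypes; within a block both are drawn
    independently from that block's pool, and blocks assort independently.
    SV deletion alleles are drawn per haplotype at their own frequency.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows: list[dict] = []
    hap_slices: list[np.ndarray] = []
    for block in blocks:
        haps = np.array([h for h, _ in block.haplotype_pool], dtype=np.int8)
        freqs = np.array([f for _, f in block.haplotype_pool])
        # (n_individuals, 2) pool indices
        choice = rng.choice(len(haps), size=(n_individuals, 2), p=freqs)
        alleles = haps[choice]  # (n, 2, n_block_variants)
        hap_slices.append(np.transpose(alleles, (2, 0, 1)))
        for k, pos in enumerate(block.variant_positions):
            rows.append(
                {
                    "variant_id": f"{block.block_id}_v{k + 1}",
                    "chrom": block.chrom,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "kind": "SNV",
                }
            )
    for sv in sv_specs or []:
        dels = (rng.random((n_individuals, 2)) < sv.deletion_freq).astype(np.int8)
        hap_slices.append(dels[None, :, :])
        rows.append(
            {
                "variant_id": sv.variant_id,
                "chrom": sv.chrom,
                "pos": sv.pos,
                "ref": "N",
                "alt": "<DEL>",
                "kind": "SV_DEL",
            }
        )
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    haplotypes = np.concatenate(hap_slices, axis=0) if hap_slices else np.zeros(
        (0, n_individuals, 2), np.int8
    )
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    individuals = [f"S{i + 1:03d}" for i in range(n_individuals)]
    return GenotypeTable(variants.iloc[order], haplotypes[order], individuals)


# ------------------------------------------------------------------- usage

def _propensity(
    genotypes: GenotypeTable, truth: SimulationTruth, eps: np.ndarray | None
) -> np.ndarray:
    """Latent gene propensities w (genes x individuals)."""
    n = genotypes.n_individuals
    genes = truth.genes
    log_w = np.array([[truth.mu[g]] * n for g in genes], dtype=float)
    if eps is not None:
        log_w += eps
    scale = np.ones((len(genes), n))
    for eff in truth.effects:
        gi = genes.index(eff.gene)
        dosage = genotypes.dosage_of(eff.variant_id).astype(float)
        if eff.mechanism == "sv_copy_number":
            cn = 2.0 - dosage  # dosage counts deleted copies
            scale[gi] *= cn / 2.0
        else:
            log_w[gi] += eff.beta * dosage
    return np.exp(log_w) * scale


def simulate_usage_and_repertoires(
    genotypes: GenotypeTable,
    truth: SimulationTruth,
    seed: int | np.random.Generator,
) -> SimulationOutput:
    """Sample repertoires and per-individual germline sets from the model."""
    for eff in truth.effects:
        genotypes.index_of(eff.variant_id)  # raises on unknown variant
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    genes = truth.genes
    n = genotypes.n_individuals
    sigma = np.array([truth.sigma_of(g) for g in genes])[:, None]
    eps = rng.normal(0.0, 1.0, size=(len(genes), n)) * sigma
    w = _propensity(genotypes, truth, eps)
    totals = w.sum(axis=0)
    if np.any(totals <= 0):
        bad = [genotypes.individuals[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"all-zero usage propensity for individuals: {bad}")
    p = w / totals

    models = _build_gene_models(truth, rng)
    germline_sets = _assign_germlines(genotypes, truth, models)

    lo, hi = truth.seq_count_range
    seq_counts = rng.integers(lo, hi + 1, size=n)
    child_seeds = np.random.SeedSequence(rng.integers(0, 2**31)).spawn(n)

    frames = []
    sample_rows = []
    count_rows = {}
    for i, ind in enumerate(genotypes.individuals):
        sub = np.random.default_rng(child_seeds[i])
        n_seq = int(seq_counts[i])
        gene_idx = sub.choice(len(genes), size=n_seq, p=p[:, i])
        chrom = sub.integers(0, 2, size=n_seq)
        mutated = sub.random(n_seq) < truth.pi_mut
        which_segment = sub.integers(0, 2, size=n_seq)  # 0: V hit, 1: J hit
        j_idx = sub.integers(0, len(truth.j_genes), size=n_seq)
        ins_len = sub.integers(0, 5, size=n_seq)
        ins_chars = sub.choice(AA_NO_C, size=int(ins_len.sum()))
        dup = sub.integers(1, 5, size=n_seq)

        gs = germline_sets[ind]
        v_calls, j_calls, junctions = [], [], []
        v_id = np.ones(n_seq)
        j_id = np.ones(n_seq)
        off = 0
        for s in range(n_seq):
            g = genes[gene_idx[s]]
            allele = gs.chrom_alleles[g][chrom[s]]
            v_calls.append(f"{g}*{allele}")
            jg = truth.j_genes[j_idx[s]]
            j_calls.append(f"{jg}*01")
            suffix = models[g]["alleles"][allele][-3:]
            prefix = models[jg]["alleles"]["01"][:2]
            insert = "".join(ins_chars[off : off + ins_len[s]])
            off += ins_len[s]
            junctions.append("C" + suffix + insert + prefix + "F")
            if mutated[s]:
                if which_segment[s] == 0:
                    v_id[s] = 0.97
                else:
                    j_id[s] = 0.97
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": [f"{ind}_seq{s + 1}" for s in range(n_seq)],
                    "sample_id": ind,
                    "v_call": v_calls,
                    "j_call": j_calls,
                    "v_identity": v_id,
                    "j_identity": j_id,
                    "junction_aa": junctions,
                    "duplicate_count": dup,
                }
            )
        )
        n_mut = int(mutated.sum())
        sample_rows.append(
            {
                "sample_id": ind,
                "n_unique": n_seq,
                "n_unmutated": n_seq - n_mut,
                "n_mutated": n_mut,
            }
        )
        unmut_genes = pd.Series(gene_idx[~mutated]).value_counts()
        count_rows[ind] = {genes[k]: int(v) for k, v in unmut_genes.items()}

    repertoire = pd.concat(frames, ignore_index=True)[AIRR_COLUMNS]
    unmut_counts = (
        pd.DataFrame(count_rows).reindex(index=genes, columns=genotypes.individuals).fillna(0).astype(int)
    )
    return SimulationOutput(
        repertoire=repertoire,
        germline_sets=germline_sets,
        expected_usage=pd.DataFrame(p, index=genes, columns=genotypes.individuals),
        sample_log=pd.DataFrame(sample_rows),
        unmutated_counts=unmut_counts,
    )


def _random_protein(rng: np.random.Generator, length: int, alphabet: list[str]) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _build_gene_models(truth: SimulationTruth, rng: np.random.Generator) -> dict[str, dict]:
    """Per-gene allele sequences; *02 alleles arise under coding effects
    or explicit allele linkage, substituting one interior residue."""
    models: dict[str, dict] = {}
    linked: dict[str, str] = dict(truth.allele_linkage)
    for eff in truth.effects:
        if eff.mechanism in ("coding_missense", "coding_stop"):
            linked.setdefault(eff.gene, eff.variant_id)
    shared: dict[str, str] = {}
    for group in truth.shared_first_allele:
        seq = _random_protein(rng, 20, AA_NO_C_NO_AROMATIC)
        for g in group:
            shared[g] = seq
    for g in truth.genes + truth.j_genes:
        base = shared.get(g, _random_protein(rng, 20, AA_NO_C_NO_AROMATIC))
        if g in truth.gene_suffix:
            base = base[: -len(truth.gene_suffix[g])] + truth.gene_suffix[g]
        alleles = {"01": base}
        if g in linked:
            pos = 8
            old = base[pos]
            new = rng.choice([a for a in AA_NO_C_NO_AROMATIC if a != old])
            alleles["02"] = base[:pos] + new + base[pos + 1 :]
        models[g] = {"alleles": alleles, "linked_variant": linked.get(g)}
    return models


def _assign_germlines(
    genotypes: GenotypeTable, truth: SimulationTruth, models: dict[str, dict]
) -> dict[str, PersonalizedGermlineSet]:
    sets: dict[str, PersonalizedGermlineSet] = {}
    for i, ind in enumerate(genotypes.individuals):
        chrom_alleles: dict[str, tuple[str, str]] = {}
        alleles: dict[str, dict[str, str]] = {}
        for g in truth.genes + truth.j_genes:
            model = models[g]
            vid = model["linked_variant"]
            if vid is None:
                pair = ("01", "01")
            else:
                vi = genotypes.index_of(vid)
                hap = genotypes.haplotypes[vi, i]
                pair = tuple("02" if a else "01" for a in hap)
            chrom_alleles[g] = pair
            alleles[g] = {a: model["alleles"][a] for a in sorted(set(pair))}
        sets[ind] = PersonalizedGermlineSet(
            individual_id=ind, alleles=alleles, chrom_alleles=chrom_alleles
        )
    return sets


# --------------------------------------------------------------- annotation

def make_annotation(
    genes: list[str],
    chrom: str = "chrS",
    origin: int = 10_000,
    gene_span: int = 1_000,
) -> LocusAnnotation:
    """Deterministic synthetic locus layout: one gene cassette per kb.

    Cassette k (0-based) starts at ``origin + k * gene_span`` and lays out
    L-Part1 (50 bp), intron (100 bp), V-exon (300 bp), RSS heptamer (7 bp),
    spacer (12 bp) and nonamer (9 bp); the gene body spans all of them.
    """
    rows = []
    for k, g in enumerate(genes):
        s = origin + k * gene_span
        parts = [
            ("L-Part1", s, s + 49),
            ("intron", s + 50, s + 149),
            ("V-exon", s + 150, s + 449),
            ("RSS_heptamer", s + 450, s + 456),
            ("RSS_spacer", s + 457, s + 468),
            ("RSS_nonamer", s + 469, s + 477),
            ("gene_body", s, s + 477),
        ]
        for feature, a, b in parts:
            rows.append({"chrom": chrom, "start": a, "end": b, "gene": g, "feature": feature})
    locus_end = origin + len(genes) * gene_span + 5_000
    rows.append({"chrom": chrom, "start": 1, "end": locus_end, "gene": "locus", "feature": "locus"})
    return LocusAnnotation(pd.DataFrame(rows))


def gene_feature_position(annotation: LocusAnnotation, gene: str, feature: str, offset: int = 0) -> int:
    """1-based position of ``offset`` bases into a gene's feature interval."""
    df = annotation.features
    row = df[(df["gene"] == gene) & (df["feature"] == feature)]
    if not len(row):
        raise KeyError(f"{gene} has no {feature} interval")
    return int(row["start"].iloc[0]) + offset


# ------------------------------------------------------------------ bundles

def write_fixture_bundle(
    out_dir: str,
    genotypes: GenotypeTable,
    repertoire: pd.DataFrame,
    germline_sets: dict[str, PersonalizedGermlineSet],
    annotation: LocusAnnotation,
    truth: SimulationTruth | None = None,
) -> dict[str, str]:
    """Write a complete cohort to disk as plain-text files.

    Emits ``genotypes.vcf``, one AIRR TSV per sample under ``airr/``,
    ``germline.fasta`` + ``germline_alleles.tsv``, ``annotation.bed`` and,
    when a truth object is given, ``truth.json``. The writing order and
    float formats are fixed, so a fixed seed yields byte-identical bundles.
    """
    os.makedirs(out_dir, exist_ok=True)
    airr_dir = os.path.join(out_dir, "airr")
    os.makedirs(airr_dir, exist_ok=True)
    paths = {"vcf": os.path.join(out_dir, "genotypes.vcf")}
    genotypes.to_vcf(paths["vcf"])

    paths["airr_dir"] = airr_dir
    for sample in sorted(repertoire["sample_id"].unique()):
        write_airr(
            repertoire[repertoire["sample_id"] == sample],
            os.path.join(airr_dir, f"{sample}.tsv"),
        )

    fasta = {}
    allele_rows = []
    for ind in sorted(germline_sets):
        gs = germline_sets[ind]
        for g in sorted(gs.alleles):
            for a, seq in sorted(gs.alleles[g].items()):
                fasta[f"{g}*{a}"] = seq
            pair = gs.chrom_alleles.get(g, ("", ""))
            allele_rows.append(
                {"individual": ind, "gene": g, "allele_h1": pair[0], "allele_h2": pair[1]}
            )
    paths["fasta"] = os.path.join(out_dir, "germline.fasta")
    with open(paths["fasta"], "w") as fh:
        for name in sorted(fasta):
            fh.write(f">{name}\n{fasta[name]}\n")
    paths["alleles"] = os.path.join(out_dir, "germline_alleles.tsv")
    pd.DataFrame(allele_rows).to_csv(paths["alleles"], sep="\t", index=False)

    paths["bed"] = os.path.join(out_dir, "annotation.bed")
    annotation.to_bed(paths["bed"])

    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        payload = asdict(truth)
        payload["seq_count_range"] = list(truth.seq_count_range)
        with open(paths["truth"], "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return paths


def read_fixture_bundle(out_dir: str):
    """Read back a bundle written by :func:`write_fixture_bundle`.

    Returns (genotypes, repertoire, germline_sets, annotation).
    """
    from Bio import SeqIO

    genotypes = GenotypeTable.from_vcf(os.path.join(out_dir, "genotypes.vcf"))
    airr_dir = os.path.join(out_dir, "airr")
    frames = [
        pd.read_csv(os.path.join(airr_dir, f), sep="\t", dtype={"sequence_id": str, "sample_id": str})
        for f in sorted(os.listdir(airr_dir))
    ]
    repertoire = pd.concat(frames, ignore_index=True)

    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(os.path.join(out_dir, "germline.fasta"), "fasta")
    }
    alleles = pd.read_csv(
        os.path.join(out_dir, "germline_alleles.tsv"),
        sep="\t",
        dtype={"allele_h1": str, "allele_h2": str},
    )
    germline_sets: dict[str, PersonalizedGermlineSet] = {}
    for ind, grp in alleles.groupby("individual"):
        amap: dict[str, dict[str, str]] = {}
        cmap: dict[str, tuple[str, str]] = {}
        for row in grp.itertuples():
            cmap[row.gene] = (row.allele_h1, row.allele_h2)
            amap[row.gene] = {
                a: seqs[f"{row.gene}*{a}"] for a in {row.allele_h1, row.allele_h2} if a
            }
        germline_sets[str(ind)] = PersonalizedGermlineSet(
            individual_id=str(ind), alleles=amap, chrom_alleles=cmap
        )
    annotation = LocusAnnotation.from_bed(os.path.join(out_dir, "annotation.bed"))
    return genotypes, repertoire, germline_sets, annotation


def simulate_usage_matrix(
    genotypes: GenotypeTable,
    truth: SimulationTruth,
    seed: int | np.random.Generator,
    multinomial_counts: bool = True,
):
    """Sample a gene-usage matrix directly from the model, skipping
    sequence-level simulation.

    Much faster than :func:`simulate_usage_and_repertoires` for scan
    calibration experiments; with ``multinomial_counts`` each sample's
    N_i unique sequences are drawn Multinomial(N_i, p_i), otherwise the
    latent frequencies are returned as-is with pseudo-counts.
    """
    from .usage import UsageMatrix

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genes = truth.genes
    n = genotypes.n_individuals
    sigma = np.array([truth.sigma_of(g) for g in genes])[:, None]
    eps = rng.normal(0.0, 1.0, size=(len(genes), n)) * sigma
    w = _propensity(genotypes, truth, eps)
    totals = w.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("all-zero usage propensity")
    p = w / totals
    lo, hi = truth.seq_count_range
    n_seq = rng.integers(lo, hi + 1, size=n)
    if multinomial_counts:
        counts = np.stack([rng.multinomial(n_seq[i], p[:, i]) for i in range(n)], axis=1)
        freqs = counts / n_seq
    else:
        freqs = p
        counts = np.rint(p * n_seq).astype(int)
    idx = pd.Index(genes)
    cols = pd.Index(genotypes.individuals)
    return UsageMatrix(
        frequencies=pd.DataFrame(freqs, index=idx, columns=cols),
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        sample_totals=pd.Series(n_seq, index=cols),
    )


# -------------------------------------------------------- canned cohorts

def two_haplotype_block(
    block_id: str, positions: list[int], freq: float = 0.5, chrom: str = "chrS"
) -> BlockSpec:
    """A block with one haplotype pair: all-ref vs all-alt (perfect LD)."""
    k = len(positions)
    return BlockSpec(
        block_id=block_id,
        variant_positions=positions,
        haplotype_pool=[(tuple([0] * k), 1 - freq), (tuple([1] * k), freq)],
        chrom=chrom,
    )


def demo_cohort(seed: int, n_individuals: int = 150):
    """A small cohort exercising every planted mechanism at once.

    Plants (i) a stop-codon variant suppressing one gene, (ii) an SV
    deletion with an additive copy-number effect, (iii) one pleiotropic LD
    block driving five genes, and (iv) an aromatic-rich germline V suffix on
    one driven gene so an aromaticity QTL emerges at the same block.

    Returns (genotypes, truth, annotation, SimulationOutput).
    """
    genes = [f"IGSV{i + 1}-{i + 1}" for i in range(10)]
    annotation = make_annotation(genes)
    # pleiotropic block spanning genes 0..4 (intergenic positions near them)
    pleio_positions = [gene_feature_position(annotation, genes[i], "gene_body", 490) for i in range(4)]
    pleio_positions.append(gene_feature_position(annotation, genes[4], "gene_body", 495))
    blocks = [
        BlockSpec("pleio", sorted(pleio_positions), [((0,) * 5, 0.5), ((1,) * 5, 0.5)]),
        # stop-codon variant inside gene 6's V-exon, on its own block
        BlockSpec(
            "stopblk",
            [gene_feature_position(annotation, genes[6], "V-exon", 120)],
            [((0,), 0.6), ((1,), 0.4)],
        ),
        # background blocks with 3 haplotypes each
        BlockSpec(
            "bg1",
            [gene_feature_position(annotation, genes[8], "gene_body", 520),
             gene_feature_position(annotation, genes[8], "gene_body", 540)],
            [((0, 0), 0.5), ((1, 0), 0.3), ((1, 1), 0.2)],
        ),
    ]
    svs = [SVSpec("sv_del_g10", gene_feature_position(annotation, genes[9], "V-exon", 0), 0.3, [genes[9]])]
    effects = [PlantedEffect(genes[i], "pleio_v1", 0.8, "intergenic") for i in range(5)]
    effects.append(PlantedEffect(genes[6], "stopblk_v1", -1.2, "coding_stop"))
    effects.append(PlantedEffect(genes[9], "sv_del_g10", 0.0, "sv_copy_number"))
    truth = SimulationTruth(
        genes=genes,
        mu={g: 0.0 for g in genes},
        effects=effects,
        sigma=0.15,
        pi_mut=0.4,
        seq_count_range=(1000, 5000),
        gene_suffix={genes[0]: "WWF"},
    )
    rng = np.random.default_rng(seed)
    genotypes = simulate_genotypes(blocks, svs, n_individuals, rng)
    out = simulate_usage_and_repertoires(genotypes, truth, rng)
    return genotypes, truth, annotation, out
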