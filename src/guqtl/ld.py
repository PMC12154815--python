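"""Linkage disequilibrium: genotype r2, D'/CI, Gabriel haplotype blocks,
perfect-LD collapsing and block-gene overlap.

Pairwise genotype r2 is the squared Pearson correlation of diploid dosage
vectors (the vcftools ``--geno-r2`` statistic). D' follows the classical
normalization D / D_max, and its 90% confidence interval comes from the
normalized multinomial likelihood of the four haplotype counts evaluated on
a |D'| grid (the Haploview construction). Blocks follow Gabriel et al.:
a candidate interval is a block when its outermost pair is in "strong LD"
(CI low >= 0.70, CI high >= 0.98) and at least 95% of informative pairs
inside are in strong LD; pairs with CI high < 0.90 show strong evidence of
historical recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

STRONG_LD = "strong_LD"
STRONG_RECOMB = "strong_recombination"
UNINFORMATIVE = "uninformative"


@dataclass
class GabrielThresholds:
    """Pair-classification and block-acceptance thresholds (Gabriel 2002)."""

    ci_low_strong: float = 0.70
    ci_high_strong: float = 0.98
    ci_high_recomb: float = 0.90
    min_strong_fraction: float = 0.95
    ci_level: float = 0.90


@dataclass
class PairLD:
    """LD summary for one variant pair."""

    variant_a: str
    variant_b: str
    r2: float | None
    d: float
    dprime: float
    ci_low: float
    ci_high: float
    informative_class: str


@dataclass
class LDBlock:
    """A Gabriel haplotype block (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    members: list[str]
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_snvs(self) -> int:
        return len(self.members)


def genotype_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (negative or NaN) are excluded pairwise. Returns None when
    fewer than two shared samples remain or either vector is constant.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b) | (a < 0) | (b < 0))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return None
    va = a - a.mean()
    vb = b - b.mean()
    sxx = float(va @ va)
    syy = float(vb @ vb)
    if sxx == 0.0 or syy == 0.0:
        return None
    return float((va @ vb) ** 2 / (sxx * syy))


def haplotype_frequencies(
    genotypes: GenotypeTable,
    variant_a: str,
    variant_b: str,
    phased: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """2x2 haplotype frequency table [[p_AB, p_Ab], [p_aB, p_ab]].

    Rows index the first variant's allele (0 = ref A, 1 = alt a), columns
    the second's. With phased genotypes haplotypes are counted directly;
    otherwise frequencies come from EM over the double-heterozygote phase
    ambiguity.
    """
    ia, ib = genotypes.index_of(variant_a), genotypes.index_of(variant_b)
    ha = genotypes.haplotypes[ia]  # (n, 2)
    hb = genotypes.haplotypes[ib]
    if phased:
        table = np.zeros((2, 2))
        for c in (0, 1):
            np.add.at(table, (ha[:, c], hb[:, c]), 1.0)
        return table / table.sum()
    return _em_haplotype_frequencies(
        ha.sum(axis=1), hb.sum(axis=1), tol=tol, max_iter=max_iter
    )


def _em_haplotype_frequencies(
    ga: np.ndarray, gb: np.ndarray, tol: float = 1e-8, max_iter: int = 1000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """EM for two-locus haplotype frequencies from unphased dosages."""
    n = ga.size
    # genotype class counts; double heterozygotes are phase-ambiguous
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga.astype(int), gb.astype(int)), 1.0)
    # known haplotype contributions (everything except the 1/1 cell)
    known = np.zeros((2, 2))
    for x in range(3):
        for y in range(3):
            if x == 1 and y == 1:
                continue
            c = counts[x, y]
            if c == 0:
                continue
            # alleles per haplotype for unambiguous genotypes
            ax = [0, 0] if x == 0 else [1, 1] if x == 2 else [0, 1]
            ay = [0, 0] if y == 0 else [1, 1] if y == 2 else [0, 1]
            if x == 1:
                known[ax[0], ay[0]] += c
                known[ax[1], ay[1]] += c
            elif y == 1:
                known[ax[0], ay[0]] += c
                known[ax[1], ay[1]] += c
            else:
                known[ax[0], ay[0]] += 2 * c
    n_dh = counts[1, 1]
    freqs = np.full((2, 2), 0.25) if init is None else np.array(init, dtype=float)
    for it in range(max_iter):
        # E: split double heterozygotes between cis (AB/ab) and trans (Ab/aB)
        p_cis = freqs[0, 0] * freqs[1, 1]
        p_trans = freqs[0, 1] * freqs[1, 0]
        denom = p_cis + p_trans
        w = 0.5 if denom == 0 else p_cis / denom
        table = known.copy()
        table[0, 0] += n_dh * w
        table[1, 1] += n_dh * w
        table[0, 1] += n_dh * (1 - w)
        table[1, 0] += n_dh * (1 - w)
        new = table / (2 * n)
        if np.abs(new - freqs).max() < tol:
            return new
        freqs = new
    raise RuntimeError(f"EM did not converge in {max_iter} iterations")


def dprime_point(hap_freqs: np.ndarray) -> tuple[float, float]:
    """(D, D') from a 2x2 haplotype frequency table."""
    p_ab = hap_freqs[0, 0]
    p_a = hap_freqs[0, :].sum()
    p_b = hap_freqs[:, 0].sum()
    d = p_ab - p_a * p_b
    q_a, q_b = 1 - p_a, 1 - p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    if d_max == 0:
        return float(d), 0.0
    return float(d), float(d / d_max)


def dprime_ci(
    hap_freqs: np.ndarray,
    n_haplotypes: int,
    level: float = 0.90,
    grid_step: float = 0.001,
) -> tuple[float, float, float]:
    """D' point estimate with a likelihood-based CI on |D'|.

    The multinomial likelihood of the observed haplotype counts is evaluated
    on a |D'| grid (allele frequencies held at their MLEs, sign of D fixed
    at the observed sign), normalized, and the (1-level)/2 and (1+level)/2
    cumulative points are returned as the CI bounds.
    """
    p_a = hap_freqs[0, :].sum()
    p_b = hap_freqs[:, 0].sum()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic site: D' undefined")
    d_obs, dp_obs = dprime_point(hap_freqs)
    sign = 1.0 if d_obs >= 0 else -1.0
    q_a, q_b = 1 - p_a, 1 - p_b
    d_max = min(p_a * q_b, q_a * p_b) if sign > 0 else min(p_a * p_b, q_a * q_b)

    counts = hap_freqs * n_haplotypes
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d_grid = sign * grid * d_max
    # haplotype probabilities as a function of D on the grid
    p00 = p_a * p_b + d_grid
    p01 = p_a * q_b - d_grid
    p10 = q_a * p_b - d_grid
    p11 = q_a * q_b + d_grid
    probs = np.stack([p00, p01, p10, p11], axis=1)
    probs = np.clip(probs, 1e-12, None)
    loglik = (np.log(probs) * counts.reshape(-1)).sum(axis=1)
    lik = np.exp(loglik - loglik.max())
    cum = np.cumsum(lik) / lik.sum()
    alpha = (1 - level) / 2
    lo = float(grid[np.searchsorted(cum, alpha)])
    hi = float(grid[min(np.searchsorted(cum, 1 - alpha), grid.size - 1)])
    return float(abs(dp_obs)), lo, hi


def classify_pair(ci_low: float, ci_high: float, thresholds: GabrielThresholds) -> str:
    if ci_low >= thresholds.ci_low_strong and ci_high >= thresholds.ci_high_strong:
        return STRONG_LD
    if ci_high < thresholds.ci_high_recomb:
        return STRONG_RECOMB
    return UNINFORMATIVE


def pairwise_ld(
    genotypes: GenotypeTable,
    thresholds: GabrielThresholds | None = None,
) -> list[PairLD]:
    """All-pairs LD summary over SNVs, in positional order."""
    thresholds = thresholds or GabrielThresholds()
    n_hap = 2 * genotypes.n_individuals
    dosages = genotypes.dosages
    ids = genotypes.variant_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            freqs = haplotype_frequencies(genotypes, ids[i], ids[j])
            try:
                dp, lo, hi = dprime_ci(freqs, n_hap, level=thresholds.ci_level)
            except ValueError:
                continue
            d, _ = dprime_point(freqs)
            out.append(
                PairLD(
                    variant_a=ids[i],
                    variant_b=ids[j],
                    r2=genotype_r2(dosages[i], dosages[j]),
                    d=d,
                    dprime=dp,
                    ci_low=lo,
                    ci_high=hi,
                    informative_class=classify_pair(lo, hi, thresholds),
                )
            )
    return out


def gabriel_blocks(
    genotypes: GenotypeTable,
    thresholds: GabrielThresholds | None = None,
) -> list[LDBlock]:
    """Gabriel-D' haplotype blocks over the table's SNVs.

    Variants must be MAF-filtered and position-sorted. Candidate intervals
    whose outermost pair is strong-LD and whose informative interior pairs
    are >= 95% strong-LD are ranked by span length (ties to the leftmost)
    and accepted greedily without overlap.
    """
    thresholds = thresholds or GabrielThresholds()
    snv = genotypes.subset_variants(
        np.flatnonzero((genotypes.variants["kind"] == "SNV").to_numpy())
    )
    m = snv.n_variants
    if m < 2:
        return []
    pairs = pairwise_ld(snv, thresholds)
    cls = {}
    for p in pairs:
        cls[(p.variant_a, p.variant_b)] = p.informative_class
    ids = snv.variant_ids
    pos = snv.variants["pos"].to_numpy()

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if cls.get((ids[i], ids[j])) != STRONG_LD:
                continue
            strong = informative = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    c = cls.get((ids[a], ids[b]))
                    if c == STRONG_LD:
                        strong += 1
                        informative += 1
                    elif c == STRONG_RECOMB:
                        informative += 1
            if informative and strong / informative >= thresholds.min_strong_fraction:
                candidates.append((i, j))
    # longest span first; ties to the leftmost start
    candidates.sort(key=lambda ij: (-(pos[ij[1]] - pos[ij[0]]), pos[ij[0]]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            LDBlock(
                chrom=str(snv.variants["chrom"].iloc[i]),
                start=int(pos[i]),
                end=int(pos[j]),
                members=ids[i : j + 1],
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


def collapse_perfect_ld(genotypes: GenotypeTable) -> list[list[str]]:
    """Partition variants into perfect-LD groups (genotype r2 exactly 1).

    Two dosage vectors are in perfect LD iff they are affinely dependent;
    each vector is canonicalized (centered, scaled by its first non-zero
    entry) so grouping is exact for integer dosages. Constant vectors form
    their own group. The number of groups is the effective test count for
    Bonferroni correction.
    """
    groups: dict[tuple, list[str]] = {}
    dosages = genotypes.dosages.astype(float)
    for vid, row in zip(genotypes.variant_ids, dosages):
        c = row - row.mean()
        nz = np.flatnonzero(np.abs(c) > 1e-12)
        if nz.size == 0:
            key = ("const",)
        else:
            c = c / c[nz[0]]
            key = tuple(np.round(c, 9))
        groups.setdefault(key, []).append(vid)
    return list(groups.values())


def blocks_overlap_genes(blocks: list[LDBlock], annotation) -> pd.DataFrame:
    """Assign each gene to every block its body interval intersects (>= 1 bp).

    Returns a long table (gene, block_start, block_end, block_length).
    Coordinates are 1-based inclusive on both sides.
    """
    rows = []
    bodies = annotation.gene_bodies()
    for block in blocks:
        hits = bodies[
            (bodies["chrom"] == block.chrom)
            & (bodies["start"] <= block.end)
            & (bodies["end"] >= block.start)
        ]
        for g in hits["gene"]:
            rows.append(
                {
                    "gene": g,
                    "block_start": block.start,
                    "block_end": block.end,
                    "block_length": block.length,
                }
            )
            if g not in block.genes:
                block.genes.append(g)
    return pd.DataFrame(rows, columns=["gene", "block_start", "block_end", "block_length"])


def blocks_to_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "length_bp": b.length,
                "n_snvs": b.n_snvs,
                "members": ",".join(b.members),
            }
            for b in blocks
        ],
        columns=["chrom", "start", "end", "length_bp", "n_snvs", "members"],
    )
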