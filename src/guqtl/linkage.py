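"""Coding-allele linkage and regulatory enrichment via Fisher exact tests.

Links germline coding-allele content to lead guQTL genotype: for each gene,
a table of diploid allele-copy counts (2 per individual) by guQTL genotype
class is tested with Fisher's exact test — exact hypergeometric for 2x2,
fixed-margin enumeration for r x c (Monte Carlo with a fixed seed when the
table space is too large). The same machinery tests enrichment of guQTL
variants over annotation tracks (e.g. TFBS clusters).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, lgamma

import numpy as np
import pandas as pd

from .repertoire import PersonalizedGermlineSet


@dataclass
class ContingencyResult:
    """Outcome of one exact contingency test."""

    label: str
    table: np.ndarray
    p: float
    sided: str
    method: str  # exact_enumeration | monte_carlo
    mc_se: float | None = None
    odds_ratio: float | None = None
    significant: bool | None = None


def _hypergeom_pmf(a: int, r1: int, c1: int, n: int) -> float:
    """P(top-left cell = a) for a 2x2 table with fixed margins."""
    return comb(c1, a) * comb(n - c1, r1 - a) / comb(n, r1)


def fisher_exact_2x2(table: np.ndarray, sided: str = "two") -> float:
    """Exact 2x2 Fisher P: hypergeometric tail(s) over the top-left cell.

    ``sided='greater'`` tests enrichment of the top-left cell; ``'two'``
    sums all tables with probability <= the observed table's (standard
    two-sided convention).
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if sided == "greater":
        return min(1.0, sum(_hypergeom_pmf(x, r1, c1, n) for x in range(a, hi + 1)))
    if sided == "less":
        return min(1.0, sum(_hypergeom_pmf(x, r1, c1, n) for x in range(lo, a + 1)))
    p_obs = _hypergeom_pmf(a, r1, c1, n)
    total = sum(
        p for x in range(lo, hi + 1)
        if (p := _hypergeom_pmf(x, r1, c1, n)) <= p_obs * (1 + 1e-7)
    )
    return min(1.0, total)


def _log_table_prob(table: np.ndarray, lg_const: float) -> float:
    return lg_const - sum(lgamma(v + 1) for v in table.reshape(-1))


def _enumerate_tables(row_margins, col_margins, max_tables):
    """Yield all non-negative integer tables with the given margins.

    Raises MemoryError-ish OverflowError when more than ``max_tables``
    tables are generated (caller falls back to Monte Carlo).
    """
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=int)
    count = [0]

    def fill(i, j, row_left, col_left):
        if count[0] > max_tables:
            raise OverflowError("table space too large")
        if i == r - 1:
            # last row is determined by the column remainders
            for k in range(c):
                table[i, k] = col_left[k]
            count[0] += 1
            yield table
            return
        if j == c - 1:
            v = row_left
            if v > col_left[j]:
                return
            table[i, j] = v
            col_left[j] -= v
            yield from fill(i + 1, 0, row_margins[i + 1], col_left)
            col_left[j] += v
            return
        for v in range(min(row_left, col_left[j]) + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from fill(i, j + 1, row_left - v, col_left)
            col_left[j] += v

    yield from fill(0, 0, row_margins[0], list(col_margins))


def fisher_exact(
    table: np.ndarray,
    sided: str = "two",
    max_tables: int = 1_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
    label: str = "",
) -> ContingencyResult:
    """Fisher's exact test for an r x c count table.

    2x2 tables use the closed-form hypergeometric tail. Larger tables are
    tested two-sided by exact enumeration over all tables with the observed
    margins when their number is <= ``max_tables``, otherwise by Monte
    Carlo permutation sampling (``n_mc`` draws, fixed seed) with a reported
    standard error. Degenerate margins (an all-zero row/column or a single
    row/column) are an error.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("negative counts")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    if table.shape[0] < 2 or table.shape[1] < 2 or (row_m == 0).any() or (col_m == 0).any():
        raise ValueError("degenerate margins")
    if table.shape == (2, 2):
        p = fisher_exact_2x2(table, sided)
        oddsr = None
        if table[0, 1] * table[1, 0] > 0:
            oddsr = float(table[0, 0] * table[1, 1]) / float(table[0, 1] * table[1, 0])
        return ContingencyResult(label, table, p, sided, "exact_enumeration", odds_ratio=oddsr)
    if sided != "two":
        raise ValueError("one-sided tests are defined for 2x2 tables only")

    n = int(table.sum())
    lg_const = (
        sum(lgamma(v + 1) for v in row_m)
        + sum(lgamma(v + 1) for v in col_m)
        - lgamma(n + 1)
    )
    logp_obs = _log_table_prob(table, lg_const)
    try:
        total = 0.0
        for t in _enumerate_tables(list(row_m), list(col_m), max_tables):
            lp = _log_table_prob(t, lg_const)
            if lp <= logp_obs + 1e-7:
                total += np.exp(lp)
        return ContingencyResult(label, table, min(1.0, total), sided, "exact_enumeration")
    except OverflowError:
        pass
    # Monte Carlo: permute column labels against row labels
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    r, c = table.shape
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros((r, c), dtype=int)
        np.add.at(sim, (rows, perm), 1)
        if _log_table_prob(sim, lg_const) <= logp_obs + 1e-7:
            hits += 1
    p_hat = hits / n_mc
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_mc))
    return ContingencyResult(label, table, max(p_hat, 1 / n_mc), sided, "monte_carlo", mc_se=se)


# --------------------------------------------------- allele-genotype tables

def allele_by_genotype_table(
    germline_sets: dict[str, PersonalizedGermlineSet],
    gene: str,
    lead_dosages: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diploid allele-copy counts by lead-guQTL genotype class.

    Rows are the gene's distinct coding alleles, columns the genotype
    classes (dosage 0/1/2) observed; each included individual contributes
    its two chromosome alleles to its genotype column. Individuals lacking
    a germline entry for the gene are excluded (and counted via the table's
    attrs). A companion carrier table reports, per genotype class, the
    fraction of individuals carrying >= 1 copy of each allele.
    """
    copy_counts: dict[tuple[str, int], int] = {}
    carrier_counts: dict[tuple[str, int], int] = {}
    class_sizes: dict[int, int] = {}
    excluded = 0
    for ind, dosage in lead_dosages.items():
        gs = germline_sets.get(ind)
        pair = gs.diploid_alleles(gene) if gs is not None else None
        if pair is None:
            excluded += 1
            continue
        g = int(dosage)
        class_sizes[g] = class_sizes.get(g, 0) + 1
        for allele in pair:
            copy_counts[(allele, g)] = copy_counts.get((allele, g), 0) + 1
        for allele in set(pair):
            carrier_counts[(allele, g)] = carrier_counts.get((allele, g), 0) + 1
    if not copy_counts:
        raise ValueError(f"no individual carries a germline entry for {gene}")
    alleles = sorted({a for a, _ in copy_counts})
    classes = sorted(class_sizes)
    copies = pd.DataFrame(
        [[copy_counts.get((a, g), 0) for g in classes] for a in alleles],
        index=alleles,
        columns=[f"genotype_{g}" for g in classes],
    )
    carriers = pd.DataFrame(
        [[carrier_counts.get((a, g), 0) / class_sizes[g] for g in classes] for a in alleles],
        index=alleles,
        columns=[f"genotype_{g}" for g in classes],
    )
    copies.attrs["n_excluded"] = excluded
    return copies, carriers


def classify_allelic_variation(
    allele_frequencies: pd.Series,
    fisher_p: float | None,
    bonferroni_threshold: float,
    major_allele_cutoff: float = 0.95,
) -> str:
    """no_variation (major allele > cutoff) vs varies_with_guQTL vs
    varies_independent (split on the Bonferroni-corrected Fisher result)."""
    if allele_frequencies.max() > major_allele_cutoff:
        return "no_variation"
    if fisher_p is not None and fisher_p < bonferroni_threshold:
        return "varies_with_guQTL"
    return "varies_independent"


def cohort_allele_frequencies(
    germline_sets: dict[str, PersonalizedGermlineSet], gene: str
) -> pd.Series:
    """Allele frequencies over all chromosomes in the cohort."""
    counts: dict[str, int] = {}
    for gs in germline_sets.values():
        pair = gs.diploid_alleles(gene)
        if pair is None:
            continue
        for a in pair:
            counts[a] = counts.get(a, 0) + 1
    s = pd.Series(counts, dtype=float).sort_index()
    return s / s.sum()


def allele_linkage_scan(
    germline_sets: dict[str, PersonalizedGermlineSet],
    leads: pd.DataFrame,
    genotypes,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Fisher linkage of coding alleles to lead guQTL genotype.

    ``leads`` is the per-gene lead table from the usage scan; only genes
    with a significant lead are tested. The Bonferroni threshold is alpha
    over the number of genes with testable allele variation.
    """
    candidates = leads[leads["significant"]]
    results = []
    for row in candidates.itertuples():
        vid = row.lead_variants.split(",")[0]
        dosage = pd.Series(genotypes.dosage_of(vid), index=genotypes.individuals)
        freqs = cohort_allele_frequencies(germline_sets, row.gene)
        if freqs.empty:
            continue
        copies, _ = allele_by_genotype_table(germline_sets, row.gene, dosage)
        tbl = copies.to_numpy()
        testable = (
            tbl.shape[0] >= 2
            and tbl.shape[1] >= 2
            and (tbl.sum(axis=1) > 0).all()
            and (tbl.sum(axis=0) > 0).all()
        )
        p = None
        method = "skipped"
        if testable and freqs.max() <= 0.95:
            res = fisher_exact(tbl, sided="two", seed=seed, label=row.gene)
            p, method = res.p, res.method
        results.append(
            {
                "gene": row.gene,
                "lead_variant": vid,
                "major_allele_freq": float(freqs.max()),
                "p": p,
                "method": method,
            }
        )
    out = pd.DataFrame(results)
    if len(out):
        n_tested = int(out["p"].notna().sum())
        threshold = alpha / max(n_tested, 1)
        out["bonferroni_threshold"] = threshold
        out["classification"] = [
            classify_allelic_variation(
                cohort_allele_frequencies(germline_sets, r.gene), r.p, threshold
            )
            for r in out.itertuples()
        ]
    return out


# ----------------------------------------------------------- TFBS enrichment

def positions_in_track(positions: np.ndarray, track: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each 1-based position overlap any track interval."""
    mask = np.zeros(len(positions), dtype=bool)
    for iv in track.itertuples():
        mask |= (positions >= iv.start) & (positions <= iv.end)
    return mask


def tfbs_enrichment(
    guqtl_variants: set[str],
    genotypes,
    track: pd.DataFrame,
    label: str = "TFBS",
) -> ContingencyResult | None:
    """One-sided Fisher enrichment of guQTL variants over a track.

    2x2: rows {guQTL, non-guQTL}, columns {overlapping, non-overlapping};
    ``greater`` tail tests over-representation of guQTLs inside the track.
    Empty tracks are skipped (None returned).
    """
    if len(track) == 0:
        return None
    pos = genotypes.variants["pos"].to_numpy()
    ids = np.array(genotypes.variant_ids)
    in_track = positions_in_track(pos, track)
    is_guqtl = np.isin(ids, list(guqtl_variants))
    table = np.array(
        [
            [int((is_guqtl & in_track).sum()), int((is_guqtl & ~in_track).sum())],
            [int((~is_guqtl & in_track).sum()), int((~is_guqtl & ~in_track).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # no contrast (e.g. the track covers the whole locus)
        return ContingencyResult(label, table, 1.0, "greater", "exact_enumeration")
    return fisher_exact(table, sided="greater", label=label)
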