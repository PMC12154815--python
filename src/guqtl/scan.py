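"""Gene-usage QTL scan: per-gene OLS association, LD-aware Bonferroni,
lead-variant selection, location classification, and fold change.

Each retained gene's usage row is regressed on every common variant's
alt-allele dosage (usage = alpha + beta * dosage, ordinary least squares);
the slope's two-sided t test gives P. Multiple testing is corrected per
gene with a locus-wide Bonferroni denominator equal to the number of
perfect-LD variant groups (r2 = 1 collapses to one effective test), so all
genes in a locus share a single significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import LOCATION_PRECEDENCE, LocusAnnotation
from .genotypes import GenotypeTable
from .ld import collapse_perfect_ld
from .usage import UsageMatrix


@dataclass
class AssociationResult:
    """OLS summary for one gene-variant test."""

    gene: str
    variant_id: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    adj_r2: float
    partition: str = "unmutated"
    testable: bool = True


@dataclass
class LeadQTL:
    """The minimum-P significant variant(s) for one gene."""

    gene: str
    variants: list[str]
    p: float | None = None
    beta: float | None = None
    location: str | None = None
    variant_type: str | None = None
    fold_change: float | None = None
    fold_change_flag: str = "homozygote_ratio"
    significant: bool = False


def _ols_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple OLS: (beta, se, t, p, adj_r2)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    beta = sxy / sxx
    rss = syy - beta * sxy
    df = n - 2
    sigma2 = max(rss, 0.0) / df
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = float(2 * stats.t.sf(abs(t), df))
    r2 = 0.0 if syy == 0.0 else 1.0 - rss / syy
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    return beta, se, t, max(p, np.nextafter(0, 1)), adj_r2


def fit_association(
    usage_row: np.ndarray | pd.Series,
    dosages: np.ndarray,
    gene: str = "",
    variant_id: str = "",
    partition: str = "unmutated",
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """Regress one gene's usage on one variant's dosage.

    Samples with missing usage (NaN) are dropped pairwise. A constant dosage
    vector yields an untestable result (flagged, not an error); fewer than 3
    shared samples is an error. ``covariates`` (samples x k) are adjusted
    for by multiple regression; the reported slope stays the dosage term.
    """
    y = np.asarray(usage_row, dtype=float)
    x = np.asarray(dosages, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != x.size:
            covariates = covariates.T
        ok &= ~np.isnan(covariates).any(axis=1)
        covariates = covariates[ok]
    x, y = x[ok], y[ok]
    n = x.size
    k = 2 + (0 if covariates is None else covariates.shape[1])
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} samples, got {n}")
    if np.ptp(x) == 0.0:
        return AssociationResult(gene, variant_id, n, 0.0, np.nan, np.nan, 1.0, 0.0,
                                 partition, testable=False)
    if np.ptp(y) == 0.0:
        return AssociationResult(gene, variant_id, n, 0.0, 0.0, 0.0, 1.0, 0.0, partition)
    if covariates is None:
        beta, se, t, p, adj_r2 = _ols_stats(x, y)
    else:
        design = np.column_stack([np.ones(n), x, covariates])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        df = n - design.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(design.T @ design)
        beta = float(coef[1])
        se = float(np.sqrt(cov[1, 1]))
        t = beta / se if se > 0 else (np.inf if beta else 0.0)
        p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p = max(p, np.nextafter(0, 1))
        syy = float(((y - y.mean()) ** 2).sum())
        r2 = 0.0 if syy == 0 else 1.0 - float(resid @ resid) / syy
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    return AssociationResult(gene, variant_id, n, beta, se, t, p, adj_r2, partition)


def transform_usage(y_mat: np.ndarray, transform: str | None) -> np.ndarray:
    """Optional phenotype transformation before scanning.

    ``"logit"`` maps frequencies through log(p/(1-p)) with clipping at
    1e-6; ``"rankint"`` is the rank-based inverse-normal transform
    (Blom offsets), applied per gene row. Default is no transformation.
    """
    if transform is None:
        return y_mat
    if transform == "logit":
        p = np.clip(y_mat, 1e-6, 1 - 1e-6)
        return np.log(p / (1 - p))
    if transform == "rankint":
        out = np.empty_like(y_mat, dtype=float)
        n = y_mat.shape[1]
        for i, row in enumerate(y_mat):
            ranks = stats.rankdata(row)
            out[i] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        return out
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class ScanResult:
    """All association results for one locus and partition."""

    results: pd.DataFrame  # gene, variant_id, n, beta, se, t, p, adj_r2, significant
    threshold: float
    n_effective_tests: int
    partition: str = "unmutated"

    def significant_sets(self) -> dict[str, set[str]]:
        """Per-gene set of significant (guQTL) variant ids."""
        sig = self.results[self.results["significant"]]
        return {g: set(grp["variant_id"]) for g, grp in sig.groupby("gene")}

    def gene_results(self, gene: str) -> pd.DataFrame:
        return self.results[self.results["gene"] == gene]


def run_scan(
    usage: UsageMatrix,
    genotypes: GenotypeTable,
    ld_groups: list[list[str]] | None = None,
    alpha: float = 0.05,
    min_maf: float = 0.05,
    partition: str = "unmutated",
    transform: str | None = None,
    covariates: pd.DataFrame | None = None,
) -> ScanResult:
    """Test every retained gene against every common variant.

    Variants are MAF-filtered (>= ``min_maf``); the significance threshold
    is ``alpha`` divided by the number of perfect-LD groups among tested
    variants, shared by all genes in the locus. Samples are matched by id
    between the usage matrix and the genotype table; missing usage is
    handled pairwise per test. ``transform`` optionally maps usage rows
    through :func:`transform_usage`; ``covariates`` (indexed by sample)
    switches every fit to adjusted multiple regression.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype table")
    gt = genotypes.filter_maf(min_maf)
    if gt.n_variants == 0:
        raise ValueError(f"no variants at MAF >= {min_maf}")
    shared = [s for s in usage.samples if s in gt.individuals]
    gt = gt.subset_individuals(shared)
    if ld_groups is None:
        ld_groups = collapse_perfect_ld(gt)
    n_eff = len(ld_groups)
    threshold = alpha / n_eff

    y_mat = usage.frequencies[shared].to_numpy(dtype=float)  # genes x n
    y_mat = transform_usage(y_mat, transform)
    x_mat = gt.dosages.astype(float)  # variants x n
    cov = None
    if covariates is not None:
        cov = covariates.loc[shared].to_numpy(dtype=float)
    rows = []
    if cov is None and not np.isnan(y_mat).any():
        rows = _vectorized_scan(usage.genes, gt.variant_ids, y_mat, x_mat, partition)
    else:
        for gi, gene in enumerate(usage.genes):
            for vi, vid in enumerate(gt.variant_ids):
                res = fit_association(y_mat[gi], x_mat[vi], gene, vid, partition,
                                      covariates=cov)
                rows.append(res.__dict__)
    df = pd.DataFrame(rows)
    df["significant"] = df["testable"] & (df["p"] < threshold)
    return ScanResult(results=df, threshold=threshold, n_effective_tests=n_eff,
                      partition=partition)


def _vectorized_scan(genes, variant_ids, y_mat, x_mat, partition) -> list[dict]:
    """All gene x variant simple OLS fits at once via centered cross-products."""
    n = y_mat.shape[1]
    xc = x_mat - x_mat.mean(axis=1, keepdims=True)
    yc = y_mat - y_mat.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)  # (k,)
    syy = (yc * yc).sum(axis=1)  # (m,)
    sxy = yc @ xc.T  # (m, k)
    testable = sxx > 0
    sxx_safe = np.where(testable, sxx, 1.0)
    beta = sxy / sxx_safe
    rss = np.maximum(syy[:, None] - beta * sxy, 0.0)
    df_resid = n - 2
    se = np.sqrt(rss / df_resid / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    p = np.maximum(p, np.nextafter(0, 1))
    r2 = np.where(syy[:, None] > 0, 1.0 - rss / np.where(syy[:, None] > 0, syy[:, None], 1.0), 0.0)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    rows = []
    for gi, gene in enumerate(genes):
        for vi, vid in enumerate(variant_ids):
            ok = bool(testable[vi])
            rows.append(
                {
                    "gene": gene,
                    "variant_id": vid,
                    "n": n,
                    "beta": float(beta[gi, vi]) if ok else 0.0,
                    "se": float(se[gi, vi]) if ok else np.nan,
                    "t": float(t[gi, vi]) if ok else np.nan,
                    "p": float(p[gi, vi]) if ok else 1.0,
                    "adj_r2": float(adj_r2[gi, vi]) if ok else 0.0,
                    "partition": partition,
                    "testable": ok,
                }
            )
    return rows


def select_lead(
    gene_results: pd.DataFrame,
    threshold: float,
    genotypes: GenotypeTable | None = None,
) -> LeadQTL:
    """Pick the lead variant(s) for one gene: minimum P among significant
    tests, ties broken by larger |beta| then smaller genomic position; all
    co-minimal variants are reported (perfect-LD leads come in groups)."""
    gene = gene_results["gene"].iloc[0] if len(gene_results) else ""
    sig = gene_results[gene_results["testable"] & (gene_results["p"] < threshold)]
    if len(sig) == 0:
        return LeadQTL(gene=gene, variants=[], significant=False)
    p_min = sig["p"].min()
    at_min = sig[np.isclose(sig["p"], p_min, rtol=1e-12, atol=0.0)]
    b_max = at_min["beta"].abs().max()
    leads = at_min[np.isclose(at_min["beta"].abs(), b_max, rtol=1e-12, atol=0.0)]
    if genotypes is not None:
        pos = {v: int(genotypes.variants["pos"].iloc[genotypes.index_of(v)])
               for v in leads["variant_id"]}
        order = sorted(leads["variant_id"], key=lambda v: pos[v])
    else:
        order = list(leads["variant_id"])
    return LeadQTL(
        gene=gene,
        variants=order,
        p=float(p_min),
        beta=float(leads["beta"].iloc[0]),
        significant=True,
    )


def classify_location(
    variant_id: str, genotypes: GenotypeTable, annotation: LocusAnnotation
) -> str:
    """Annotate a variant position: coding > intron > L-Part1 > RSS subfield
    > intergenic. Raises when the position falls outside the locus bounds."""
    idx = genotypes.index_of(variant_id)
    pos = int(genotypes.variants["pos"].iloc[idx])
    lo, hi = annotation.locus_bounds
    if not lo <= pos <= hi:
        raise ValueError(f"variant {variant_id} at {pos} outside locus [{lo}, {hi}]")
    features = {f for _, f in annotation.features_at(pos)}
    for label, members in LOCATION_PRECEDENCE:
        if features & members:
            return label
    return "intergenic"


def fold_change(
    usage_row: np.ndarray | pd.Series, dosages: np.ndarray
) -> tuple[float | None, str]:
    """Ratio of genotype-group mean usages, max over min.

    Preferred contrast is the two homozygote classes (dosage 0 vs 2); when
    one is absent the ratio falls back to the extremes over the genotype
    classes present (flagged). A zero minimum or a single genotype class is
    reported as undefined.
    """
    y = np.asarray(usage_row, dtype=float)
    x = np.asarray(dosages, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    means = {g: y[x == g].mean() for g in np.unique(x)}
    if len(means) < 2:
        return None, "single_genotype_class"
    if 0.0 in means and 2.0 in means:
        hi, lo = max(means[0.0], means[2.0]), min(means[0.0], means[2.0])
        flag = "homozygote_ratio"
    else:
        vals = sorted(means.values())
        hi, lo = vals[-1], vals[0]
        flag = "present_class_ratio"
    if lo <= 0:
        return None, "zero_minimum"
    return float(hi / lo), flag


def additive_sv_check(
    usage_row: np.ndarray | pd.Series, copy_numbers: np.ndarray
) -> pd.DataFrame:
    """Mean usage per diploid gene copy number, with a monotonicity flag.

    Under an additive copy-number model the group means are non-decreasing
    in copy number; the returned frame carries one row per class and a
    ``monotone_nondecreasing`` attribute-style column repeated per row.
    """
    y = np.asarray(usage_row, dtype=float)
    cn = np.asarray(copy_numbers)
    classes = np.unique(cn)
    means = [float(y[cn == c].mean()) for c in classes]
    monotone = bool(np.all(np.diff(means) >= 0))
    return pd.DataFrame(
        {
            "copy_number": classes,
            "n": [int((cn == c).sum()) for c in classes],
            "mean_usage": means,
            "monotone_nondecreasing": monotone,
        }
    )


def summarize_leads(
    scan: ScanResult,
    usage: UsageMatrix,
    genotypes: GenotypeTable,
    annotation: LocusAnnotation | None = None,
) -> pd.DataFrame:
    """Per-gene lead table: lead variant(s), P, beta, location, type, fold
    change — the per-locus summary mirroring a guQTL results table."""
    gt = genotypes.filter_maf(0.0)
    shared = [s for s in usage.samples if s in gt.individuals]
    rows = []
    for gene in usage.genes:
        lead = select_lead(scan.gene_results(gene), scan.threshold, genotypes)
        row = {
            "gene": gene,
            "significant": lead.significant,
            "lead_variants": ",".join(lead.variants),
            "p": lead.p,
            "beta": lead.beta,
            "location": None,
            "variant_type": None,
            "fold_change": None,
            "fold_change_flag": None,
        }
        if lead.significant:
            vid = lead.variants[0]
            idx = genotypes.index_of(vid)
            row["variant_type"] = (
                "SV" if genotypes.variants["kind"].iloc[idx] == "SV_DEL" else "SNV"
            )
            if annotation is not None:
                row["location"] = classify_location(vid, genotypes, annotation)
            dos = genotypes.subset_individuals(shared).dosage_of(vid)
            fc, flag = fold_change(usage.frequencies.loc[gene, shared], dos)
            row["fold_change"], row["fold_change_flag"] = fc, flag
        rows.append(row)
    return pd.DataFrame(rows)
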