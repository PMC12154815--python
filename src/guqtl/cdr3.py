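"""CDR3 physicochemical properties and property-QTL scans.

The junction spans the conserved cysteine (C104) through the conserved
F/W (118); the CDR3 is the junction with those two residues trimmed. Nine
per-sequence properties are computed from standard amino-acid scales
(Kyte-Doolittle hydropathy for GRAVY, Zimmerman bulkiness, Grantham
polarity, the aliphatic index, residue-class fractions, and a
Henderson-Hasselbalch side-chain net charge with the EMBOSS pK table),
averaged per sample, and scanned against common variants with the same OLS
plus LD-collapsed Bonferroni machinery as the gene-usage scan.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .repertoire import gene_of
from .scan import ScanResult, run_scan, select_lead
from .usage import UsageMatrix

PROPERTY_NAMES = [
    "length",
    "gravy",
    "bulk",
    "aliphatic",
    "polarity",
    "charge",
    "basic",
    "acidic",
    "aromatic",
]

AROMATIC_SET = frozenset("FWHY")
AROMATIC_SET_NO_H = frozenset("FWY")
BASIC_SET = frozenset("RHK")
ACIDIC_SET = frozenset("DE")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def load_scales() -> dict[str, dict[str, float]]:
    """Amino-acid scale tables shipped with the package."""
    with resources.files("guqtl.data").joinpath("aa_scales.json").open() as fh:
        return json.load(fh)


_SCALES = load_scales()


def cdr3_from_junction(junction_aa: str, trim: bool = True) -> str:
    """Strip the conserved first (C) and last (F/W) junction residues.

    With ``trim=False`` the junction is returned unchanged. Junctions
    shorter than 2 residues trim to the empty string.
    """
    if not trim:
        return junction_aa
    if len(junction_aa) < 2:
        return ""
    return junction_aa[1:-1]


def compute_properties(
    cdr3_aa: str,
    ph: float = 7.4,
    scales: dict[str, dict[str, float]] | None = None,
    aromatic_set: frozenset[str] = AROMATIC_SET,
) -> dict[str, float]:
    """Per-sequence property vector for one CDR3 amino-acid string.

    charge sums side-chain ionizations only (termini excluded):
    basic side chains R, H, K contribute 1/(1+10^(pH-pK)); acidic side
    chains D, E, C, Y contribute -1/(1+10^(pK-pH)).
    """
    scales = scales or _SCALES
    bad = set(cdr3_aa) - STANDARD_AA
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {cdr3_aa!r}")
    n = len(cdr3_aa)
    if n == 0:
        return {name: np.nan for name in PROPERTY_NAMES} | {"length": 0.0}
    kd = scales["kyte_doolittle_hydropathy"]
    bulk = scales["zimmerman_bulkiness"]
    pol = scales["grantham_polarity"]
    pk = scales["emboss_pk"]
    counts = {aa: cdr3_aa.count(aa) for aa in set(cdr3_aa)}

    def frac(members) -> float:
        return sum(counts.get(aa, 0) for aa in members) / n

    charge = 0.0
    for aa in "RHK":
        charge += counts.get(aa, 0) / (1.0 + 10 ** (ph - pk[aa]))
    for aa in "DECY":
        charge -= counts.get(aa, 0) / (1.0 + 10 ** (pk[aa] - ph))
    aliphatic = (
        counts.get("A", 0) + 2.9 * counts.get("V", 0) + 3.9 * (counts.get("I", 0) + counts.get("L", 0))
    ) / n
    return {
        "length": float(n),
        "gravy": sum(kd[aa] * c for aa, c in counts.items()) / n,
        "bulk": sum(bulk[aa] * c for aa, c in counts.items()) / n,
        "aliphatic": aliphatic,
        "polarity": sum(pol[aa] * c for aa, c in counts.items()) / n,
        "charge": charge,
        "basic": frac(BASIC_SET),
        "acidic": frac(ACIDIC_SET),
        "aromatic": frac(aromatic_set),
    }


def sequence_properties(
    repertoire: pd.DataFrame, ph: float = 7.4, trim: bool = True
) -> pd.DataFrame:
    """Property table, one row per sequence (empty CDR3s get NaN rows)."""
    rows = []
    for rec in repertoire.itertuples():
        cdr3 = cdr3_from_junction(rec.junction_aa, trim=trim)
        props = compute_properties(cdr3, ph=ph) if cdr3 else {
            name: np.nan for name in PROPERTY_NAMES
        }
        rows.append({"sequence_id": rec.sequence_id, "sample_id": rec.sample_id, **props})
    return pd.DataFrame(rows)


def sample_mean_properties(
    repertoire: pd.DataFrame, properties: pd.DataFrame | None = None, ph: float = 7.4
) -> pd.DataFrame:
    """Per-sample unweighted mean of each property over scorable sequences.

    Returns properties x samples (so rows slot straight into the scan).
    Samples whose sequences all lack a scorable CDR3 come out as NaN.
    """
    if properties is None:
        properties = sequence_properties(repertoire, ph=ph)
    means = properties.groupby("sample_id", sort=True)[PROPERTY_NAMES].mean()
    return means.T


def property_qtl_scan(
    sample_means: pd.DataFrame,
    genotypes: GenotypeTable,
    ld_groups: list[list[str]] | None = None,
    alpha: float = 0.05,
    min_maf: float = 0.05,
    guqtl_sets: dict[str, set[str]] | None = None,
) -> tuple[ScanResult, pd.DataFrame]:
    """Associate per-sample property means with all common variants.

    Same machinery as the gene-usage scan; the Bonferroni denominator is the
    per-locus effective test count, not further divided by the number of
    properties. Returns the scan plus a per-property lead table including,
    when ``guqtl_sets`` is given, the genes whose guQTL sets contain the
    lead property variant.
    """
    phenotypes = UsageMatrix(
        frequencies=sample_means,
        counts=sample_means.notna().astype(int),
        sample_totals=pd.Series(1, index=sample_means.columns),
    )
    scan = run_scan(phenotypes, genotypes, ld_groups, alpha=alpha, min_maf=min_maf,
                    partition="property")
    rows = []
    for prop in sample_means.index:
        lead = select_lead(scan.gene_results(prop), scan.threshold, genotypes)
        overlap = []
        if lead.significant and guqtl_sets:
            overlap = sorted(
                g for g, s in guqtl_sets.items() if set(lead.variants) & s
            )
        rows.append(
            {
                "property": prop,
                "significant": lead.significant,
                "lead_variants": ",".join(lead.variants),
                "p": lead.p,
                "beta": lead.beta,
                "n_guqtl_genes_at_lead": len(overlap),
                "guqtl_genes_at_lead": ",".join(overlap),
            }
        )
    return scan, pd.DataFrame(rows)


def gene_subset_property(
    repertoire: pd.DataFrame,
    gene: str,
    property_name: str,
    ph: float = 7.4,
) -> pd.Series:
    """Per-sample mean of one property over sequences calling one V gene.

    Samples with no sequence calling the gene are missing (NaN). Useful for
    asking whether a single gene's germline-encoded residues explain a
    locus-wide CDR3 property shift.
    """
    genes = repertoire["v_call"].map(gene_of)
    if gene not in set(genes):
        raise KeyError(f"gene {gene!r} not called in repertoire")
    sub = repertoire[genes == gene]
    props = sequence_properties(sub, ph=ph)
    means = props.groupby("sample_id")[property_name].mean()
    all_samples = sorted(repertoire["sample_id"].unique())
    return means.reindex(all_samples)
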