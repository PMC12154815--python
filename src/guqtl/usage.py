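"""Gene-usage matrix: per-sample gene frequencies and gene retention.

Usage is counted at the gene level (allele suffix ignored) over unique
sequences, one column per sample: C[g, s] = count(g in s) / total unique
sequences in s. Frequencies are computed before gene filtering and are
deliberately not renormalized afterwards, so a column may sum to < 1 once
rare genes are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import gene_of


@dataclass
class UsageMatrix:
    """Genes x samples usage frequencies with companion raw counts."""

    frequencies: pd.DataFrame  # genes x samples, float
    counts: pd.DataFrame  # genes x samples, int
    sample_totals: pd.Series  # per-sample unique-sequence totals

    @property
    def genes(self) -> list[str]:
        return list(self.frequencies.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frequencies.columns)

    def row(self, gene: str) -> pd.Series:
        return self.frequencies.loc[gene]

    def to_tsv(self, freq_path: str, counts_path: str | None = None) -> None:
        self.frequencies.to_csv(freq_path, sep="\t", float_format="%.8g")
        if counts_path:
            self.counts.to_csv(counts_path, sep="\t")


def compute_usage(repertoire: pd.DataFrame, segment: str = "V") -> UsageMatrix:
    """Count gene usage per sample over unique sequences.

    ``segment`` selects ``v_call`` or ``j_call``; calls are collapsed to the
    gene (allele suffix after ``*`` dropped). Every sample must be non-empty:
    empty samples should have been removed by the sample filter upstream.
    """
    col = {"V": "v_call", "J": "j_call"}[segment.upper()]
    if len(repertoire) == 0:
        raise ValueError("empty repertoire")
    df = repertoire[["sample_id", col]].copy()
    df["gene"] = df[col].map(gene_of)
    counts = (
        df.groupby(["gene", "sample_id"], sort=True).size().unstack(fill_value=0)
    )
    totals = repertoire.groupby("sample_id", sort=True).size()
    if (totals == 0).any():
        raise ValueError("sample with zero sequences")
    counts = counts.reindex(columns=totals.index, fill_value=0)
    freqs = counts / totals
    return UsageMatrix(frequencies=freqs, counts=counts.astype(int), sample_totals=totals)


def mask_undisambiguated(usage: UsageMatrix, status: pd.DataFrame) -> UsageMatrix:
    """Restrict paralog-pair gene rows to their disambiguated subcohort.

    ``status`` is the per-individual table from paralog collapsing
    (individual, proximal, distal, disambiguated). For samples where a pair
    could not be disambiguated, the proximal and distal gene usages become
    missing (NaN) rather than zero, so association tests for those genes
    run pairwise-complete over the disambiguated subcohort only.
    """
    freqs = usage.frequencies.copy()
    counts = usage.counts.astype(float).copy()
    for row in status.itertuples():
        if row.disambiguated:
            continue
        for gene in (row.proximal, row.distal):
            if gene in freqs.index and row.individual in freqs.columns:
                freqs.loc[gene, row.individual] = np.nan
                counts.loc[gene, row.individual] = np.nan
    return UsageMatrix(frequencies=freqs, counts=counts, sample_totals=usage.sample_totals)


def retain_genes(usage: UsageMatrix, min_count: int = 10) -> UsageMatrix:
    """Keep genes whose count reaches ``min_count`` in at least one sample.

    Frequencies are not renormalized: they stay fractions of all unique
    sequences in the sample.
    """
    keep = usage.counts.max(axis=1) >= min_count
    return UsageMatrix(
        frequencies=usage.frequencies[keep],
        counts=usage.counts[keep],
        sample_totals=usage.sample_totals,
    )
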