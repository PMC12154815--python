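"""Phased diploid genotype container and VCF round-trip.

A :class:`GenotypeTable` holds biallelic SNVs and SV deletions for a cohort:
per-variant metadata plus a ``(n_variants, n_individuals, 2)`` haplotype
allele array. Diploid dosage is always the sum of the two haplotype alleles,
so phased information is never discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "kind"]


@dataclass
class GenotypeTable:
    """Variants x individuals phased genotype matrix.

    Parameters
    ----------
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, alt, kind``
        (kind is ``"SNV"`` or ``"SV_DEL"``), one row per variant, in
        positional order.
    haplotypes
        int8 array of shape ``(n_variants, n_individuals, 2)`` with allele
        codes 0 (ref) / 1 (alt). For SV deletions the alt allele is the
        deleted state.
    individuals
        Sample identifiers, one per column.
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.haplotypes.shape[0] != len(self.variants):
            raise ValueError("haplotype array and variant table disagree on n_variants")
        if self.haplotypes.shape[1] != len(self.individuals):
            raise ValueError("haplotype array and individual list disagree on n")
        if self.haplotypes.shape[2] != 2:
            raise ValueError("expected diploid haplotypes")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    @property
    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix, shape (n_variants, n_individuals)."""
        return self.haplotypes.sum(axis=2).astype(np.int16)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = self.index_of(variant_id)
        return self.haplotypes[idx].sum(axis=1).astype(np.int16)

    def index_of(self, variant_id: str) -> int:
        hits = np.flatnonzero((self.variants["variant_id"] == variant_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(hits[0])

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant from haplotype counts."""
        p = self.haplotypes.reshape(self.n_variants, -1).mean(axis=1)
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, min_maf: float = 0.05) -> "GenotypeTable":
        keep = self.maf() >= min_maf - 1e-12
        return self.subset_variants(np.flatnonzero(keep))

    def subset_variants(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        return GenotypeTable(
            self.variants.iloc[idx].reset_index(drop=True),
            self.haplotypes[idx],
            list(self.individuals),
        )

    def subset_individuals(self, ids) -> "GenotypeTable":
        pos = [self.individuals.index(i) for i in ids]
        return GenotypeTable(self.variants.copy(), self.haplotypes[:, pos, :], list(ids))

    # ------------------------------------------------------------------ VCF

    def to_vcf(self, path: str) -> None:
        """Write a minimal VCF v4.2 with phased GT calls."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(self.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            fh.write("\t".join(cols + list(self.individuals)) + "\n")
            for i, row in self.variants.iterrows():
                info = "SVTYPE=DEL" if row["kind"] == "SV_DEL" else "."
                gts = ["%d|%d" % (a, b) for a, b in self.haplotypes[i]]
                fh.write(
                    "\t".join(
                        [
                            str(row["chrom"]),
                            str(int(row["pos"])),
                            str(row["variant_id"]),
                            str(row["ref"]),
                            str(row["alt"]),
                            ".",
                            "PASS",
                            info,
                            "GT",
                        ]
                        + gts
                    )
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeTable":
        """Read phased biallelic records from a VCF into a GenotypeTable."""
        with pysam.VariantFile(path) as vf:
            individuals = list(vf.header.samples)
            rows = []
            haps = []
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError(f"record {rec.id} is not biallelic")
                kind = "SV_DEL" if rec.info.get("SVTYPE") == "DEL" else "SNV"
                rows.append(
                    {
                        "variant_id": rec.id,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": rec.alts[0],
                        "kind": kind,
                    }
                )
                haps.append([list(rec.samples[s]["GT"]) for s in individuals])
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        hap_arr = np.asarray(haps, dtype=np.int8) if haps else np.zeros((0, len(individuals), 2), np.int8)
        return cls(variants, hap_arr, individuals)
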