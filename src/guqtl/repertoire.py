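"""AIRR repertoire preparation with personalized germline sets.

Covers the pre-association bookkeeping for light-chain repertoires:
IGK paralog collapsing/disambiguation, the unmutated/mutated partition
(100% germline V and J identity), per-sample sequence-count filtering, and
restriction of allele calls to each individual's personalized germline set.

Repertoires are plain pandas DataFrames with AIRR Rearrangement columns
``sequence_id, sample_id, v_call, j_call, v_identity, j_identity,
junction_aa, duplicate_count``; identities are fractions in [0, 1]
(AIRR convention — use :func:`percent_to_fraction` for Change-O style
percent identities).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

AIRR_COLUMNS = [
    "sequence_id",
    "sample_id",
    "v_call",
    "j_call",
    "v_identity",
    "j_identity",
    "junction_aa",
    "duplicate_count",
]

#: gene pairs always collapsed to a single ambiguous label (sequence identity
#: between proximal/distal paralog alleles makes them inseparable cohort-wide)
DEFAULT_AMBI_MAP = {
    "IGKV1-37": "IGKV1-37ambi",
    "IGKV1D-37": "IGKV1-37ambi",
    "IGKV1-39": "IGKV1-39ambi",
    "IGKV1D-39": "IGKV1-39ambi",
    "IGKV2-40": "IGKV2-40ambi",
    "IGKV2D-40": "IGKV2-40ambi",
    "IGKV1-33": "IGKV1-33ambi",
    "IGKV1D-33": "IGKV1-33ambi",
    "IGKV2-28": "IGKV2-28ambi",
    "IGKV2D-28": "IGKV2-28ambi",
    # IGLJ2/IGLJ3 cassette genes are indistinguishable in expressed data
    "IGLJ2": "IGLJ2-3ambi",
    "IGLJ3": "IGLJ2-3ambi",
    "IGLJ3-1": "IGLJ2-3ambi",
    "IGLJ3-2": "IGLJ2-3ambi",
    "IGLJ3-3": "IGLJ2-3ambi",
    "IGLJ3-4": "IGLJ2-3ambi",
}

#: proximal/distal pairs that CAN be disambiguated per individual when every
#: proximal allele sequence differs from every distal allele sequence
DEFAULT_PARALOG_PAIRS = [
    ("IGKV1-12", "IGKV1D-12", "IGKV1-12ambi"),
    ("IGKV1-13", "IGKV1D-13", "IGKV1-13ambi"),
    ("IGKV6-21", "IGKV6D-21", "IGKV6-21ambi"),
]

_CALL_RE = re.compile(r"^(?P<gene>[^*]+)\*(?P<allele>.+)$")


def split_call(call: str) -> tuple[str, str]:
    """Split ``GENE*allele`` into its parts; allele may be empty-suffixed."""
    m = _CALL_RE.match(call)
    if m is None:
        return call, ""
    return m.group("gene"), m.group("allele")


def gene_of(call: str) -> str:
    """Gene name of the first listed call, allele suffix dropped."""
    return split_call(call.split(",")[0])[0]


def percent_to_fraction(identity: float) -> float:
    """Convert a Change-O percent identity (0-100) to an AIRR fraction."""
    return identity / 100.0


@dataclass
class PersonalizedGermlineSet:
    """Germline alleles carried by one individual.

    ``alleles`` maps gene -> {allele name -> amino-acid sequence};
    ``chrom_alleles`` maps gene -> (allele on haplotype 0, allele on
    haplotype 1) and supports diploid allele-copy counting;
    ``paralog_map`` is the symmetric proximal<->distal map with ambi labels.
    """

    individual_id: str
    alleles: dict[str, dict[str, str]]
    chrom_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    paralog_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def allele_names(self, gene: str) -> set[str]:
        return set(self.alleles.get(gene, {}))

    def has_call(self, call: str) -> bool:
        gene, allele = split_call(call)
        return allele in self.alleles.get(gene, {})

    def diploid_alleles(self, gene: str) -> tuple[str, str] | None:
        return self.chrom_alleles.get(gene)

    def can_disambiguate(self, proximal: str, distal: str) -> bool:
        """True when every proximal allele sequence differs from every distal one."""
        prox = set(self.alleles.get(proximal, {}).values())
        dist = set(self.alleles.get(distal, {}).values())
        if not prox or not dist:
            return True  # only one paralog present: nothing to confuse
        return prox.isdisjoint(dist)


def _rewrite_call(call: str, gene_map: dict[str, str]) -> str | None:
    """Map each member of a (possibly comma-separated) call; None = drop.

    Multi-gene calls are kept only when all members resolve to one label.
    """
    labels = []
    for member in call.split(","):
        gene, allele = split_call(member)
        mapped = gene_map.get(gene, gene)
        labels.append((mapped, allele))
    genes = {g for g, _ in labels}
    if len(genes) == 1:
        gene = genes.pop()
        allele = labels[0][1]
        return f"{gene}*{allele}" if allele else gene
    return None


def collapse_paralogs(
    repertoire: pd.DataFrame,
    germline_sets: dict[str, PersonalizedGermlineSet],
    ambi_map: dict[str, str] | None = None,
    paralog_pairs: list[tuple[str, str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rewrite paralog-ambiguous gene calls to their ``ambi`` labels.

    Genes in the fixed ``ambi_map`` are always rewritten. For each
    configurable proximal/distal pair, calls stay distinct only for
    individuals whose proximal allele sequences are all distinct from the
    distal ones; otherwise both genes are rewritten to the pair's ambi label.

    Returns the rewritten repertoire and a per-individual disambiguation
    status table (individual, proximal, distal, disambiguated).
    """
    ambi_map = DEFAULT_AMBI_MAP if ambi_map is None else ambi_map
    paralog_pairs = DEFAULT_PARALOG_PAIRS if paralog_pairs is None else paralog_pairs

    status_rows = []
    per_ind_maps: dict[str, dict[str, str]] = {}
    for sample in repertoire["sample_id"].unique():
        gs = germline_sets.get(sample)
        if gs is None:
            raise KeyError(f"no germline set for sample {sample!r}")
        gene_map = dict(ambi_map)
        for proximal, distal, label in paralog_pairs:
            ok = gs.can_disambiguate(proximal, distal)
            if not ok:
                gene_map[proximal] = label
                gene_map[distal] = label
            status_rows.append(
                {"individual": sample, "proximal": proximal, "distal": distal, "disambiguated": ok}
            )
        per_ind_maps[sample] = gene_map

    out = repertoire.copy()
    keep = []
    for i, row in enumerate(out.itertuples()):
        gene_map = per_ind_maps[row.sample_id]
        for col in ("v_call", "j_call"):
            call = getattr(row, col)
            new = _rewrite_call(call, gene_map)
            if new is None:
                keep.append(False)
                break
            out.iat[i, out.columns.get_loc(col)] = new
        else:
            keep.append(True)
    out = out[pd.Series(keep, index=out.index)].reset_index(drop=True)
    return out, pd.DataFrame(status_rows)


def partition_by_mutation(repertoire: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into unmutated (V and J identity both 1.0) and mutated records.

    Unmutated sequences match their assigned germline V and J alleles at
    100% identity and enrich for the antigen-naive repertoire; everything
    else is treated as mutated (antigen experienced).
    """
    if repertoire[["v_identity", "j_identity"]].isna().any().any():
        raise ValueError("v_identity / j_identity must be present for every record")
    unmut_mask = (repertoire["v_identity"] == 1.0) & (repertoire["j_identity"] == 1.0)
    unmutated = repertoire[unmut_mask].reset_index(drop=True)
    mutated = repertoire[~unmut_mask].reset_index(drop=True)
    return unmutated, mutated


def filter_samples(
    repertoire: pd.DataFrame, min_unique: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with fewer than ``min_unique`` unique sequences.

    Returns the filtered table and a removal log (sample_id, n_sequences).
    """
    counts = repertoire.groupby("sample_id", sort=True).size()
    dropped = counts[counts < min_unique]
    log = dropped.rename("n_sequences").reset_index()
    kept = repertoire[~repertoire["sample_id"].isin(dropped.index)].reset_index(drop=True)
    return kept, log


def restrict_to_germline(
    repertoire: pd.DataFrame, germline_sets: dict[str, PersonalizedGermlineSet]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only records whose V and J allele calls exist in the caller's
    personalized germline set; dropped records are counted per sample."""
    keep = []
    for row in repertoire.itertuples():
        gs = germline_sets.get(row.sample_id)
        ok = gs is not None and gs.has_call(row.v_call) and gs.has_call(row.j_call)
        keep.append(ok)
    mask = pd.Series(keep, index=repertoire.index)
    dropped = (
        repertoire[~mask].groupby("sample_id").size().rename("n_dropped").reset_index()
    )
    return repertoire[mask].reset_index(drop=True), dropped


# ---------------------------------------------------------------------- I/O

def read_airr(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "sample_id": str})
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR table {path} missing columns: {missing}")
    return df[AIRR_COLUMNS]


def write_airr(repertoire: pd.DataFrame, path: str) -> None:
    repertoire[AIRR_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
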