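"""Locus annotation: gene-feature intervals from BED, interval queries.

BED input is 0-based half-open; everything in memory is converted to 1-based
inclusive coordinates to match VCF positions. The ``name`` column encodes
``gene|feature`` where feature is one of ``V-exon``, ``J-exon``, ``intron``,
``L-Part1``, ``RSS_heptamer``, ``RSS_spacer``, ``RSS_nonamer``, ``gene_body``
or ``locus``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

#: location-class precedence: coding wins over intron, etc.
LOCATION_PRECEDENCE = [
    ("coding", {"V-exon", "J-exon"}),
    ("intron", {"intron"}),
    ("L-Part1", {"L-Part1"}),
    ("RSS_heptamer", {"RSS_heptamer"}),
    ("RSS_spacer", {"RSS_spacer"}),
    ("RSS_nonamer", {"RSS_nonamer"}),
]


@dataclass
class LocusAnnotation:
    """Feature intervals for one locus (1-based inclusive)."""

    features: pd.DataFrame  # chrom, start, end, gene, feature

    def __post_init__(self) -> None:
        self._tree = IntervalTree()
        for row in self.features.itertuples():
            # IntervalTree is half-open; store [start, end+1)
            self._tree[row.start : row.end + 1] = (row.gene, row.feature)

    @property
    def locus_bounds(self) -> tuple[int, int]:
        loc = self.features[self.features["feature"] == "locus"]
        if len(loc):
            return int(loc["start"].iloc[0]), int(loc["end"].iloc[0])
        return int(self.features["start"].min()), int(self.features["end"].max())

    def features_at(self, pos: int) -> list[tuple[str, str]]:
        """(gene, feature) pairs overlapping a 1-based position."""
        return sorted(iv.data for iv in self._tree[pos])

    def gene_bodies(self) -> pd.DataFrame:
        return self.features[self.features["feature"] == "gene_body"].reset_index(drop=True)

    @classmethod
    def from_bed(cls, path: str) -> "LocusAnnotation":
        bed = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "name"], comment="#"
        )
        gene_feature = bed["name"].str.split("|", expand=True)
        out = pd.DataFrame(
            {
                "chrom": bed["chrom"],
                "start": bed["start"] + 1,  # 0-based half-open -> 1-based inclusive
                "end": bed["end"],
                "gene": gene_feature[0],
                "feature": gene_feature[1],
            }
        )
        return cls(out)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for row in self.features.itertuples():
                fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}|{row.feature}\n")


def read_track_bed(path: str) -> pd.DataFrame:
    """Read a plain interval track (e.g. TFBS clusters) as 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {"chrom": bed[0], "start": bed[1] + 1, "end": bed[2]}
    )
    if bed.shape[1] > 3:
        out["name"] = bed[3]
    return out
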