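"""Genome annotation model and priority region labeling.

The budding-yeast genome is partitioned into six functional region types —
centromere, pericentromere, telomere, replication origin, gene, intergenic —
with a fixed priority in that order: where feature annotations overlap, every
base receives the highest-priority covering label, so the labels partition the
genome exactly. Pericentromeres are derived, not annotated: each centromere
extended by a flank (default 20 kb, the cohesin-enriched domain) on both
sides, clipped to the chromosome and excluding the centromere itself.

Coordinates are 0-based half-open throughout (BED convention). Gene TSS/TTS
are stored as genomic base positions of the first/last transcribed base, so a
'-' strand gene has tss > tts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

BED_COLUMNS = ("chrom", "start", "end")


class RegionLabel(IntEnum):
    """Functional region types; smaller value = higher assignment priority."""

    CENTROMERE = 0
    PERICENTROMERE = 1
    TELOMERE = 2
    ORIGIN = 3
    GENE = 4
    INTERGENIC = 5

    @property
    def label(self) -> str:
        return self.name.lower()


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def intervals(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a BED-like interval frame from (chrom, start, end[, name]) rows."""
    rows = list(rows)
    if not rows:
        return empty_intervals()
    ncol = len(rows[0])
    cols = list(BED_COLUMNS) + (["name"] if ncol > 3 else [])
    df = pd.DataFrame(rows, columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass
class Gene:
    """A transcript with experimentally derived TSS/TTS.

    tss/tts are genomic positions of the first and last transcribed base
    (0-based). The transcript extent (half-open span) is therefore
    [min(tss, tts), max(tss, tts) + 1).
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    expression_level: Optional[float] = None
    de_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.id}: '+' strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.id}: '-' strand requires tss > tts")
        if self.de_class is not None and self.de_class not in ("up", "down", "unchanged"):
            raise ValueError(f"gene {self.id}: bad de_class {self.de_class!r}")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts) + 1


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus typed feature sets.

    Interval frames have columns (chrom, start, end[, name]); aux_region_sets
    holds named auxiliary sets such as CLRs, LCNCRs or H2A.Z nucleosome
    positions.
    """

    chromosomes: dict[str, int]
    centromeres: pd.DataFrame = field(default_factory=empty_intervals)
    telomeres: pd.DataFrame = field(default_factory=empty_intervals)
    origins: pd.DataFrame = field(default_factory=empty_intervals)
    genes: list[Gene] = field(default_factory=list)
    ndrs: pd.DataFrame = field(default_factory=empty_intervals)
    rdna_mask: pd.DataFrame = field(default_factory=empty_intervals)
    pericentromere_flank: int = 20_000
    aux_region_sets: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pericentromere_flank < 0:
            raise ValueError("pericentromere_flank must be >= 0")
        named = {"centromeres": self.centromeres, "telomeres": self.telomeres,
                 "origins": self.origins, "ndrs": self.ndrs,
                 "rdna_mask": self.rdna_mask, **self.aux_region_sets}
        for name, df in named.items():
            for row in df.itertuples(index=False):
                if row.chrom not in self.chromosomes:
                    raise ValueError(f"{name}: unknown chromosome {row.chrom!r}")
                size = self.chromosomes[row.chrom]
                if not (0 <= row.start < row.end <= size):
                    raise ValueError(
                        f"{name}: interval {row.chrom}:{row.start}-{row.end} "
                        f"outside chromosome bounds [0, {size})")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom!r}")
            if not (0 <= g.start and g.end <= self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.id}: outside chromosome bounds")

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [g.id for g in self.genes],
             "chrom": [g.chrom for g in self.genes],
             "strand": [g.strand for g in self.genes],
             "tss": [g.tss for g in self.genes],
             "tts": [g.tts for g in self.genes],
             "start": [g.start for g in self.genes],
             "end": [g.end for g in self.genes],
             "expression_level": [g.expression_level for g in self.genes],
             "de_class": [g.de_class for g in self.genes]})


class RegionMap:
    """Per-base region labels for every chromosome.

    Stored densely (one int8 per base; a yeast-scale genome is ~12 MB) with
    run-length encoded export via :meth:`runs` / :meth:`to_frame`.
    """

    def __init__(self, labels: dict[str, np.ndarray]):
        self.labels = labels

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.labels

    @property
    def chromosomes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.labels.items()}

    def label_at(self, chrom: str, pos: int) -> RegionLabel:
        arr = self.labels[chrom]
        if not 0 <= pos < len(arr):
            raise IndexError(f"position {chrom}:{pos} outside chromosome")
        return RegionLabel(int(arr[pos]))

    def runs(self, chrom: str) -> list[tuple[int, int, RegionLabel]]:
        """Run-length encoding of one chromosome: (start, end, label)."""
        arr = self.labels[chrom]
        if len(arr) == 0:
            return []
        breaks = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(arr)]])
        return [(int(s), int(e), RegionLabel(int(arr[s])))
                for s, e in zip(starts, ends)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, s, e, lab.label)
                for c in self.labels for (s, e, lab) in self.runs(c)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def base_counts(self) -> pd.Series:
        counts = np.zeros(len(RegionLabel), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(RegionLabel))
        return pd.Series(counts, index=[l.label for l in RegionLabel])


def _paint(arr: np.ndarray, df: pd.DataFrame, chrom: str, value: int) -> None:
    sub = df[df["chrom"] == chrom]
    for row in sub.itertuples(index=False):
        arr[row.start:row.end] = value


def build_region_map(annotation: GenomeAnnotation) -> RegionMap:
    """Assign every base its highest-priority covering region label.

    Lower-priority layers are painted first and overwritten by higher
    priority ones, ending with centromeres. Pericentromere intervals are
    centromeres extended by ``pericentromere_flank`` per side, clipped to the
    chromosome, minus the centromere itself (painting order handles the
    subtraction). Raises on overlapping centromeres within one chromosome,
    which would make the normalization reference ambiguous.
    """
    annotation.validate()
    for chrom in annotation.chromosomes:
        cen = annotation.centromeres[annotation.centromeres["chrom"] == chrom]
        cen = cen.sort_values("start")
        if (cen["start"].values[1:] < cen["end"].values[:-1]).any():
            raise ValueError(f"overlapping centromeres on {chrom}")

    genes_bed = intervals([(g.chrom, g.start, g.end) for g in annotation.genes])
    flank = annotation.pericentromere_flank
    labels: dict[str, np.ndarray] = {}
    for chrom, size in annotation.chromosomes.items():
        arr = np.full(size, RegionLabel.INTERGENIC, dtype=np.int8)
        _paint(arr, genes_bed, chrom, RegionLabel.GENE)
        _paint(arr, annotation.origins, chrom, RegionLabel.ORIGIN)
        _paint(arr, annotation.telomeres, chrom, RegionLabel.TELOMERE)
        cen = annotation.centromeres[annotation.centromeres["chrom"] == chrom]
        for row in cen.itertuples(index=False):
            lo = max(0, row.start - flank)
            hi = min(size, row.end + flank)
            arr[lo:hi] = RegionLabel.PERICENTROMERE
        _paint(arr, annotation.centromeres, chrom, RegionLabel.CENTROMERE)
        labels[chrom] = arr
    return RegionMap(labels)


def genome_composition(region_map: RegionMap) -> pd.Series:
    """Percent of genome bases per region label; sums to 100."""
    counts = region_map.base_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("empty genome: no bases to classify")
    return 100.0 * counts / total


_DIRECTION = {("+", "+"): "tandem", ("-", "-"): "tandem",
              ("+", "-"): "convergent", ("-", "+"): "divergent"}


def classify_intergenic(genes: list[Gene]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify intergenic regions by the transcription direction of the
    flanking genes, and attach the class to each gene end.

    An intergenic region bounded on the left by a '+' (rightward) gene and on
    the right by another '+' gene is *tandem*; ('+','-') is *convergent* (the
    genes transcribe toward each other); ('-','+') is *divergent*. Regions at
    chromosome ends or with overlapping flanking genes are not emitted; gene
    ends without a bounded adjacent region are labeled ``unclassified``.

    Returns
    -------
    regions : DataFrame (chrom, start, end, left_id, right_id, direction)
    ends : DataFrame indexed by gene id with columns five_prime, three_prime
    """
    regions = []
    five = {g.id: "unclassified" for g in genes}
    three = {g.id: "unclassified" for g in genes}
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        left = gs[0] if gs else None
        for right in gs[1:]:
            if right.start <= left.end:
                # overlapping or abutting spans: no intergenic region; keep
                # whichever gene reaches further right as the next boundary
                if right.end > left.end:
                    left = right
                continue
            klass = _DIRECTION[(left.strand, right.strand)]
            regions.append((chrom, left.end, right.start,
                            left.id, right.id, klass))
            # which end of each flanking gene faces this region
            if left.strand == "+":
                three[left.id] = klass
            else:
                five[left.id] = klass
            if right.strand == "+":
                five[right.id] = klass
            else:
                three[right.id] = klass
            left = right
    regions_df = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "left_id", "right_id",
                          "direction"])
    ends = pd.DataFrame({"five_prime": pd.Series(five),
                         "three_prime": pd.Series(three)})
    ends.index.name = "id"
    return regions_df, ends
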