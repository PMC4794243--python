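"""Assignment of called peaks to genomic features.

Peaks are assigned one-region-each through their single center base (so a
peak straddling a boundary is still counted once), genes are scored for
peak hits in fixed flanks around the TSS (promoter) or TTS (3' end), and
peak sequence composition / auxiliary-set overlap are quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import PeakSet
from .genome import Gene, RegionLabel, RegionMap


@dataclass
class PeakRegionSummary:
    """Per-region-label peak counts; each peak counted exactly once."""

    table: pd.DataFrame  # index: label, columns: count, percent
    per_peak: pd.Series  # label per peak, aligned to the peak frame
    sample: str = ""


@dataclass
class GeneHitTable:
    per_gene: pd.DataFrame  # columns: id, hit
    n_hit: int
    n_genes: int
    side: str

    @property
    def percent(self) -> float:
        return 100.0 * self.n_hit / self.n_genes if self.n_genes else 0.0


def _peak_frame(peaks) -> pd.DataFrame:
    return peaks.df if isinstance(peaks, PeakSet) else peaks


def assign_peak_regions(peaks, region_map: RegionMap,
                        sample: str = "") -> PeakRegionSummary:
    """Label each peak by the region type at its center base."""
    df = _peak_frame(peaks)
    labels = []
    for row in df.itertuples(index=False):
        if row.chrom not in region_map:
            raise ValueError(f"peak center on unknown chromosome {row.chrom!r}")
        try:
            labels.append(region_map.label_at(row.chrom, row.center).label)
        except IndexError as err:
            raise ValueError(str(err)) from err
    per_peak = pd.Series(labels, index=df.index, dtype=str)
    names = [l.label for l in RegionLabel]
    counts = per_peak.value_counts().reindex(names, fill_value=0)
    total = counts.sum()
    table = pd.DataFrame({"count": counts,
                          "percent": 100.0 * counts / total if total else 0.0})
    return PeakRegionSummary(table=table, per_peak=per_peak, sample=sample)


def _gene_window(gene: Gene, flank: int, side: str,
                 chrom_size: int) -> tuple[int, int]:
    """Half-open window upstream of the TSS (promoter) or downstream of the
    TTS (3' end), in transcription orientation, clipped to the chromosome.
    For '-' strand genes upstream is toward larger coordinates."""
    if side == "promoter":
        if gene.strand == "+":
            w = (gene.tss - flank, gene.tss)
        else:
            w = (gene.tss + 1, gene.tss + 1 + flank)
    elif side == "three_prime":
        if gene.strand == "+":
            w = (gene.tts + 1, gene.tts + 1 + flank)
        else:
            w = (gene.tts - flank, gene.tts)
    else:
        raise ValueError("side must be 'promoter' or 'three_prime'")
    return max(0, w[0]), min(chrom_size, w[1])


def genes_with_peaks(peaks, genes: list[Gene], chromosomes: dict[str, int],
                     flank: int = 500, side: str = "promoter",
                     mode: str = "center") -> GeneHitTable:
    """Flag genes with >= 1 peak in the flank window on the given side.

    mode='center' (default) requires a peak *center* inside the window,
    matching the one-peak-one-region convention; mode='any' accepts any
    base overlap between peak and window.
    """
    df = _peak_frame(peaks)
    if mode not in ("center", "any"):
        raise ValueError("mode must be 'center' or 'any'")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        if mode == "center":
            pos = np.sort(sub["center"].to_numpy())
            by_chrom[chrom] = (pos, pos + 1)
        else:
            order = np.argsort(sub["start"].to_numpy())
            by_chrom[chrom] = (sub["start"].to_numpy()[order],
                               sub["end"].to_numpy()[order])
    hits = []
    for gene in genes:
        lo, hi = _gene_window(gene, flank, side, chromosomes[gene.chrom])
        hit = False
        if hi > lo and gene.chrom in by_chrom:
            starts, ends = by_chrom[gene.chrom]
            i = np.searchsorted(starts, hi, side="left")
            # peaks are disjoint and sorted, so only the run before hi matters
            hit = bool((ends[:i] > lo).any())
        hits.append(hit)
    per_gene = pd.DataFrame({"id": [g.id for g in genes], "hit": hits})
    return GeneHitTable(per_gene=per_gene, n_hit=int(np.sum(hits)),
                        n_genes=len(genes), side=side)


def at_content(peaks, genome_sequence: dict[str, str]) -> pd.DataFrame:
    """Percent A/T per peak span, case-insensitive; N bases are excluded
    from both numerator and denominator (all-N spans give NaN)."""
    df = _peak_frame(peaks)
    rows = []
    for row in df.itertuples(index=False):
        seq = genome_sequence.get(row.chrom)
        if seq is None:
            raise ValueError(f"no sequence for chromosome {row.chrom!r}")
        if row.end > len(seq) or row.start < 0:
            raise ValueError(f"peak {row.chrom}:{row.start}-{row.end} beyond "
                             f"sequence end ({len(seq)})")
        span = seq[row.start:row.end].upper()
        denom = len(span) - span.count("N")
        at = span.count("A") + span.count("T")
        rows.append((row.chrom, row.start, row.end,
                     100.0 * at / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "at_pct"])


def _merged_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for row in sub.itertuples(index=False):
            if starts and row.start <= ends[-1]:
                ends[-1] = max(ends[-1], row.end)
            else:
                starts.append(row.start)
                ends.append(row.end)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def interval_overlap_flags(queries: pd.DataFrame,
                           subjects: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: shares >= 1 base with any subject."""
    merged = _merged_by_chrom(subjects)
    flags = np.zeros(len(queries), dtype=bool)
    for i, row in enumerate(queries.itertuples(index=False)):
        if row.chrom not in merged:
            continue
        starts, ends = merged[row.chrom]
        j = np.searchsorted(starts, row.end, side="left")
        flags[i] = j > 0 and ends[j - 1] > row.start
    return flags


def overlap_fraction(region_set: pd.DataFrame, peaks) -> float:
    """Fraction of regions sharing >= 1 base with any peak
    (full-interval overlap, not center-based)."""
    if len(region_set) == 0:
        raise ValueError("empty region set")
    df = _peak_frame(peaks)
    if len(df) == 0:
        return 0.0
    flags = interval_overlap_flags(region_set, df)
    return float(flags.mean())
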