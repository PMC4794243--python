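"""Fragment filtering, occupancy tracks, normalization and peak calling.

The signal chain mirrors a centromere-referenced MNase ChIP-seq analysis:

1. keep properly paired mononucleosome-scale fragments (mapping score >= 30,
   insert length in [50, 240], bounds inclusive);
2. per-base fragment pileup for ChIP and input samples;
3. depth-scale the input to the ChIP's total fragment-base count and subtract
   it, clamping at zero;
4. scale the subtracted track so the mean signal over all centromeric bases
   equals a fixed reference level (the centromere carries a CENP-A nucleosome
   constitutively, making it the common yardstick across strains);
5. zero out the rDNA repeat (unmappable at single-copy resolution);
6. call peaks as maximal runs of bases strictly above a threshold, where the
   threshold is the minimum per-centromere mean coverage in a reference
   strain's normalized track.

Fragments are plain DataFrames with columns (chrom, start, end, score)
(0-based half-open), as read from BEDPE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FragmentFilterSpec:
    """Mononucleosome fragment filter: score and insert-size bounds.

    Insert-size bounds are inclusive on both sides ("between 50 and 240"
    read as a closed interval).
    """

    min_mapping_score: int = 30
    min_insert: int = 50
    max_insert: int = 240
    require_proper_pair: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_insert <= self.max_insert:
            raise ValueError("need 0 < min_insert <= max_insert")


@dataclass
class CoverageTrack:
    """Per-chromosome signal at 1 bp resolution.

    stage is one of raw / subtracted / normalized / smoothed / masked;
    norm_factor records the multiplier applied by centromere normalization.
    """

    data: dict[str, np.ndarray]
    stage: str = "raw"
    norm_factor: float = 1.0

    @property
    def chromosomes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def with_data(self, data: dict[str, np.ndarray], stage: str,
                  norm_factor: float | None = None) -> "CoverageTrack":
        return CoverageTrack(data=data, stage=stage,
                             norm_factor=self.norm_factor
                             if norm_factor is None else norm_factor)


@dataclass
class PeakSet:
    """Disjoint, sorted above-threshold intervals with center and score."""

    df: pd.DataFrame  # columns: chrom, start, end, center, score
    threshold: float

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def empty(threshold: float = 0.0) -> "PeakSet":
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64),
                           "center": pd.Series(dtype=np.int64),
                           "score": pd.Series(dtype=float)})
        return PeakSet(df=df, threshold=threshold)


def filter_fragments(raw_pairs: pd.DataFrame,
                     spec: FragmentFilterSpec | None = None) -> pd.DataFrame:
    """Keep fragments with score >= min_mapping_score and insert length in
    [min_insert, max_insert] (inclusive). Length is end - start.

    If the frame has a boolean ``proper_pair`` column and the spec requires
    proper pairs, improper pairs are dropped as well.
    """
    spec = spec or FragmentFilterSpec()
    if raw_pairs.empty:
        return raw_pairs.copy()
    length = raw_pairs["end"] - raw_pairs["start"]
    keep = ((raw_pairs["score"] >= spec.min_mapping_score)
            & (length >= spec.min_insert) & (length <= spec.max_insert))
    if spec.require_proper_pair and "proper_pair" in raw_pairs.columns:
        keep &= raw_pairs["proper_pair"].astype(bool)
    return raw_pairs[keep].reset_index(drop=True)


def compute_occupancy(fragments: pd.DataFrame,
                      chromosomes: dict[str, int]) -> CoverageTrack:
    """Per-base pileup: value at base b = number of fragments covering b."""
    data = {c: np.zeros(size, dtype=np.int64)
            for c, size in chromosomes.items()}
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in chromosomes:
            bad = sub.index[0]
            raise ValueError(f"fragment {bad} on unknown chromosome {chrom!r}")
        size = chromosomes[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = (starts < 0) | (ends > size) | (starts >= ends)
        if bad.any():
            i = sub.index[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"fragment {i} ({chrom}:{starts[bad][0]}-{ends[bad][0]}) "
                f"outside chromosome bounds [0, {size})")
        diff = np.bincount(starts, minlength=size + 1).astype(np.int64)
        diff -= np.bincount(ends, minlength=size + 1)
        data[chrom] = np.cumsum(diff[:size])
    return CoverageTrack(data=data, stage="raw")


def subtract_background(chip: CoverageTrack,
                        input_track: CoverageTrack) -> CoverageTrack:
    """max(chip - scaled input, 0), input depth-scaled so its total
    fragment-base count matches the ChIP's."""
    if chip.stage != "raw" or input_track.stage != "raw":
        raise ValueError("subtract_background expects two raw tracks")
    if chip.chromosomes != input_track.chromosomes:
        raise ValueError("tracks are on different genomes")
    input_total = input_track.total()
    if input_total == 0:
        raise ValueError("input track has zero total coverage")
    scale = chip.total() / input_total
    data = {c: np.maximum(chip.data[c] - scale * input_track.data[c], 0.0)
            for c in chip.data}
    return CoverageTrack(data=data, stage="subtracted")


def _centromere_values(track: CoverageTrack,
                       centromeres: pd.DataFrame) -> list[np.ndarray]:
    vals = []
    for row in centromeres.itertuples(index=False):
        if row.chrom not in track.data:
            raise ValueError(f"centromere on unknown chromosome {row.chrom!r}")
        vals.append(track.data[row.chrom][row.start:row.end])
    return vals


def normalize_to_centromeres(track: CoverageTrack, centromeres: pd.DataFrame,
                             reference_level: float = 10_000.0) -> CoverageTrack:
    """Scale the track so the mean signal over all centromeric bases equals
    reference_level. Idempotent; errors on zero centromeric coverage
    (a failed ChIP has no reference signal)."""
    if len(centromeres) == 0:
        raise ValueError("normalization requires at least one centromere")
    vals = _centromere_values(track, centromeres)
    mean = float(np.concatenate(vals).mean())
    if mean <= 0:
        raise ValueError("zero centromeric coverage: cannot normalize "
                         "(failed ChIP?)")
    factor = reference_level / mean
    data = {c: a * factor for c, a in track.data.items()}
    return CoverageTrack(data=data, stage="normalized",
                         norm_factor=track.norm_factor * factor)


def smooth(track: CoverageTrack, window_bp: int) -> CoverageTrack:
    """Centered moving average with edge truncation; window must be odd."""
    if window_bp < 1 or window_bp % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    half = window_bp // 2
    data = {}
    for chrom, arr in track.data.items():
        n = len(arr)
        csum = np.concatenate([[0.0], np.cumsum(arr, dtype=np.float64)])
        idx = np.arange(n)
        lo = np.clip(idx - half, 0, n)
        hi = np.clip(idx + half + 1, 0, n)
        data[chrom] = (csum[hi] - csum[lo]) / (hi - lo)
    return CoverageTrack(data=data, stage="smoothed",
                         norm_factor=track.norm_factor)


def mask_regions(track: CoverageTrack,
                 mask_intervals: pd.DataFrame) -> CoverageTrack:
    """Zero the signal inside the mask intervals (e.g. the rDNA repeat)."""
    data = {c: a.astype(np.float64, copy=True) for c, a in track.data.items()}
    for row in mask_intervals.itertuples(index=False):
        if row.chrom in data:
            data[row.chrom][row.start:row.end] = 0.0
    return CoverageTrack(data=data, stage="masked",
                         norm_factor=track.norm_factor)


def compute_threshold(reference_track: CoverageTrack,
                      centromeres: pd.DataFrame) -> float:
    """Minimum over centromeres of the mean coverage across that centromere's
    bases, in the reference strain's normalized track."""
    if len(centromeres) == 0:
        raise ValueError("threshold requires at least one centromere")
    vals = _centromere_values(reference_track, centromeres)
    return float(min(v.mean() for v in vals))


def call_peaks(track: CoverageTrack, threshold: float, merge_gap: int = 0,
               min_width: int = 0) -> PeakSet:
    """Maximal runs of consecutive bases strictly above threshold.

    Runs separated by gaps <= merge_gap are merged; peaks narrower than
    min_width are dropped. center = floor((start + end - 1) / 2); score is
    the maximum value inside the peak.
    """
    rows = []
    for chrom, arr in track.data.items():
        above = arr > threshold
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        if merge_gap > 0 and len(starts) > 1:
            keep_s, keep_e = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s - keep_e[-1] <= merge_gap:
                    keep_e[-1] = e
                else:
                    keep_s.append(s)
                    keep_e.append(e)
            starts, ends = np.array(keep_s), np.array(keep_e)
        for s, e in zip(starts, ends):
            if e - s < min_width:
                continue
            rows.append((chrom, int(s), int(e), (int(s) + int(e) - 1) // 2,
                         float(arr[s:e].max())))
    if not rows:
        return PeakSet.empty(threshold)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center",
                                     "score"])
    return PeakSet(df=df, threshold=float(threshold))
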