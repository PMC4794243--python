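"""Anchored metaprofiles: mean coverage in fixed windows around oriented
genomic anchors (TSS, TTS, NDR/origin/centromere midpoints).

Signal is extracted over [pos - flank, pos + flank) for each anchor,
averaged in consecutive ``step`` bp bins (default 10), and reversed for '-'
oriented anchors so upstream is always at negative x. The profile is the
unweighted mean over anchors; anchors whose window runs off the chromosome
are dropped and counted. Bins are labeled by their start coordinate: 2 *
flank / step bins covering [-flank, +flank), no center bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import GenomeAnnotation, classify_intergenic

ANCHOR_COLUMNS = ("chrom", "pos", "strand")

GROUPING_SCHEMES = ("expression_quartile", "ndr_presence", "ndr_length_bins",
                    "direction", "de_class")


@dataclass
class Profile:
    bin_starts: np.ndarray  # bp relative to anchor, step apart
    mean: np.ndarray
    n_anchors: int
    n_dropped: int = 0
    step: int = 10
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_starts, "mean": self.mean,
                             "n": self.n_anchors})

    def argmax_bin(self) -> int:
        """Start coordinate of the bin with the highest mean."""
        return int(self.bin_starts[int(np.argmax(self.mean))])


def metaprofile(track: CoverageTrack, anchors: pd.DataFrame, flank: int = 500,
                step: int = 10, label: str = "") -> Profile:
    """Mean signal in ``step`` bp bins over [-flank, +flank) around anchors."""
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    n_bins = 2 * flank // step
    total = np.zeros(n_bins, dtype=np.float64)
    used = dropped = 0
    for row in anchors.itertuples(index=False):
        arr = track.data.get(row.chrom)
        if arr is None:
            raise ValueError(f"anchor on unknown chromosome {row.chrom!r}")
        lo, hi = row.pos - flank, row.pos + flank
        if lo < 0 or hi > len(arr):
            dropped += 1
            continue
        window = arr[lo:hi]
        if row.strand == "-":
            window = window[::-1]
        total += window.reshape(n_bins, step).mean(axis=1)
        used += 1
    mean = total / used if used else np.full(n_bins, np.nan)
    return Profile(bin_starts=np.arange(-flank, flank, step), mean=mean,
                   n_anchors=used, n_dropped=dropped, step=step, label=label)


def gene_anchors(annotation: GenomeAnnotation, kind: str = "TSS",
                 gene_ids: list[str] | None = None) -> pd.DataFrame:
    """TSS or TTS anchors, oriented by gene strand."""
    if kind not in ("TSS", "TTS"):
        raise ValueError("kind must be 'TSS' or 'TTS'")
    genes = annotation.genes
    if gene_ids is not None:
        wanted = set(gene_ids)
        genes = [g for g in genes if g.id in wanted]
    return pd.DataFrame(
        {"chrom": [g.chrom for g in genes],
         "pos": [(g.tss if kind == "TSS" else g.tts) for g in genes],
         "strand": [g.strand for g in genes],
         "gene_id": [g.id for g in genes]})


def interval_anchors(intervals_df: pd.DataFrame) -> pd.DataFrame:
    """Midpoint anchors (orientation '+') for NDRs, origins or centromeres."""
    return pd.DataFrame(
        {"chrom": intervals_df["chrom"],
         "pos": (intervals_df["start"] + intervals_df["end"]) // 2,
         "strand": "+"})


def _promoter_ndr_lengths(annotation: GenomeAnnotation,
                          flank: int = 500) -> pd.Series:
    """NDR length per gene, for NDRs overlapping the promoter window;
    genes without a promoter NDR are absent from the result."""
    ndr_by_chrom = {c: sub for c, sub in annotation.ndrs.groupby("chrom")}
    out = {}
    for g in annotation.genes:
        sub = ndr_by_chrom.get(g.chrom)
        if sub is None:
            continue
        if g.strand == "+":
            lo, hi = g.tss - flank, g.tss + 1
        else:
            lo, hi = g.tss, g.tss + 1 + flank
        hit = sub[(sub["start"] < hi) & (sub["end"] > lo)]
        if len(hit):
            out[g.id] = int((hit["end"] - hit["start"]).max())
    return pd.Series(out, dtype=np.int64)


def group_anchors(annotation: GenomeAnnotation, scheme: str,
                  kind: str = "TSS",
                  ndr_edges: tuple[int, ...] = (65,),
                  expression: pd.Series | None = None,
                  de_classes: pd.Series | None = None,
                  ) -> dict[str, pd.DataFrame]:
    """Partition gene anchors into labeled groups for grouped metaprofiles.

    Schemes: expression_quartile (rank-based quarters Q1 lowest .. Q4
    highest, ties broken by stable gene order), ndr_presence, ndr_length_bins
    (configurable edges, default a single split at 65 bp), direction
    (tandem/convergent/divergent of the adjacent intergenic region;
    unclassified ends are excluded) and de_class. Expression and DE class
    default to the per-gene metadata on the annotation.
    """
    if scheme not in GROUPING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    genes = annotation.genes
    groups: dict[str, list[str]] = {}

    if scheme == "expression_quartile":
        if expression is None:
            expression = pd.Series(
                {g.id: g.expression_level for g in genes
                 if g.expression_level is not None}, dtype=float)
        if expression.empty:
            raise ValueError("expression_quartile scheme needs expression "
                             "levels")
        ranks = expression.rank(method="first")
        quart = np.ceil(4 * ranks / len(ranks)).astype(int)
        for q in (1, 2, 3, 4):
            groups[f"Q{q}"] = list(expression.index[quart == q])
    elif scheme in ("ndr_presence", "ndr_length_bins"):
        lengths = _promoter_ndr_lengths(annotation)
        if scheme == "ndr_presence":
            with_ndr = set(lengths.index)
            groups["with_ndr"] = [g.id for g in genes if g.id in with_ndr]
            groups["without_ndr"] = [g.id for g in genes
                                     if g.id not in with_ndr]
        else:
            if lengths.empty:
                raise ValueError("ndr_length_bins scheme needs annotated NDRs")
            edges = sorted(ndr_edges)
            labels = ([f"<{edges[0]}"]
                      + [f"{a}-{b - 1}" for a, b in zip(edges[:-1], edges[1:])]
                      + [f">={edges[-1]}"])
            which = np.searchsorted(edges, lengths.values, side="right")
            for i, lab in enumerate(labels):
                ids = list(lengths.index[which == i])
                if ids:
                    groups[lab] = ids
    elif scheme == "direction":
        _, ends = classify_intergenic(genes)
        col = "five_prime" if kind == "TSS" else "three_prime"
        for klass in ("tandem", "convergent", "divergent"):
            ids = list(ends.index[ends[col] == klass])
            if ids:
                groups[klass] = ids
    elif scheme == "de_class":
        if de_classes is None:
            de_classes = pd.Series({g.id: g.de_class for g in genes
                                    if g.de_class is not None}, dtype=str)
        if de_classes.empty:
            raise ValueError("de_class scheme needs DE classes")
        for klass in ("up", "down", "unchanged"):
            ids = list(de_classes.index[de_classes == klass])
            if ids:
                groups[klass] = ids

    return {label: gene_anchors(annotation, kind=kind, gene_ids=ids)
            for label, ids in groups.items()}


@dataclass
class ProfileComparison:
    table: pd.DataFrame  # bin_start, mean_a, mean_b, ratio
    argmax_a: int
    argmax_b: int


def compare_profiles(profile_a: Profile, profile_b: Profile
                     ) -> ProfileComparison:
    """Align two profiles on one bin grid: paired values, per-bin ratio and
    each profile's argmax bin start."""
    if (profile_a.step != profile_b.step
            or not np.array_equal(profile_a.bin_starts, profile_b.bin_starts)):
        raise ValueError("profiles are on different bin grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.divide(profile_a.mean, profile_b.mean)
    table = pd.DataFrame({"bin_start": profile_a.bin_starts,
                          "mean_a": profile_a.mean, "mean_b": profile_b.mean,
                          "ratio": ratio})
    return ProfileComparison(table=table, argmax_a=profile_a.argmax_bin(),
                             argmax_b=profile_b.argmax_bin())
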