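"""Readers and writers for the formats the pipeline consumes and emits.

On-disk conventions follow each standard: BED/BEDPE/bedGraph are 0-based
half-open; GFF3 is 1-based closed and converted at the boundary; WIG export
is fixed-step at 10 bp (each value the mean over its step window). FASTA
goes through Biopython.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTrack, FragmentFilterSpec, PeakSet
from .genome import Gene, GenomeAnnotation, empty_intervals


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------ BED

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """BED3/4/5/6 -> frame with as many of (chrom, start, end, name, score,
    strand) as the file provides."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df.columns = BED6_COLUMNS[:df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    """Peaks as BED6: name carries the center, score the peak maximum."""
    df = peaks.df.copy()
    if df.empty:
        Path(path).write_text("")
        return
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                        "end": df["end"],
                        "name": "center=" + df["center"].astype(str),
                        "score": df["score"], "strand": "."})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> PeakSet:
    df = read_bed(path)
    if df.empty:
        return PeakSet.empty()
    center = (df["name"].str.replace("center=", "", regex=False).astype(np.int64)
              if "name" in df.columns
              else (df["start"] + df["end"] - 1) // 2)
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                        "end": df["end"], "center": center,
                        "score": df.get("score", 0.0)})
    return PeakSet(df=out, threshold=float("nan"))


# ---------------------------------------------------------------- BEDPE

def read_bedpe(path) -> pd.DataFrame:
    """Paired-end fragments: outer span of the two mates plus score.

    Accepts either full 8+ column BEDPE (chrom1 start1 end1 chrom2 start2
    end2 name score) or the 4-column short form (chrom start end score).
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "score": pd.Series(dtype=np.int64)})
    if raw.shape[1] >= 8:
        frame = pd.DataFrame({
            "chrom": raw[0].astype(str),
            "start": np.minimum(raw[1], raw[4]).astype(np.int64),
            "end": np.maximum(raw[2], raw[5]).astype(np.int64),
            "score": pd.to_numeric(raw[7], errors="coerce").fillna(0)})
        if (raw[0] != raw[3]).any():
            raise ValueError(f"{path}: inter-chromosomal pair encountered")
    else:
        frame = pd.DataFrame({"chrom": raw[0].astype(str),
                              "start": raw[1].astype(np.int64),
                              "end": raw[2].astype(np.int64),
                              "score": pd.to_numeric(raw[3], errors="coerce")
                              .fillna(0)})
    return frame


def write_bedpe(fragments: pd.DataFrame, path) -> None:
    """Fragments as 8-column BEDPE; each mate spans half the insert."""
    if fragments.empty:
        Path(path).write_text("")
        return
    mid = (fragments["start"] + fragments["end"]) // 2
    out = pd.DataFrame({
        0: fragments["chrom"], 1: fragments["start"], 2: mid,
        3: fragments["chrom"], 4: mid, 5: fragments["end"],
        6: [f"frag{i}" for i in range(len(fragments))],
        7: fragments["score"]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------- GFF3

def write_genes_gff3(genes: list[Gene], path) -> None:
    """Gene records, 1-based closed; TSS/TTS are implied by strand
    (the span is the transcript extent)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            fh.write("\t".join([g.chrom, "cenmap", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs])
                     + "\n")


def read_genes_gff3(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, "
                                 f"got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            ident = dict(kv.split("=", 1) for kv in attrs.split(";")
                         if "=" in kv).get("ID", f"line{ln}")
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            strand = strand if strand in "+-" else "+"
            if strand == "+":
                tss, tts = start0, end0 - 1
            else:
                tss, tts = end0 - 1, start0
            genes.append(Gene(id=ident, chrom=chrom, strand=strand,
                              tss=tss, tts=tts))
    return genes


def read_gene_table(path) -> pd.DataFrame:
    """Per-gene metadata TSV: columns id plus any of expression_level,
    de_class."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"{path}: gene table needs an 'id' column")
    return df


def attach_gene_table(genes: list[Gene], table: pd.DataFrame) -> None:
    meta = table.set_index("id")
    for g in genes:
        if g.id in meta.index:
            row = meta.loc[g.id]
            if "expression_level" in meta.columns and pd.notna(
                    row.get("expression_level")):
                g.expression_level = float(row["expression_level"])
            if "de_class" in meta.columns and pd.notna(row.get("de_class")):
                g.de_class = str(row["de_class"])


# ----------------------------------------------------- coverage formats

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encoded coverage (zero runs included)."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path, chromosomes: dict[str, int],
                  stage: str = "normalized") -> CoverageTrack:
    data = {c: np.zeros(size, dtype=np.float64)
            for c, size in chromosomes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom not in data:
            raise ValueError(f"{path}: unknown chromosome {row.chrom!r}")
        data[row.chrom][row.start:row.end] = row.value
    return CoverageTrack(data=data, stage=stage)


def write_wig(track: CoverageTrack, path, step: int = 10) -> None:
    """Fixed-step WIG; each value is the mean over its step window
    (trailing partial windows are dropped)."""
    with open(path, "w") as fh:
        fh.write("track type=wiggle_0\n")
        for chrom, arr in track.data.items():
            n = (len(arr) // step) * step
            if n == 0:
                continue
            means = arr[:n].reshape(-1, step).mean(axis=1)
            fh.write(f"fixedStep chrom={chrom} start=1 step={step} "
                     f"span={step}\n")
            fh.write("\n".join(f"{v:g}" for v in means) + "\n")


def read_wig(path, chromosomes: dict[str, int],
             stage: str = "normalized") -> CoverageTrack:
    """Read fixed-step WIG back to a per-base track (step-constant values)."""
    data = {c: np.zeros(size, dtype=np.float64)
            for c, size in chromosomes.items()}
    chrom, pos, step, span = None, 0, 10, 10
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                if chrom not in data:
                    raise ValueError(f"{path}: unknown chromosome {chrom!r}")
                pos = int(kv.get("start", 1)) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
                continue
            if chrom is None:
                raise ValueError(f"{path}: value before fixedStep header")
            end = min(pos + span, len(data[chrom]))
            data[chrom][pos:end] = float(line)
            pos += step
    return CoverageTrack(data=data, stage=stage)


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run; round-trips via YAML."""

    genome_fasta: Optional[str] = None
    centromeres_bed: Optional[str] = None
    telomeres_bed: Optional[str] = None
    origins_bed: Optional[str] = None
    genes_gff3: Optional[str] = None
    ndrs_bed: Optional[str] = None
    rdna_bed: Optional[str] = None
    gene_table: Optional[str] = None
    reference_sample: Optional[str] = None
    samples: dict[str, dict[str, str]] = field(default_factory=dict)
    filter_spec: FragmentFilterSpec = field(default_factory=FragmentFilterSpec)
    pericentromere_flank: int = 20_000
    reference_level: float = 10_000.0
    profile_flank: int = 500
    profile_step: int = 10
    smoothing_window: int = 75
    merge_gap: int = 0
    gene_flank: int = 500
    seed: int = 0
    output_dir: str = "cenmap_out"

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        spec = payload.pop("filter_spec", None)
        cfg = cls(**payload)
        if spec is not None:
            cfg.filter_spec = FragmentFilterSpec(**spec)
        return cfg


def load_annotation(config: PipelineConfig) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from the files a config points at."""
    sequences = read_fasta(config.genome_fasta)
    chromosomes = {name: len(seq) for name, seq in sequences.items()}

    def bed_or_empty(path):
        if path is None:
            return empty_intervals()
        df = read_bed(path)
        return df[[c for c in ("chrom", "start", "end", "name")
                   if c in df.columns]]

    genes = read_genes_gff3(config.genes_gff3) if config.genes_gff3 else []
    if config.gene_table:
        attach_gene_table(genes, read_gene_table(config.gene_table))
    return GenomeAnnotation(
        chromosomes=chromosomes,
        centromeres=bed_or_empty(config.centromeres_bed),
        telomeres=bed_or_empty(config.telomeres_bed),
        origins=bed_or_empty(config.origins_bed),
        genes=genes,
        ndrs=bed_or_empty(config.ndrs_bed),
        rdna_mask=bed_or_empty(config.rdna_bed),
        pericentromere_flank=config.pericentromere_flank)
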