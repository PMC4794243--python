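"""Synthetic genomes and MNase ChIP fragment sets with planted enrichment.

The generator emulates the structural features the pipeline depends on:

* chromosomes tiled by gene units whose promoters carry nucleosome-depleted
  regions (NDRs) flanked by -1/+1 nucleosomes, a regular nucleosome lattice
  elsewhere (165 bp repeat length), one AT-rich point centromere per
  chromosome with a single constitutive CENP-A nucleosome, telomeres, a few
  replication origins, and one rDNA-like high-copy interval;
* paired input/ChIP fragment sets: mononucleosome-sized fragments (truncated
  normal lengths, mean 150 sd 25, bounded to [50, 240]) whose midpoints
  jitter around nucleosome centers; ChIP sampling weights each nucleosome by
  a planted enrichment multiplier, input sampling is uniform per lattice copy;
* strain presets mirroring the four ChIP-seq strains: WT (centromere only),
  psh1 (a few ectopic promoters), OE (overexpression, many promoters), and
  psh1_OE (no proteolysis + overexpression, all NDR promoters). The
  centromeric ChIP multiplier is deliberately modest (the centromere is
  under-recovered by MNase in vivo), which is what allows strong ectopic
  promoter nucleosomes to exceed the centromere-mean peak threshold;
* differential-expression gene lists with an exactly planted overlap for the
  hypergeometric test.

Everything derives deterministically from ``SimulationConfig.seed``; the four
presets share a byte-identical genome for a given seed because genome layout
draws come from seed streams that do not depend on the preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .genome import Gene, GenomeAnnotation, empty_intervals, intervals

NUCLEOSOME_BP = 147  # DNA protected by one nucleosome

# independent deterministic rng streams derived from the one config seed
_STREAM_GENOME = 0
_STREAM_INPUT = 1
_STREAM_CHIP = 2
_STREAM_ECTOPIC = 3
_STREAM_DE = 4


@dataclass(frozen=True)
class StrainPreset:
    promoter_flank_mult: float
    ectopic_fraction: float


PRESETS: dict[str, StrainPreset] = {
    "WT": StrainPreset(1.0, 0.0),
    "psh1": StrainPreset(12.0, 0.03),
    "OE": StrainPreset(15.0, 0.35),
    "psh1_OE": StrainPreset(20.0, 1.0),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_lengths: Optional[tuple[int, ...]] = None
    nucleosome_spacing: int = 165
    ndr_length_range: tuple[int, int] = (48, 58)  # supports up to 557
    ndr_fraction: float = 0.9
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 25.0
    fragment_length_bounds: tuple[int, int] = (50, 240)
    n_fragments: int = 200_000
    strain_preset: str = "WT"
    centromere_mult: float = 10.0
    promoter_flank_mult: Optional[float] = None  # preset value if None
    ectopic_fraction: Optional[float] = None  # preset value if None
    baseline_mult: float = 1.0
    rdna_copies: int = 20
    rdna_chip_mult: float = 3.0
    centromere_at: float = 0.9
    background_at: float = 0.6
    gene_length: int = 1500
    promoter_length: int = 300
    telomere_length: int = 500
    centromere_length: int = 120
    rdna_length: int = 2000
    origin_length: int = 200
    midpoint_jitter_sd: float = 25.0
    mapping_score: int = 60

    def __post_init__(self) -> None:
        if self.chromosome_lengths is None:
            self.chromosome_lengths = (100_000,) * self.n_chromosomes
        self.chromosome_lengths = tuple(self.chromosome_lengths)
        self.n_chromosomes = len(self.chromosome_lengths)
        if self.strain_preset not in PRESETS:
            raise ValueError(f"unknown strain preset {self.strain_preset!r}; "
                             f"choose from {sorted(PRESETS)}")
        lo, hi = self.fragment_length_bounds
        if not 50 <= lo <= hi <= 240:
            raise ValueError("fragment length bounds must lie within [50, 240]")
        for name in ("centromere_mult", "baseline_mult", "rdna_chip_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.promoter_flank_mult is not None and self.promoter_flank_mult < 0:
            raise ValueError("promoter_flank_mult must be >= 0")

    @property
    def resolved_flank_mult(self) -> float:
        if self.promoter_flank_mult is not None:
            return self.promoter_flank_mult
        return PRESETS[self.strain_preset].promoter_flank_mult

    @property
    def resolved_ectopic_fraction(self) -> float:
        if self.ectopic_fraction is not None:
            return self.ectopic_fraction
        return PRESETS[self.strain_preset].ectopic_fraction


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score every pipeline stage.

    nucleosomes: DataFrame (chrom, center, start, end, kind, gene_id,
    weight, chip_mult) where kind is one of centromere / minus1 / plus1 /
    body / rdna, weight is the lattice copy number (rdna_copies inside the
    repeat, else 1) and chip_mult the planted ChIP enrichment multiplier.
    """

    nucleosomes: pd.DataFrame
    config: SimulationConfig

    def ectopic_centers(self, min_mult: float = 10.0) -> pd.DataFrame:
        nuc = self.nucleosomes
        mask = (nuc["kind"].isin(["minus1", "plus1"])
                & (nuc["chip_mult"] >= min_mult))
        return nuc[mask]

    def baseline_centers(self) -> pd.DataFrame:
        nuc = self.nucleosomes
        return nuc[(nuc["kind"] == "body")
                   & (nuc["chip_mult"] == self.config.baseline_mult)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _lattice(start: int, end: int, spacing: int) -> list[int]:
    """Nucleosome centers tiling [start, end): one per full repeat length."""
    centers = []
    c = start + spacing // 2
    while c + spacing // 2 <= end:
        centers.append(c)
        c += spacing
    return centers


def make_genome(config: SimulationConfig
                ) -> tuple[GenomeAnnotation, dict[str, str], SyntheticTruth]:
    """Build the synthetic genome, its annotation and planted truth.

    Raises if chromosomes are too short to host telomeres, a centromere and
    at least one gene unit.
    """
    rng = _rng(config, _STREAM_GENOME)
    unit = config.promoter_length + config.gene_length
    spacing = config.nucleosome_spacing
    half_nuc = NUCLEOSOME_BP // 2

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = dict(zip(chrom_names, config.chromosome_lengths))
    for name, length in chromosomes.items():
        needed = 2 * config.telomere_length + config.centromere_length + unit
        if length < needed:
            raise ValueError(f"{name}: length {length} too small to place "
                             f"telomeres, centromere and one gene unit "
                             f"(needs >= {needed})")

    cen_rows, tel_rows, ori_rows, ndr_rows, rdna_rows = [], [], [], [], []
    genes: list[Gene] = []
    nuc_rows = []  # chrom, center, kind, gene_id
    gene_n = 0

    for ci, (chrom, length) in enumerate(chromosomes.items()):
        tel = config.telomere_length
        tel_rows += [(chrom, 0, tel), (chrom, length - tel, length)]
        cen_mid = length // 2
        cen_lo = cen_mid - config.centromere_length // 2
        cen_rows.append((chrom, cen_lo, cen_lo + config.centromere_length))
        nuc_rows.append((chrom, cen_mid, "centromere", ""))

        reserved = [(cen_lo - 200, cen_lo + config.centromere_length + 200)]
        if ci == 0 and config.rdna_length > 0:
            r0 = int(length * 0.75)
            # mask padded by the max fragment length: fragments from edge
            # repeat nucleosomes spill coverage past the repeat boundary
            pad = config.fragment_length_bounds[1]
            rdna_rows.append((chrom, max(0, r0 - pad),
                              min(length, r0 + config.rdna_length + pad)))
            reserved.append((r0 - pad - 100,
                             r0 + config.rdna_length + pad + 100))
            for c in _lattice(r0, r0 + config.rdna_length, spacing):
                nuc_rows.append((chrom, c, "rdna", ""))
        for frac in (0.15, 0.9):
            o0 = int(length * frac)
            ori_rows.append((chrom, o0, o0 + config.origin_length))

        pos = tel
        while pos + unit <= length - tel:
            hit = next((r for r in reserved if pos < r[1] and pos + unit > r[0]),
                       None)
            if hit is not None:
                pos = max(pos + 1, hit[1])
                continue
            a, b = pos, pos + unit
            strand = "+" if rng.random() < 0.5 else "-"
            has_ndr = rng.random() < config.ndr_fraction
            ndr_len = int(rng.integers(config.ndr_length_range[0],
                                       config.ndr_length_range[1] + 1))
            gid = f"g{gene_n:04d}"
            gene_n += 1
            if strand == "+":
                tss, tts = a + config.promoter_length, b - 1
            else:
                tss, tts = b - 1 - config.promoter_length, a
            genes.append(Gene(id=gid, chrom=chrom, strand=strand, tss=tss,
                              tts=tts,
                              expression_level=float(rng.lognormal(2.0, 1.0))))
            if has_ndr:
                sign = 1 if strand == "+" else -1
                p1 = tss + 5 * sign
                m1 = p1 - sign * (NUCLEOSOME_BP + ndr_len)
                nuc_rows.append((chrom, m1, "minus1", gid))
                nuc_rows.append((chrom, p1, "plus1", gid))
                lo_c, hi_c = min(m1, p1), max(m1, p1)
                ndr_rows.append((chrom, lo_c + half_nuc + 1,
                                 hi_c - half_nuc, gid))
                c = lo_c - spacing
                while c - half_nuc >= a:
                    nuc_rows.append((chrom, c, "body", gid))
                    c -= spacing
                c = hi_c + spacing
                while c + half_nuc + 1 <= b:
                    nuc_rows.append((chrom, c, "body", gid))
                    c += spacing
            else:
                for c in _lattice(a, b, spacing):
                    nuc_rows.append((chrom, c, "body", gid))
            pos = b

    nuc = pd.DataFrame(nuc_rows, columns=["chrom", "center", "kind",
                                          "gene_id"])
    nuc["start"] = nuc["center"] - half_nuc
    nuc["end"] = nuc["center"] + half_nuc + 1
    nuc["weight"] = np.where(nuc["kind"] == "rdna",
                             float(config.rdna_copies), 1.0)
    nuc["chip_mult"] = config.baseline_mult
    nuc.loc[nuc["kind"] == "centromere", "chip_mult"] = config.centromere_mult
    nuc.loc[nuc["kind"] == "rdna", "chip_mult"] = config.rdna_chip_mult

    # preset-dependent ectopic enrichment at -1/+1 pairs of NDR promoters
    frac = config.resolved_ectopic_fraction
    ndr_genes = sorted(nuc.loc[nuc["kind"] == "plus1", "gene_id"].unique())
    if frac > 0 and ndr_genes:
        k = max(1, int(round(frac * len(ndr_genes))))
        pick = _rng(config, _STREAM_ECTOPIC).choice(
            ndr_genes, size=min(k, len(ndr_genes)), replace=False)
        sel = (nuc["kind"].isin(["minus1", "plus1"])
               & nuc["gene_id"].isin(pick))
        nuc.loc[sel, "chip_mult"] = config.resolved_flank_mult
    nuc = nuc.sort_values(["chrom", "center"]).reset_index(drop=True)

    # H2A.Z-like nucleosome set: all -1/+1 footprints (strain-independent)
    flank = nuc[nuc["kind"].isin(["minus1", "plus1"])]
    h2az = flank[["chrom", "start", "end"]].reset_index(drop=True)

    annotation = GenomeAnnotation(
        chromosomes=chromosomes,
        centromeres=intervals(cen_rows),
        telomeres=intervals(tel_rows),
        origins=intervals(ori_rows),
        genes=genes,
        ndrs=intervals(ndr_rows),
        rdna_mask=intervals(rdna_rows) if rdna_rows else empty_intervals(),
        aux_region_sets={"h2az_nucleosomes": h2az},
    )

    sequences = _draw_sequences(config, annotation, rng)
    truth = SyntheticTruth(nucleosomes=nuc, config=config)
    return annotation, sequences, truth


def _draw_sequences(config: SimulationConfig, annotation: GenomeAnnotation,
                    rng: np.random.Generator) -> dict[str, str]:
    sequences = {}
    for chrom, length in annotation.chromosomes.items():
        at_prob = np.full(length, config.background_at)
        cen = annotation.centromeres[annotation.centromeres["chrom"] == chrom]
        for row in cen.itertuples(index=False):
            at_prob[row.start:row.end] = config.centromere_at
        is_at = rng.random(length) < at_prob
        pick = rng.integers(0, 2, size=length)
        codes = np.where(is_at, pick, pick + 2)  # 0:A 1:T 2:G 3:C
        sequences[chrom] = "".join(np.array(["A", "T", "G", "C"])[codes])
    return sequences


def simulate_fragments(annotation: GenomeAnnotation, truth: SyntheticTruth,
                       config: SimulationConfig, role: str) -> pd.DataFrame:
    """Draw mononucleosome fragments for one sample.

    role='input': nucleosomes sampled proportional to lattice copy weight.
    role='chip': sampled proportional to weight x planted ChIP multiplier.
    Fragment midpoints jitter normally around nucleosome centers; lengths are
    truncated-normal within the configured bounds, so every simulated
    fragment passes the default mononucleosome filter unchanged.
    """
    if role not in ("input", "chip"):
        raise ValueError("role must be 'input' or 'chip'")
    n = config.n_fragments
    if n == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "score": pd.Series(dtype=np.int64)})
    rng = _rng(config, _STREAM_INPUT if role == "input" else _STREAM_CHIP)
    nuc = truth.nucleosomes
    w = nuc["weight"].to_numpy(float)
    if role == "chip":
        w = w * nuc["chip_mult"].to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    idx = rng.choice(len(nuc), size=n, p=w / w.sum())

    lo, hi = config.fragment_length_bounds
    mean, sd = config.fragment_length_mean, config.fragment_length_sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    lengths = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                            random_state=rng)
    lengths = np.clip(np.rint(lengths).astype(np.int64), lo, hi)

    centers = nuc["center"].to_numpy()[idx]
    jitter = np.rint(rng.normal(0.0, config.midpoint_jitter_sd, size=n))
    mids = centers + jitter.astype(np.int64)
    starts = mids - lengths // 2
    chroms = nuc["chrom"].to_numpy()[idx]
    sizes = np.array([annotation.chromosomes[c] for c in chroms])
    starts = np.clip(starts, 0, sizes - lengths)
    frags = pd.DataFrame({"chrom": chroms, "start": starts,
                          "end": starts + lengths,
                          "score": np.full(n, config.mapping_score,
                                           dtype=np.int64)})
    return frags.sort_values(["chrom", "start", "end"],
                             kind="stable").reset_index(drop=True)


def simulate_de_lists(genes: list, n_up_a: int, n_up_b: int, overlap_k: int,
                      seed: int) -> tuple[list[str], list[str], list[str]]:
    """Two gene lists over a shared universe with |A ∩ B| = overlap_k exactly.

    ``genes`` may be Gene objects or plain identifiers. Raises when the
    requested sizes are infeasible for the universe.
    """
    universe = [g.id if isinstance(g, Gene) else str(g) for g in genes]
    n = len(universe)
    if len(set(universe)) != n:
        raise ValueError("duplicate gene ids in universe")
    if not 0 <= overlap_k <= min(n_up_a, n_up_b):
        raise ValueError("need 0 <= overlap_k <= min(n_up_a, n_up_b)")
    if n_up_a + n_up_b - overlap_k > n:
        raise ValueError("lists cannot fit in the universe with the "
                         "requested overlap")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_DE]))
    perm = list(rng.permutation(universe))
    shared = perm[:overlap_k]
    a_only = perm[overlap_k:n_up_a]
    b_only = perm[n_up_a:n_up_a + (n_up_b - overlap_k)]
    return shared + a_only, shared + b_only, universe
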