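import numpy as np
import pandas as pd
import pytest

from cenmap import Gene, GenomeAnnotation, simulate_strain_panel
from cenmap.genome import intervals


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """1 kb chromosome: centromere [100,220), gene [150,500), flank 100."""
    return GenomeAnnotation(
        chromosomes={"chrI": 1000},
        centromeres=intervals([("chrI", 100, 220)]),
        genes=[Gene(id="g1", chrom="chrI", strand="+", tss=150, tts=499)],
        pericentromere_flank=100)


def brute_force_labels(chromosomes, feature_lists, flank):
    """Independent per-base labeling oracle: check each base against every
    feature set in priority order (centromere, pericentromere, telomere,
    origin, gene, intergenic)."""
    cen, tel, ori, gene_spans = feature_lists
    out = {}
    for chrom, size in chromosomes.items():
        arr = np.empty(size, dtype=np.int8)
        peri = [(c, max(0, s - flank), min(size, e + flank))
                for (c, s, e) in cen if c == chrom]
        for b in range(size):
            if any(s <= b < e for (c, s, e) in cen if c == chrom):
                arr[b] = 0
            elif any(s <= b < e for (c, s, e) in peri):
                arr[b] = 1
            elif any(s <= b < e for (c, s, e) in tel if c == chrom):
                arr[b] = 2
            elif any(s <= b < e for (c, s, e) in ori if c == chrom):
                arr[b] = 3
            elif any(s <= b < e for (c, s, e) in gene_spans if c == chrom):
                arr[b] = 4
            else:
                arr[b] = 5
        out[chrom] = arr
    return out


def brute_force_pileup(fragments: pd.DataFrame, chromosomes) -> dict:
    out = {c: np.zeros(size, dtype=int) for c, size in chromosomes.items()}
    for row in fragments.itertuples(index=False):
        for b in range(row.start, row.end):
            out[row.chrom][b] += 1
    return out


def brute_force_runs(values, threshold):
    """Maximal runs of consecutive indices strictly above threshold."""
    runs, start = [], None
    for i, v in enumerate(values):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


@pytest.fixture(scope="session")
def strain_panel():
    """Shared four-preset synthetic experiment (2 x 100 kb, 200k fragments
    per sample) analyzed at the WT-derived threshold."""
    return simulate_strain_panel(seed=1)
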