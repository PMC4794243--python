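"""Peak–nucleosome overlap and hypergeometric gene-list overlap tests.

The gene-list test asks: drawing |B| genes from a universe of N that
contains |A| marked genes, what is the probability of an intersection at
least as large as the one observed? That upper tail P(X >= k) is the
convention here ("at least the observed overlap"); a strict variant
P(X > k) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .regions import _peak_frame, interval_overlap_flags


@dataclass
class OverlapFractions:
    """Directional interval-overlap fractions between two interval sets."""

    frac_peaks: float  # fraction of peaks overlapping >= 1 nucleosome
    frac_nucleosomes: float  # fraction of nucleosomes overlapping >= 1 peak
    peak_flags: np.ndarray
    nucleosome_flags: np.ndarray


def peak_nucleosome_overlap(peaks, nucleosome_set: pd.DataFrame
                            ) -> OverlapFractions:
    """Fraction of peaks sharing >= 1 base with any nucleosome, and the
    converse fraction; per-interval flags are kept for stratified summaries.
    Empty sets yield fraction 0.0 rather than an error."""
    pdf = _peak_frame(peaks)
    p_flags = (interval_overlap_flags(pdf, nucleosome_set)
               if len(pdf) and len(nucleosome_set)
               else np.zeros(len(pdf), dtype=bool))
    n_flags = (interval_overlap_flags(nucleosome_set, pdf)
               if len(pdf) and len(nucleosome_set)
               else np.zeros(len(nucleosome_set), dtype=bool))
    return OverlapFractions(
        frac_peaks=float(p_flags.mean()) if len(p_flags) else 0.0,
        frac_nucleosomes=float(n_flags.mean()) if len(n_flags) else 0.0,
        peak_flags=p_flags, nucleosome_flags=n_flags)


@dataclass
class HypergeomTest:
    n_universe: int
    n_a: int
    n_b: int
    overlap: int
    p_value: float
    strict: bool = False


def hypergeom_overlap(list_a, list_b, universe,
                      strict: bool = False) -> HypergeomTest:
    """Upper-tail hypergeometric probability of the observed overlap.

    p = P(X >= k) by default (k = |A ∩ B|); strict=True gives P(X > k).
    Both lists must be subsets of the universe; offenders are listed in the
    error message.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    bad = sorted((a | b) - uni)
    if bad:
        raise ValueError(f"elements outside universe: {bad[:10]}"
                         + (" ..." if len(bad) > 10 else ""))
    n, na, nb = len(uni), len(a), len(b)
    k = len(a & b)
    # sf(x) = P(X > x); upper tail P(X >= k) = sf(k - 1)
    p = float(hypergeom.sf(k if strict else k - 1, n, na, nb))
    return HypergeomTest(n_universe=n, n_a=na, n_b=nb, overlap=k,
                         p_value=p, strict=strict)


@dataclass
class DeOverlap:
    direction: str
    a_only: int
    b_only: int
    shared: int
    test: HypergeomTest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"direction": self.direction, "a_only": self.a_only,
              "b_only": self.b_only, "shared": self.shared,
              "universe": self.test.n_universe,
              "p_value": self.test.p_value}])


def compare_de_lists(de_a: pd.Series, de_b: pd.Series, direction: str = "up",
                     universe: list | None = None,
                     strict: bool = False) -> DeOverlap:
    """Contingency (A-only / B-only / shared) and upper-tail test for the
    genes classed ``direction`` in two differential-expression tables.

    de_a / de_b map gene id -> class in {up, down, unchanged} over the same
    universe; a mismatch in universes is an error.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if universe is None:
        universe = sorted(de_a.index)
    if set(de_a.index) != set(universe) or set(de_b.index) != set(universe):
        raise ValueError("DE tables cover inconsistent universes")
    a = set(de_a.index[de_a == direction])
    b = set(de_b.index[de_b == direction])
    test = hypergeom_overlap(a, b, universe, strict=strict)
    shared = len(a & b)
    return DeOverlap(direction=direction, a_only=len(a) - shared,
                     b_only=len(b) - shared, shared=shared, test=test)
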