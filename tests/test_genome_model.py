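"""Region labeling, genome composition and intergenic direction classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenmap import (Gene, GenomeAnnotation, RegionLabel, build_region_map,
                    classify_intergenic, genome_composition)
from cenmap.genome import intervals

from conftest import brute_force_labels


class TestRegionMap:
    def test_toy_composition(self, toy_annotation):
        comp = genome_composition(build_region_map(toy_annotation))
        assert comp["centromere"] == pytest.approx(12.0)
        assert comp["pericentromere"] == pytest.approx(20.0)
        assert comp["gene"] == pytest.approx(18.0)
        assert comp["intergenic"] == pytest.approx(50.0)

    def test_toy_matches_brute_force(self, toy_annotation):
        rmap = build_region_map(toy_annotation)
        oracle = brute_force_labels(
            {"chrI": 1000}, ([("chrI", 100, 220)], [], [],
                             [("chrI", 150, 500)]), flank=100)
        assert np.array_equal(rmap.labels["chrI"], oracle["chrI"])

    def test_full_cover_single_gene(self):
        ann = GenomeAnnotation(
            chromosomes={"c": 300},
            genes=[Gene(id="g", chrom="c", strand="+", tss=0, tts=299)])
        comp = genome_composition(build_region_map(ann))
        assert comp["gene"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, toy_annotation):
        comp = genome_composition(build_region_map(toy_annotation))
        assert comp.sum() == pytest.approx(100.0, abs=0.01)

    def test_partition_exact(self, toy_annotation):
        rmap = build_region_map(toy_annotation)
        assert rmap.base_counts().sum() == 1000

    def test_two_equal_labels_split_50_50(self):
        ann = GenomeAnnotation(
            chromosomes={"c": 200},
            genes=[Gene(id="g", chrom="c", strand="+", tss=0, tts=99)])
        comp = genome_composition(build_region_map(ann))
        assert comp["gene"] == pytest.approx(50.0)
        assert comp["intergenic"] == pytest.approx(50.0)

    def test_zero_flank_gives_no_pericentromere(self, toy_annotation):
        toy_annotation.pericentromere_flank = 0
        comp = genome_composition(build_region_map(toy_annotation))
        assert comp["pericentromere"] == 0.0

    def test_pericentromere_never_overlaps_centromere(self, toy_annotation):
        rmap = build_region_map(toy_annotation)
        arr = rmap.labels["chrI"]
        assert (arr[100:220] == RegionLabel.CENTROMERE).all()

    def test_overlapping_centromeres_rejected(self):
        ann = GenomeAnnotation(
            chromosomes={"c": 1000},
            centromeres=intervals([("c", 100, 220), ("c", 200, 320)]))
        with pytest.raises(ValueError, match="overlapping centromeres"):
            build_region_map(ann)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            GenomeAnnotation(chromosomes={"c": 100},
                             centromeres=intervals([("c", 50, 150)]))

    def test_empty_genome_composition_errors(self):
        rmap = build_region_map(GenomeAnnotation(chromosomes={}))
        with pytest.raises(ValueError, match="empty genome"):
            genome_composition(rmap)

    def test_runs_reconstruct_labels(self, toy_annotation):
        rmap = build_region_map(toy_annotation)
        rebuilt = np.empty(1000, dtype=np.int8)
        for s, e, lab in rmap.runs("chrI"):
            rebuilt[s:e] = lab
        assert np.array_equal(rebuilt, rmap.labels["chrI"])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_priority_matches_brute_force_oracle(self, data):
        """Random small genomes: the label of every base equals the
        highest-priority covering feature, per the per-base oracle."""
        size = data.draw(st.integers(60, 200))
        flank = data.draw(st.integers(0, 30))

        def iv(max_n):
            out = []
            for _ in range(data.draw(st.integers(0, max_n))):
                s = data.draw(st.integers(0, size - 2))
                e = data.draw(st.integers(s + 1, size))
                out.append(("c", s, e))
            return out

        cen_s = data.draw(st.integers(0, size - 10))
        cen = [("c", cen_s, cen_s + data.draw(st.integers(1, 9)))]
        tel, ori = iv(2), iv(2)
        gene_spans = iv(3)
        genes = [Gene(id=f"g{i}", chrom="c", strand="+", tss=s, tts=e - 1)
                 for i, (_, s, e) in enumerate(gene_spans) if e - s >= 2]
        gene_spans = [("c", g.start, g.end) for g in genes]
        ann = GenomeAnnotation(chromosomes={"c": size},
                               centromeres=intervals(cen),
                               telomeres=intervals(tel),
                               origins=intervals(ori), genes=genes,
                               pericentromere_flank=flank)
        rmap = build_region_map(ann)
        oracle = brute_force_labels({"c": size}, (cen, tel, ori, gene_spans),
                                    flank)
        assert np.array_equal(rmap.labels["c"], oracle["c"])


def _genes(specs):
    out = []
    for i, (strand, start, end) in enumerate(specs):
        tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
        out.append(Gene(id=f"g{i}", chrom="c", strand=strand, tss=tss,
                        tts=tts))
    return out


class TestDirectionClasses:
    @pytest.mark.parametrize("left,right,expected", [
        ("+", "+", "tandem"), ("-", "-", "tandem"),
        ("+", "-", "convergent"), ("-", "+", "divergent")])
    def test_pair_classification(self, left, right, expected):
        regions, _ = classify_intergenic(
            _genes([(left, 10, 50), (right, 100, 150)]))
        assert list(regions["direction"]) == [expected]
        assert list(regions[["start", "end"]].iloc[0]) == [50, 100]

    def test_gene_end_labels(self):
        # tandem '+' pair: left gene's 3' end and right gene's 5' end face
        # the shared region; outer ends are unclassified
        _, ends = classify_intergenic(_genes([("+", 10, 50), ("+", 100, 150)]))
        assert ends.loc["g0", "three_prime"] == "tandem"
        assert ends.loc["g0", "five_prime"] == "unclassified"
        assert ends.loc["g1", "five_prime"] == "tandem"
        assert ends.loc["g1", "three_prime"] == "unclassified"

    def test_single_gene_unclassified(self):
        regions, ends = classify_intergenic(_genes([("+", 10, 50)]))
        assert regions.empty
        assert set(ends.loc["g0"]) == {"unclassified"}

    def test_true_reflection_preserves_classes(self):
        """Mirroring coordinates AND flipping strands is a rigid motion of
        the locus: every direction class is preserved."""
        size = 400
        specs = [("+", 10, 60), ("-", 100, 160), ("+", 200, 260),
                 ("-", 300, 380)]
        fwd, _ = classify_intergenic(_genes(specs))
        flipped = [("-" if s == "+" else "+", size - e, size - a)
                   for s, a, e in specs][::-1]
        rev, _ = classify_intergenic(_genes(flipped))
        assert list(rev["direction"])[::-1] == list(fwd["direction"])

    def test_coordinate_reversal_swaps_convergent_divergent(self):
        """Mirroring coordinates while keeping strands swaps convergent and
        divergent but fixes tandem."""
        size = 400
        specs = [("+", 10, 60), ("-", 100, 160), ("+", 200, 260)]
        fwd, _ = classify_intergenic(_genes(specs))
        mirrored = [(s, size - e, size - a) for s, a, e in specs][::-1]
        rev, _ = classify_intergenic(_genes(mirrored))
        swap = {"tandem": "tandem", "convergent": "divergent",
                "divergent": "convergent"}
        assert list(rev["direction"])[::-1] == [swap[d]
                                                for d in fwd["direction"]]

    def test_strand_orientation_invariant_enforced(self):
        with pytest.raises(ValueError, match="tss < tts"):
            Gene(id="bad", chrom="c", strand="+", tss=100, tts=50)
        with pytest.raises(ValueError, match="tss > tts"):
            Gene(id="bad", chrom="c", strand="-", tss=50, tts=100)
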