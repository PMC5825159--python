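"""Interval engine: BED I/O contracts, center extension, overlap, consensus, Venn classes."""

import numpy as np
import pytest

from conftest import brute_force_overlap, random_intervals
from crossbind.intervals import (
    BedFormatError,
    GenomicInterval,
    PeakSet,
    center_extend,
    classify_overlap,
    consensus_peaks,
    intersect_sets,
    merge_intervals,
    overlaps,
    read_bed,
    write_bed,
)

LAYERS = {"cortex": "CNS", "spinal_cord": "CNS", "stomach": "endoderm", "lung": "endoderm"}


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 300, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_peakset_keeps_intervals_sorted(self):
        ivs = (GenomicInterval("chr2", 5, 10), GenomicInterval("chr1", 50, 60),
               GenomicInterval("chr1", 5, 10))
        ps = PeakSet(ivs)
        assert [(iv.chrom, iv.start) for iv in ps] == [("chr1", 5), ("chr1", 50), ("chr2", 5)]


class TestBedIO:
    def test_basic_line_parses(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t300\n")
        ps = read_bed(p)
        assert ps.intervals == (GenomicInterval("chr1", 100, 300),)

    def test_round_trip_identity(self, tmp_path):
        ps = PeakSet((
            GenomicInterval("chr1", 100, 300, "a", 5.0),
            GenomicInterval("chr1", 400, 500, "b", 1.0),
            GenomicInterval("chr2", 0, 10, "c", 0.0),
        ))
        p = tmp_path / "rt.bed"
        write_bed(ps, p)
        back = read_bed(p)
        assert back.intervals == ps.intervals
        assert [iv.name for iv in back] == [iv.name for iv in ps]
        assert [iv.score for iv in back] == [iv.score for iv in ps]

    @pytest.mark.parametrize(
        "line", ["chr1\t300\t100", "chr1\tx\t100", "chr1\t100"]
    )
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(BedFormatError) as err:
            read_bed(p)
        assert err.value.line_number == 2
        assert "line 2" in str(err.value)


class TestCenterExtend:
    @pytest.mark.parametrize(
        "iv,ext,expected",
        [
            (("chr1", 100, 300), 100, (100, 300)),  # center 200, symmetric
            (("chr1", 10, 20), 100, (0, 115)),  # clipped at chromosome start
            (("chr1", 0, 1), 100, (0, 100)),  # degenerate 1-bp peak
            (("chr1", 100, 301), 100, (100, 300)),  # floor midpoint of odd width
        ],
    )
    def test_extension_contract(self, iv, ext, expected):
        out = center_extend(GenomicInterval(*iv), ext)
        assert (out.start, out.end) == expected

    def test_width_is_twice_ext_away_from_chrom_start(self):
        rng = np.random.default_rng(0)
        for iv in random_intervals(rng, 50):
            shifted = GenomicInterval(iv.chrom, iv.start + 200, iv.end + 200)
            assert center_extend(shifted, 100).width == 200


class TestOverlap:
    def test_one_bp_overlap_under_half_open_coords(self):
        assert overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 199, 300))

    def test_half_open_abutment_is_not_overlap(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300))

    def test_overlaps_is_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(1)
        ivs = random_intervals(rng, 60)
        for a in ivs[:30]:
            for b in ivs[30:]:
                assert overlaps(a, b) == overlaps(b, a) == brute_force_overlap(a, b)

    def test_intersect_sets_equals_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = PeakSet(tuple(random_intervals(rng, 200)))
            B = PeakSet(tuple(random_intervals(rng, 200)))
            got = set(intersect_sets(A, B).intervals)
            expect = {a for a in A if any(brute_force_overlap(a, b) for b in B)}
            assert got == expect

    def test_intersect_with_empty_set_is_empty_and_subset_of_A(self):
        rng = np.random.default_rng(3)
        A = PeakSet(tuple(random_intervals(rng, 50)))
        assert len(intersect_sets(A, PeakSet(()))) == 0
        B = PeakSet(tuple(random_intervals(rng, 50)))
        assert set(intersect_sets(A, B).intervals) <= set(A.intervals)


class TestConsensus:
    def test_peak_in_both_replicates_retained_at_width_200(self):
        merged = PeakSet((GenomicInterval("chr1", 1000, 1400),))
        rep1 = PeakSet((GenomicInterval("chr1", 1100, 1200),))
        rep2 = PeakSet((GenomicInterval("chr1", 1300, 1500),))
        out = consensus_peaks(merged, [rep1, rep2])
        assert len(out) == 1
        assert out.intervals[0].width == 200
        assert out.intervals[0].center == 1200

    def test_peak_in_only_one_replicate_dropped(self):
        merged = PeakSet((GenomicInterval("chr1", 1000, 1400),))
        rep1 = PeakSet((GenomicInterval("chr1", 1100, 1200),))
        rep2 = PeakSet((GenomicInterval("chr2", 1100, 1200),))
        assert len(consensus_peaks(merged, [rep1, rep2])) == 0

    def test_empty_merged_gives_empty_output(self):
        out = consensus_peaks(PeakSet(()), [PeakSet((GenomicInterval("chr1", 0, 10),))])
        assert len(out) == 0

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks(PeakSet((GenomicInterval("chr1", 0, 10),)), [])

    def test_output_subset_of_extended_merged_calls(self):
        rng = np.random.default_rng(4)
        merged = PeakSet(tuple(random_intervals(rng, 100)))
        reps = [PeakSet(tuple(random_intervals(rng, 100))) for _ in range(2)]
        out = consensus_peaks(merged, reps)
        extended = {(center_extend(iv, 100).start, center_extend(iv, 100).end, iv.chrom)
                    for iv in merged}
        assert all((iv.start, iv.end, iv.chrom) in extended for iv in out)


def _brute_force_classes(peaksets, layers):
    """All-pairs overlap oracle for per-tissue class labels."""
    all_tissues = frozenset(peaksets)
    labels = {}
    for tissue, ps in peaksets.items():
        for iv in ps:
            found = {tissue}
            for other, ops in peaksets.items():
                if other != tissue and any(brute_force_overlap(iv, o) for o in ops):
                    found.add(other)
            if len(found) == 1:
                cls = f"specific:{tissue}"
            elif found == all_tissues:
                cls = "all-common"
            elif len({layers[t] for t in found}) == 1:
                cls = f"{layers[next(iter(found))]}-common"
            else:
                cls = "both-germ-layers"
            labels[(tissue, iv.chrom, iv.start, iv.end)] = cls
    return labels


class TestClassifyOverlap:
    def test_two_cns_peaks_are_cns_common(self):
        peaksets = {
            "cortex": PeakSet((GenomicInterval("chr1", 100, 300),), tissue="cortex"),
            "spinal_cord": PeakSet((GenomicInterval("chr1", 150, 350),), tissue="spinal_cord"),
            "stomach": PeakSet(()),
            "lung": PeakSet(()),
        }
        res = classify_overlap(peaksets, LAYERS)
        assert set(res.per_tissue["class"]) == {"CNS-common"}

    def test_interval_shared_by_all_four_tissues_counts_once_in_union(self):
        iv = GenomicInterval("chr1", 1000, 1200)
        peaksets = {t: PeakSet((iv,), tissue=t) for t in LAYERS}
        res = classify_overlap(peaksets, LAYERS)
        assert res.union_counts == {"all-common": 1}
        assert set(res.per_tissue["class"]) == {"all-common"}

    def test_union_class_counts_sum_to_merged_union_size(self):
        rng = np.random.default_rng(5)
        peaksets = {t: PeakSet(tuple(random_intervals(rng, 50)), tissue=t) for t in LAYERS}
        res = classify_overlap(peaksets, LAYERS)
        union = merge_intervals([iv for ps in peaksets.values() for iv in ps])
        assert sum(res.union_counts.values()) == len(union)

    def test_labels_match_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        peaksets = {t: PeakSet(tuple(random_intervals(rng, 50)), tissue=t) for t in LAYERS}
        res = classify_overlap(peaksets, LAYERS)
        oracle = _brute_force_classes(peaksets, LAYERS)
        for _, row in res.per_tissue.iterrows():
            assert oracle[(row["tissue"], row["chrom"], row["start"], row["end"])] == row["class"]

    def test_missing_layer_assignment_rejected(self):
        peaksets = {t: PeakSet((GenomicInterval("chr1", 0, 10),)) for t in ("a", "b")}
        with pytest.raises(ValueError):
            classify_overlap(peaksets, {"a": "CNS"})


class TestConsensusExclusion:
    def test_merged_calls_in_excluded_regions_dropped(self):
        merged = PeakSet((GenomicInterval("chr1", 1000, 1400),
                          GenomicInterval("chr1", 5000, 5400)))
        rep = PeakSet(merged.intervals)
        exclude = PeakSet((GenomicInterval("chr1", 900, 1100),))
        out = consensus_peaks(merged, [rep, rep], exclude=exclude)
        assert len(out) == 1
        assert out.intervals[0].center == 5200
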