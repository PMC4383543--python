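"""Hamming-scan mapping, category tallies and coverage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tagdge.datasets import hazelnut_mapping_summaries
from tagdge.tag_mapping import (
    GeneMappingProfile,
    ReferenceGene,
    TagHit,
    build_gene_profiles,
    count_unambiguous,
    gene_coverage,
    map_tag,
    reverse_complement,
    summarize_mapping,
)


def brute_force_scan(tag, reference, max_mismatch=2):
    """Independent per-position Hamming scan (oracle for map_tag)."""
    hits = []
    for gene in reference:
        for strand, query in (("+", tag), ("-", reverse_complement(tag))):
            for start in range(gene.length - len(tag) + 1):
                window = gene.sequence[start : start + len(tag)]
                mism = 0
                for a, b in zip(query, window):
                    if a != b or a == "N" or b == "N":
                        mism += 1
                        if mism > max_mismatch:
                            break
                if mism <= max_mismatch:
                    hits.append(TagHit(gene.gene_id, start, strand, mism))
    return hits


class TestMapTag:
    def test_exact_unique_substring(self, toy_reference):
        gene = toy_reference[0]
        tag = gene.sequence[100:149]
        hits = map_tag(tag, toy_reference)
        assert TagHit(gene.gene_id, 100, "+", 0) in hits
        perfect = [h for h in hits if h.mismatches == 0]
        assert perfect == [TagHit(gene.gene_id, 100, "+", 0)]

    def test_reverse_strand_hit(self, toy_reference):
        gene = toy_reference[1]
        tag = reverse_complement(gene.sequence[200:249])
        hits = map_tag(tag, toy_reference)
        assert TagHit(gene.gene_id, 200, "-", 0) in hits

    def test_three_mismatches_unmapped(self):
        ref = [ReferenceGene("g", "A" * 60)]
        tag = "A" * 46 + "CCC"
        assert map_tag(tag, ref) == []

    def test_n_counts_as_mismatch(self):
        ref = [ReferenceGene("g", "ACGTACGTACGT")]
        assert map_tag("ACGTACGTACGT", ref)[0].mismatches == 0
        hits = map_tag("NNNTACGTACGT", ref, max_mismatch=2)
        assert all(h.start != 0 or h.mismatches > 2 for h in hits) or hits == []

    def test_empty_inputs_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            map_tag("", toy_reference)
        with pytest.raises(ValueError):
            map_tag("ACGT", [])

    def test_matches_brute_force_on_random_tags(self, toy_reference, rng):
        """200 seeded tags (planted and random) against the scan oracle."""
        tags = []
        for _ in range(150):
            gene = toy_reference[rng.integers(0, 3)]
            start = int(rng.integers(0, gene.length - 49 + 1))
            tag = list(gene.sequence[start : start + 49])
            for pos in rng.choice(49, size=int(rng.integers(0, 4)), replace=False):
                tag[pos] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5:
                tag = list(reverse_complement("".join(tag)))
            tags.append("".join(tag))
        for _ in range(50):
            tags.append("".join(rng.choice(list("ACGT"), size=49)))
        for tag in tags:
            assert sorted(map_tag(tag, toy_reference), key=str) == sorted(
                brute_force_scan(tag, toy_reference), key=str
            )


class TestSummarizeMapping:
    def test_three_read_example(self):
        hits = [
            [TagHit("g1", 0, "+", 0)],
            [TagHit("g1", 5, "+", 1), TagHit("g2", 9, "-", 2)],
            [],
        ]
        s = summarize_mapping(hits)
        assert (s.total_mapped, s.perfect_match, s.le2_mismatch) == (2, 1, 1)
        assert (s.unique_match, s.multi_position, s.unmapped) == (1, 1, 1)

    def test_published_library_percentages(self):
        """Mapped-read percentages recomputed from the printed tallies."""
        summaries = hazelnut_mapping_summaries()
        for s in summaries.values():
            s.check_invariants()
        assert round(summaries["empty"].mapped_percent, 2) == 88.05
        assert round(summaries["full"].mapped_percent, 2) == 87.04

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.booleans()), min_size=0, max_size=60
        )
    )
    def test_partition_identities(self, shape):
        hits = [
            [TagHit(f"g{j}", 0, "+", 0 if perfect else 1) for j in range(n_hits)]
            for n_hits, perfect in shape
        ]
        s = summarize_mapping(hits)
        assert s.perfect_match + s.le2_mismatch == s.total_mapped
        assert s.unique_match + s.multi_position == s.total_mapped
        assert s.total_mapped + s.unmapped == s.total_reads


class TestUnambiguousCounts:
    def test_unique_hits_counted_multi_excluded(self):
        hits = [[TagHit("G", 0, "+", 0)]] * 5 + [
            [TagHit("G", 0, "+", 1), TagHit("H", 3, "+", 1)]
        ]
        counts = count_unambiguous(hits)
        assert counts == {"G": 5}

    def test_same_gene_two_offsets_is_ambiguous(self):
        hits = [[TagHit("G", 0, "+", 1), TagHit("G", 7, "-", 2)]]
        assert count_unambiguous(hits) == {}


class TestGeneCoverage:
    @pytest.mark.parametrize(
        "intervals, length, expected",
        [([(0, 50)], 100, 50.0), ([(0, 50), (25, 75)], 100, 75.0), ([], 100, 0.0)],
    )
    def test_union_semantics(self, intervals, length, expected):
        assert gene_coverage(intervals, length) == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            gene_coverage([(0, 101)], 100)

    def test_matches_base_mask_and_permutation_invariance(self, rng):
        length = 500
        intervals = []
        for _ in range(100):
            a = int(rng.integers(0, length))
            b = int(rng.integers(a, length + 1))
            intervals.append((a, b))
        mask = np.zeros(length, dtype=bool)
        for a, b in intervals:
            mask[a:b] = True
        expected = 100.0 * mask.sum() / length
        assert gene_coverage(intervals, length) == pytest.approx(expected)
        shuffled = [intervals[i] for i in rng.permutation(len(intervals))]
        assert gene_coverage(shuffled, length) == pytest.approx(expected)

    def test_splitting_intervals_is_invariant(self):
        assert gene_coverage([(10, 90)], 100) == gene_coverage(
            [(10, 40), (40, 66), (66, 90)], 100
        )


class TestGeneProfiles:
    def test_counts_and_coverage_from_unique_hits(self, toy_reference):
        gene = toy_reference[0]
        hits = [
            [TagHit(gene.gene_id, 0, "+", 0)],
            [TagHit(gene.gene_id, 10, "+", 0)],
            [TagHit(gene.gene_id, 0, "+", 1), TagHit(gene.gene_id, 99, "+", 2)],
        ]
        profiles = build_gene_profiles(hits, toy_reference, [49, 49, 49])
        prof = profiles[gene.gene_id]
        assert prof.unambiguous_count == 2
        assert prof.coverage_percent == pytest.approx(100.0 * 59 / gene.length)
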