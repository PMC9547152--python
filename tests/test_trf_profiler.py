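"""Read assignment, fragment calling and the profile analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snoguard.references import TrnaRecord
from snoguard.trf_profiler import (
    FragmentCall,
    assign_reads,
    call_fragments,
    coverage_profile,
    fragment_fraction,
    length_class_histogram,
    parse_trf_name,
    rpm_normalize,
    summarize_profile,
)

from conftest import random_rna


@pytest.fixture
def two_refs(rng):
    # two references sharing a 20-nt block (a multi-mapping trap) but with
    # otherwise distinct sequence
    shared = random_rna(rng, 20, alphabet="ACGU")
    a = random_rna(rng, 30) + shared + random_rna(rng, 30)
    b = random_rna(rng, 25) + shared + random_rna(rng, 35)
    return [TrnaRecord(id="refA", sequence=a), TrnaRecord(id="refB", sequence=b)], shared


class TestAssignReads:
    def test_unique_exact_match_gets_true_coordinates(self, trna):
        read = trna.sequence[46:64]  # positions 47-64
        result = assign_reads([("r1", read)], [trna])
        (a,) = result.assignments
        assert (a.parent_id, a.start, a.end) == (trna.id, 47, 64)

    def test_mismatched_read_is_unassigned(self, trna):
        read = list(trna.sequence[46:64])
        read[8] = {"A": "C"}.get(read[8], "A")  # guaranteed substitution
        result = assign_reads([("r1", "".join(read))], [trna])
        assert result.n_assigned == 0
        assert result.n_unassigned == 1

    def test_short_read_is_dropped_and_counted(self, trna):
        result = assign_reads([("r1", trna.sequence[:10])], [trna])
        assert result.n_dropped == 1
        assert result.n_assigned == 0

    def test_no_refs_is_an_error(self):
        with pytest.raises(ValueError, match="references"):
            assign_reads([("r1", "ACGU" * 5)], [])

    def test_multimapper_goes_to_highest_unique_count_parent(self, two_refs):
        refs, shared = two_refs
        a, b = refs
        reads = [(f"ua{i}", a.sequence[:16]) for i in range(10)]
        reads += [(f"ub{i}", b.sequence[-16:]) for i in range(2)]
        reads += [("mm", shared[:16])]
        result = assign_reads(reads, refs)
        mm = next(x for x in result.assignments if x.read_id == "mm")
        assert mm.parent_id == "refA"
        assert result.n_multimapped == 1

    def test_multimapper_tie_breaks_lexicographically(self, two_refs):
        refs, shared = two_refs
        result = assign_reads([("mm", shared[:16])], refs)
        assert result.assignments[0].parent_id == "refA"

    def test_read_conservation_and_order_invariance(self, trna, rng):
        reads = []
        for i in range(300):
            kind = rng.integers(0, 4)
            if kind == 0:  # true fragment
                s = int(rng.integers(0, trna.length - 20))
                reads.append((f"r{i}", trna.sequence[s : s + 20]))
            elif kind == 1:  # garbage
                reads.append((f"r{i}", random_rna(rng, 20)))
            elif kind == 2:  # too short
                reads.append((f"r{i}", trna.sequence[:10]))
            else:  # full length
                reads.append((f"r{i}", trna.sequence))
        result = assign_reads(reads, [trna])
        assert result.n_assigned + result.n_unassigned + result.n_dropped == len(reads)

        shuffled = list(reads)
        rng.shuffle(shuffled)
        result2 = assign_reads(shuffled, [trna])
        assert result2.n_assigned == result.n_assigned
        assert result2.n_unassigned == result.n_unassigned
        assert result2.n_dropped == result.n_dropped
        per_parent = lambda r: sorted(
            (a.parent_id, a.start, a.end) for a in r.assignments
        )
        assert per_parent(result2) == per_parent(result)


class TestCallFragments:
    def test_grouped_call_with_canonical_name(self, trna):
        reads = [(f"r{i}", trna.sequence[46:64]) for i in range(3)]
        calls = call_fragments(assign_reads(reads, [trna]))
        (call,) = calls
        assert call.count == 3
        assert call.length == 18
        assert call.name == "tRF 47–64"
        assert call.category == "tRF"

    def test_long_read_classed_mature_not_trf(self, trna):
        calls = call_fragments(assign_reads([("r1", trna.sequence)], [trna]))
        (call,) = calls
        assert call.category == "mature"
        assert call.length == trna.length

    def test_counts_conserve_assigned_reads(self, trna, rng):
        reads = []
        for i in range(500):
            s = int(rng.integers(0, trna.length - 18))
            ln = int(rng.integers(16, min(50, trna.length - s) + 1))
            reads.append((f"r{i}", trna.sequence[s : s + ln]))
        result = assign_reads(reads, [trna])
        calls = call_fragments(result)
        assert sum(c.count for c in calls) == result.n_assigned


class TestRpmNormalize:
    def test_simple_values(self):
        assert rpm_normalize(5, 1_000_000) == 5
        assert rpm_normalize(7, 7) == 1e6

    def test_zero_library_is_an_error(self):
        with pytest.raises(ValueError):
            rpm_normalize(5, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=20))
    def test_partitioned_counts_sum_to_one_million(self, counts):
        total = sum(counts)
        if total == 0:
            return
        rpm = rpm_normalize(np.array(counts), total)
        assert np.isclose(rpm.sum(), 1e6)


class TestLengthHistogram:
    def _call(self, start, length, count=1, parent="p"):
        return FragmentCall(parent, start, start + length - 1, count,
                            category="tRF" if length < 45 else "mature")

    def test_even_split_between_classes(self):
        hist = length_class_histogram([self._call(1, 18), self._call(1, 30)])
        assert hist.small_pct == 50.0
        assert hist.large_pct == 50.0

    def test_all_small(self):
        hist = length_class_histogram([self._call(1, 18, count=4)])
        assert hist.small_pct == 100.0
        assert hist.large_reads == 0

    def test_seeded_mixture_proportions_recovered_exactly(self, rng):
        n_small = int(rng.integers(50, 150))
        n_large = int(rng.integers(50, 150))
        calls = [self._call(int(rng.integers(1, 30)), int(rng.integers(18, 30)))
                 for _ in range(n_small)]
        calls += [self._call(int(rng.integers(1, 30)), int(rng.integers(30, 46)))
                  for _ in range(n_large)]
        calls = [c for c in calls if c.category == "tRF"]
        n_large_trf = sum(1 for c in calls if c.length >= 30)
        hist = length_class_histogram(calls)
        assert hist.small_reads == n_small
        assert hist.large_reads == n_large_trf
        assert hist.counts.sum() == hist.small_reads + hist.large_reads

    def test_histogram_sums_to_total_trf_reads(self, trna, rng):
        reads = [(f"r{i}", trna.sequence[s : s + ln])
                 for i, (s, ln) in enumerate(
                     (int(rng.integers(0, 60)), int(rng.integers(18, 24)))
                     for _ in range(200))]
        calls = call_fragments(assign_reads(reads, [trna]))
        hist = length_class_histogram(calls)
        trf_total = sum(c.count for c in calls if c.category == "tRF")
        assert hist.counts.sum() == trf_total


class TestCoverage:
    def test_single_call_covers_its_span(self, trna):
        depth = coverage_profile([FragmentCall(trna.id, 47, 64, 1)], trna)
        assert depth.sum() == 18
        assert all(depth[46:64] == 1)
        assert depth[45] == 0 and depth[64] == 0

    def test_overlap_adds(self, trna):
        calls = [FragmentCall(trna.id, 40, 60, 1), FragmentCall(trna.id, 50, 70, 1)]
        depth = coverage_profile(calls, trna)
        assert all(depth[49:60] == 2)
        assert depth[39] == 1 and depth[60] == 1

    def test_mass_conservation(self, trna, rng):
        calls = []
        for _ in range(100):
            s = int(rng.integers(1, trna.length - 17))
            e = int(rng.integers(s + 10, min(s + 44, trna.length) + 1)) - 1
            calls.append(FragmentCall(trna.id, s, e, int(rng.integers(1, 5))))
        depth = coverage_profile(calls, trna)
        assert depth.sum() == sum(c.count * c.length for c in calls)

    def test_unknown_parent_errors_in_summary(self, trna):
        result = assign_reads([("r1", trna.sequence[46:64])], [trna])
        summary = summarize_profile(result, [trna])
        with pytest.raises(KeyError):
            summary.coverage_for("nope")


class TestFragmentFraction:
    def test_even_split_gives_fifty_percent(self, trna):
        calls = [FragmentCall(trna.id, 47, 64, 50), FragmentCall(trna.id, 1, 30, 50)]
        assert fragment_fraction(calls, trna.id, "tRF 47–64") == 50.0

    def test_sole_family_gives_hundred_percent(self, trna):
        calls = [FragmentCall(trna.id, 47, 64, 7), FragmentCall(trna.id, 47, 66, 3)]
        assert fragment_fraction(calls, trna.id, "tRF 47-64") == 100.0

    def test_extension_window_bounds_family_membership(self, trna):
        calls = [
            FragmentCall(trna.id, 47, 64, 1),
            FragmentCall(trna.id, 47, 66, 1),  # +2, in family
            FragmentCall(trna.id, 47, 67, 1),  # +3, outside window
            FragmentCall(trna.id, 48, 64, 1),  # different 5' start
        ]
        assert fragment_fraction(calls, trna.id, "tRF 47-64") == 50.0

    def test_zero_trf_reads_is_an_error(self, trna):
        calls = [FragmentCall(trna.id, 1, trna.length, 5, category="mature")]
        with pytest.raises(ValueError, match="no tRF reads"):
            fragment_fraction(calls, trna.id, "tRF 47-64")

    def test_matches_recount_from_assignment_table(self, trna, rng):
        reads = []
        for i in range(400):
            s = int(rng.integers(0, trna.length - 20))
            reads.append((f"r{i}", trna.sequence[s : s + int(rng.integers(18, 21))]))
        result = assign_reads(reads, [trna])
        calls = call_fragments(result)
        got = fragment_fraction(calls, trna.id, "tRF 47–64", extension_3p=2)
        trf = [a for a in result.assignments
               if a.end - a.start + 1 < 45 and a.parent_id == trna.id]
        family = [a for a in trf if a.start == 47 and 64 <= a.end <= 66]
        assert got == pytest.approx(100.0 * len(family) / len(trf))

    def test_name_parsing_accepts_dash_variants(self):
        assert parse_trf_name("tRF 47–64") == (47, 64)
        assert parse_trf_name("tRF 47-64") == (47, 64)
        with pytest.raises(ValueError):
            parse_trf_name("fragment 47..64")


class TestProfileSummary:
    def test_class_rpm_sums_to_at_most_one_million(self, trna, rng):
        reads = [(f"r{i}", trna.sequence[s : s + 20])
                 for i, s in enumerate(rng.integers(0, 60, size=100))]
        reads.append(("junk", random_rna(rng, 20)))
        result = assign_reads(reads, [trna])
        summary = summarize_profile(result, [trna])
        assert sum(summary.class_rpm.values()) <= 1e6 + 1e-6
        assert summary.class_rpm["tRNA"] == pytest.approx(1e6)

    def test_fragment_table_counts_match_assignments(self, trna, rng):
        reads = [(f"r{i}", trna.sequence[s : s + 20])
                 for i, s in enumerate(rng.integers(0, 60, size=100))]
        result = assign_reads(reads, [trna])
        summary = summarize_profile(result, [trna])
        assert summary.fragment_table["count"].sum() == result.n_assigned
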