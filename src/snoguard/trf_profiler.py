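"""Small-RNA read assignment and tRNA-fragment (tRF) analytics.

Reads are assigned to mature tRNA references by exact full-length substring
match (0 mismatches) — a desk-scale stand-in for a genome aligner that keeps
results reproducible and dependency-free.  Multi-mapping reads follow the
single-assignment convention used for small-RNA class quantification: reads
matching exactly one reference are counted first, and each multi-mapper is
then assigned to the matching reference with the highest unique-read count
(ties break by lexicographic reference id, logged).

Downstream analytics mirror standard small-RNA-seq summaries: fragment calls
named by their 1-based inclusive span on the parent tRNA (``tRF 47–64``),
reads-per-million normalization, an 18–45-nt length histogram with
small (18–29) / large (30–45) classes, per-position coverage, and the share
of a named fragment family among all tRFs of its parent.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import defaults
from .references import TrnaRecord, normalize_rna

logger = logging.getLogger(__name__)

EN_DASH = "–"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    parent_id: str
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssignmentResult:
    """Outcome of read assignment with conservation-checkable counters."""

    assignments: list[ReadAssignment]
    n_input: int
    n_unassigned: int
    n_dropped: int
    n_multimapped: int
    unique_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class FragmentCall:
    """A read-derived fragment: parent tRNA, 1-based inclusive span, count.

    Calls shorter than the tRF/mature boundary (45 nt) are tRFs; longer reads
    are classed mature/precursor rather than tRF.
    """

    parent_id: str
    start: int
    end: int
    count: int
    category: str = "tRF"  # "tRF" or "mature"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid fragment span")
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")
        if self.category not in ("tRF", "mature"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        prefix = "tRF" if self.category == "tRF" else "mature"
        return f"{prefix} {self.start}{EN_DASH}{self.end}"


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file (Phred+33; qualities ignored) into (id, seq) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def _as_pairs(reads: Iterable) -> list[tuple[str, str]]:
    pairs = []
    for item in reads:
        if isinstance(item, tuple):
            pairs.append((item[0], item[1]))
        else:  # Bio.SeqRecord
            pairs.append((item.id, str(item.seq)))
    return pairs


def assign_reads(
    reads: Iterable,
    refs: Sequence[TrnaRecord],
    min_len: int = defaults.MIN_READ_LEN,
    max_len: int | None = None,
) -> AssignmentResult:
    """Assign reads to references by exact full-length substring match.

    Uniquely matching reads are assigned first; multi-mappers go to the
    reference with the highest unique-read count (lexicographic id on ties).
    Reads outside the [min_len, max_len] window are dropped and logged.
    Totals are independent of input read order.
    """
    if not refs:
        raise ValueError("no references provided")
    pairs = _as_pairs(reads)
    n_input = len(pairs)

    kept: list[tuple[str, str]] = []
    n_dropped = 0
    for rid, seq in pairs:
        seq = normalize_rna(seq, context=f"read {rid!r}")
        if len(seq) < min_len or (max_len is not None and len(seq) > max_len):
            n_dropped += 1
            continue
        kept.append((rid, seq))
    if n_dropped:
        logger.info("dropped %d reads outside the length window", n_dropped)

    # Group identical sequences; match each unique sequence once.
    seq_reads: dict[str, list[str]] = defaultdict(list)
    for rid, seq in kept:
        seq_reads[seq].append(rid)
    matches: dict[str, list[tuple[str, int]]] = {}
    for seq in seq_reads:
        found = []
        for ref in refs:
            pos = ref.sequence.find(seq)  # leftmost occurrence
            if pos != -1:
                found.append((ref.id, pos))
        matches[seq] = found

    unique_counts: Counter[str] = Counter()
    for seq, found in matches.items():
        if len(found) == 1:
            unique_counts[found[0][0]] += len(seq_reads[seq])

    chosen: dict[str, tuple[str, int]] = {}
    n_unassigned = 0
    n_multimapped = 0
    n_ties = 0
    for seq, found in matches.items():
        if not found:
            n_unassigned += len(seq_reads[seq])
            continue
        if len(found) == 1:
            chosen[seq] = found[0]
        else:
            n_multimapped += len(seq_reads[seq])
            best = max(unique_counts[rid] for rid, _ in found)
            candidates = sorted(rid for rid, _ in found if unique_counts[rid] == best)
            if len(candidates) > 1:
                n_ties += len(seq_reads[seq])
            winner = candidates[0]
            chosen[seq] = next((rid, pos) for rid, pos in found if rid == winner)
    if n_ties:
        logger.info(
            "%d multi-mapping reads had tied unique counts; assigned by "
            "lexicographic reference id",
            n_ties,
        )

    assignments = [
        ReadAssignment(rid, parent, pos + 1, pos + len(seq))
        for rid, seq in kept
        if seq in chosen
        for parent, pos in [chosen[seq]]
    ]
    return AssignmentResult(
        assignments=assignments,
        n_input=n_input,
        n_unassigned=n_unassigned,
        n_dropped=n_dropped,
        n_multimapped=n_multimapped,
        unique_counts=dict(unique_counts),
    )


def call_fragments(
    assignments: AssignmentResult | Iterable[ReadAssignment],
    trf_max_len: int = defaults.TRF_MAX_LEN,
) -> list[FragmentCall]:
    """Group assigned reads by (parent, start, end) into fragment calls."""
    if isinstance(assignments, AssignmentResult):
        assignments = assignments.assignments
    counts: Counter[tuple[str, int, int]] = Counter()
    for a in assignments:
        counts[(a.parent_id, a.start, a.end)] += 1
    calls = [
        FragmentCall(
            parent_id=parent,
            start=start,
            end=end,
            count=n,
            category="tRF" if end - start + 1 < trf_max_len else "mature",
        )
        for (parent, start, end), n in counts.items()
    ]
    calls.sort(key=lambda c: (c.parent_id, c.start, c.end))
    return calls


def rpm_normalize(counts, library_size: int):
    """Scale counts to reads per million: count / library_size * 1e6.

    Accepts a scalar, mapping, pandas Series or numpy array and returns the
    matching type.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if isinstance(counts, Mapping):
        return {k: v / library_size * 1e6 for k, v in counts.items()}
    if isinstance(counts, pd.Series):
        return counts / library_size * 1e6
    if isinstance(counts, (list, tuple, np.ndarray)):
        return np.asarray(counts, dtype=float) / library_size * 1e6
    return counts / library_size * 1e6


@dataclass
class LengthHistogram:
    """Per-length tRF read counts over 18–45 nt with small/large class totals.

    Percentages are relative to total tRNA-assigned reads (tRFs plus
    mature/precursor reads), matching how fragment-length distributions are
    reported as a share of all tRNA reads.
    """

    counts: "pd.Series"
    small_reads: int
    large_reads: int
    total_trna_reads: int
    min_len: int
    max_len: int
    small_max: int

    @property
    def small_pct(self) -> float:
        return 100.0 * self.small_reads / self.total_trna_reads

    @property
    def large_pct(self) -> float:
        return 100.0 * self.large_reads / self.total_trna_reads

    @property
    def percentages(self) -> "pd.Series":
        return 100.0 * self.counts / self.total_trna_reads


def length_class_histogram(
    calls: Iterable[FragmentCall],
    min_len: int = 18,
    max_len: int = 45,
    small_max: int = 29,
) -> LengthHistogram:
    """Histogram tRF reads by exact fragment length with 18–29/30–45 classes."""
    calls = list(calls)
    counts = pd.Series(0, index=range(min_len, max_len + 1), dtype=int)
    small = large = 0
    total = sum(c.count for c in calls)
    for c in calls:
        if c.category != "tRF":
            continue
        if min_len <= c.length <= max_len:
            counts[c.length] += c.count
        if min_len <= c.length <= small_max:
            small += c.count
        elif small_max < c.length <= max_len:
            large += c.count
    return LengthHistogram(
        counts=counts,
        small_reads=small,
        large_reads=large,
        total_trna_reads=total,
        min_len=min_len,
        max_len=max_len,
        small_max=small_max,
    )


def coverage_profile(
    calls: Iterable[FragmentCall],
    parent: TrnaRecord,
) -> np.ndarray:
    """Per-position read depth over the parent (index 0 = position 1, 5'→3').

    depth[p] sums the counts of every call covering position p.  Calls for
    other parents are ignored; rendering may flip the axis to 3'→5' for
    display, the returned vector is always 5'→3'.
    """
    depth = np.zeros(parent.length, dtype=int)
    for c in calls:
        if c.parent_id != parent.id:
            continue
        if c.end > parent.length:
            raise ValueError(
                f"call {c.name} extends beyond parent {parent.id!r} ({parent.length} nt)"
            )
        depth[c.start - 1 : c.end] += c.count
    return depth


_TRF_NAME_RE = re.compile(r"^tRF\s*(\d+)\s*[–—-]\s*(\d+)$")


def parse_trf_name(name: str) -> tuple[int, int]:
    """Parse a canonical tRF name like ``tRF 47–64`` (en dash or hyphen)."""
    m = _TRF_NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse tRF name {name!r}")
    return int(m.group(1)), int(m.group(2))


def fragment_fraction(
    calls: Iterable[FragmentCall],
    parent_id: str,
    name: str,
    extension_3p: int = defaults.FAMILY_EXTENSION_3P,
) -> float:
    """Percentage of a parent's tRF reads belonging to a named fragment family.

    The family groups 3'-end-jittered variants: calls with the named start and
    an end within ``extension_3p`` nt downstream of the named end (cleavage
    produces a ladder of 3' ends at a shared 5' boundary).
    """
    start, end = parse_trf_name(name)
    family = 0
    total = 0
    for c in calls:
        if c.parent_id != parent_id or c.category != "tRF":
            continue
        total += c.count
        if c.start == start and end <= c.end <= end + extension_3p:
            family += c.count
    if total == 0:
        raise ValueError(f"parent {parent_id!r} has no tRF reads")
    return 100.0 * family / total


@dataclass
class ProfileSummary:
    """Profile-level analytics bundle for one small-RNA library."""

    class_rpm: dict[str, float]
    fragment_table: pd.DataFrame
    histogram: LengthHistogram
    coverage: dict[str, np.ndarray]
    n_assigned: int
    n_unassigned: int
    n_dropped: int

    def coverage_for(self, parent_id: str) -> np.ndarray:
        if parent_id not in self.coverage:
            raise KeyError(f"unknown parent {parent_id!r}")
        return self.coverage[parent_id]


def summarize_profile(
    result: AssignmentResult,
    refs: Sequence[TrnaRecord],
    trf_max_len: int = defaults.TRF_MAX_LEN,
) -> ProfileSummary:
    """Build the per-class RPM, fragment table, histogram and coverage summary.

    The RPM denominator is the number of reads assigned to any reference
    class; references may carry an ``rna_class`` attribute (default "tRNA").
    """
    calls = call_fragments(result, trf_max_len=trf_max_len)
    ref_by_id = {r.id: r for r in refs}
    class_counts: Counter[str] = Counter()
    for a in result.assignments:
        cls = getattr(ref_by_id[a.parent_id], "rna_class", "tRNA")
        class_counts[cls] += 1
    class_rpm = rpm_normalize(dict(class_counts), result.n_assigned) if result.n_assigned else {}

    rows = []
    for c in calls:
        rows.append(
            {
                "parent_id": c.parent_id,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "count": c.count,
                "rpm": c.count / result.n_assigned * 1e6 if result.n_assigned else 0.0,
                "name": c.name,
                "category": c.category,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["parent_id", "start", "end", "length", "count", "rpm", "name", "category"],
    )
    coverage = {r.id: coverage_profile(calls, r) for r in refs}
    return ProfileSummary(
        class_rpm=class_rpm,
        fragment_table=table,
        histogram=length_class_histogram(calls),
        coverage=coverage,
        n_assigned=result.n_assigned,
        n_unassigned=result.n_unassigned,
        n_dropped=result.n_dropped,
    )


def write_fragments_tsv(summary: ProfileSummary, path: str | Path) -> None:
    summary.fragment_table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_coverage_tsv(summary: ProfileSummary, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["parent_id", "position", "depth"])
        for parent_id in sorted(summary.coverage):
            for pos0, depth in enumerate(summary.coverage[parent_id]):
                writer.writerow([parent_id, pos0 + 1, int(depth)])


def write_histogram_tsv(summary: ProfileSummary, path: str | Path) -> None:
    hist = summary.histogram
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["length", "reads", "pct_of_trna_reads"])
        for length, reads in hist.counts.items():
            pct = 100.0 * reads / hist.total_trna_reads if hist.total_trna_reads else 0.0
            writer.writerow([length, int(reads), f"{pct:.4f}"])
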