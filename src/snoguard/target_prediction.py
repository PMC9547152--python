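"""Antisense duplex search and 2'-O-methylation site placement.

A C/D-box snoRNA selects its methylation target by Watson-Crick base-pairing
of an antisense element with the target RNA.  The guide duplex is
antiparallel: the element's 5' end pairs the 3' end of the target window.
Once the duplex forms, the target nucleotide paired with the element residue
5 positions upstream of the adjacent D/D' box (counting the element's 3'-most
residue as +1) is positioned in the fibrillarin catalytic site and receives
the 2'-O-methyl mark.

The search reports, for every target window of element length, the longest
contiguous perfectly complementary run; a window qualifies as a hit when that
core reaches ``min_core`` and all mismatches sit within the outermost
``max_terminal_mismatches`` positions at each element end.  G:U wobble counts
as a mismatch by default (set ``wobble_pairs`` to treat it as a pair).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from . import defaults
from .references import AntisenseElement, TrnaRecord, normalize_rna

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def bases_pair(element_base: str, target_base: str, wobble_pairs: bool = False) -> bool:
    """Watson-Crick pairing test, optionally admitting G:U wobble."""
    if _COMPLEMENT[element_base] == target_base:
        return True
    return wobble_pairs and (element_base, target_base) in _WOBBLE


@dataclass(frozen=True)
class DuplexHit:
    """A predicted snoRNA:target duplex over one target window.

    ``mismatch_positions`` are element-relative 1-based positions (1 = element
    5' end).  ``methylation_position`` is the 1-based target coordinate of the
    predicted 2'Ome nucleotide, or None with ``methylation_note`` explaining
    why placement failed.
    """

    target_id: str
    target_start: int
    target_end: int
    element_start: int | None
    element_end: int | None
    core_length: int
    mismatch_positions: tuple[int, ...]
    methylation_position: int | None = None
    methylation_note: str | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def element_length(self) -> int:
        return self.target_end - self.target_start + 1


def _longest_true_run(flags: list[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def find_duplex_hits(
    element: AntisenseElement | str,
    target: TrnaRecord,
    min_core: int = defaults.MIN_CORE,
    max_terminal_mismatches: int = defaults.MAX_TERMINAL_MISMATCHES,
    wobble_pairs: bool = False,
) -> list[DuplexHit]:
    """Scan every target window for an antiparallel antisense duplex.

    Hits are sorted by (core_length descending, target start ascending), so
    equal-core ties break toward the smallest target coordinate.
    """
    if isinstance(element, AntisenseElement):
        el_seq = element.sequence
        el_span = (element.start, element.end)
        el_obj: AntisenseElement | None = element
    else:
        el_seq = normalize_rna(element, context="element")
        el_span = (None, None)
        el_obj = None
    L = len(el_seq)
    if L == 0:
        raise ValueError("empty element")
    if min_core > L:
        raise ValueError(f"min_core {min_core} exceeds element length {L}")
    tseq = target.sequence
    if not tseq:
        raise ValueError("empty target")
    if len(tseq) < L:
        raise ValueError(
            f"target {target.id!r} ({len(tseq)} nt) shorter than element ({L} nt)"
        )

    hits: list[DuplexHit] = []
    for s0 in range(len(tseq) - L + 1):
        # element position i (1-based) pairs target position s0 + L - i + 1
        paired = [
            bases_pair(el_seq[i], tseq[s0 + L - 1 - i], wobble_pairs) for i in range(L)
        ]
        core = _longest_true_run(paired)
        if core < min_core:
            continue
        mismatches = tuple(i + 1 for i, ok in enumerate(paired) if not ok)
        if any(
            max_terminal_mismatches < m <= L - max_terminal_mismatches
            for m in mismatches
        ):
            continue
        hit = DuplexHit(
            target_id=target.id,
            target_start=s0 + 1,
            target_end=s0 + L,
            element_start=el_span[0],
            element_end=el_span[1],
            core_length=core,
            mismatch_positions=mismatches,
        )
        if el_obj is not None and L >= 5:
            pos = place_methylation_site(hit, el_obj)
            note = None if pos is not None else "unpaired at +5"
            hit = DuplexHit(
                **{
                    **hit.__dict__,
                    "methylation_position": pos,
                    "methylation_note": note,
                }
            )
        hits.append(hit)
    hits.sort(key=lambda h: (-h.core_length, h.target_start))
    return hits


def place_methylation_site(hit: DuplexHit, element: AntisenseElement) -> int | None:
    """Place the predicted 2'Ome nucleotide by the +5 box-proximity rule.

    The element residue 5 positions upstream of the adjacent D/D' box (the
    3'-most element residue counts as +1) must be paired; by antiparallel
    pairing the methylated target nucleotide is ``target_start + 4``.
    Returns None when that element position is a mismatch in this hit.
    """
    L = len(element)
    if L < 5:
        raise ValueError(f"element length {L} < 5: the +5 rule cannot apply")
    if element.adjacent_box not in ("D", "D_prime"):
        raise ValueError("element must be adjacent to a D or D' box")
    plus5_element_pos = L - 4  # element-relative, 5' -> 3'
    if plus5_element_pos in hit.mismatch_positions:
        return None
    return hit.target_start + 4


def write_hits_tsv(hits: Iterable[DuplexHit], path: str | Path) -> None:
    """Write hits as TSV (one row per hit, 1-based inclusive coordinates)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "target_id",
                "target_start",
                "target_end",
                "core_length",
                "n_mismatches",
                "mismatch_positions",
                "methylation_position",
            ]
        )
        for h in hits:
            writer.writerow(
                [
                    h.target_id,
                    h.target_start,
                    h.target_end,
                    h.core_length,
                    h.n_mismatches,
                    ",".join(map(str, h.mismatch_positions)),
                    "" if h.methylation_position is None else h.methylation_position,
                ]
            )
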