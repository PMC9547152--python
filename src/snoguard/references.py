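"""Reference handling for mature tRNAs and C/D-box snoRNAs.

A C/D-box snoRNA carries conserved sequence motifs — the C box (consensus
RUGAUGA, R = A/G) near the 5' end and the D box (CUGA) near the 3' end, with
an optional internal D' box (CUGA or a one-mismatch variant).  The stretches
immediately upstream of the D and D' boxes are the antisense elements: they
are not covered by the ribonucleoprotein core and are free to base-pair with
target RNAs.  This module reads and validates reference sequences, locates
the boxes, and extracts the antisense elements with 1-based inclusive
coordinates throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import defaults

RNA_ALPHABET = frozenset("ACGU")

#: C box consensus RUGAUGA with R in {A, G}.
_BOX_C_RE = re.compile(r"[AG]UGAUGA")
_BOX_D = "CUGA"

#: GtRNAdb-style identifier, e.g. ``tRNA-Leu-TAA-1-1``.
_TRNA_ID_RE = re.compile(r"tRNA-([A-Za-z]{3})-([ACGTUacgtu]{3})")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the RNA alphabet."""


class DuplicateIdError(ValueError):
    """Two FASTA records share the same identifier."""


class BoxNotFoundError(ValueError):
    """A required C/D-box motif is missing."""


def normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase a sequence and convert DNA T to RNA U, validating the alphabet.

    Raises :class:`InvalidSequenceError` naming the 1-based position of the
    first offending character.
    """
    seq = str(sequence).strip().upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise InvalidSequenceError(
                f"{context}: non-ACGTU character {ch!r} at position {i + 1}"
            )
    return seq


@dataclass(frozen=True)
class TrnaRecord:
    """A mature tRNA reference on the sense strand, RNA alphabet, 1-based coords.

    ``cca_appended`` records whether the 3' CCA tail is part of ``sequence``;
    references are stored without it by default so fragment coordinates (e.g.
    tRF 47-64) stay stable across database versions.
    """

    id: str
    sequence: str
    species: str | None = None
    amino_acid: str | None = None
    anticodon: str | None = None
    cca_appended: bool = False

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"tRNA {self.id!r}")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidSequenceError(f"tRNA {self.id!r}: empty sequence")
        if not 60 <= len(seq) <= 100:
            raise InvalidSequenceError(
                f"tRNA {self.id!r}: length {len(seq)} outside the 60-100 nt "
                "range expected for a mature tRNA"
            )
        if self.anticodon is not None:
            ac = normalize_rna(self.anticodon, context=f"anticodon of {self.id!r}")
            object.__setattr__(self, "anticodon", ac)
            if ac not in seq:
                raise InvalidSequenceError(
                    f"tRNA {self.id!r}: anticodon {ac} not found in sequence"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_cca(self) -> "TrnaRecord":
        """Return a copy with the 3' CCA tail appended (no-op if present)."""
        if self.cca_appended:
            return self
        return replace(self, sequence=self.sequence + "CCA", cca_appended=True)


@dataclass(frozen=True)
class AntisenseElement:
    """An antisense element: the nt stretch ending 1 nt before a D/D' box."""

    adjacent_box: str  # "D" or "D_prime"
    start: int  # 1-based inclusive, on the snoRNA
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.adjacent_box not in ("D", "D_prime"):
            raise ValueError(f"adjacent_box must be D or D_prime, got {self.adjacent_box!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("element sequence length does not match its span")

    def __len__(self) -> int:
        return len(self.sequence)


_BOX_ORDER = ("C", "D_prime", "C_prime", "D")


@dataclass(frozen=True)
class SnoRecord:
    """A C/D-box snoRNA with located boxes and extracted antisense elements."""

    id: str
    sequence: str
    boxes: dict[str, tuple[int, int]] = field(default_factory=dict)
    antisense_elements: tuple[AntisenseElement, ...] = ()

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"snoRNA {self.id!r}")
        object.__setattr__(self, "sequence", seq)
        # box order along the sequence must be C < D' < C' < D (present subset)
        present = [(name, span) for name in _BOX_ORDER if (span := self.boxes.get(name))]
        starts = [span[0] for _, span in present]
        if starts != sorted(starts):
            raise ValueError(f"snoRNA {self.id!r}: boxes out of C < D' < C' < D order")
        for name, (start, end) in self.boxes.items():
            if not (1 <= start <= end <= len(seq)):
                raise ValueError(f"snoRNA {self.id!r}: box {name} span outside sequence")
        for el in self.antisense_elements:
            box = self.boxes.get(el.adjacent_box)
            if box is None or el.end + 1 != box[0]:
                raise ValueError(
                    f"snoRNA {self.id!r}: element for {el.adjacent_box} does not "
                    "end 1 nt before its box"
                )
            if self.sequence[el.start - 1 : el.end] != el.sequence:
                raise ValueError(f"snoRNA {self.id!r}: element sequence mismatch")

    @classmethod
    def from_sequence(
        cls,
        id: str,
        sequence: str,
        element_length: int = defaults.ANTISENSE_LENGTH,
    ) -> "SnoRecord":
        """Locate boxes by motif and extract every extractable antisense element."""
        seq = normalize_rna(sequence, context=f"snoRNA {id!r}")
        boxes = locate_boxes(seq)
        rec = cls(id=id, sequence=seq, boxes=boxes)
        elements = []
        for box in ("D_prime", "D"):
            if box in boxes and boxes[box][0] > element_length:
                elements.append(extract_antisense_element(rec, box, element_length))
        return cls(id=id, sequence=seq, boxes=boxes, antisense_elements=tuple(elements))

    def element_for(self, box: str) -> AntisenseElement:
        for el in self.antisense_elements:
            if el.adjacent_box == box:
                return el
        raise KeyError(f"snoRNA {self.id!r} has no antisense element for box {box!r}")


def locate_boxes(sequence: str) -> dict[str, tuple[int, int]]:
    """Locate C, D' and D boxes in a snoRNA sequence (1-based inclusive spans).

    The D box is the last exact CUGA; the C box the first RUGAUGA upstream of
    it; the D' box the first internal CUGA between C box and D box, falling
    back to a one-mismatch variant when no exact internal match exists.
    Absent boxes are simply absent from the returned map; a missing D box is
    an error because a C/D snoRNA cannot be processed without one.
    """
    seq = normalize_rna(sequence)
    if len(seq) < 40:
        raise ValueError(f"sequence too short to be a C/D-box snoRNA ({len(seq)} < 40 nt)")
    d_idx = seq.rfind(_BOX_D)
    if d_idx == -1:
        raise BoxNotFoundError("no D box")
    boxes: dict[str, tuple[int, int]] = {"D": (d_idx + 1, d_idx + 4)}

    c_match = _BOX_C_RE.search(seq)
    if c_match is None or c_match.end() > d_idx:
        return boxes
    boxes["C"] = (c_match.start() + 1, c_match.end())

    # D' box: prefer an exact CUGA strictly between C box and D box.
    dp_idx = seq.find(_BOX_D, c_match.end(), d_idx)
    if dp_idx == -1:
        for j in range(c_match.end(), d_idx - 3):
            window = seq[j : j + 4]
            if sum(a != b for a, b in zip(window, _BOX_D)) == 1:
                dp_idx = j
                break
    if dp_idx != -1:
        boxes["D_prime"] = (dp_idx + 1, dp_idx + 4)
    return boxes


def extract_antisense_element(
    sno: SnoRecord,
    box: str,
    length: int = defaults.ANTISENSE_LENGTH,
) -> AntisenseElement:
    """Extract the ``length``-nt element ending exactly 1 nt before ``box``."""
    if box not in ("D", "D_prime"):
        raise ValueError(f"box must be D or D_prime, got {box!r}")
    if box not in sno.boxes:
        raise BoxNotFoundError(f"snoRNA {sno.id!r}: box {box} absent")
    box_start = sno.boxes[box][0]
    start = box_start - length
    end = box_start - 1
    if start < 1:
        raise ValueError(
            f"snoRNA {sno.id!r}: only {box_start - 1} nt upstream of {box} box, "
            f"{length} requested"
        )
    return AntisenseElement(
        adjacent_box=box,
        start=start,
        end=end,
        sequence=sno.sequence[start - 1 : end],
    )


def _parse_trna_metadata(identifier: str) -> tuple[str | None, str | None]:
    m = _TRNA_ID_RE.search(identifier)
    if m is None:
        return None, None
    return m.group(1), m.group(2).upper().replace("T", "U")


def read_fasta_records(
    path: str | Path,
    kind: str = "trna",
    append_cca: bool = False,
) -> list[TrnaRecord] | list[SnoRecord]:
    """Read a multi-record FASTA into validated, RNA-normalized records.

    ``kind='trna'`` yields :class:`TrnaRecord` (amino acid / anticodon parsed
    from GtRNAdb-style identifiers when present); ``kind='snorna'`` yields
    un-annotated :class:`SnoRecord` (use :meth:`SnoRecord.from_sequence` or
    packaged fixtures to obtain boxes).  Input order is preserved; duplicate
    ids and empty files are errors.
    """
    if kind not in ("trna", "snorna"):
        raise ValueError(f"kind must be 'trna' or 'snorna', got {kind!r}")
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise ValueError(f"{path}: empty FASTA")
    seen: set[str] = set()
    records: list = []
    for rec in raw:
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_rna(str(rec.seq), context=f"record {rec.id!r}")
        if kind == "trna":
            aa, anticodon = _parse_trna_metadata(rec.id)
            trec = TrnaRecord(
                id=rec.id, sequence=seq, amino_acid=aa, anticodon=anticodon
            )
            if append_cca:
                trec = trec.with_cca()
            records.append(trec)
        else:
            records.append(SnoRecord(id=rec.id, sequence=seq))
    return records


def write_fasta_records(
    records: Iterable[TrnaRecord | SnoRecord],
    path: str | Path,
) -> None:
    """Write records as FASTA (RNA alphabet, id only, 60-column wrapping)."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
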