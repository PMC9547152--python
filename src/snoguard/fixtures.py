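"""Packaged reference fixtures.

The tRNA-Leu-TAA-like and SNORD113-6-like sequences shipped here are
**synthetic reconstructions** — engineered so that the structural facts the
pipeline is built around hold exactly, rather than copies of database
entries:

* the target carries the AACCCCA antisense-site motif at positions 62–68,
* the snoRNA's 9-nt D'-adjacent antisense element (CUGGGGUUA) forms a duplex
  with a perfect 7-nt core against that motif, with mismatches only at the
  two outermost element positions,
* the predicted 2'-O-methylation site falls at target position 65,
  immediately 3' of the dominant fragment's 47–64 boundary,
* the anticodon UAA sits in the anticodon loop.

The snoRNA's box annotations are pre-annotated constants, so pipeline
results never depend on de-novo motif calling; the annotations are verified
against :func:`snoguard.references.locate_boxes` in the test suite.
"""

from __future__ import annotations

from importlib.resources import files

import yaml

from . import defaults
from .references import (
    SnoRecord,
    TrnaRecord,
    extract_antisense_element,
    read_fasta_records,
)
from .synthetic import CleavageProfile, CutSite

_DATA = files("snoguard") / "data"

TRNA_FASTA = "trna_leu_taa_like.fasta"
SNO_FASTA = "snord113_6_like.fasta"
PROFILES_YAML = "cleavage_profiles.yaml"

#: Pre-annotated box spans (1-based inclusive) of the packaged snoRNA.
SNO_BOX_ANNOTATIONS: dict[str, tuple[int, int]] = {
    "C": (5, 11),
    "D_prime": (27, 30),
    "D": (60, 63),
}

#: 1-based target coordinate of the predicted 2'Ome nucleotide on the
#: packaged tRNA (immediately 3' of the 47–64 fragment boundary).
PREDICTED_METHYLATION_POSITION = 65


def fixture_path(name: str):
    """Filesystem path of a packaged data file."""
    return _DATA / name


def load_trna_reference() -> TrnaRecord:
    """The packaged tRNA-Leu-TAA-like mature reference (83 nt, no CCA tail)."""
    records = read_fasta_records(str(fixture_path(TRNA_FASTA)), kind="trna")
    return records[0]


def load_snorna_reference(
    element_length: int = defaults.ANTISENSE_LENGTH,
) -> SnoRecord:
    """The packaged SNORD113-6-like snoRNA with pre-annotated boxes and elements."""
    raw = read_fasta_records(str(fixture_path(SNO_FASTA)), kind="snorna")[0]
    rec = SnoRecord(id=raw.id, sequence=raw.sequence, boxes=dict(SNO_BOX_ANNOTATIONS))
    elements = tuple(
        extract_antisense_element(rec, box, element_length) for box in ("D_prime", "D")
    )
    return SnoRecord(
        id=rec.id,
        sequence=rec.sequence,
        boxes=dict(SNO_BOX_ANNOTATIONS),
        antisense_elements=elements,
    )


def load_cleavage_profiles() -> dict[str, CleavageProfile]:
    """All packaged cleavage profiles, keyed by name.

    Each YAML entry also documents its analytically expected protected-family
    share (``expected_protected_share_pct``); the loader attaches it as the
    ``expected_protected_share_pct`` attribute for tests and reporting.
    """
    text = fixture_path(PROFILES_YAML).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    profiles: dict[str, CleavageProfile] = {}
    for name, entry in raw["profiles"].items():
        expected = entry.pop("expected_protected_share_pct")
        cut_sites = tuple(CutSite(**cs) for cs in entry.pop("cut_sites"))
        profile = CleavageProfile(cut_sites=cut_sites, name=name, **entry)
        profile.expected_protected_share_pct = expected  # type: ignore[attr-defined]
        profiles[name] = profile
    return profiles
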