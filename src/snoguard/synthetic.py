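"""Synthetic data with the statistical structure the pipeline assumes.

The generator is a phenomenological stand-in for the wet-lab measurements —
it encodes the *direction and magnitude of effects* the analysis is built to
detect, not cleavage enzymology:

* **Reads.** Each tRNA molecule independently carries the 2'-O-methyl mark
  with probability ``methylated_fraction`` (m), stays full length with
  probability ``intact_fraction``, and is otherwise cleaved at one of a small
  set of sites drawn by weight.  On methylated molecules the weight of the
  *protected* cut site — the one whose 3' boundary abuts the methylation
  position — is multiplied by ``protection_factor`` (< 1 means the mark
  suppresses that cleavage).  Fragment 3' ends jitter by Uniform{0..end_jitter}
  nt, emulating the ladder of 18–20-nt fragment sizes seen on gels.
* **qPCR.** Ct responds log2-linearly to template abundance:
  Ct = base_ct − log2(abundance) + Normal(0, noise_sd).
* **RTL-Q.** Under low dNTPs the downstream (R_D) primer's RT yield on a
  methylated template is attenuated by 2^−δ (δ = pause penalty in cycles), so
  the expected EMF is −log2((1−m) + m·2^−δ): 0 for unmethylated template and
  → δ at full methylation.

Given the same seed, output FASTQ records and Ct values are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .references import TrnaRecord


@dataclass(frozen=True)
class CutSite:
    """A cleavage product spanning [start, end] (1-based inclusive) with a draw weight."""

    start: int
    end: int
    weight: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid cut site span {self.start}-{self.end}")
        if self.weight < 0:
            raise ValueError("cut-site weight must be >= 0")


@dataclass
class CleavageProfile:
    """Generative model of methylation-dependent site-specific tRNA cleavage.

    ``methylation_position`` is the 1-based coordinate of the 2'Ome site on
    the parent; exactly one cut site must end at ``methylation_position - 1``
    (cleavage immediately upstream of the mark) — that site is the protected
    one.  ``abundance_multiplier`` scales total molecule abundance for stress
    variants and leaves fragmentation structure untouched.
    """

    parent_id: str
    intact_fraction: float
    cut_sites: tuple[CutSite, ...]
    methylated_fraction: float
    protection_factor: float
    methylation_position: int
    end_jitter: int = 2
    abundance_multiplier: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        self.cut_sites = tuple(
            cs if isinstance(cs, CutSite) else CutSite(**cs) for cs in self.cut_sites
        )
        for prob_name in ("intact_fraction", "methylated_fraction", "protection_factor"):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prob_name} must be in [0, 1], got {v}")
        if not self.cut_sites or not any(cs.weight > 0 for cs in self.cut_sites):
            raise ValueError("cut sites must be non-empty with at least one positive weight")
        if self.end_jitter < 0:
            raise ValueError("end_jitter must be >= 0")
        if self.abundance_multiplier <= 0:
            raise ValueError("abundance_multiplier must be positive")
        protected = [
            cs for cs in self.cut_sites if cs.end == self.methylation_position - 1
        ]
        if len(protected) != 1:
            raise ValueError(
                "exactly one cut site must end 1 nt before the methylation "
                f"position {self.methylation_position} (found {len(protected)})"
            )

    @property
    def protected_site(self) -> CutSite:
        return next(
            cs for cs in self.cut_sites if cs.end == self.methylation_position - 1
        )

    def validate_against(self, ref: TrnaRecord) -> None:
        """Check that every fragment and the methylation site fit on the reference."""
        if ref.id != self.parent_id:
            raise ValueError(f"profile parent {self.parent_id!r} does not match {ref.id!r}")
        if not 1 <= self.methylation_position <= ref.length:
            raise ValueError("methylation position outside the reference")
        for cs in self.cut_sites:
            if cs.end + self.end_jitter > ref.length:
                raise ValueError(
                    f"cut site {cs.start}-{cs.end} (+{self.end_jitter} jitter) "
                    f"extends beyond {ref.id!r} ({ref.length} nt)"
                )

    def expected_fragment_share(self, site: CutSite | None = None) -> float:
        """Analytic expected share (%) of a cut site among all cleaved molecules.

        Cleavage-site choice is a two-component mixture over the methylation
        state: with probability m the protected weight is scaled by the
        protection factor.  For the protected site with weight w_p, other
        weights summing W_o and factor f:

            share = (1−m)·w_p/(W_o+w_p) + m·f·w_p/(W_o + f·w_p)
        """
        site = site or self.protected_site
        w_total = sum(cs.weight for cs in self.cut_sites)
        w_p = self.protected_site.weight
        m = self.methylated_fraction
        f = self.protection_factor

        def share_given_state(methylated: bool) -> float:
            w_site = site.weight
            total = w_total
            if methylated:
                total = total - w_p + f * w_p
                if site is self.protected_site or site == self.protected_site:
                    w_site = f * w_p
            return w_site / total if total > 0 else 0.0

        return 100.0 * ((1 - m) * share_given_state(False) + m * share_given_state(True))


@dataclass(frozen=True)
class RtlqSimParams:
    """Parameters of the RTL-Q measurement model (Ct cycles throughout)."""

    methylated_fraction: float
    pause_penalty: float
    base_ct: float = 25.0
    ct_noise_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.methylated_fraction <= 1.0:
            raise ValueError("methylated_fraction must be in [0, 1]")
        if self.pause_penalty < 0:
            raise ValueError("pause_penalty must be >= 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    @property
    def expected_emf(self) -> float:
        """Closed-form expected EMF: −log2((1−m) + m·2^−δ)."""
        m, delta = self.methylated_fraction, self.pause_penalty
        return -math.log2((1 - m) + m * 2.0 ** -delta)


def simulate_trna_reads(
    profile: CleavageProfile,
    refs: Sequence[TrnaRecord],
    n_reads: int,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate small-RNA reads from one tRNA under the cleavage model.

    Returns (read_id, sequence) pairs ready for :func:`write_fastq` (constant
    'I' qualities — Phred 40, ignored downstream) plus a ground-truth table
    recording every draw.  Reproducible: the same seed yields byte-identical
    records and table.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    ref = next((r for r in refs if r.id == profile.parent_id), None)
    if ref is None:
        raise ValueError(f"profile parent {profile.parent_id!r} not among references")
    profile.validate_against(ref)

    rng = np.random.default_rng(seed)
    methylated = rng.random(n_reads) < profile.methylated_fraction
    intact = rng.random(n_reads) < profile.intact_fraction

    base_w = np.array([cs.weight for cs in profile.cut_sites], dtype=float)
    protected_idx = profile.cut_sites.index(profile.protected_site)
    meth_w = base_w.copy()
    meth_w[protected_idx] *= profile.protection_factor

    site_idx = np.full(n_reads, -1, dtype=int)
    for state, weights in ((False, base_w), (True, meth_w)):
        mask = (~intact) & (methylated == state)
        n = int(mask.sum())
        if n == 0:
            continue
        if weights.sum() == 0:
            # full protection with no alternative site: the molecule cannot be
            # cleaved at all and stays intact
            intact[mask] = True
            continue
        site_idx[mask] = rng.choice(len(base_w), size=n, p=weights / weights.sum())

    jitter = rng.integers(0, profile.end_jitter + 1, size=n_reads)

    starts = np.empty(n_reads, dtype=int)
    ends = np.empty(n_reads, dtype=int)
    site_starts = np.array([cs.start for cs in profile.cut_sites])
    site_ends = np.array([cs.end for cs in profile.cut_sites])
    cleaved = ~intact
    starts[intact] = 1
    ends[intact] = ref.length
    starts[cleaved] = site_starts[site_idx[cleaved]]
    ends[cleaved] = np.minimum(site_ends[site_idx[cleaved]] + jitter[cleaved], ref.length)

    width = len(str(n_reads))
    read_ids = [f"read{str(i + 1).zfill(width)}" for i in range(n_reads)]
    records = [
        (read_ids[i], ref.sequence[starts[i] - 1 : ends[i]]) for i in range(n_reads)
    ]
    cut_labels = np.where(
        intact,
        "",
        np.char.add(
            np.char.add(site_starts[site_idx].astype(str), "-"),
            site_ends[site_idx].astype(str),
        ),
    )
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "parent_id": ref.id,
            "methylated": methylated,
            "intact": intact,
            "cut_site": cut_labels,
            "jitter": np.where(intact, 0, ends - site_ends[site_idx]),
            "start": starts,
            "end": ends,
        }
    )
    return records, truth


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTQ with constant 'I' (Phred 40) quality."""
    with open(path, "w", encoding="utf-8") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_qpcr_ct(
    abundance: float,
    base_ct: float = 25.0,
    noise_sd: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Log2-linear qPCR response: Ct = base_ct − log2(abundance) + noise."""
    if abundance <= 0:
        raise ValueError("abundance must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return base_ct - math.log2(abundance) + noise


def simulate_rtlq_quadruple(
    params: RtlqSimParams,
    rng: np.random.Generator | None = None,
    replicate_id: str | int | None = None,
):
    """Simulate one RTL-Q Ct quadruple under the pause model.

    R_U primers and the high-dNTP R_D reaction read the full template; the
    low-dNTP R_D yield is attenuated to (1−m) + m·2^−δ, raising its Ct by
    −log2 of that factor.  Hence the expected EMF is −log2((1−m) + m·2^−δ).
    """
    from .rtlq import CtQuadruple  # local import to avoid a cycle at import time

    if rng is None:
        rng = np.random.default_rng(params.seed)
    m, delta = params.methylated_fraction, params.pause_penalty
    low_rd_yield = (1 - m) + m * 2.0 ** -delta

    def ct(yield_factor: float) -> float:
        noise = rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd > 0 else 0.0
        return params.base_ct - math.log2(yield_factor) + noise

    return CtQuadruple(
        ct_low_rd=ct(low_rd_yield),
        ct_high_rd=ct(1.0),
        ct_low_ru=ct(1.0),
        ct_high_ru=ct(1.0),
        replicate_id=replicate_id,
    )


def simulate_rtlq_replicates(
    params: RtlqSimParams,
    n_replicates: int,
    seed: int | None = None,
):
    """Simulate ``n_replicates`` quadruples from one shared random stream."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return [
        simulate_rtlq_quadruple(params, rng=rng, replicate_id=i + 1)
        for i in range(n_replicates)
    ]


def make_fixture_profiles() -> dict[str, CleavageProfile]:
    """The packaged cleavage profiles (knockdown/overexpression + stress variants).

    Loaded from the in-package YAML fixture file; see
    :mod:`snoguard.fixtures`.
    """
    from .fixtures import load_cleavage_profiles

    return load_cleavage_profiles()
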