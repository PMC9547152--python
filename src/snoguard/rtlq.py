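"""RTL-Q analysis: estimated methylated fraction (EMF) from Ct quadruples.

RTL-Q detects 2'-O-ribose methylation by reverse transcription at low dNTP
concentration: extension of a primer annealing 1 nt downstream of the
candidate site (R_D) pauses at a methylated ribose under low dNTPs, while a
primer annealing exactly on the site (R_U) is unaffected, as is any primer
under high dNTPs.  Quantifying the four RT products by qPCR gives the
dimensionless Ct-difference score

    EMF = (Ct_low,RD − Ct_high,RD) − (Ct_low,RU − Ct_high,RU)

EMF > 0 calls methylation present; EMF ≤ 0 calls it absent.  The score is
invariant to template abundance (a common Ct shift cancels) and is an
estimate, not a calibrated stoichiometric fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import defaults


@dataclass(frozen=True)
class CtQuadruple:
    """The four Ct measurements of one RTL-Q replicate.

    Cycle numbers, not concentrations; values at or above the detection
    threshold (45 cycles by default) are flagged and excluded from
    aggregation rather than rejected at construction, because they do occur
    in real plates (e.g. low-abundance precursor transcripts).
    """

    ct_low_rd: float
    ct_high_rd: float
    ct_low_ru: float
    ct_high_ru: float
    replicate_id: str | int | None = None

    def __post_init__(self) -> None:
        for name in ("ct_low_rd", "ct_high_rd", "ct_low_ru", "ct_high_ru"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive cycle number, got {value!r}")

    def above_detection_threshold(
        self, threshold: float = defaults.CT_DETECTION_THRESHOLD
    ) -> bool:
        return any(
            ct >= threshold
            for ct in (self.ct_low_rd, self.ct_high_rd, self.ct_low_ru, self.ct_high_ru)
        )


@dataclass(frozen=True)
class EmfResult:
    """Replicate-aggregated EMF with its methylation call."""

    emf: float
    methylated: bool
    n_replicates: int
    emf_sem: float
    n_excluded: int = 0


def compute_emf(q: CtQuadruple) -> float:
    """EMF of a single quadruple: (low−high) for R_D minus (low−high) for R_U."""
    return (q.ct_low_rd - q.ct_high_rd) - (q.ct_low_ru - q.ct_high_ru)


def aggregate_emf(
    quadruples: Iterable[CtQuadruple],
    detection_threshold: float = defaults.CT_DETECTION_THRESHOLD,
) -> EmfResult:
    """Mean EMF over valid replicates with its SEM and methylation call.

    Replicates with any Ct at or above the detection threshold are excluded;
    SEM is 0 for a single replicate.  All replicates excluded is an error.
    """
    quadruples = list(quadruples)
    valid = [q for q in quadruples if not q.above_detection_threshold(detection_threshold)]
    n_excluded = len(quadruples) - len(valid)
    if not valid:
        raise ValueError("no valid replicates")
    emfs = np.array([compute_emf(q) for q in valid], dtype=float)
    mean = float(emfs.mean())
    sem = float(emfs.std(ddof=1) / np.sqrt(len(emfs))) if len(emfs) > 1 else 0.0
    return EmfResult(
        emf=mean,
        methylated=mean > 0,
        n_replicates=len(valid),
        emf_sem=sem,
        n_excluded=n_excluded,
    )


def read_ct_table(path: str | Path) -> dict[str, list[CtQuadruple]]:
    """Read a long-format RTL-Q Ct table into per-sample quadruples.

    Expected columns: sample, replicate, primer (RD/RU), dntp (low/high), ct.
    CSV or TSV, sniffed by extension (.tsv/.txt → tab).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "replicate", "primer", "dntp", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.assign(
        primer=df["primer"].str.upper().str.replace("_", "", regex=False),
        dntp=df["dntp"].str.lower(),
    )
    out: dict[str, list[CtQuadruple]] = {}
    for (sample, replicate), grp in df.groupby(["sample", "replicate"], sort=True):
        cts = {(row.primer, row.dntp): row.ct for row in grp.itertuples()}
        try:
            quad = CtQuadruple(
                ct_low_rd=cts[("RD", "low")],
                ct_high_rd=cts[("RD", "high")],
                ct_low_ru=cts[("RU", "low")],
                ct_high_ru=cts[("RU", "high")],
                replicate_id=replicate,
            )
        except KeyError as exc:
            raise ValueError(
                f"{path}: sample {sample!r} replicate {replicate!r} missing "
                f"primer/dNTP combination {exc.args[0]}"
            ) from None
        out.setdefault(str(sample), []).append(quad)
    return out


def emf_table(
    quadruples_by_sample: dict[str, list[CtQuadruple]],
    detection_threshold: float = defaults.CT_DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Aggregate every sample's quadruples into a tidy EMF result table."""
    rows = []
    for sample in sorted(quadruples_by_sample):
        res = aggregate_emf(quadruples_by_sample[sample], detection_threshold)
        rows.append(
            {
                "sample": sample,
                "emf": res.emf,
                "emf_sem": res.emf_sem,
                "n_replicates": res.n_replicates,
                "n_excluded": res.n_excluded,
                "methylated": res.methylated,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "emf", "emf_sem", "n_replicates", "n_excluded", "methylated"]
    )
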