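"""qPCR-derived expression indices and group comparisons.

Covers the arithmetic used throughout the experimental read-outs:

* relative expression by the 2^−ΔCt method against a reference RNA (U6, or a
  geometric-mean combination of references such as RPLP0 + U6),
* the fragmentation ratio mature-tRNA Ct / tRF Ct (a *larger* ratio means
  relatively more fragment, because abundant tRFs have *lower* Ct),
* baseline normalization for decay assays (expression at t over t0),
* two-tailed t tests (unpaired, paired, and ratio-paired — the latter a
  paired t test on log-transformed values) with the significance/trend
  verdict convention p < 0.05 significant, 0.05 ≤ p < 0.1 trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import defaults


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR well in a long-format design table."""

    sample: str
    target: str
    ct: float
    treatment: str | None = None
    stress: str | None = None
    experiment: str | int | None = None

    def __post_init__(self) -> None:
        _validate_ct(self.ct)


def _validate_ct(ct: float, max_ct: float = defaults.CT_DETECTION_THRESHOLD) -> None:
    if not math.isfinite(ct) or not 0 < ct < max_ct:
        raise ValueError(f"invalid Ct value {ct!r} (expected 0 < Ct < {max_ct})")


def relative_expression_dct(target_ct: float, reference_ct) -> float:
    """Relative expression 2^−(target Ct − reference Ct).

    ``reference_ct`` may be a scalar or an iterable of reference Cts; with
    several references their mean Ct is used, which equals normalizing to the
    geometric mean of the individual reference expressions.
    """
    _validate_ct(target_ct)
    if isinstance(reference_ct, (int, float)):
        ref = float(reference_ct)
        _validate_ct(ref)
    else:
        refs = [float(c) for c in reference_ct]
        if not refs:
            raise ValueError("no reference Ct values")
        for c in refs:
            _validate_ct(c)
        ref = float(np.mean(refs))
    return 2.0 ** -(target_ct - ref)


def fragmentation_ratio(mature_ct: float, trf_ct: float) -> float:
    """Mature-tRNA Ct divided by tRF Ct.

    Because Ct falls as abundance rises, the ratio increases when more tRF is
    present relative to its parent tRNA.
    """
    _validate_ct(mature_ct)
    _validate_ct(trf_ct)
    return mature_ct / trf_ct


def normalize_to_baseline(expr_t: float, expr_t0: float) -> float:
    """Fraction of a transcript remaining at time t relative to time 0."""
    if expr_t0 <= 0:
        raise ValueError("baseline expression must be positive")
    return expr_t / expr_t0


def verdict_for(
    pvalue: float,
    significance: float = defaults.P_SIGNIFICANT,
    trend: float = defaults.P_TREND,
) -> str:
    if pvalue < significance:
        return "significant"
    if pvalue < trend:
        return "trend"
    return "not significant"


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    test_name: str
    verdict: str

    @property
    def significant(self) -> bool:
        return self.verdict == "significant"

    @property
    def trend(self) -> bool:
        return self.verdict == "trend"


def compare_groups(
    values_a: Sequence[float] | Iterable[float],
    values_b: Sequence[float] | Iterable[float],
    paired: bool = False,
    ratio_paired: bool = False,
    significance: float = defaults.P_SIGNIFICANT,
    trend: float = defaults.P_TREND,
) -> ComparisonResult:
    """Two-tailed t test between two groups with significance/trend verdicts.

    ``paired`` matches observations by position (the pairing unit, e.g. an
    independent experiment); ``ratio_paired`` tests the per-pair ratio by a
    paired t test on log-transformed values and requires positive data.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if ratio_paired:
        paired = True
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal group sizes")
    if ratio_paired:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("ratio-paired test requires positive values")
        res = stats.ttest_rel(np.log(a), np.log(b))
        name = "ratio paired t test"
    elif paired:
        res = stats.ttest_rel(a, b)
        name = "paired t test"
    else:
        res = stats.ttest_ind(a, b)
        name = "unpaired t test"
    statistic = float(res.statistic)
    pvalue = float(res.pvalue)
    return ComparisonResult(
        statistic=statistic,
        pvalue=pvalue,
        n_a=len(a),
        n_b=len(b),
        test_name=name,
        verdict=verdict_for(pvalue, significance, trend),
    )
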