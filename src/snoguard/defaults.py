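"""Package-wide default thresholds.

All analysis-facing cutoffs live here so a single place documents them:

* ``P_SIGNIFICANT`` / ``P_TREND`` — two-tailed p-value verdicts: below 0.05 a
  comparison is called significant, between 0.05 and 0.1 a trend.
* ``CT_DETECTION_THRESHOLD`` — qPCR cycle ceiling; Ct values at or above it are
  treated as beyond the detection limit and excluded from EMF aggregation.
* ``TRF_MAX_LEN`` — reads shorter than this are tRNA-derived fragments (tRFs),
  reads of this length or longer are classed mature/precursor.
* ``MIN_CORE`` / ``MAX_TERMINAL_MISMATCHES`` — duplex acceptance: at least a
  7-nt contiguous Watson-Crick core, with mismatches confined to the outermost
  2 positions at each element end.
* ``ANTISENSE_LENGTH`` — nt extracted immediately upstream of a D/D' box.
* ``FAMILY_EXTENSION_3P`` — 3' end jitter tolerated when grouping fragment
  calls into a named family (tRF 47-64 covers 47-64/65/66 by default).
* ``MIN_READ_LEN`` — reads below this are dropped before assignment.
"""

P_SIGNIFICANT = 0.05
P_TREND = 0.1
CT_DETECTION_THRESHOLD = 45.0
TRF_MAX_LEN = 45
MIN_CORE = 7
MAX_TERMINAL_MISMATCHES = 2
ANTISENSE_LENGTH = 9
FAMILY_EXTENSION_3P = 2
MIN_READ_LEN = 15
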