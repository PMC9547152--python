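# Methods

This note documents the models behind `snoguard`, the parameter defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions that were genuinely open.

## Coordinates and references

All user-facing coordinates are 1-based inclusive on the mature sense strand,
RNA alphabet (DNA input is converted T→U on read). Mature tRNA references are
stored **without** the 3′ CCA tail by default (`cca_appended=False`, with a
loader flag to append it): database entries differ in whether they carry the
tail, and fragment nomenclature such as "tRF 47–64" is only stable if the
coordinate origin is fixed. Validation enforces 60–100 nt for a mature tRNA
and that a declared anticodon occurs in the sequence.

C/D-box motif calling uses the standard consensus definitions — C box
RUGAUGA (R ∈ {A, G}), D and D′ boxes CUGA — because generic inputs need
them. The D box is the last exact CUGA; the C box the first RUGAUGA upstream
of it; the D′ box the first exact CUGA strictly between them, falling back to
a one-mismatch variant only when no exact internal CUGA exists. Exact-first
matters: antisense elements themselves often contain one-mismatch CUGA
variants (the packaged element `CUGGGGUUA` starts with one), and a
mismatch-tolerant first pass would misplace the D′ box. The packaged snoRNA
ships with pre-annotated boxes, so fixture-based results never depend on
motif calling at all (the annotations are cross-checked against the caller in
the test suite).

The default antisense-element length is 9 nt: a 7-nt perfectly pairing core
plus one potentially mismatching nucleotide at each end, the geometry of the
conserved site the packaged fixtures reproduce. It is configurable.

## Duplex search and 2′Ome placement

For an element of length L, every length-L window of the target is scored in
antiparallel orientation (element position i pairs window position L−i+1).
A window is a hit when its longest contiguous Watson–Crick run is at least
`min_core` (default 7) and every mismatch lies within the outermost
`max_terminal_mismatches` (default 2) positions at each element end. G:U
wobble counts as a mismatch by default — guide-duplex selection is treated as
strict Watson–Crick pairing — with a `wobble_pairs` flag to relax it. Hits
sort by core length (descending), then target start (ascending), which also
defines the deterministic tie-break between equal-core hits.

The predicted 2′Ome nucleotide is the target base paired with the element
residue 5 positions upstream of the adjacent D/D′ box, counting the element's
3′-most residue as +1 (the standard box-counting convention; the count origin
is a convention, not a measurable). Under antiparallel pairing this is target
position `window_start + 4`, independent of element length. If that element
position is mismatched in a given hit, placement is refused with the reason
"unpaired at +5" rather than guessed.

The implementation is verified against an exhaustive window-by-window
brute-force oracle on hundreds of seeded random instances, plus
reverse-complement symmetry and threshold-monotonicity properties.

## Read assignment and tRF analytics

Desk-scale read assignment replaces a genome aligner with exact full-length
substring matching (0 mismatches): it is reproducible, dependency-free, and
sufficient for reads simulated from known references. Reads shorter than
15 nt are dropped (and counted); there is no default upper length cutoff —
reads of ≥ 45 nt are instead *classified* mature/precursor rather than tRF,
which keeps full-length molecules visible to coverage and class summaries. A
`max_len` parameter restores a hard window when wanted.

Multi-mapping reads follow the single-assignment convention: uniquely
matching reads are tallied first, then each multi-mapper is assigned to the
matching reference with the highest unique-read count; ties break by
lexicographic reference id and are logged. Totals are invariant to input
read order.

Fragment calls group reads by (parent, start, end); the canonical tRF name
renders the 1-based inclusive span. RPM is `count / assigned_reads × 10⁶`,
with the denominator taken as all reads assigned to any reference class (a
choice — the alternative, per-class denominators, would break cross-class
comparability). The length histogram covers 18–45 nt with small = 18–29 and
large = 30–45 classes, reported as percentages of all tRNA-assigned reads;
it counts exact lengths, not families. A named fragment *family* includes
3′-end-jittered variants up to +2 nt downstream of the named end (cleavage
produces a short ladder of 3′ ends from one 5′ boundary); the window is
configurable, and the family share is the family's percentage of the
parent's tRF reads.

## RTL-Q and EMF

EMF is raw Ct arithmetic, `(low−high)_RD − (low−high)_RU`, with no
amplification-efficiency correction — the index is a Ct-difference score, not
a calibrated stoichiometric fraction. Replicates aggregate by the mean of
per-replicate EMFs with the standard error over replicates (0 for n = 1);
any replicate with a Ct at or above the 45-cycle detection threshold
(configurable) is excluded, and all-excluded is an error rather than a
silent zero. EMF > 0 calls methylation present. Two exact invariances are
tested: adding a constant to all four Cts leaves EMF unchanged (abundance
invariance), and swapping the R_D/R_U roles negates it.

## Expression indices and tests

Relative expression is 2^−ΔCt against a reference RNA; passing several
references uses their mean Ct, equivalent to normalizing to the geometric
mean of the individual reference expressions (used for dual-reference decay
assays). The fragmentation ratio is mature-tRNA Ct divided by tRF Ct; since
Ct falls with abundance, a larger ratio means relatively more fragment.
Group comparisons are two-tailed t tests (equal-variance unpaired, paired,
or ratio-paired); the "ratio paired" test is implemented as a paired t test
on log-transformed values, the standard construction when only per-pair
ratios are meaningful. Verdicts: p < 0.05 significant, 0.05 ≤ p < 0.1 a
trend; both thresholds are parameters. No multiple-testing correction is
applied by default.

## The synthetic-data generator

The generator encodes the statistical structure the analysis must detect; it
is **not** a mechanistic model of cleavage enzymology (no endonuclease
kinetics, no stress-response dynamics).

**Cleavage model.** Each molecule independently: carries the 2′Ome mark with
probability m (`methylated_fraction`); stays full-length with probability
`intact_fraction` (default 0.70 in the packaged profiles — most molecules of
an abundant tRNA are intact); otherwise is cleaved at one of a small set of
cut sites drawn proportionally to weight. On methylated molecules the
*protected* site's weight is multiplied by `protection_factor` < 1. The
profile validator enforces that exactly one cut site ends 1 nt before the
methylation position — protection is structurally tied to cleavage
immediately upstream of the mark. Fragment 3′ ends extend by
Uniform{0..`end_jitter`} nt (default 2, giving the three observed fragment
sizes of 18–20 nt). The expected share of the protected family among tRFs is
the analytic mixture

    share(m) = (1−m)·w_p/(W_o+w_p) + m·f·w_p/(W_o+f·w_p)

**Packaged condition profiles.** `af25_low` (snoRNA knocked down, m = 0) and
`af25_high` (snoRNA overexpressed, m = 1) share cut sites
(47–64 w = 1.0, 1–18 w = 0.55, 30–47 w = 0.45) and protection factor 7/13,
chosen so the expected 47–64 family shares are exactly 50 % and 35 % — the
two condition-level shares the pipeline is expected to recover. m = 0/1 are
the contrast's extremes; intermediate methylation levels interpolate
monotonically (a tested property). Stress variants multiply total abundance
by 2.0 (hypoxia) and 1.5 (oxidative stress) — magnitudes are this package's
choice; only the direction (increase) is constrained by the biology being
emulated — and leave fragmentation structure unchanged.

**qPCR.** Ct = base_ct − log2(abundance) + N(0, sd), with default
base_ct = 25 and sd = 0.2 cycles (typical technical replicate scatter).

**RTL-Q.** R_U reactions and the high-dNTP R_D reaction see the full
template; the low-dNTP R_D yield is attenuated to (1−m) + m·2^−δ, where δ
(`pause_penalty`, default 4 cycles in the pipeline) is the effective
extension penalty at a methylated ribose. Hence
E[EMF] = −log2((1−m) + m·2^−δ): exactly 0 at m = 0 and → δ at m = 1.
Parameter recovery over an (m, δ) grid within 3 SE is part of the test
suite.

**What passing tests do not show.** The generator emits perfect reads
(no sequencing error, no adapters/UMIs), exact cut-site boundaries with only
3′ jitter, a single parent tRNA, and Gaussian Ct noise. Recovery on this
data validates the pipeline's arithmetic and decision rules, not robustness
to alignment ambiguity, modification-induced RT artifacts, or real library
chemistry.

## Pipeline and reproducibility

The five stages (simulate → predict targets → profile tRFs → EMF → stats)
run from one YAML configuration. Stage random streams derive from the run
seed via `SeedSequence(seed, spawn_key=(stage_index,))`, so any stage can be
re-run alone and reproduce its outputs byte-identically. The manifest
records package version, seed, full configuration with SHA-256, and digests
of all outputs. Configuration validation reports *all* problems at once.
The simulated qPCR contrast pairs a control arm (high-methylation profile)
with a knockdown arm (low), with a shared per-experiment abundance factor
(2^N(0,0.3)) that pairing removes — a deliberately simple demonstration of
why the paired test is the right tool there.

## Problem sizes

Default simulations use 100,000 reads per condition (≈ 30,000 tRFs, putting
3 binomial SE on a 50 % share at ≈ ±0.9 percentage points) and 6–15 RTL-Q
replicates per grid point; unit tests use 300–30,000 reads. These sizes give
tight Monte-Carlo tolerances while keeping any full run in seconds.

## Known limitations

- Exact-match assignment cannot place reads with sequencing errors or
  post-transcriptional edits; it is a desk-scale stand-in, not an aligner.
- EMF is a relative score; converting it to an absolute methylated fraction
  would require calibration against synthetic methylated/unmethylated
  standards.
- The cleavage generator's protection mechanism is phenomenological; it
  makes no claim about which endonuclease cuts or how stress modulates it.
- Intron-containing pre-tRNAs, CCA-intermediate states and
  modification-aware alphabets are out of scope.
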