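"""End-to-end pipeline orchestration with fixed-seed reproducibility.

Stage order mirrors the analysis flow: simulate (or ingest) small-RNA reads
and Ct tables → predict snoRNA:tRNA duplex targets → profile tRFs → compute
EMF → expression statistics.  Every stage writes plain-text outputs under the
run directory and is individually re-runnable; stage seeds derive
deterministically from the run seed, so re-running any stage reproduces its
outputs byte-identically.  A JSON manifest records the package version, the
seed, the full configuration with its hash, and a SHA-256 digest of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, defaults, expression_stats, rtlq, synthetic, trf_profiler
from .fixtures import load_cleavage_profiles, load_snorna_reference, load_trna_reference
from .references import read_fasta_records
from .target_prediction import find_duplex_hits, write_hits_tsv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "predict_targets", "profile_trfs", "emf", "stats")

#: Treatment labels of the simulated knockdown contrast and the fixture
#: profiles whose parameters generate each arm's Ct data.
_TREATMENT_PROFILES = (("GM-ctrl", "af25_high"), ("GM-AF25", "af25_low"))


class ConfigError(ValueError):
    """Raised with the full list of configuration problems, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class RunConfig:
    """One pipeline run: inputs, thresholds, seed, output directory."""

    out_dir: str
    mode: str = "simulate"  # "simulate" or "ingest"
    profile: str = "af25_low"
    reads_path: str | None = None  # required in ingest mode
    trna_fasta: str | None = None  # packaged fixture when None
    n_reads: int = 100_000
    seed: int = 42
    min_core: int = defaults.MIN_CORE
    max_terminal_mismatches: int = defaults.MAX_TERMINAL_MISMATCHES
    trf_max_len: int = defaults.TRF_MAX_LEN
    family_extension_3p: int = defaults.FAMILY_EXTENSION_3P
    significance: float = defaults.P_SIGNIFICANT
    trend: float = defaults.P_TREND
    ct_detection_threshold: float = defaults.CT_DETECTION_THRESHOLD
    rtlq_pause_penalty: float = 4.0
    rtlq_replicates: int = 6
    qpcr_experiments: int = 4
    ct_noise_sd: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
        return cls(**raw)

    def validate(self) -> None:
        problems: list[str] = []
        if self.mode not in ("simulate", "ingest"):
            problems.append(f"mode must be simulate or ingest, got {self.mode!r}")
        if self.mode == "ingest":
            if not self.reads_path:
                problems.append("ingest mode requires reads_path")
            elif not Path(self.reads_path).exists():
                problems.append(f"reads_path does not exist: {self.reads_path}")
        if self.mode == "simulate" and self.profile not in load_cleavage_profiles():
            problems.append(f"unknown cleavage profile {self.profile!r}")
        if self.trna_fasta is not None and not Path(self.trna_fasta).exists():
            problems.append(f"trna_fasta does not exist: {self.trna_fasta}")
        if self.n_reads < 1:
            problems.append("n_reads must be >= 1")
        if self.min_core < 1:
            problems.append("min_core must be >= 1")
        if self.max_terminal_mismatches < 0:
            problems.append("max_terminal_mismatches must be >= 0")
        if not 15 <= self.trf_max_len <= 100:
            problems.append("trf_max_len must be within 15-100 nt")
        if not 0 < self.significance < self.trend < 1:
            problems.append("require 0 < significance < trend < 1")
        if self.ct_detection_threshold <= 0:
            problems.append("ct_detection_threshold must be positive")
        if self.rtlq_replicates < 1 or self.qpcr_experiments < 2:
            problems.append("need >= 1 RTL-Q replicate and >= 2 qPCR experiments")
        if problems:
            raise ConfigError(problems)


def _stage_seed(config: RunConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(STAGES.index(stage),))
    return np.random.default_rng(ss)


def _stage_int_seed(config: RunConfig, stage: str) -> int:
    # sub-2^31 deterministic integer seed for APIs that take a plain seed
    return (config.seed * 1_000_003 + STAGES.index(stage)) % (2**31 - 1)


def _load_refs(config: RunConfig):
    if config.trna_fasta:
        return read_fasta_records(config.trna_fasta, kind="trna")
    return [load_trna_reference()]


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    profiles = load_cleavage_profiles()
    profile = profiles[config.profile]
    refs = _load_refs(config)

    records, truth = synthetic.simulate_trna_reads(
        profile, refs, config.n_reads, seed=_stage_int_seed(config, "simulate")
    )
    synthetic.write_fastq(records, out / "reads.fastq")
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    rng = _stage_seed(config, "simulate")
    # RTL-Q table: one sample per treatment arm, parameters from the paired profiles
    rtlq_rows = []
    for treatment, profile_name in _TREATMENT_PROFILES:
        params = synthetic.RtlqSimParams(
            methylated_fraction=profiles[profile_name].methylated_fraction,
            pause_penalty=config.rtlq_pause_penalty,
            ct_noise_sd=config.ct_noise_sd,
        )
        for rep in range(1, config.rtlq_replicates + 1):
            quad = synthetic.simulate_rtlq_quadruple(params, rng=rng, replicate_id=rep)
            for primer, dntp, ct in (
                ("RD", "low", quad.ct_low_rd),
                ("RD", "high", quad.ct_high_rd),
                ("RU", "low", quad.ct_low_ru),
                ("RU", "high", quad.ct_high_ru),
            ):
                rtlq_rows.append(
                    {"sample": treatment, "replicate": rep, "primer": primer,
                     "dntp": dntp, "ct": round(ct, 4)}
                )
    pd.DataFrame(rtlq_rows).to_csv(out / "rtlq_ct.tsv", sep="\t", index=False)

    # qPCR table: mature tRNA, tRF and U6 Cts per treatment and experiment.
    # A shared per-experiment abundance factor emulates biological batch
    # variation that pairing removes.
    qpcr_rows = []
    exp_factor = 2.0 ** rng.normal(0.0, 0.3, size=config.qpcr_experiments)
    for treatment, profile_name in _TREATMENT_PROFILES:
        p = profiles[profile_name]
        share = p.expected_fragment_share() / 100.0
        abundances = {
            "U6": 1.0,
            "mature_tRNA-Leu-TAA": p.intact_fraction * p.abundance_multiplier,
            "tRF_47-64": (1 - p.intact_fraction) * share * p.abundance_multiplier,
        }
        for exp in range(1, config.qpcr_experiments + 1):
            for target, abundance in abundances.items():
                ct = synthetic.simulate_qpcr_ct(
                    abundance * exp_factor[exp - 1],
                    noise_sd=config.ct_noise_sd,
                    rng=rng,
                )
                qpcr_rows.append(
                    {"sample": f"{treatment}_exp{exp}", "target": target,
                     "treatment": treatment, "experiment": exp, "ct": round(ct, 4)}
                )
    pd.DataFrame(qpcr_rows).to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
    return ["reads.fastq", "ground_truth.tsv", "rtlq_ct.tsv", "qpcr_ct.tsv"]


def _stage_predict_targets(config: RunConfig, out: Path) -> list[str]:
    refs = _load_refs(config)
    sno = load_snorna_reference()
    element = sno.element_for("D_prime")
    hits = []
    for ref in refs:
        hits.extend(
            find_duplex_hits(
                element,
                ref,
                min_core=config.min_core,
                max_terminal_mismatches=config.max_terminal_mismatches,
            )
        )
    write_hits_tsv(hits, out / "duplex_hits.tsv")
    return ["duplex_hits.tsv"]


def _stage_profile_trfs(config: RunConfig, out: Path) -> list[str]:
    refs = _load_refs(config)
    reads_path = (
        Path(config.reads_path) if config.mode == "ingest" else out / "reads.fastq"
    )
    reads = trf_profiler.read_fastq(reads_path)
    result = trf_profiler.assign_reads(reads, refs)
    summary = trf_profiler.summarize_profile(result, refs, trf_max_len=config.trf_max_len)
    trf_profiler.write_fragments_tsv(summary, out / "fragments.tsv")
    trf_profiler.write_coverage_tsv(summary, out / "coverage.tsv")
    trf_profiler.write_histogram_tsv(summary, out / "histogram.tsv")

    rows = [
        {"metric": "n_assigned", "value": summary.n_assigned},
        {"metric": "n_unassigned", "value": summary.n_unassigned},
        {"metric": "n_dropped", "value": summary.n_dropped},
    ]
    calls = trf_profiler.call_fragments(result, trf_max_len=config.trf_max_len)
    for ref in refs:
        if any(c.parent_id == ref.id and c.category == "tRF" for c in calls):
            share = trf_profiler.fragment_fraction(
                calls, ref.id, "tRF 47-64", extension_3p=config.family_extension_3p
            )
            rows.append(
                {"metric": f"family_share_47-64_pct[{ref.id}]", "value": round(share, 4)}
            )
    pd.DataFrame(rows).to_csv(out / "profile_summary.tsv", sep="\t", index=False)
    return ["fragments.tsv", "coverage.tsv", "histogram.tsv", "profile_summary.tsv"]


def _stage_emf(config: RunConfig, out: Path) -> list[str]:
    quads = rtlq.read_ct_table(out / "rtlq_ct.tsv")
    table = rtlq.emf_table(quads, detection_threshold=config.ct_detection_threshold)
    table.to_csv(out / "emf.tsv", sep="\t", index=False, float_format="%.4f")
    return ["emf.tsv"]


def _stage_stats(config: RunConfig, out: Path) -> list[str]:
    df = pd.read_csv(out / "qpcr_ct.tsv", sep="\t")
    treatments = [t for t, _ in _TREATMENT_PROFILES]

    def series(treatment: str, metric: str) -> list[float]:
        values = []
        for exp, grp in df[df["treatment"] == treatment].groupby("experiment"):
            cts = dict(zip(grp["target"], grp["ct"]))
            if metric == "fragmentation_ratio":
                values.append(
                    expression_stats.fragmentation_ratio(
                        cts["mature_tRNA-Leu-TAA"], cts["tRF_47-64"]
                    )
                )
            else:  # relative tRF expression vs U6
                values.append(
                    expression_stats.relative_expression_dct(cts["tRF_47-64"], cts["U6"])
                )
        return values

    rows = []
    for metric, ratio_paired in (
        ("fragmentation_ratio", False),
        ("trf_relative_expression", True),
    ):
        a = series(treatments[1], metric)  # knockdown arm
        b = series(treatments[0], metric)  # control arm
        res = expression_stats.compare_groups(
            a,
            b,
            paired=True,
            ratio_paired=ratio_paired,
            significance=config.significance,
            trend=config.trend,
        )
        rows.append(
            {
                "metric": metric,
                "group_a": treatments[1],
                "group_b": treatments[0],
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "test": res.test_name,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "verdict": res.verdict,
            }
        )
    pd.DataFrame(rows).to_csv(out / "stats.tsv", sep="\t", index=False, float_format="%.6g")
    return ["stats.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "predict_targets": _stage_predict_targets,
    "profile_trfs": _stage_profile_trfs,
    "emf": _stage_emf,
    "stats": _stage_stats,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (all by default) and write the manifest.

    Returns the manifest dict.  Raises :class:`ConfigError` listing every
    validation failure when the configuration is invalid.
    """
    config.validate()
    selected = list(STAGES) if stages is None else list(stages)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if config.mode == "ingest":
        selected = [s for s in selected if s != "simulate"]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_outputs: dict[str, list[str]] = {}
    for stage in STAGES:
        if stage not in selected:
            continue
        logger.info("running stage %s", stage)
        stage_outputs[stage] = _STAGE_FUNCS[stage](config, out)

    config_dict = asdict(config)
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest_path = out / "manifest.json"
    existing: dict = {}
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text(encoding="utf-8"))
    all_outputs = dict(existing.get("stages", {}))
    all_outputs.update(stage_outputs)
    manifest = {
        "package": "snoguard",
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": all_outputs,
        "output_sha256": {
            name: _sha256(out / name)
            for outputs in all_outputs.values()
            for name in outputs
            if (out / name).exists()
        },
    }
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
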