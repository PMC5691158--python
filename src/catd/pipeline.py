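"""Pipeline orchestration: count -> call (optionally simulate/design first),
duplicate concordance, and the machine-readable run report."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from catd.genotype_calling import (
    ThresholdRule,
    call_deletions,
    score_panel,
    snp_alt_fraction,
)
from catd.read_counting import (
    HeadcountTable,
    TARGET_DEPTH,
    count_read_array,
    count_reads,
    normalize_depth,
)
from catd.simulator import Cohort, SimConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "call_cohort",
    "count_cohort",
    "duplicate_concordance",
    "false_negative_rate",
    "run_pipeline",
    "validate_report",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Duplicate concordance
# ---------------------------------------------------------------------------


def duplicate_pairs(samples: pd.DataFrame) -> List[Tuple[str, str]]:
    """(replicate_of, sample) pairs from the sample sheet."""
    pairs = []
    for row in samples.itertuples():
        if row.replicate_of:
            pairs.append((row.replicate_of, row.sample_id))
    return pairs


def duplicate_concordance(
    table: HeadcountTable, pairs: Sequence[Tuple[str, str]]
) -> Dict[Tuple[str, str], float]:
    """Pearson r over per-product normalized counts for each duplicate pair.

    Constant or undefined vectors yield NaN (flagged downstream, not raised).
    """
    if table.normalized is None:
        raise ValueError("normalize_depth must run before concordance")
    out: Dict[Tuple[str, str], float] = {}
    for a, b in pairs:
        if len(table.normalized.columns) < 3:
            raise ValueError("need >= 3 products for a meaningful correlation")
        x = table.normalized.loc[a].to_numpy(dtype=float)
        y = table.normalized.loc[b].to_numpy(dtype=float)
        if (
            np.isnan(x).any() or np.isnan(y).any()
            or np.ptp(x) == 0 or np.ptp(y) == 0
        ):
            out[(a, b)] = float("nan")
            continue
        out[(a, b)] = float(stats.pearsonr(x, y).statistic)
    return out


# ---------------------------------------------------------------------------
# Count stage
# ---------------------------------------------------------------------------


def count_cohort(cohort: Cohort,
                 target_depth: int = TARGET_DEPTH) -> HeadcountTable:
    """Count every sample of an in-memory cohort and depth-normalize."""
    sample_counts = {}
    for truth in cohort.truths:
        reads = cohort.reads.get(truth.sample_id)
        if reads is None:
            raise ValueError(
                f"{truth.sample_id}: no in-memory reads (cohort written to "
                "disk only? use the file-based count stage)"
            )
        sample_counts[truth.sample_id] = count_read_array(
            reads, cohort.design.products
        )
    table = HeadcountTable.from_sample_counts(sample_counts,
                                              cohort.design.products)
    return normalize_depth(table, target_depth)


def count_fastq_samples(
    samples: pd.DataFrame,
    products,
    target_depth: int = TARGET_DEPTH,
) -> HeadcountTable:
    """File-based count stage: one FASTQ per sample-sheet row."""
    from catd.io import read_fastq_seqs

    sample_counts = {}
    for row in samples.itertuples():
        if not row.fastq:
            raise ValueError(f"{row.sample_id}: no FASTQ path in sample sheet")
        sample_counts[row.sample_id] = count_reads(
            read_fastq_seqs(row.fastq), products
        )
    table = HeadcountTable.from_sample_counts(sample_counts, products)
    return normalize_depth(table, target_depth)


# ---------------------------------------------------------------------------
# Call stage
# ---------------------------------------------------------------------------


@dataclass
class CallResult:
    scores: pd.DataFrame  # per sample x panel score records (incl. kebab)
    calls: pd.DataFrame   # per sample x target genotype calls (the matrix)
    thresholds: Dict[str, float]
    flags: Dict[str, List[str]]


def call_cohort(
    table: HeadcountTable,
    samples: pd.DataFrame,
    rule: ThresholdRule = ThresholdRule(),
    maf_threshold: float = 0.05,
    het_band: Tuple[float, float] = (0.2, 0.8),
    pseudocount: float = 1.0,
) -> CallResult:
    """Score every panel and emit the genotype-call matrix.

    Panels are derived from the table's product annotations: one Cat-D panel
    per deletion target, the (shared) Kebab panel, and one minor-allele panel
    per small mutation.  The call matrix holds one row per sample per
    *target* (each deletion and each small mutation); the Kebab panel feeds
    zygosity resolution and appears in the score table only.
    """
    wt_samples = list(samples.loc[samples["role"] == "wt_control", "sample_id"])
    if not wt_samples:
        raise ValueError("sample sheet designates no wt_control samples")
    meta = table.product_meta
    if table.normalized is None:
        raise ValueError("normalize_depth must run before calling")
    deletion_targets = sorted(meta.loc[meta["kind"] == "catd", "target"].unique())
    kebab_targets = sorted(meta.loc[meta["kind"] == "kebab", "target"].unique())

    def pooled_headcount(kind: str, target: str) -> pd.Series:
        cols = meta.index[(meta["kind"] == kind) & (meta["target"] == target)]
        return table.normalized[cols].sum(axis=1)

    score_frames: List[pd.DataFrame] = []
    thresholds: Dict[str, float] = {}

    catd_calls: Dict[str, pd.Series] = {}
    for target in deletion_targets:
        head = pooled_headcount("catd", target)
        panel = score_panel(head, wt_samples, "catd", rule, pseudocount)
        panel.insert(0, "target", target)
        panel.insert(1, "kind", "catd")
        thresholds[f"{target}:catd"] = float(panel["threshold"].iloc[0])
        catd_calls[target] = panel["call"] == "positive"
        score_frames.append(panel.reset_index())

    kebab_positive = pd.Series(False, index=table.counts.index)
    for target in kebab_targets:
        head = pooled_headcount("kebab", target)
        panel = score_panel(head, wt_samples, "kebab", rule, pseudocount)
        panel.insert(0, "target", target)
        panel.insert(1, "kind", "kebab")
        thresholds[f"{target}:kebab"] = float(panel["threshold"].iloc[0])
        kebab_positive |= panel["call"] == "positive"
        score_frames.append(panel.reset_index())

    deletion_calls = call_deletions(catd_calls, kebab_positive)

    # --- small mutations ---------------------------------------------------
    alt_rows = meta[(meta["kind"] == "snp") & (meta["allele"] == "alt")]
    probe_of_snp = dict(zip(alt_rows["target"], alt_rows["probe"]))
    norm = table.normalized
    snp_rows = []
    snp_scores = []
    for snp_name in sorted(probe_of_snp):
        probe_name = probe_of_snp[snp_name]
        fractions = {}
        depths = {}
        for sample in table.counts.index:
            frac, depth = snp_alt_fraction(
                norm.loc[sample], table.product_meta, probe_name, snp_name
            )
            fractions[sample] = frac
            depths[sample] = depth
        frac_series = pd.Series(fractions)
        max_frac = frac_series.max()
        degenerate = not (max_frac > 0)
        if degenerate:
            scaled = frac_series * 0.0
            threshold = 100.0
        else:
            scaled = frac_series * (100.0 / max_frac)
            scaled[frac_series == max_frac] = 100.0
            threshold = maf_threshold * 100.0 / max_frac
        thresholds[f"{snp_name}:snp"] = float(threshold)
        for sample in table.counts.index:
            frac = fractions[sample]
            flags = []
            if degenerate:
                flags.append("degenerate_panel")
            if not np.isnan(frac) and frac > maf_threshold:
                positive = True
                if frac > het_band[1]:
                    genotype = "hom"
                elif frac >= het_band[0]:
                    genotype = "het"
                else:
                    genotype = "lowfrac"
                    flags.append("low_alt_fraction")
            else:
                positive = False
                genotype = "ref"
                if np.isnan(frac):
                    flags.append("zero_depth")
            snp_rows.append(
                {
                    "sample": sample,
                    "target": snp_name,
                    "genotype": genotype,
                    "positive": positive,
                    "flags": ";".join(flags),
                }
            )
            snp_scores.append(
                {
                    "sample": sample,
                    "target": snp_name,
                    "kind": "snp",
                    "headcount": depths[sample],
                    "standard_weight": float("nan"),
                    "raw_score": frac,
                    "scaled_score": float(scaled[sample]),
                    "threshold": float(threshold),
                    "call": "positive" if positive else "negative",
                    "flags": ";".join(flags),
                }
            )
    score_frames.append(pd.DataFrame(snp_scores))

    calls = pd.concat(
        [deletion_calls, pd.DataFrame(snp_rows)], ignore_index=True
    )
    scores = pd.concat(score_frames, ignore_index=True)

    # --- duplicate confirmation -------------------------------------------
    partner: Dict[str, str] = {}
    for a, b in duplicate_pairs(samples):
        partner[a] = b
        partner[b] = a
    pos = calls.set_index(["sample", "target"])["positive"]

    def _confirm(row) -> str:
        mate = partner.get(row["sample"])
        if row["positive"] and mate is not None:
            if not bool(pos.get((mate, row["target"]), False)):
                return ";".join(filter(None, [row["flags"], "unconfirmed"]))
        return row["flags"]

    calls["flags"] = calls.apply(_confirm, axis=1)

    flag_summary: Dict[str, List[str]] = {
        "unconfirmed_positives": [
            f"{r['sample']}:{r['target']}"
            for _, r in calls.iterrows()
            if "unconfirmed" in r["flags"]
        ],
        "kebab_inconsistent": sorted(
            set(
                r["sample"]
                for _, r in calls.iterrows()
                if "kebab_inconsistent" in r["flags"]
            )
        ),
        "zero_depth_samples": list(table.flagged_samples),
    }
    return CallResult(scores=scores, calls=calls, thresholds=thresholds,
                      flags=flag_summary)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _schema() -> dict:
    with resources.files("catd.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def validate_report(report: Mapping, schema: Optional[dict] = None) -> None:
    """Validate a run report against the shipped schema (a small subset of
    JSON Schema: ``type``, ``required``, ``properties``)."""

    def check(node, spec, path):
        expected = spec.get("type")
        if expected and not isinstance(node, _TYPES[expected]):
            raise ValueError(f"report{path}: expected {expected}")
        if isinstance(node, bool) and expected in ("integer", "number"):
            raise ValueError(f"report{path}: expected {expected}")
        for key in spec.get("required", []):
            if key not in node:
                raise ValueError(f"report{path}: missing key {key!r}")
        for key, sub in spec.get("properties", {}).items():
            if isinstance(node, dict) and key in node:
                check(node[key], sub, f"{path}.{key}")

    check(dict(report), schema or _schema(), "")


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if math.isnan(v) else v
    if isinstance(value, Path):
        return str(value)
    return value


def build_report(
    cohort_config: Optional[SimConfig],
    table: HeadcountTable,
    result: CallResult,
    samples: pd.DataFrame,
    rule: ThresholdRule,
    seed: int,
) -> dict:
    concordance = duplicate_concordance(table, duplicate_pairs(samples))
    n_targets = result.calls["target"].nunique()
    report = {
        "seed": int(seed),
        "n_samples": int(len(table.counts.index)),
        "n_targets": int(n_targets),
        "n_calls": int(len(result.calls)),
        "threshold_rule": dataclasses.asdict(rule),
        "thresholds": result.thresholds,
        "samples": {
            s: {
                "mapped": int(table.mapped_total[s]),
                "unmapped": int(table.unmapped_total[s]),
                "mapping_rate": float(
                    table.mapped_total[s]
                    / max(1, table.mapped_total[s] + table.unmapped_total[s])
                ),
            }
            for s in table.counts.index
        },
        "duplicate_concordance": {
            f"{a}|{b}": r for (a, b), r in concordance.items()
        },
        "flags": result.flags,
        "config": dataclasses.asdict(cohort_config) if cohort_config else {},
    }
    report = _jsonable(report)
    validate_report(report)
    return report


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """simulate -> count -> call configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    target_depth: int = TARGET_DEPTH
    rule: ThresholdRule = field(default_factory=ThresholdRule)
    maf_threshold: float = 0.05
    het_band: Tuple[float, float] = (0.2, 0.8)
    pseudocount: float = 1.0
    outdir: Optional[Path] = None
    write_fastq: bool = False
    #: keep every sample's read matrix on the result's cohort (memory heavy)
    keep_reads: bool = False


@dataclass
class PipelineResult:
    cohort: Cohort
    table: HeadcountTable
    scores: pd.DataFrame
    calls: pd.DataFrame
    report: dict

    @property
    def truth(self) -> pd.DataFrame:
        return self.cohort.truth_frame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate a cohort, count its reads, call genotypes, build the report.

    With ``config.outdir`` all stage outputs are written (counts/scores/calls
    TSV, report JSON, plus FASTQs and cohort inputs when ``write_fastq``).
    """
    outdir = Path(config.outdir) if config.outdir else None
    sample_counts = {}

    def _count_stream(cohort, sample_id, reads):
        sample_counts[sample_id] = count_read_array(
            reads, cohort.design.products
        )

    cohort = simulate_cohort(
        config.sim,
        outdir=outdir if config.write_fastq else None,
        keep_reads=config.keep_reads,
        on_reads=_count_stream,
    )
    table = HeadcountTable.from_sample_counts(sample_counts,
                                              cohort.design.products)
    table = normalize_depth(table, config.target_depth)
    result = call_cohort(
        table,
        cohort.samples,
        rule=config.rule,
        maf_threshold=config.maf_threshold,
        het_band=config.het_band,
        pseudocount=config.pseudocount,
    )
    report = build_report(
        config.sim, table, result, cohort.samples, config.rule, config.sim.seed
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_long().to_csv(outdir / "counts.tsv", sep="\t", index=False)
        result.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        result.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        cohort.truth_frame.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return PipelineResult(
        cohort=cohort,
        table=table,
        scores=result.scores,
        calls=result.calls,
        report=report,
    )


def false_negative_rate(calls: pd.DataFrame,
                        truth: pd.DataFrame) -> Tuple[float, int, int]:
    """(rate, n false negatives, n truth positives) over a call matrix.

    A false negative is a truth-positive (sample, target) pair whose call is
    negative.
    """
    merged = truth.merge(
        calls[["sample", "target", "positive"]],
        on=["sample", "target"],
        suffixes=("_truth", "_call"),
        how="left",
        validate="one_to_one",
    )
    if merged["positive_call"].isna().any():
        missing = merged[merged["positive_call"].isna()]
        raise ValueError(
            f"calls missing for {len(missing)} truth entries, e.g. "
            f"{missing.iloc[0][['sample', 'target']].tolist()}"
        )
    pos = merged[merged["positive_truth"]]
    n_pos = int(len(pos))
    fn = int((~pos["positive_call"].astype(bool)).sum())
    rate = fn / n_pos if n_pos else 0.0
    return rate, fn, n_pos
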