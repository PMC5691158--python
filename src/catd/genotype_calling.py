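"""Genotype scores and calls.

Deletion calling: a per-sample *headcount* (pooled normalized counts of one
probe kind for one target) is divided by the *standard weight* (mean headcount
of the wild-type control samples) to give a raw genotype score; tiling (Kebab)
probes report negatively, so their score is the inverse ratio.  Raw scores are
rescaled so the panel maximum is exactly 100, compared against a threshold,
and positive Cat-D / Kebab calls are combined into wt / het / hom genotypes.

Point-mutation calling: per-probe allele frequencies over the captured region
(read positions 21..67) are thresholded on the minor-allele fraction
(default 5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdRule",
    "allele_frequencies",
    "call_deletions",
    "call_point_mutation",
    "call_threshold",
    "raw_genotype_score",
    "scale_scores",
    "score_panel",
    "standard_weight",
]

logger = logging.getLogger(__name__)

#: 1-based read positions of the captured region used for allele frequencies.
CAPTURE_WINDOW = (21, 67)


def standard_weight(
    headcounts: pd.Series,
    wt_samples: Sequence[str],
    allow_single: bool = True,
) -> float:
    """Mean headcount over the designated wild-type control samples."""
    wt = [s for s in wt_samples if s in headcounts.index]
    if not wt:
        raise ValueError("no wild-type control samples with headcounts")
    values = headcounts.loc[wt].astype(float)
    if values.isna().any():
        raise ValueError(f"undefined headcounts among WT controls: {wt}")
    if len(wt) == 1:
        if not allow_single:
            raise ValueError("only one WT control sample designated")
        logger.warning("standard weight from a single WT control (%s)", wt[0])
    return float(values.mean())


def raw_genotype_score(
    headcount: float,
    w: float,
    kind: str,
    pseudocount: float = 1.0,
) -> float:
    """Raw genotype score: ``headcount / w`` for positively reporting (catd)
    probes, ``w / (headcount + pseudocount)`` for negatively reporting
    (kebab) probes.

    The pseudocount bounds the inverse score when a homozygous deletion
    leaves a true zero headcount.
    """
    if w <= 0:
        raise ValueError(f"standard weight must be positive, got {w}")
    if kind == "catd":
        return float(headcount) / w
    if kind == "kebab":
        return w / (float(headcount) + pseudocount)
    raise ValueError(f"raw genotype score undefined for kind {kind!r}")


def scale_scores(raw_scores: pd.Series) -> pd.Series:
    """Rescale so the panel maximum is exactly 100 (others proportional)."""
    raw = raw_scores.astype(float)
    if len(raw) == 0:
        raise ValueError("empty score vector")
    top = raw.max()
    if not top > 0:
        raise ValueError("all raw scores are zero; panel cannot be scaled")
    scaled = raw * (100.0 / top)
    # the top-scoring sample is 100 by definition, not by float rounding
    scaled[raw == top] = 100.0
    return scaled


@dataclass(frozen=True)
class ThresholdRule:
    """Configurable genotype-call threshold.

    * ``fold`` (default): positive when the raw score exceeds ``fold`` times
      the wild-type baseline, i.e. scaled threshold = ``fold * 100 / max(raw)``.
    * ``midpoint``: midway between the highest WT scaled score and the lowest
      scaled score among ``known_positives`` (falls back to ``mean_sd`` when
      none are supplied).
    * ``mean_sd``: mean + k * SD of the WT scaled scores.
    """

    kind: str = "fold"
    fold: float = 10.0
    k: float = 5.0
    known_positives: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("fold", "midpoint", "mean_sd"):
            raise ValueError(f"unknown threshold rule {self.kind!r}")


def call_threshold(
    scaled_scores: pd.Series,
    wt_samples: Sequence[str],
    rule: ThresholdRule = ThresholdRule(),
    raw_scores: Optional[pd.Series] = None,
) -> float:
    """Threshold on the scaled (max-100) score scale under ``rule``."""
    wt = [s for s in wt_samples if s in scaled_scores.index]
    if not wt:
        raise ValueError("no WT control samples among scored samples")
    wt_scaled = scaled_scores.loc[wt].astype(float)
    if wt_scaled.isna().any():
        raise ValueError("undefined scaled scores among WT controls")

    if rule.kind == "midpoint" and rule.known_positives:
        pos = [s for s in rule.known_positives if s in scaled_scores.index]
        if not pos:
            raise ValueError("known positives not found among scored samples")
        return float((wt_scaled.max() + scaled_scores.loc[pos].min()) / 2.0)
    if rule.kind == "fold":
        if raw_scores is None:
            raise ValueError("fold rule needs the raw score vector")
        top = float(raw_scores.max())
        if not top > 0:
            raise ValueError("all raw scores zero; threshold undefined")
        return rule.fold * 100.0 / top
    # mean_sd (also the midpoint fallback)
    sd = float(wt_scaled.std(ddof=1)) if len(wt_scaled) > 1 else 0.0
    return float(wt_scaled.mean()) + rule.k * sd


def score_panel(
    headcounts: pd.Series,
    wt_samples: Sequence[str],
    kind: str,
    rule: ThresholdRule = ThresholdRule(),
    pseudocount: float = 1.0,
    min_weight: float = 1.0,
) -> pd.DataFrame:
    """Score one target panel across samples and call the positives.

    Returns a frame indexed by sample with columns ``headcount``,
    ``standard_weight``, ``raw_score``, ``scaled_score``, ``threshold``,
    ``call`` and ``flags``.  A zero standard weight (possible for Cat-D
    panels when controls carry no background) is floored at ``min_weight``
    normalized reads and flagged.
    """
    flags = ""
    w = standard_weight(headcounts, wt_samples)
    if w <= 0:
        if kind == "kebab":
            raise ValueError("kebab standard weight is zero; controls empty?")
        w = min_weight
        flags = "zero_standard_weight"
        logger.warning("standard weight floored at %g normalized reads", w)
    raw = headcounts.astype(float).map(
        lambda h: raw_genotype_score(h, w, kind, pseudocount)
    )
    scaled = scale_scores(raw)
    threshold = call_threshold(scaled, wt_samples, rule, raw_scores=raw)
    out = pd.DataFrame(
        {
            "headcount": headcounts.astype(float),
            "standard_weight": w,
            "raw_score": raw,
            "scaled_score": scaled,
            "threshold": threshold,
            "call": np.where(scaled > threshold, "positive", "negative"),
            "flags": flags,
        }
    )
    out.index.name = "sample"
    return out


def call_deletions(
    catd_calls: Mapping[str, pd.Series],
    kebab_call: pd.Series,
) -> pd.DataFrame:
    """Combine per-deletion Cat-D calls with the shared Kebab call.

    ``catd_calls`` maps deletion name -> per-sample boolean (Cat-D positive);
    ``kebab_call`` is the per-sample boolean of the shared tiling panel
    (positive = no wild-type copy of the commonly deleted region).

    Genotype logic per sample: a positive Cat-D call marks a deletion allele;
    Kebab positivity upgrades a single Cat-D positive to homozygous, while
    two Cat-D positives with Kebab positive form a compound heterozygote.
    Kebab positive with no Cat-D positive is flagged inconsistent.
    """
    deletions = list(catd_calls)
    samples = kebab_call.index
    rows = []
    for sample in samples:
        pos = [d for d in deletions if bool(catd_calls[d].loc[sample])]
        kebab_pos = bool(kebab_call.loc[sample])
        flags = ""
        if not kebab_pos:
            genotype = {d: ("het" if d in pos else "wt") for d in deletions}
        elif len(pos) == 1:
            genotype = {d: ("hom" if d in pos else "wt") for d in deletions}
        elif len(pos) >= 2:
            genotype = {d: ("het" if d in pos else "wt") for d in deletions}
            flags = "compound_het"
        else:
            genotype = {d: "wt" for d in deletions}
            flags = "kebab_inconsistent"
        for d in deletions:
            rows.append(
                {
                    "sample": sample,
                    "target": d,
                    "genotype": genotype[d],
                    "positive": genotype[d] != "wt",
                    "flags": flags,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Point mutations
# ---------------------------------------------------------------------------


def allele_frequencies(
    product_counts: pd.Series,
    product_keys: Mapping[str, str],
    window: Tuple[int, int] = CAPTURE_WINDOW,
) -> pd.DataFrame:
    """Per-position A/C/G/T frequencies over one probe's matched reads.

    ``product_counts`` maps product name -> mapped reads; ``product_keys``
    maps product name -> match key.  Because matching is exact, every read
    assigned to a product carries that product's bases, so frequencies are
    count-weighted product bases.  Returns a frame indexed by 1-based read
    position (``window``) with columns A/C/G/T and ``depth``.
    """
    depth = float(product_counts.sum())
    if depth <= 0:
        raise ValueError("zero depth: allele frequencies undefined")
    lo, hi = window
    positions = range(lo, hi + 1)
    freq = pd.DataFrame(
        0.0, index=pd.Index(positions, name="read_pos"), columns=list("ACGT")
    )
    for product, count in product_counts.items():
        if count == 0:
            continue
        key = product_keys[product]
        for pos in positions:
            base = key[pos - 1]
            if base in "ACGT":
                freq.at[pos, base] += count
    freq = freq / depth
    freq["depth"] = depth
    return freq


def call_point_mutation(
    freqs: pd.DataFrame,
    snp_read_pos: int,
    alt_base: str,
    maf_threshold: float = 0.05,
    het_band: Tuple[float, float] = (0.2, 0.8),
) -> Tuple[bool, float, str]:
    """Call a point mutation from an allele-frequency matrix.

    Positive iff the alternate-base frequency at the variant's read position
    is strictly greater than ``maf_threshold``.  Returns
    ``(positive, alt_fraction, genotype_label)`` with the label derived from
    ``het_band``: het inside the band, hom above it, ``lowfrac`` for a
    positive below it, ``ref`` when negative.
    """
    lo, hi = CAPTURE_WINDOW
    if not (lo <= snp_read_pos <= hi):
        raise ValueError(
            f"variant read position {snp_read_pos} outside captured "
            f"window {lo}..{hi}"
        )
    alt_fraction = float(freqs.at[snp_read_pos, alt_base])
    positive = alt_fraction > maf_threshold
    if not positive:
        label = "ref"
    elif alt_fraction > het_band[1]:
        label = "hom"
    elif alt_fraction >= het_band[0]:
        label = "het"
    else:
        label = "lowfrac"
    return positive, alt_fraction, label


def snp_alt_fraction(
    product_counts: pd.Series,
    product_meta: pd.DataFrame,
    probe_name: str,
    snp_name: str,
) -> Tuple[float, float]:
    """Alternate-allele fraction for one variant from allele-product counts.

    Denominator: all mapped reads of the probe; numerator: reads matching the
    variant's alt product.  Returns ``(alt_fraction, depth)``; fraction is
    NaN at zero depth.
    """
    meta = product_meta[product_meta["probe"] == probe_name]
    if meta.empty:
        raise KeyError(f"no products for probe {probe_name!r}")
    total = float(product_counts.reindex(meta.index).sum())
    alt_rows = meta[(meta["allele"] == "alt") & (meta["target"] == snp_name)]
    if alt_rows.empty:
        raise KeyError(f"probe {probe_name!r} has no alt product for {snp_name!r}")
    if total <= 0:
        return float("nan"), 0.0
    alt = float(product_counts.reindex(alt_rows.index).sum())
    return alt / total, total
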