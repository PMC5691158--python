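"""Expected capture products and exact-match read counting.

A sequencing read is assigned to a capture product when its first
``KEY_LENGTH`` (88) nucleotides equal the product's match key exactly; any
mismatch inside the key, or a read shorter than the key, leaves the read
unmapped.  There is no fuzzy matching and no alignment.  Counts are
depth-normalized to a fixed per-sample total (default 200,000 reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from catd.probe_design import ProbeLibrary, TargetSNP

__all__ = [
    "KEY_LENGTH",
    "ExpectedProduct",
    "HeadcountTable",
    "build_expected_products",
    "count_read_array",
    "count_reads",
    "headcount_by_target",
    "normalize_depth",
]

logger = logging.getLogger(__name__)

#: Number of leading read bases compared against each expected product.
KEY_LENGTH = 88

#: Default per-sample normalization depth.
TARGET_DEPTH = 200_000


@dataclass(frozen=True)
class ExpectedProduct:
    """Reference sequence of one probe's capture product (one per allele for
    SNP probes)."""

    name: str
    probe_name: str
    kind: str
    target: str
    allele_label: str  # "NA" for catd/kebab, "ref"/"alt" for snp probes
    match_key: str
    full_product: str

    def __post_init__(self) -> None:
        if len(self.match_key) != KEY_LENGTH:
            raise ValueError(
                f"{self.name}: match key is {len(self.match_key)} nt, "
                f"expected {KEY_LENGTH}"
            )
        if not self.full_product.startswith(self.match_key):
            raise ValueError(f"{self.name}: match key is not a product prefix")


def _product_meta(products: Sequence[ExpectedProduct]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "product": [p.name for p in products],
            "probe": [p.probe_name for p in products],
            "kind": [p.kind for p in products],
            "target": [p.target for p in products],
            "allele": [p.allele_label for p in products],
            "match_key": [p.match_key for p in products],
        }
    ).set_index("product")


def build_expected_products(
    library: ProbeLibrary,
    reference: Mapping[str, str],
    snps: Sequence[TargetSNP] = (),
    key_length: int = KEY_LENGTH,
) -> List[ExpectedProduct]:
    """Expected read sequence per probe (per allele for SNP probes).

    The read layout is ``ligation arm + captured gap + extension arm +
    linker``; for SNP probes one product is built per allele by substituting
    the variant base(s) inside the gap.  Match keys must be unique across the
    returned list; duplicates are a hard error because counting would be
    ill-defined.
    """
    snp_by_name = {s.name: s for s in snps}
    products: List[ExpectedProduct] = []
    for probe in library.probes:
        if probe.chrom not in reference:
            raise KeyError(f"{probe.name}: template {probe.chrom!r} not in reference")
        chrom_seq = reference[probe.chrom]
        if probe.arm_end > len(chrom_seq) or probe.arm_start < 0:
            raise ValueError(f"{probe.name}: capture interval off reference")
        core = chrom_seq[probe.arm_start:probe.arm_end]
        if not core.startswith(probe.ligation_arm) or not core.endswith(
            probe.extension_arm
        ):
            raise ValueError(f"{probe.name}: arms do not match template")
        full = core + probe.linker
        if len(full) < key_length:
            raise ValueError(
                f"{probe.name}: expected product ({len(full)} nt) shorter "
                f"than the {key_length} nt match key"
            )
        if probe.kind != "snp":
            products.append(
                ExpectedProduct(
                    name=probe.name,
                    probe_name=probe.name,
                    kind=probe.kind,
                    target=probe.target,
                    allele_label="NA",
                    match_key=full[:key_length],
                    full_product=full,
                )
            )
            continue
        # SNP probe: reference product plus one alt product per variant.
        products.append(
            ExpectedProduct(
                name=f"{probe.name}:ref",
                probe_name=probe.name,
                kind="snp",
                target=probe.target,
                allele_label="ref",
                match_key=full[:key_length],
                full_product=full,
            )
        )
        for target in probe.targets:
            snp = snp_by_name.get(target)
            if snp is None:
                raise KeyError(f"{probe.name}: unknown variant {target!r}")
            offset = len(probe.ligation_arm) + (snp.pos - probe.capture_interval[0])
            if full[offset:offset + len(snp.ref_allele)] != snp.ref_allele:
                raise ValueError(
                    f"{probe.name}: ref allele of {snp.name} absent from product"
                )
            alt_full = (
                full[:offset] + snp.alt_allele
                + full[offset + len(snp.ref_allele):]
            )
            if len(alt_full) < key_length:
                raise ValueError(f"{probe.name}: alt product shorter than key")
            products.append(
                ExpectedProduct(
                    name=f"{probe.name}:alt:{snp.name}",
                    probe_name=probe.name,
                    kind="snp",
                    target=snp.name,
                    allele_label="alt",
                    match_key=alt_full[:key_length],
                    full_product=alt_full,
                )
            )
    keys = [p.match_key for p in products]
    if len(set(keys)) != len(keys):
        seen: Dict[str, str] = {}
        for p in products:
            if p.match_key in seen:
                raise ValueError(
                    f"duplicate match key between {seen[p.match_key]} and {p.name}"
                )
            seen[p.match_key] = p.name
    return products


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _key_index(products: Sequence[ExpectedProduct],
               as_bytes: bool = False) -> Dict:
    index: Dict = {}
    for i, p in enumerate(products):
        key = p.match_key.encode() if as_bytes else p.match_key
        if key in index:
            raise ValueError(f"duplicate match key on {p.name}")
        index[key] = i
    return index


def count_reads(
    reads: Iterable, products: Sequence[ExpectedProduct]
) -> Tuple[np.ndarray, int, int]:
    """Count reads by exact match of the first ``KEY_LENGTH`` nt.

    ``reads`` yields sequences (str or bytes).  Returns
    ``(counts, mapped_total, unmapped_total)`` with one count per product.
    """
    index = _key_index(products)
    counts = np.zeros(len(products), dtype=np.int64)
    mapped = unmapped = 0
    for read in reads:
        if isinstance(read, (bytes, bytearray)):
            read = read.decode()
        hit = index.get(read[:KEY_LENGTH]) if len(read) >= KEY_LENGTH else None
        if hit is None:
            unmapped += 1
        else:
            counts[hit] += 1
            mapped += 1
    return counts, mapped, unmapped


def count_read_array(
    reads: np.ndarray, products: Sequence[ExpectedProduct]
) -> Tuple[np.ndarray, int, int]:
    """:func:`count_reads` for a (n_reads, read_length) uint8 ASCII matrix."""
    if reads.ndim != 2 or reads.dtype != np.uint8:
        raise ValueError("expected a 2-D uint8 ASCII read matrix")
    n, length = reads.shape
    counts = np.zeros(len(products), dtype=np.int64)
    if length < KEY_LENGTH:
        return counts, 0, n
    index = _key_index(products, as_bytes=True)
    blob = np.ascontiguousarray(reads).tobytes()
    mapped = 0
    get = index.get
    for i in range(n):
        start = i * length
        hit = get(blob[start:start + KEY_LENGTH])
        if hit is not None:
            counts[hit] += 1
            mapped += 1
    return counts, mapped, n - mapped


# ---------------------------------------------------------------------------
# Headcount table
# ---------------------------------------------------------------------------


@dataclass
class HeadcountTable:
    """Per-sample, per-product read counts, raw and depth-normalized.

    ``counts`` is samples x products; ``normalized`` (same shape) exists after
    :func:`normalize_depth`.  ``product_meta`` carries probe/kind/target/
    allele/match-key annotations indexed by product name.
    """

    counts: pd.DataFrame
    mapped_total: pd.Series
    unmapped_total: pd.Series
    product_meta: pd.DataFrame
    normalized: Optional[pd.DataFrame] = None
    target_depth: int = TARGET_DEPTH
    flagged_samples: List[str] = field(default_factory=list)

    @classmethod
    def from_sample_counts(
        cls,
        sample_counts: Mapping[str, Tuple[np.ndarray, int, int]],
        products: Sequence[ExpectedProduct],
    ) -> "HeadcountTable":
        names = [p.name for p in products]
        counts = pd.DataFrame(
            {s: c for s, (c, _, _) in sample_counts.items()},
            index=names,
        ).T
        mapped = pd.Series({s: m for s, (_, m, _) in sample_counts.items()})
        unmapped = pd.Series({s: u for s, (_, _, u) in sample_counts.items()})
        return cls(
            counts=counts,
            mapped_total=mapped,
            unmapped_total=unmapped,
            product_meta=_product_meta(products),
        )

    @property
    def samples(self) -> List[str]:
        return list(self.counts.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (sample, product, annotations, counts)."""
        long = (
            self.counts.stack().rename("raw_count").reset_index()
        )
        long.columns = ["sample", "product", "raw_count"]
        if self.normalized is not None:
            norm = self.normalized.stack().rename("normalized_count")
            norm.index.names = ["sample", "product"]
            long = long.merge(norm.reset_index(), on=["sample", "product"],
                              how="left")
        meta = self.product_meta.reset_index()
        return long.merge(meta, on="product", how="left")


def normalize_depth(table: HeadcountTable,
                    target_depth: int = TARGET_DEPTH) -> HeadcountTable:
    """Scale each sample's counts so they sum to ``target_depth``.

    Samples with zero mapped reads cannot be normalized: their rows become
    NaN, they are recorded in ``flagged_samples`` and a warning is logged.
    """
    totals = table.mapped_total.reindex(table.counts.index).astype(float)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        logger.warning(
            "samples with zero mapped reads excluded from normalization: %s",
            ", ".join(zero),
        )
    factors = target_depth / totals.where(totals > 0)
    normalized = table.counts.mul(factors, axis=0)
    return replace(
        table,
        normalized=normalized,
        target_depth=target_depth,
        flagged_samples=zero,
    )


def headcount_by_target(
    table: HeadcountTable,
    library: ProbeLibrary,
    target: str,
    kind: str,
) -> pd.Series:
    """Pooled normalized count over all ``kind`` probes of ``target``.

    This is the per-sample headcount entering the genotype score: e.g. the
    sum over all Cat-D products of one deletion.
    """
    if table.normalized is None:
        raise ValueError("normalize_depth must run before pooling headcounts")
    probe_names = {
        p.name for p in library.probes if p.kind == kind and target in p.targets
    }
    if not probe_names:
        raise KeyError(f"no {kind} probes target {target!r}")
    meta = table.product_meta
    cols = meta.index[meta["probe"].isin(probe_names)]
    return table.normalized[cols].sum(axis=1)
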