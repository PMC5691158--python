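"""Padlock-probe design.

Three probe classes are supported:

* **Cat-D** probes anchor their extension arm in an artificial adapter carried
  on one primer of a deletion-spanning pre-amplification, so capture succeeds
  only when the deletion allele amplified.  The ligation arm lands a few bases
  downstream of the primer's 3' end, which forces the captured region across
  the adapter/genomic junction and rejects nonspecific-priming noise.
* **Kebab** probes tile the interval that is deleted in every mutant allele;
  loss of their products marks a homozygous deletion.
* **SNP** probes straddle one or more small mutations so that the variant
  base is read inside the captured gap, never hybridized over by an arm.

Coordinate convention: 0-based, half-open, on the *capture-product strand* of
the template the probe was designed against (the genome plus strand for Kebab
and SNP probes; the reverse complement of ``adapter + downstream context`` for
Cat-D probes).  Arm sequences are stored in read orientation, i.e. the
expected sequencing read starts with the ligation arm verbatim.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "DEFAULT_LINKER",
    "Adapter",
    "DesignError",
    "PadlockProbe",
    "ProbeLibrary",
    "TargetDeletion",
    "TargetSNP",
    "TmParams",
    "catd_capture_template",
    "design_adapter",
    "design_catd_probe_set",
    "design_kebab_tiling",
    "design_snp_probe",
    "design_snp_probes",
    "melting_temperature",
    "reverse_complement",
    "self_complementarity_screen",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

#: Common probe backbone joining the two arms.  The real backbone sequence is
#: a synthesis/primer-binding constant; any fixed sequence works for analysis,
#: it only fills the read tail beyond the captured region.  60 nt keeps every
#: expected product at least 100 nt long.
DEFAULT_LINKER = (
    "TTCAGACGTGTGCTCTTCCGATCTGGAACGTGATCCGAAGGCTTAGCTAGTCCGTTAGCA"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_RC)[::-1]


class DesignError(ValueError):
    """A probe/adapter design constraint could not be satisfied."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetDeletion:
    """A large deletion with flexible boundaries.

    ``flank5_end``/``flank3_start`` bound the maximal known extent of the
    deletion; ``commonly_deleted`` is the sub-interval removed by every known
    mutant allele (where tiling probes may sit).
    """

    name: str
    chrom: str
    flank5_end: int
    flank3_start: int
    commonly_deleted: Tuple[int, int]

    def __post_init__(self) -> None:
        c0, c1 = self.commonly_deleted
        if not (self.flank5_end <= c0 < c1 <= self.flank3_start):
            raise ValueError(
                f"{self.name}: commonly_deleted {self.commonly_deleted} not "
                f"within [{self.flank5_end}, {self.flank3_start})"
            )
        if self.flank3_start - self.flank5_end < 1000:
            raise ValueError(
                f"{self.name}: extent {self.flank3_start - self.flank5_end} nt "
                "is below the large-deletion regime (>= 1000 nt)"
            )


@dataclass(frozen=True)
class TargetSNP:
    """A small mutation: a substitution or a short (<= 3 nt) indel."""

    name: str
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or len(allele) > 3 or set(allele) - set("ACGT"):
                raise ValueError(f"{self.name}: bad allele {allele!r}")


@dataclass(frozen=True)
class Adapter:
    """Artificial pre-amplification adapter, absent from the reference."""

    name: str
    sequence: str
    linked_primer: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 20:
            raise ValueError(
                f"adapter {self.name}: {len(self.sequence)} nt < 20 nt minimum"
            )


@dataclass(frozen=True)
class PadlockProbe:
    """One padlock probe, with capture geometry on its design template.

    The expected capture product (in read orientation) is the contiguous
    template slice ``[arm_start, arm_end)`` followed by the linker:
    ``ligation_arm + captured gap + extension_arm + linker``.
    """

    name: str
    kind: str  # catd | kebab | snp
    extension_arm: str
    ligation_arm: str
    linker: str
    target: str
    chrom: str
    arm_start: int
    capture_interval: Tuple[int, int]
    arm_end: int
    adapter: str = ""
    secondary_targets: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("catd", "kebab", "snp"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        g0, g1 = self.capture_interval
        if not (self.arm_start + len(self.ligation_arm) == g0 <= g1
                and g1 + len(self.extension_arm) == self.arm_end):
            raise ValueError(f"{self.name}: inconsistent capture geometry")
        if min(len(self.extension_arm), len(self.ligation_arm)) < 20:
            raise ValueError(f"{self.name}: arm shorter than 20 nt")

    @property
    def targets(self) -> Tuple[str, ...]:
        return (self.target, *self.secondary_targets)


@dataclass
class ProbeLibrary:
    probes: List[PadlockProbe] = field(default_factory=list)
    adapters: List[Adapter] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate probe names: {sorted(dupes)}")
        adapter_names = {a.name for a in self.adapters}
        for p in self.probes:
            if p.kind == "catd" and p.adapter not in adapter_names:
                raise ValueError(f"{p.name}: adapter {p.adapter!r} not in library")

    @property
    def composition(self) -> Dict[str, int]:
        out: Dict[str, int] = {"catd": 0, "kebab": 0, "snp": 0}
        for p in self.probes:
            out[p.kind] += 1
        return out

    def by_kind(self, kind: str) -> List[PadlockProbe]:
        return [p for p in self.probes if p.kind == kind]


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TmParams:
    """Nearest-neighbor melting-temperature settings.

    Unified nearest-neighbor parameters, 50 mM monovalent salt, 250 nM oligo;
    arms are tuned toward ``target`` and accepted within ``tolerance``.
    """

    target: float = 55.0
    tolerance: float = 3.0
    na_mM: float = 50.0
    oligo_nM: float = 250.0
    min_arm: int = 20
    max_arm: int = 36


def melting_temperature(seq: str, tm_params: TmParams = TmParams()) -> float:
    """Nearest-neighbor Tm (degrees C) of ``seq`` under ``tm_params``."""
    if len(seq) < 8:
        raise ValueError(f"sequence too short for Tm ({len(seq)} nt < 8)")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {seq!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=tm_params.na_mM,
            dnac1=tm_params.oligo_nM,
            dnac2=tm_params.oligo_nM,
        )
    )


def _fit_arm(
    template: str,
    anchor: int,
    side: str,
    tm_params: TmParams,
    max_len: Optional[int] = None,
) -> Optional[str]:
    """Best-Tm arm anchored at ``anchor``, growing left or right.

    ``side='left'`` returns ``template[anchor-L:anchor]``, ``side='right'``
    returns ``template[anchor:anchor+L]`` for the length L in
    ``[min_arm, max_len]`` whose Tm is closest to target; None if no length
    lands within tolerance.
    """
    candidates = _fit_arm_candidates(template, anchor, side, tm_params, max_len)
    return candidates[0] if candidates else None


def _fit_arm_candidates(
    template: str,
    anchor: int,
    side: str,
    tm_params: TmParams,
    max_len: Optional[int] = None,
) -> List[str]:
    """All in-tolerance arms anchored at ``anchor``, best Tm first."""
    limit = min(max_len or tm_params.max_arm, tm_params.max_arm)
    acceptable: List[Tuple[float, str]] = []
    for length in range(tm_params.min_arm, limit + 1):
        if side == "left":
            lo, hi = anchor - length, anchor
        else:
            lo, hi = anchor, anchor + length
        if lo < 0 or hi > len(template):
            break
        arm = template[lo:hi]
        if set(arm) - set("ACGT"):
            return []
        tm = melting_temperature(arm, tm_params)
        dev = abs(tm - tm_params.target)
        if dev <= tm_params.tolerance:
            acceptable.append((dev, arm))
        if tm > tm_params.target + tm_params.tolerance:
            break  # extension only raises Tm further
    acceptable.sort(key=lambda pair: pair[0])
    return [arm for _, arm in acceptable]


# ---------------------------------------------------------------------------
# Adapter design
# ---------------------------------------------------------------------------


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlap-aware exact substring count."""
    n, start = 0, haystack.find(needle)
    while start != -1:
        n += 1
        start = haystack.find(needle, start + 1)
    return n


def _occurrences_in_reference(reference: Mapping[str, str], seq: str) -> int:
    rc = reverse_complement(seq)
    total = 0
    for chrom_seq in reference.values():
        total += _count_occurrences(chrom_seq, seq)
        total += _count_occurrences(chrom_seq, rc)
    return total


def _max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def design_adapter(
    reference: Mapping[str, str],
    length: int = 28,
    rng_seed: int = 0,
    name: str = "adapter",
    linked_primer: str = "",
    gc_range: Tuple[float, float] = (0.4, 0.6),
    max_homopolymer: int = 4,
    max_attempts: int = 10_000,
    tm_params: Optional[TmParams] = None,
) -> Adapter:
    """Rejection-sample an adapter absent from ``reference``.

    The adapter (and its reverse complement) must have zero exact occurrences
    in the reference, GC fraction within ``gc_range`` and no homopolymer run
    longer than ``max_homopolymer``.  When ``tm_params`` is given, at least
    one adapter suffix of >= ``min_arm`` nt must melt within tolerance of the
    arm target, so that a Cat-D extension arm can later be carved from it.
    """
    if length < 20:
        raise DesignError(f"adapter length {length} < 20 nt minimum")
    if not reference:
        raise DesignError("empty reference")
    rng = np.random.default_rng(rng_seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for _ in range(max_attempts):
        cand = b"".join(rng.choice(bases, size=length)).decode()
        gc = (cand.count("G") + cand.count("C")) / length
        if not (gc_range[0] <= gc <= gc_range[1]):
            continue
        if _max_homopolymer(cand) > max_homopolymer:
            continue
        if tm_params is not None:
            rc = reverse_complement(cand)
            if _fit_arm(rc, 0, "right", tm_params, max_len=length) is None:
                continue
        if _occurrences_in_reference(reference, cand) == 0:
            return Adapter(name=name, sequence=cand, linked_primer=linked_primer)
    raise DesignError(
        f"no adapter of length {length} found in {max_attempts} attempts "
        "(reference too dense or length too short)"
    )


# ---------------------------------------------------------------------------
# Cat-D probes
# ---------------------------------------------------------------------------


def catd_capture_template(adapter: Adapter, primer_3prime_context: str) -> str:
    """Capture-strand template of the adapter-tagged amplicon.

    The amplicon top strand reads ``adapter + downstream genomic context``;
    padlock capture is strand specific and Cat-D probes read the bottom
    strand, so the template (and hence the sequencing read) is the reverse
    complement: genomic context first, adapter-derived sequence after the
    junction.
    """
    return reverse_complement(adapter.sequence + primer_3prime_context)


def design_catd_probe_set(
    adapter: Adapter,
    primer_3prime_context: str,
    n_probes: int,
    tm_params: TmParams = TmParams(),
    target: str = "deletion",
    template_id: Optional[str] = None,
    linker: str = DEFAULT_LINKER,
    max_lig_offset: int = 30,
) -> List[PadlockProbe]:
    """Design ``n_probes`` Cat-D probes against one adapter-tagged amplicon.

    Every extension arm is the reverse complement of an adapter suffix and
    every ligation arm matches amplicon sequence starting at most
    ``max_lig_offset`` nt downstream of the primer 3' end; the captured gap
    therefore spans the adapter/genomic junction.  Probes are staggered by
    ligation-arm start offset.  Probe coordinates refer to
    :func:`catd_capture_template` of (adapter, context).
    """
    if len(primer_3prime_context) < 100:
        raise DesignError(
            f"primer context too short ({len(primer_3prime_context)} nt < 100)"
        )
    if n_probes == 0:
        return []
    template = catd_capture_template(adapter, primer_3prime_context)
    template_id = template_id or f"{target}_catd_template"
    junction = len(primer_3prime_context)  # adapter-derived sequence starts here

    ext_arm = _fit_arm(template, junction, "right", tm_params,
                       max_len=len(adapter.sequence))
    if ext_arm is None:
        raise DesignError(
            f"{target}: no adapter suffix melts within "
            f"{tm_params.tolerance} degC of {tm_params.target} degC"
        )

    probes: List[PadlockProbe] = []
    used_offsets: set = set()
    offset = 0
    while len(probes) < n_probes:
        if offset > max_lig_offset:
            raise DesignError(
                f"{target}: could not place {n_probes} Cat-D probes within "
                f"ligation offset {max_lig_offset}"
            )
        if offset not in used_offsets:
            gap_start = junction - offset
            # distinct capture products require distinct ligation-arm starts:
            # the product reads through lig arm + gap contiguously, so only
            # arm_start (not the gap split) shapes the sequence
            used_starts = {p.arm_start for p in probes}
            lig_arm = next(
                (
                    arm
                    for arm in _fit_arm_candidates(
                        template, gap_start, "left", tm_params
                    )
                    if gap_start - len(arm) not in used_starts
                ),
                None,
            )
            if lig_arm is not None:
                used_offsets.add(offset)
                i = len(probes) + 1
                probes.append(
                    PadlockProbe(
                        name=f"{target}_catd_{i:02d}",
                        kind="catd",
                        extension_arm=ext_arm,
                        ligation_arm=lig_arm,
                        linker=linker,
                        target=target,
                        chrom=template_id,
                        arm_start=gap_start - len(lig_arm),
                        capture_interval=(gap_start, junction),
                        arm_end=junction + len(ext_arm),
                        adapter=adapter.name,
                    )
                )
        offset += 1
    return probes


# ---------------------------------------------------------------------------
# Kebab probes
# ---------------------------------------------------------------------------


def design_kebab_tiling(
    deletion: TargetDeletion,
    reference: Mapping[str, str],
    n_probes: int,
    tm_params: TmParams = TmParams(),
    gap_length: int = 47,
    linker: str = DEFAULT_LINKER,
    require_unique_arms: bool = True,
) -> List[PadlockProbe]:
    """Tile ``n_probes`` probes across the commonly deleted interval.

    Capture intervals lie entirely inside ``deletion.commonly_deleted`` and
    are pairwise disjoint; with ``require_unique_arms`` every arm occurs
    exactly once in the reference (both strands scanned), a stand-in for
    avoiding repetitive DNA.
    """
    if n_probes == 0:
        return []
    chrom_seq = reference[deletion.chrom]
    c0, c1 = deletion.commonly_deleted
    footprint = gap_length + 2 * tm_params.min_arm
    if c1 - c0 < n_probes * footprint:
        raise DesignError(
            f"{deletion.name}: commonly deleted interval ({c1 - c0} nt) too "
            f"small for {n_probes} probes"
        )
    slot = (c1 - c0) // n_probes
    probes: List[PadlockProbe] = []
    prev_end = c0
    for i in range(n_probes):
        slot_lo = max(c0 + i * slot, prev_end)
        slot_hi = c0 + (i + 1) * slot if i < n_probes - 1 else c1
        placed = None
        for g0 in range(slot_lo, slot_hi - gap_length + 1, 3):
            g1 = g0 + gap_length
            lig_arm = _fit_arm(chrom_seq, g0, "left", tm_params)
            ext_arm = _fit_arm(chrom_seq, g1, "right", tm_params)
            if lig_arm is None or ext_arm is None:
                continue
            if require_unique_arms and any(
                _occurrences_in_reference(reference, arm) != 1
                for arm in (lig_arm, ext_arm)
            ):
                continue
            placed = (g0, g1, lig_arm, ext_arm)
            break
        if placed is None:
            raise DesignError(
                f"{deletion.name}: no placement for Kebab probe {i + 1} in "
                f"[{slot_lo}, {slot_hi})"
            )
        g0, g1, lig_arm, ext_arm = placed
        prev_end = g1
        probes.append(
            PadlockProbe(
                name=f"{deletion.name}_kebab_{i + 1:02d}",
                kind="kebab",
                extension_arm=ext_arm,
                ligation_arm=lig_arm,
                linker=linker,
                target=deletion.name,
                chrom=deletion.chrom,
                arm_start=g0 - len(lig_arm),
                capture_interval=(g0, g1),
                arm_end=g1 + len(ext_arm),
            )
        )
    return probes


# ---------------------------------------------------------------------------
# SNP probes
# ---------------------------------------------------------------------------

# The captured gap is read starting at position (lig_arm_len + 1) of the
# product; placements are accepted only when every variant lands in read
# positions 21..67, the window the allele-frequency caller inspects.
_SNP_GAP = 47  # nominal gap length; the designer may vary it by a few nt
_SNP_WINDOW = 24  # max span of variants sharing one probe


def design_snp_probe(
    snp: TargetSNP,
    reference: Mapping[str, str],
    tm_params: TmParams = TmParams(),
    extra_snps: Sequence[TargetSNP] = (),
    linker: str = DEFAULT_LINKER,
    name: Optional[str] = None,
) -> PadlockProbe:
    """Design one probe reading ``snp`` (plus any ``extra_snps``) in its gap.

    The variant position(s) fall strictly inside the captured gap, within
    read positions 21..67, so the variant base is sequenced rather than
    hybridized over.
    """
    snps = sorted((snp, *extra_snps), key=lambda s: s.pos)
    chrom_seq = reference[snp.chrom]
    if any(s.chrom != snp.chrom for s in snps):
        raise DesignError(f"{snp.name}: grouped variants on different contigs")
    pmin, pmax = snps[0].pos, snps[-1].pos
    span = pmax - pmin
    if span > _SNP_WINDOW:
        raise DesignError(
            f"{snp.name}: grouped variants span {span} nt > {_SNP_WINDOW}"
        )
    if pmin < 100 or pmax + 100 > len(chrom_seq):
        raise DesignError(f"{snp.name}: needs >= 100 nt flank on both sides")
    for s in snps:
        if chrom_seq[s.pos:s.pos + len(s.ref_allele)] != s.ref_allele:
            raise DesignError(
                f"{s.name}: ref allele {s.ref_allele!r} does not match "
                f"reference at {s.chrom}:{s.pos}"
            )

    probe = None
    shifts = sorted(range(-18, 19), key=abs)
    gap_lengths = sorted(range(_SNP_GAP - 6, _SNP_GAP + 7), key=lambda g: abs(g - _SNP_GAP))
    for shift in shifts:
        g0 = pmin - (_SNP_GAP - span) // 2 + shift
        if not g0 < pmin:
            continue
        lig_arm = _fit_arm(chrom_seq, g0, "left", tm_params)
        if lig_arm is None:
            continue
        read_pos = [len(lig_arm) + (s.pos - g0) + 1 for s in snps]  # 1-based
        if not all(21 <= rp <= 67 for rp in read_pos):
            continue
        for gap in gap_lengths:
            g1 = g0 + gap
            if pmax + 3 > g1:
                continue
            ext_arm = _fit_arm(chrom_seq, g1, "right", tm_params)
            if ext_arm is not None:
                probe = (g0, g1, lig_arm, ext_arm)
                break
        if probe is not None:
            break
    if probe is None:
        raise DesignError(f"{snp.name}: no arm placement satisfies Tm window")
    g0, g1, lig_arm, ext_arm = probe
    return PadlockProbe(
        name=name or f"snp_{snp.name}",
        kind="snp",
        extension_arm=ext_arm,
        ligation_arm=lig_arm,
        linker=linker,
        target=snp.name,
        chrom=snp.chrom,
        arm_start=g0 - len(lig_arm),
        capture_interval=(g0, g1),
        arm_end=g1 + len(ext_arm),
        secondary_targets=tuple(s.name for s in snps if s.name != snp.name),
    )


def design_snp_probes(
    snps: Sequence[TargetSNP],
    reference: Mapping[str, str],
    tm_params: TmParams = TmParams(),
    linker: str = DEFAULT_LINKER,
) -> List[PadlockProbe]:
    """Design probes for all ``snps``, merging variants close enough to share
    one captured gap (one probe may report several mutations)."""
    ordered = sorted(snps, key=lambda s: (s.chrom, s.pos))
    probes: List[PadlockProbe] = []
    group: List[TargetSNP] = []
    for s in ordered:
        if group and (s.chrom != group[0].chrom
                      or s.pos - group[0].pos > _SNP_WINDOW):
            probes.append(design_snp_probe(group[0], reference, tm_params,
                                           extra_snps=group[1:], linker=linker))
            group = []
        group.append(s)
    if group:
        probes.append(design_snp_probe(group[0], reference, tm_params,
                                       extra_snps=group[1:], linker=linker))
    return probes


# ---------------------------------------------------------------------------
# Secondary-structure screen
# ---------------------------------------------------------------------------


def self_complementarity_screen(probe: PadlockProbe,
                                max_hairpin_stem: int = 7) -> bool:
    """Pass/fail screen for probe-internal base pairing.

    Fails when any two distinct segments (extension arm, ligation arm,
    linker) share a reverse-complement match longer than
    ``max_hairpin_stem``.  A coarse stand-in for a full secondary-structure
    fold of the probe.
    """
    k = max_hairpin_stem + 1
    segments = [probe.extension_arm, probe.ligation_arm, probe.linker]
    kmer_sets = [
        {seg[i:i + k] for i in range(len(seg) - k + 1)} for seg in segments
    ]
    rc_sets = [{reverse_complement(m) for m in s} for s in kmer_sets]
    for a in range(len(segments)):
        for b in range(a + 1, len(segments)):
            if kmer_sets[a] & rc_sets[b]:
                return False
    return True
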