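"""Synthetic references, libraries, cohorts and capture reads.

The simulator emulates the signal structure of padlock capture after a
deletion-spanning pre-amplification: tiling (Kebab) products scale with the
number of intact copies of the commonly deleted interval, adapter-anchored
(Cat-D) products are high whenever the deletion allele is present and near a
small background otherwise, and SNP-probe products split between alleles
according to genotype.  Reads are drawn multinomially at a configured depth,
substitution errors are applied per base, and a fixed fraction of junk reads
matches nothing.

Everything is a pure function of the seed: one seed, one byte-identical
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from catd import io as catd_io
from catd.probe_design import (
    Adapter,
    DesignError,
    PadlockProbe,
    ProbeLibrary,
    TargetDeletion,
    TargetSNP,
    TmParams,
    catd_capture_template,
    design_adapter,
    design_catd_probe_set,
    design_kebab_tiling,
    design_snp_probes,
)
from catd.read_counting import ExpectedProduct, build_expected_products

__all__ = [
    "Cohort",
    "SimConfig",
    "SimDesign",
    "SimTruth",
    "default_cohort_plan",
    "simulate_cohort",
    "simulate_reference_and_library",
    "simulate_sample_reads",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (defaults mimic the validation run: 18 samples,
    ~184 K reads each, 36 probes)."""

    seed: int = 0
    depth: int = 184_000
    read_length: int = 100
    reference_length: int = 200_000
    n_catd_per_deletion: int = 5
    n_kebab: int = 17
    n_snps: int = 10
    efficiency_sigma: float = 0.5
    error_rate: float = 0.005
    junk_fraction: float = 0.05
    #: expected normalized reads per Cat-D product in deletion-free samples
    catd_background: float = 5.0
    #: relative capture weight of one probe per diploid target copy
    capture_unit: float = 4000.0
    tm: TmParams = field(default_factory=TmParams)
    #: cohort plan: (base name, role, n replicates, {target: genotype})
    cohort_plan: Optional[Tuple[Tuple[str, str, int, Tuple[Tuple[str, str], ...]], ...]] = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.error_rate <= 0.2):
            raise ValueError("error rate outside [0, 0.2]")
        if not (0.0 <= self.junk_fraction < 1.0):
            raise ValueError("junk fraction outside [0, 1)")
        if self.read_length < 88:
            raise ValueError("read length below the 88 nt match key")


@dataclass(frozen=True)
class SimTruth:
    """Assigned genotypes for one sample.

    ``deletions`` maps deletion name -> wt|het|hom; ``snps`` maps variant
    name -> ref|het|hom.  Unlisted targets are wild type.
    """

    sample_id: str
    deletions: Mapping[str, str] = field(default_factory=dict)
    snps: Mapping[str, str] = field(default_factory=dict)

    def deletion_dosage(self, name: str) -> int:
        return {"wt": 0, "het": 1, "hom": 2}[self.deletions.get(name, "wt")]

    def alt_fraction(self, snp_name: str) -> float:
        return {"ref": 0.0, "het": 0.5, "hom": 1.0}[self.snps.get(snp_name, "ref")]


@dataclass
class SimDesign:
    """A simulated reference plus the probe library designed against it."""

    genome: Dict[str, str]
    templates: Dict[str, str]  # Cat-D capture-strand templates
    deletions: List[TargetDeletion]
    kebab_target: TargetDeletion  # shared commonly-deleted interval
    snps: List[TargetSNP]
    library: ProbeLibrary
    products: List[ExpectedProduct]

    @property
    def reference(self) -> Dict[str, str]:
        return {**self.genome, **self.templates}


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _ASCII[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_reference_and_library(cfg: SimConfig) -> SimDesign:
    """Random reference with two overlapping deletion loci and a SNP locus,
    plus a probe library at the default composition (5+5 Cat-D, 17 Kebab,
    9 SNP probes covering 10 variants)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    length = max(cfg.reference_length, 150_000)
    chrom = "chrS"
    genome = {chrom: _random_genome(rng, length)}

    del_a = TargetDeletion("delA", chrom, 40_000, 70_000, (45_000, 66_000))
    del_b = TargetDeletion("delB", chrom, 50_000, 80_000, (54_000, 76_000))
    kebab_target = TargetDeletion(
        "kebab_shared", chrom, del_a.flank5_end, del_b.flank3_start,
        (54_000, 66_000),
    )

    def _make_snp(name: str, pos: int) -> TargetSNP:
        ref = genome[chrom][pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        return TargetSNP(name, chrom, pos, ref, alt)

    def _place_snp(name: str, anchor: int, paired: bool) -> TargetSNP:
        # synthetic variant positions are free: slide until probe design
        # succeeds at this locus (arm Tm windows are sequence dependent)
        from catd.probe_design import DesignError, design_snp_probe

        for delta in range(0, 4000, 40):
            for pos in (anchor + delta, anchor - delta) if delta else (anchor,):
                snp = _make_snp(name, pos)
                try:
                    if paired:
                        mate = _make_snp(f"{name}b", pos + 5)
                        design_snp_probe(snp, genome, cfg.tm, extra_snps=(mate,))
                    else:
                        design_snp_probe(snp, genome, cfg.tm)
                except DesignError:
                    continue
                return snp
        raise DesignError(f"{name}: no designable position near {anchor}")

    snps: List[TargetSNP] = []
    snp_base = 120_000
    for i in range(cfg.n_snps):
        # variants 5 and 6 share one captured gap, mirroring a probe that
        # reads more than one mutation
        if i == 5 and snps:
            snps.append(_make_snp(f"SNP{i + 1:02d}", snps[-1].pos + 5))
            continue
        pair_next = i == 4 and cfg.n_snps > 5
        snp = _place_snp(
            f"SNP{i + 1:02d}",
            snp_base + 8_000 * i,
            paired=pair_next,
        )
        snps.append(snp)

    probes: List[PadlockProbe] = []
    adapters: List[Adapter] = []
    templates: Dict[str, str] = {}
    for j, deletion in enumerate((del_a, del_b)):
        adapter = design_adapter(
            genome,
            rng_seed=int(rng.integers(0, 2**31)),
            name=f"{deletion.name}_adapter",
            linked_primer=f"{deletion.name}_preamp_primer",
            tm_params=cfg.tm,
        )
        adapters.append(adapter)
        template_id = f"{deletion.name}_catd_template"
        # primer placement within the retained flank is free: slide the
        # amplicon context until the full Cat-D probe set designs cleanly
        catd_probes = None
        for shift in range(0, 3000, 35):
            context = genome[chrom][
                deletion.flank5_end - 160 - shift:deletion.flank5_end - 10 - shift
            ]
            try:
                catd_probes = design_catd_probe_set(
                    adapter,
                    context,
                    cfg.n_catd_per_deletion,
                    cfg.tm,
                    target=deletion.name,
                    template_id=template_id,
                )
            except DesignError:
                continue
            break
        if catd_probes is None:
            raise DesignError(f"{deletion.name}: no Cat-D placement found")
        templates[template_id] = catd_capture_template(adapter, context)
        probes.extend(catd_probes)
    probes.extend(
        design_kebab_tiling(kebab_target, genome, cfg.n_kebab, cfg.tm)
    )
    probes.extend(design_snp_probes(snps, genome, cfg.tm))
    library = ProbeLibrary(probes=probes, adapters=adapters)
    design = SimDesign(
        genome=genome,
        templates=templates,
        deletions=[del_a, del_b],
        kebab_target=kebab_target,
        snps=snps,
        library=library,
        products=[],
    )
    design.products = build_expected_products(library, design.reference, snps)
    return design


# ---------------------------------------------------------------------------
# Cohort plan
# ---------------------------------------------------------------------------


def default_cohort_plan() -> Tuple[Tuple[str, str, int, Tuple[Tuple[str, str], ...]], ...]:
    """8 samples in duplicate plus 2 singletons (18 libraries): wild-type
    controls, het/hom/compound-het deletion carriers and a het SNP carrier."""
    return (
        ("wtA", "wt_control", 2, ()),
        ("wtB", "wt_control", 2, ()),
        ("delA_het", "test", 2, (("delA", "het"),)),
        ("delB_het", "test", 2, (("delB", "het"),)),
        ("delA_hom", "test", 2, (("delA", "hom"),)),
        ("compound", "test", 2, (("delA", "het"), ("delB", "het"))),
        ("snp_het", "test", 2, (("SNP01", "het"),)),
        ("all_wt", "test", 2, ()),
        ("delB_het_lot2", "test", 1, (("delB", "het"),)),
        ("single_wt", "test", 1, ()),
    )


def _plan_to_truth(
    plan, deletion_names: Sequence[str], snp_names: Sequence[str]
) -> Tuple[pd.DataFrame, List[SimTruth]]:
    sheet_rows = []
    truths = []
    for base, role, n_reps, genotype in plan:
        gmap = dict(genotype)
        unknown = set(gmap) - set(deletion_names) - set(snp_names)
        if unknown:
            raise KeyError(f"{base}: unknown targets {sorted(unknown)}")
        for rep in range(1, n_reps + 1):
            sample_id = f"{base}.{rep}" if n_reps > 1 else base
            replicate_of = f"{base}.1" if (n_reps > 1 and rep > 1) else ""
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "fastq": "",
                    "role": role,
                    "replicate_of": replicate_of,
                }
            )
            truths.append(
                SimTruth(
                    sample_id=sample_id,
                    deletions={d: gmap[d] for d in deletion_names if d in gmap},
                    snps={s: gmap[s] for s in snp_names if s in gmap},
                )
            )
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id", drop=False)
    return sheet, truths


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _product_weights(
    cfg: SimConfig,
    truth: SimTruth,
    design: SimDesign,
    efficiencies: Mapping[str, float],
) -> np.ndarray:
    probe_by_name = {p.name: p for p in design.library.probes}
    kebab_names = {design.kebab_target.name}
    total_del_alleles = sum(
        truth.deletion_dosage(d.name) for d in design.deletions
    )
    intact_copies = max(0, 2 - total_del_alleles)

    weights = np.zeros(len(design.products))
    snp_probe_totals: Dict[str, float] = {}
    for i, product in enumerate(design.products):
        probe = probe_by_name[product.probe_name]
        eff = efficiencies[probe.name]
        if probe.kind == "kebab":
            weights[i] = cfg.capture_unit * eff * intact_copies / 2.0
        elif probe.kind == "catd":
            present = truth.deletion_dosage(probe.target) > 0
            weights[i] = eff * (cfg.capture_unit if present else cfg.catd_background)
        else:  # snp: split probe weight across allele products
            w_probe = cfg.capture_unit * eff
            snp_probe_totals.setdefault(probe.name, w_probe)
            if product.allele_label == "alt":
                weights[i] = w_probe * truth.alt_fraction(product.target)
            else:
                alt_total = sum(
                    truth.alt_fraction(t) for t in probe.targets
                )
                weights[i] = w_probe * max(0.0, 1.0 - alt_total)
    return weights


class _Workspace:
    """Reusable per-cohort buffers (large allocations are the hot path)."""

    def __init__(self, depth: int, length: int) -> None:
        self.codes = np.empty((depth, length), dtype=np.uint8)
        self.rand = np.empty((depth, length), dtype=np.float32)
        self.mask = np.empty((depth, length), dtype=bool)
        self.reads = np.empty((depth, length), dtype=np.uint8)


def simulate_sample_reads(
    cfg: SimConfig,
    truth: SimTruth,
    design: SimDesign,
    efficiencies: Mapping[str, float],
    rng: np.random.Generator,
    workspace: Optional[_Workspace] = None,
) -> np.ndarray:
    """One sample's reads as a (depth, read_length) uint8 ASCII matrix.

    Read counts per product are multinomial over capture weights; junk reads
    are uniform random sequence; substitution errors hit every base
    independently at ``cfg.error_rate``.  With a shared ``workspace`` the
    returned matrix is a reused buffer, overwritten by the next call.
    """
    weights = _product_weights(cfg, truth, design, efficiencies)
    mapped_weight = weights.sum()
    junk_weight = (
        cfg.junk_fraction / (1.0 - cfg.junk_fraction) * mapped_weight
        if cfg.junk_fraction > 0
        else 0.0
    )
    all_weights = np.append(weights, junk_weight)
    draws = rng.multinomial(cfg.depth, all_weights / all_weights.sum())

    length = cfg.read_length
    ws = workspace or _Workspace(cfg.depth, length)
    codes = ws.codes
    offset = 0
    ascii_to_code = np.zeros(256, dtype=np.uint8)
    ascii_to_code[_ASCII] = np.arange(4, dtype=np.uint8)
    for product, n in zip(design.products, draws[:-1]):
        if n == 0:
            continue
        seq = product.full_product
        if len(seq) < length:
            raise ValueError(
                f"{product.name}: product ({len(seq)} nt) shorter than "
                f"read length {length}"
            )
        row = ascii_to_code[np.frombuffer(seq[:length].encode(), np.uint8)]
        codes[offset:offset + n] = row
        offset += n
    n_junk = draws[-1]
    if n_junk:
        codes[offset:] = rng.integers(0, 4, size=(int(n_junk), length),
                                      dtype=np.uint8)

    if cfg.error_rate > 0:
        rng.random(out=ws.rand, dtype=np.float32)
        mask = np.less(ws.rand, np.float32(cfg.error_rate), out=ws.mask)
        n_err = int(mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
            codes[mask] = (codes[mask] + shift) % 4
    return np.take(_ASCII, codes, out=ws.reads)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    config: SimConfig
    design: SimDesign
    samples: pd.DataFrame  # sample sheet
    truths: List[SimTruth]
    efficiencies: Dict[str, float]
    reads: Dict[str, np.ndarray] = field(default_factory=dict)
    outdir: Optional[Path] = None

    @property
    def truth_frame(self) -> pd.DataFrame:
        """Long truth table over every (sample, target) pair."""
        deletion_names = [d.name for d in self.design.deletions]
        snp_names = [s.name for s in self.design.snps]
        rows = []
        for truth in self.truths:
            for d in deletion_names:
                g = truth.deletions.get(d, "wt")
                rows.append(
                    {"sample": truth.sample_id, "target": d, "genotype": g,
                     "positive": g != "wt"}
                )
            for s in snp_names:
                g = truth.snps.get(s, "ref")
                rows.append(
                    {"sample": truth.sample_id, "target": s, "genotype": g,
                     "positive": g != "ref"}
                )
        return pd.DataFrame(rows)


def simulate_cohort(
    cfg: SimConfig,
    outdir: Optional[Path] = None,
    keep_reads: bool = True,
    gzip_fastq: bool = False,
    on_reads=None,
) -> Cohort:
    """Simulate a full cohort: design, truth table and per-sample reads.

    With ``outdir`` the cohort is materialized on disk (FASTQ per sample,
    sample sheet, truth table, library directory, reference FASTA).  Probe
    capture efficiencies are drawn once per cohort, so duplicates share the
    capture profile and differ only by counting noise and errors.

    ``on_reads(cohort, sample_id, reads)`` streams each sample's read matrix
    as soon as it is generated; with ``keep_reads=False`` the matrix is a shared
    buffer valid only during the callback.
    """
    design = simulate_reference_and_library(cfg)
    plan = cfg.cohort_plan or default_cohort_plan()
    sheet, truths = _plan_to_truth(
        plan,
        [d.name for d in design.deletions],
        [s.name for s in design.snps],
    )

    eff_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    efficiencies = {
        p.name: float(eff_rng.lognormal(0.0, cfg.efficiency_sigma))
        for p in design.library.probes
    }

    cohort = Cohort(
        config=cfg,
        design=design,
        samples=sheet,
        truths=truths,
        efficiencies=efficiencies,
        outdir=Path(outdir) if outdir else None,
    )

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "fastq").mkdir(parents=True, exist_ok=True)
        catd_io.write_fasta(outdir / "reference.fa", design.genome)
        catd_io.write_library(outdir / "library", design.library,
                              templates=design.templates)
        catd_io.write_deletions(
            outdir / "deletions.bed", outdir / "common.bed", design.deletions
        )
        catd_io.write_snps(outdir / "snps.tsv", design.snps)
        cohort.truth_frame.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    workspace = _Workspace(cfg.depth, cfg.read_length)
    for i, truth in enumerate(truths):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 303, i])
        )
        reads = simulate_sample_reads(cfg, truth, design, efficiencies, rng,
                                      workspace=workspace)
        if keep_reads:
            reads = reads.copy()
            cohort.reads[truth.sample_id] = reads
        if on_reads is not None:
            on_reads(cohort, truth.sample_id, reads)
        if outdir is not None:
            ext = "fastq.gz" if gzip_fastq else "fastq"
            fastq = Path(outdir) / "fastq" / f"{truth.sample_id}.{ext}"
            catd_io.write_fastq(fastq, reads, sample_id=truth.sample_id)
            sheet.loc[truth.sample_id, "fastq"] = str(fastq)

    if outdir is not None:
        catd_io.write_sample_sheet(Path(outdir) / "samples.tsv", sheet)
    return cohort
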