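"""File formats: FASTA/FASTQ, BED targets, SNP/sample-sheet/library TSVs.

All tabular formats are tab-separated with a header row (except BED, which is
headerless per convention).  Coordinates are 0-based half-open in BED and
internal structures; the SNP table is 1-based in the file, as is customary
for variant tables.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from catd.probe_design import (
    Adapter,
    PadlockProbe,
    ProbeLibrary,
    TargetDeletion,
    TargetSNP,
)

PathLike = Union[str, Path]

__all__ = [
    "read_deletions",
    "read_fasta",
    "read_fastq_seqs",
    "read_library",
    "read_sample_sheet",
    "read_snps",
    "write_deletions",
    "write_fasta",
    "write_fastq",
    "write_library",
    "write_sample_sheet",
    "write_snps",
]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA / FASTQ ----------------------------------------------------------


def read_fasta(path: PathLike) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq_seqs(path: PathLike) -> List[str]:
    """Read sequences from a (possibly gzipped) FASTQ; qualities ignored."""
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(path: PathLike, reads: Union[np.ndarray, Iterable[str]],
                sample_id: str = "read") -> None:
    """Write reads (strings, or a uint8 ASCII matrix) as FASTQ.

    Qualities are constant ('I'): the matcher never consults them.
    """
    if isinstance(reads, np.ndarray):
        length = reads.shape[1]
        blob = np.ascontiguousarray(reads).tobytes()
        seqs = (
            blob[i * length:(i + 1) * length].decode()
            for i in range(reads.shape[0])
        )
    else:
        seqs = iter(reads)
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{sample_id}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- Targets ----------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_deletions(deletions_bed: PathLike,
                   common_bed: PathLike) -> List[TargetDeletion]:
    """Deletion targets from a 6-column BED of maximal extents plus a BED of
    commonly deleted intervals (matched by name)."""
    extents = pd.read_csv(deletions_bed, sep="\t", header=None,
                          names=_BED_COLS, comment="#")
    common = pd.read_csv(common_bed, sep="\t", header=None,
                         names=_BED_COLS, comment="#").set_index("name")
    deletions = []
    for row in extents.itertuples():
        if row.name not in common.index:
            raise KeyError(f"deletion {row.name!r} missing from common BED")
        c = common.loc[row.name]
        deletions.append(
            TargetDeletion(
                name=str(row.name),
                chrom=str(row.chrom),
                flank5_end=int(row.start),
                flank3_start=int(row.end),
                commonly_deleted=(int(c["start"]), int(c["end"])),
            )
        )
    return deletions


def write_deletions(deletions_bed: PathLike, common_bed: PathLike,
                    deletions: Sequence[TargetDeletion]) -> None:
    with open(deletions_bed, "w") as fh:
        for d in deletions:
            fh.write(f"{d.chrom}\t{d.flank5_end}\t{d.flank3_start}\t{d.name}\t0\t+\n")
    with open(common_bed, "w") as fh:
        for d in deletions:
            c0, c1 = d.commonly_deleted
            fh.write(f"{d.chrom}\t{c0}\t{c1}\t{d.name}\t0\t+\n")


def read_snps(path: PathLike) -> List[TargetSNP]:
    """SNP table: chrom, pos (1-based), ref, alt, name."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str})
    return [
        TargetSNP(
            name=str(r["name"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]) - 1,
            ref_allele=str(r["ref"]),
            alt_allele=str(r["alt"]),
        )
        for _, r in df.iterrows()
    ]


def write_snps(path: PathLike, snps: Sequence[TargetSNP]) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos + 1 for s in snps],
            "ref": [s.ref_allele for s in snps],
            "alt": [s.alt_allele for s in snps],
            "name": [s.name for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


# -- Probe library ----------------------------------------------------------

_LIB_COLS = [
    "name", "kind", "extension_arm", "ligation_arm", "linker", "target",
    "secondary_targets", "chrom", "arm_start", "capture_start", "capture_end",
    "arm_end", "adapter",
]


def write_library(libdir: PathLike, library: ProbeLibrary,
                  templates: Mapping[str, str] = ()) -> None:
    """Write a library directory: probes.tsv, adapters.fa, probes.fa and the
    Cat-D capture templates (templates.fa)."""
    libdir = Path(libdir)
    libdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in library.probes:
        rows.append(
            {
                "name": p.name,
                "kind": p.kind,
                "extension_arm": p.extension_arm,
                "ligation_arm": p.ligation_arm,
                "linker": p.linker,
                "target": p.target,
                "secondary_targets": ",".join(p.secondary_targets),
                "chrom": p.chrom,
                "arm_start": p.arm_start,
                "capture_start": p.capture_interval[0],
                "capture_end": p.capture_interval[1],
                "arm_end": p.arm_end,
                "adapter": p.adapter,
            }
        )
    pd.DataFrame(rows, columns=_LIB_COLS).to_csv(
        libdir / "probes.tsv", sep="\t", index=False
    )
    if library.adapters:
        write_fasta(libdir / "adapters.fa",
                    {a.name: a.sequence for a in library.adapters})
    # Oligo orientation: arms flank the linker, ligation arm 5', extension 3'.
    write_fasta(
        libdir / "probes.fa",
        {p.name: p.ligation_arm + p.linker + p.extension_arm
         for p in library.probes},
    )
    if templates:
        write_fasta(libdir / "templates.fa", dict(templates))


def read_library(libdir: PathLike) -> Tuple[ProbeLibrary, Dict[str, str]]:
    """Read a library directory; returns (library, capture templates)."""
    libdir = Path(libdir)
    df = pd.read_csv(libdir / "probes.tsv", sep="\t",
                     keep_default_na=False, dtype=str)
    probes = [
        PadlockProbe(
            name=r["name"],
            kind=r["kind"],
            extension_arm=r["extension_arm"],
            ligation_arm=r["ligation_arm"],
            linker=r["linker"],
            target=r["target"],
            chrom=r["chrom"],
            arm_start=int(r["arm_start"]),
            capture_interval=(int(r["capture_start"]), int(r["capture_end"])),
            arm_end=int(r["arm_end"]),
            adapter=r["adapter"],
            secondary_targets=tuple(
                t for t in r["secondary_targets"].split(",") if t
            ),
        )
        for _, r in df.iterrows()
    ]
    adapters_fa = libdir / "adapters.fa"
    adapters = []
    if adapters_fa.exists():
        adapters = [
            Adapter(name=n, sequence=s)
            for n, s in read_fasta(adapters_fa).items()
        ]
    templates_fa = libdir / "templates.fa"
    templates = read_fasta(templates_fa) if templates_fa.exists() else {}
    return ProbeLibrary(probes=probes, adapters=adapters), templates


# -- Expected products ------------------------------------------------------


def write_products(path: PathLike, products: Sequence["ExpectedProduct"]) -> None:
    pd.DataFrame(
        {
            "name": [p.name for p in products],
            "probe": [p.probe_name for p in products],
            "kind": [p.kind for p in products],
            "target": [p.target for p in products],
            "allele": [p.allele_label for p in products],
            "match_key": [p.match_key for p in products],
            "full_product": [p.full_product for p in products],
        }
    ).to_csv(path, sep="\t", index=False)


def read_products(path: PathLike) -> List["ExpectedProduct"]:
    from catd.read_counting import ExpectedProduct

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return [
        ExpectedProduct(
            name=r["name"],
            probe_name=r["probe"],
            kind=r["kind"],
            target=r["target"],
            allele_label=r["allele"],
            match_key=r["match_key"],
            full_product=r["full_product"],
        )
        for _, r in df.iterrows()
    ]


# -- Sample sheet -----------------------------------------------------------


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Sample sheet: sample_id, fastq, role (wt_control|test), replicate_of."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    required = {"sample_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "fastq" not in df.columns:
        df["fastq"] = ""
    if "replicate_of" not in df.columns:
        df["replicate_of"] = ""
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(path: PathLike, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)
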