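"""Annotated genome container and plain-text genome IO.

The unit of analysis throughout the package is an assembly together with its
CDS annotation: variant counts and per-100-kbp rates are partitioned into the
coding (CDS) and non-coding (nCDS) compartments, so the container keeps merged
CDS intervals and the derived compartment lengths alongside the sequences.

Coordinates are 0-based, half-open everywhere inside the package; GFF3 input
(1-based, inclusive) is converted on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FiloplastError(Exception):
    """Base class for package errors."""


class ConfigurationError(FiloplastError):
    """Invalid configuration value."""


class CoordinateError(FiloplastError):
    """A coordinate falls outside the sequence it refers to."""


class MalformedPileupError(FiloplastError):
    """A pileup line violates the dialect (e.g. depth != allele sum)."""


class PileupOrderError(FiloplastError):
    """Pileup positions are not in ascending coordinate order."""


class NoAlignmentError(FiloplastError):
    """No contig pair of the two assemblies could be anchored."""


class UndefinedRateError(FiloplastError):
    """Rate requested with a zero-length denominator."""


class InternalConsistencyError(FiloplastError):
    """An internal invariant was violated (indicates a bug)."""


def merge_intervals(intervals) -> np.ndarray:
    """Merge possibly overlapping [start, end) intervals into a sorted,
    non-overlapping ``(n, 2)`` int64 array."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if np.any(arr[:, 1] < arr[:, 0]):
        raise CoordinateError("interval with end < start")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class AnnotatedGenome:
    """A sequence set plus merged CDS intervals.

    Parameters
    ----------
    contigs
        Ordered mapping of contig name to uppercase nucleotide sequence.
    cds_intervals
        Per contig, ``(n, 2)`` array of 0-based half-open CDS intervals;
        merged and bounds-checked on construction.
    name
        Assembly identifier used in reports.
    """

    contigs: dict[str, str]
    cds_intervals: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}
        merged = {}
        for cname, seq in self.contigs.items():
            iv = merge_intervals(self.cds_intervals.get(cname, []))
            if iv.size and (iv[0, 0] < 0 or iv[-1, 1] > len(seq)):
                raise CoordinateError(
                    f"CDS interval out of bounds on contig {cname!r}"
                )
            merged[cname] = iv
        self.cds_intervals = merged

    # -- derived bookkeeping -------------------------------------------------

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def cds_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.cds_intervals.values())
        )

    @property
    def ncds_length(self) -> int:
        return self.total_length - self.cds_length

    @property
    def coding_fraction(self) -> float:
        return self.cds_length / self.total_length if self.total_length else 0.0

    def in_cds(self, contig: str, positions) -> np.ndarray:
        """Vectorised CDS membership test for 0-based positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        iv = self.cds_intervals.get(contig)
        if iv is None or iv.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < iv[idx[ok], 1]
        return out

    # -- IO ------------------------------------------------------------------

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None,
                   name: str = "") -> "AnnotatedGenome":
        contigs = read_fasta(fasta)
        cds = read_gff3(gff3) if gff3 is not None else {}
        return cls(contigs=contigs, cds_intervals=cds,
                   name=name or Path(fasta).stem)

    def write(self, fasta: str | Path, gff3: str | Path | None = None) -> None:
        write_fasta(self.contigs, fasta)
        if gff3 is not None:
            write_gff3(self, gff3)


GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | Path) -> dict[str, np.ndarray]:
    """Read CDS features from a GFF3 file into 0-based half-open intervals."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "type": str, "start": np.int64, "end": np.int64},
        usecols=["seqid", "type", "start", "end"],
    )
    df = df[df["type"] == "CDS"]
    out: dict[str, np.ndarray] = {}
    for seqid, grp in df.groupby("seqid", sort=False):
        # GFF3 is 1-based inclusive
        out[str(seqid)] = np.column_stack(
            [grp["start"].to_numpy() - 1, grp["end"].to_numpy()]
        )
    return out


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cname, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cname} 1 {len(seq)}\n")
        for cname in genome.contigs:
            for i, (s, e) in enumerate(genome.cds_intervals.get(cname, []), 1):
                fh.write(
                    f"{cname}\tfiloplast\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                    f"ID=cds_{cname}_{i}\n"
                )
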