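"""FASTA and population-map I/O with fixed-window barcode quality control.

The analyses downstream operate on gap-free, unambiguous nucleotide
sequences confined to fixed marker windows: a 657 bp fragment of the
mitochondrial COI gene and a 518 bp fragment of COII (1175 bp combined).
This module reads/writes the plain-text inputs (FASTA, a tab-separated
population map) and enforces those windows: sequences are sliced to the
window, uppercased, and rejected if they are too short or contain any
character outside ``{A, C, G, T}`` (IUPAC ambiguity codes such as Y, W,
N, S, and alignment gaps ``-`` all count as ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusSpec",
    "COI",
    "COII",
    "COMBINED",
    "LOCI",
    "SequenceRecord",
    "PopulationMap",
    "FastaError",
    "QCRejection",
    "read_fasta",
    "write_fasta",
    "qc_trim",
    "qc_filter",
    "read_popmap",
    "write_popmap",
]

VALID_BASES = frozenset("ACGT")


class FastaError(ValueError):
    """Malformed FASTA input (empty header, duplicated identifier...)."""


class QCRejection(ValueError):
    """A sequence failed window QC; ``reason`` is ``"short"`` or ``"ambiguous"``."""

    def __init__(self, individual_id: str, reason: str, detail: str = ""):
        self.individual_id = individual_id
        self.reason = reason
        msg = f"{individual_id}: rejected ({reason})"
        if detail:
            msg += f" - {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class LocusSpec:
    """A marker locus with its fixed analysis window length in bp."""

    name: str
    window_length: int

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")


COI = LocusSpec("COI", 657)
COII = LocusSpec("COII", 518)
COMBINED = LocusSpec("COMBINED", COI.window_length + COII.window_length)

#: Registry of the default loci by name.
LOCI: Mapping[str, LocusSpec] = {spec.name: spec for spec in (COI, COII, COMBINED)}


@dataclass(frozen=True)
class SequenceRecord:
    """One individual's sequence at one locus.

    After QC (:func:`qc_trim`) ``bases`` contains only A/C/G/T and has
    length exactly ``window_length`` of the locus.
    """

    individual_id: str
    locus: str
    bases: str


def read_fasta(path: str | Path, locus: LocusSpec) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The individual identifier is the first whitespace-delimited token of
    the header line. File order is preserved. Duplicated identifiers are
    an error; an empty file yields an empty list. No QC is applied here.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FastaError(f"{path}: entry {i + 1} has an empty header")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicated identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, locus.name, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (one entry per record, id-only headers)."""
    seq_records = [
        SeqRecord(Seq(r.bases), id=r.individual_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def qc_trim(
    record: SequenceRecord, locus: LocusSpec, window_start: int = 0
) -> SequenceRecord:
    """Restrict a sequence to the locus window and validate its alphabet.

    The window is ``bases[window_start : window_start + window_length]``,
    uppercased. Raises :class:`QCRejection` with reason ``"short"`` if the
    sequence does not span the window, or ``"ambiguous"`` if the windowed
    sequence contains any character outside A/C/G/T (ambiguity codes and
    gap characters alike). Idempotent on accepted records.
    """
    if window_start < 0:
        raise ValueError("window_start must be non-negative")
    end = window_start + locus.window_length
    if len(record.bases) < end:
        raise QCRejection(
            record.individual_id,
            "short",
            f"{len(record.bases)} bp < window end {end}",
        )
    window = record.bases[window_start:end].upper()
    bad = set(window) - VALID_BASES
    if bad:
        raise QCRejection(
            record.individual_id,
            "ambiguous",
            f"disallowed characters {sorted(bad)}",
        )
    return SequenceRecord(record.individual_id, locus.name, window)


def qc_filter(
    records: Iterable[SequenceRecord], locus: LocusSpec, window_start: int = 0
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Apply :func:`qc_trim` to many records, partitioning the outcome.

    Returns ``(accepted, rejected)`` where ``rejected`` pairs each failing
    record with its reason; ``len(accepted) + len(rejected)`` always equals
    the number of inputs (no silent drops).
    """
    accepted: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        try:
            accepted.append(qc_trim(rec, locus, window_start))
        except QCRejection as exc:
            rejected.append((rec, exc.reason))
    return accepted, rejected


@dataclass(frozen=True)
class PopulationMap:
    """individual_id -> (country, region) metadata for every sampled bug."""

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for ind, (country, region) in self.entries.items():
            if not country or not region:
                raise ValueError(f"{ind}: country/region must be non-empty")

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.entries

    def country(self, individual_id: str) -> str:
        return self.entries[individual_id][0]

    def region(self, individual_id: str) -> str:
        return self.entries[individual_id][1]


POPMAP_COLUMNS: Sequence[str] = ("individual_id", "country", "region")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a tab-separated population map.

    Expected header: ``individual_id<TAB>country<TAB>region``. Individual
    identifiers must be unique.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in POPMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"{path}: duplicated individual_id entries {dups}")
    entries = {
        row.individual_id: (row.country, row.region)
        for row in df.itertuples(index=False)
    }
    return PopulationMap(entries)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(POPMAP_COLUMNS) + "\n")
        for ind, (country, region) in popmap.entries.items():
            fh.write(f"{ind}\t{country}\t{region}\n")
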