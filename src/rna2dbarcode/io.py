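"""Sequence and manifest ingestion.

All sequences are held internally on the RNA alphabet: ``T`` is transcribed to
``U`` on input and only written back as DNA on request.  FASTA headers may carry
specimen metadata as ``id|taxon|voucher|marker``; plain headers are accepted
with empty metadata.

The specimen manifest is a UTF-8 TSV with the columns ``SPECIES``, ``LOCALITY``,
``VOUCHER``, ``H3``, ``16S``, ``COI`` — one row per specimen, a blank cell
meaning the accession was never deposited.  A transcription of the study's
47-specimen manifest ships with the package (``data/specimen_manifest.tsv``).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

IUPAC_RNA = set("ACGUNRYSWKMBDHV")
MARKERS = ("H3", "16S", "COI")

__all__ = [
    "SequenceRecord",
    "ManifestEntry",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "count_manifest",
    "fetch_accessions",
    "packaged_manifest_path",
]


@dataclass
class SequenceRecord:
    """One nucleotide sequence with specimen metadata.

    ``residues`` are stored uppercase on the RNA alphabet; ``genus`` defaults
    to the first word of the species binomial.
    """

    id: str
    residues: str
    taxon: str = ""
    voucher: str = ""
    marker: str = "16S"
    genus: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        seq = self.residues.upper().replace("T", "U")
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_RNA:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos + 1}"
                )
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.residues = seq
        if not self.genus and self.taxon:
            self.genus = self.taxon.split()[0]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ManifestEntry:
    """One manifest row: a specimen with its deposited accessions."""

    species: str
    locality: str = ""
    voucher: str = ""
    accession_by_marker: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accession_by_marker = {
            m: a.strip() for m, a in self.accession_by_marker.items() if a and a.strip()
        }
        if not self.accession_by_marker:
            raise ValueError(
                f"manifest row for {self.species!r} has no accession in any marker"
            )

    @property
    def binomial(self) -> str:
        """Species binomial without the authority string."""
        return " ".join(self.species.split()[:2])

    @property
    def genus(self) -> str:
        return self.species.split()[0]


def _parse_header(header: str) -> dict[str, str]:
    parts = header.split("|")
    if len(parts) >= 4:
        return {
            "id": parts[0].strip(),
            "taxon": parts[1].strip(),
            "voucher": parts[2].strip(),
            "marker": parts[3].strip(),
        }
    return {"id": parts[0].split()[0] if parts[0].split() else parts[0]}


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects (DNA transcribed to RNA).

    Raises ``ValueError`` on an empty file, duplicate ids or non-IUPAC residues.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(bio.description)
        rec = SequenceRecord(
            id=meta["id"],
            residues=str(bio.seq),
            taxon=meta.get("taxon", ""),
            voucher=meta.get("voucher", ""),
            marker=meta.get("marker", "16S"),
        )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, as_dna: bool = False) -> None:
    """Write records as FASTA wrapped at 70 columns.

    Metadata-bearing records get ``id|taxon|voucher|marker`` headers so that a
    read/write cycle is the identity.  ``as_dna`` back-transcribes U to T.
    """
    bio_records = []
    for rec in records:
        seq = rec.residues.replace("U", "T") if as_dna else rec.residues
        if rec.taxon or rec.voucher or rec.marker != "16S":
            header = f"{rec.id}|{rec.taxon}|{rec.voucher}|{rec.marker}"
        else:
            header = rec.id
        bio_records.append(_BioRecord(Seq(seq), id=header, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(bio_records)


def packaged_manifest_path() -> Path:
    """Path of the packaged 47-specimen manifest."""
    return Path(resources.files("rna2dbarcode").joinpath("data/specimen_manifest.tsv"))


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a specimen manifest TSV.

    Blank cells become absent accessions; a row with all three accession cells
    blank is an error, as is a missing mandatory column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    required = ["SPECIES", "LOCALITY", "VOUCHER", *MARKERS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing mandatory column(s): {', '.join(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                ManifestEntry(
                    species=row["SPECIES"].strip(),
                    locality=row["LOCALITY"].strip(),
                    voucher=row["VOUCHER"].strip(),
                    accession_by_marker={m: row[m] for m in MARKERS},
                )
            )
        except ValueError as exc:
            raise ValueError(f"manifest {path}, row {i + 2}: {exc}") from exc
    return entries


def count_manifest(entries: list[ManifestEntry]) -> dict[str, int]:
    """Summarise a manifest: accession, specimen, species and genus counts."""
    if not entries:
        raise ValueError("empty manifest")
    return {
        "n_sequences": sum(len(e.accession_by_marker) for e in entries),
        "n_specimens": len(entries),
        "n_species": len({e.binomial for e in entries}),
        "n_genera": len({e.genus for e in entries}),
    }


def fetch_accessions(
    entries: list[ManifestEntry],
    marker: str,
    *,
    email: str = "rna2dbarcode@example.org",
    retries: int = 3,
    logger=None,
) -> list[SequenceRecord]:
    """Download the sequences behind a manifest's accessions from GenBank.

    Network-dependent and therefore never exercised by the test suite; every
    other operation in the package accepts local FASTA instead.  Entries
    without an accession for ``marker`` are skipped (and logged).  Unknown
    accessions raise ``ValueError``; transient network failures are retried
    ``retries`` times before raising ``IOError``.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    from Bio import Entrez  # deferred: network-only dependency surface

    Entrez.email = email
    wanted = [(e, e.accession_by_marker[marker]) for e in entries if marker in e.accession_by_marker]
    for entry in entries:
        if marker not in entry.accession_by_marker and logger is not None:
            logger.info("no %s accession for %s; skipped", marker, entry.species)
    records = []
    for entry, acc in wanted:
        last_exc: Exception | None = None
        for attempt in range(retries):
            try:
                with Entrez.efetch(db="nucleotide", id=acc, rettype="fasta", retmode="text") as h:
                    bio = next(SeqIO.parse(h, "fasta"), None)
                break
            except IOError as exc:  # transient — retry
                last_exc = exc
                time.sleep(1 + attempt)
        else:
            raise IOError(f"GenBank fetch failed for {acc} after {retries} attempts") from last_exc
        if bio is None:
            raise ValueError(f"unknown accession {acc!r} (no record returned)")
        records.append(
            SequenceRecord(
                id=acc,
                residues=str(bio.seq),
                taxon=entry.binomial,
                voucher=entry.voucher,
                marker=marker,
            )
        )
    return records
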