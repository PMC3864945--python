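"""Reference sequence collection keyed by full taxonomic lineages.

The classification database used throughout the pipeline is a FASTA file
whose record names are semicolon-delimited taxonomies (SILVA SSURef style),
e.g. ``Metazoa;Cnidaria;Scyphozoa;Coronatae;Nausithoidae;Nausithoe;
Nausithoe_rubra``.  RNA sequences are converted to DNA on load (U -> T).
Headers may optionally carry an accession token before the lineage, as real
SILVA exports do; the accession then becomes the record id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TaxonLineage",
    "ReferenceRecord",
    "ReferenceParseError",
    "parse_reference_fasta",
    "write_reference_fasta",
    "lineage_contains",
    "export_reference_tsv",
]

# IUPAC nucleotide codes accepted after RNA->DNA conversion
_IUPAC_DNA = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")


class ReferenceParseError(ValueError):
    """Raised for malformed reference FASTA input."""


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered taxonomy, most-general rank first, species last."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must have at least one rank")
        if any(not r for r in self.ranks):
            raise ValueError(f"lineage has empty rank label: {self.ranks!r}")

    @classmethod
    def parse(cls, text: str) -> "TaxonLineage":
        ranks = tuple(part.strip() for part in text.strip().split(";") if part.strip())
        if not ranks:
            raise ValueError(f"no taxon labels in lineage text {text!r}")
        return cls(ranks)

    def render(self) -> str:
        return ";".join(self.ranks)

    @property
    def species(self) -> str:
        """The most specific (last) rank label."""
        return self.ranks[-1]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class ReferenceRecord:
    """One database entry: a DNA sequence named by its full lineage."""

    record_id: str
    lineage: TaxonLineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")
        bad = set(self.sequence) - _IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.record_id}: non-IUPAC DNA characters {sorted(bad)!r}"
            )


def lineage_contains(lineage: TaxonLineage, taxon: str) -> bool:
    """True iff ``taxon`` equals any rank label (case-sensitive, trimmed)."""
    taxon = taxon.strip()
    if not taxon:
        raise ValueError("taxon label must be non-empty")
    return any(rank == taxon for rank in lineage.ranks)


def _split_header(header: str) -> tuple[str | None, str]:
    """Split a FASTA header into (accession or None, lineage text).

    Accepts both lineage-only headers and ``accession<space>lineage``
    headers.  A leading token with no semicolon, followed by text that has
    one, is treated as an accession.
    """
    header = header.strip()
    if not header:
        raise ReferenceParseError("empty FASTA header")
    parts = header.split(None, 1)
    if len(parts) == 2 and ";" not in parts[0] and ";" in parts[1]:
        return parts[0], parts[1]
    return None, header


def parse_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Load a lineage-named reference FASTA; U/u are converted to T/t."""
    path = Path(path)
    records: list[ReferenceRecord] = []
    # Reject sequence data appearing before the first header with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ReferenceParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        header = rec.description
        accession, lineage_text = _split_header(header)
        try:
            lineage = TaxonLineage.parse(lineage_text)
        except ValueError as exc:
            raise ReferenceParseError(f"{path}: record {i + 1}: {exc}") from exc
        seq = str(rec.seq).replace("U", "T").replace("u", "t")
        records.append(
            ReferenceRecord(
                record_id=accession if accession is not None else str(i),
                lineage=lineage,
                sequence=seq,
            )
        )
    return records


def write_reference_fasta(
    records: Iterable[ReferenceRecord], path: str | Path, with_accession: bool = False
) -> None:
    """Write records back out; inverse of :func:`parse_reference_fasta`."""
    seqrecs: Iterator[SeqRecord] = (
        SeqRecord(
            Seq(r.sequence),
            id=(f"{r.record_id} {r.lineage.render()}" if with_accession else r.lineage.render()),
            description="",
        )
        for r in records
    )
    SeqIO.write(seqrecs, str(path), "fasta-2line")


def export_reference_tsv(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Inspection export: record_id, lineage, sequence length."""
    with open(path, "w") as fh:
        fh.write("record_id\tlineage\tlength\n")
        for r in records:
            fh.write(f"{r.record_id}\t{r.lineage.render()}\t{len(r.sequence)}\n")
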