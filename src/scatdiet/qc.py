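"""Read quality/length filtering and dual-tag demultiplexing.

The filtering order follows the assay's processing scheme: whole-read mean
quality filter (mean Phred >= 30 keeps), then minimum length (>= 120 bp
keeps), then assignment of reads to scats by recognising the forward tag +
primer at the 5' end and the reverse-complemented primer + tag at the 3'
end.  The 5' end of a read is high quality, so the forward tag must match
exactly; the 3' end is error-prone on this chemistry, so the number of
mismatches tolerated in the reverse tag is configurable (default 0, the
strict rule, which is what makes reads with corrupted 3' ends unassignable
and drives the characteristic read loss at high 3' error rates).
Assigned reads are trimmed of tags and primers before clustering so the
conserved primer text cannot inflate inter-taxon identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tags import TagScheme

__all__ = [
    "SequencingRead",
    "DemuxResult",
    "ConfigurationError",
    "read_fastq",
    "write_fastq",
    "mean_quality_filter",
    "length_filter",
    "demultiplex",
    "write_demux_report",
]


class ConfigurationError(ValueError):
    """Sample sheet / tag scheme inconsistency."""


@dataclass(frozen=True)
class SequencingRead:
    """One read: bases plus per-base integer Phred scores."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality scores"
            )
        if self.qualities and not (0 <= min(self.qualities) <= max(self.qualities) <= 93):
            raise ValueError(f"read {self.read_id}: Phred scores outside [0, 93]")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path: str | Path) -> list[SequencingRead]:
    """Load a Phred+33 FASTQ file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SequencingRead(
                read_id=rec.id,
                bases=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def mean_quality_filter(
    reads: Sequence[SequencingRead], threshold: float = 30.0
) -> tuple[list[SequencingRead], list[str]]:
    """Keep reads whose arithmetic mean Phred score is >= threshold."""
    kept, rejected = [], []
    for r in reads:
        if r.mean_quality >= threshold:
            kept.append(r)
        else:
            rejected.append(r.read_id)
    return kept, rejected


def length_filter(
    reads: Sequence[SequencingRead], min_length: int = 120
) -> tuple[list[SequencingRead], list[str]]:
    """Keep reads of length >= min_length (removes partials/primer-dimer)."""
    kept, rejected = [], []
    for r in reads:
        if len(r) >= min_length:
            kept.append(r)
        else:
            rejected.append(r.read_id)
    return kept, rejected


@dataclass
class DemuxResult:
    """Partition of the input reads into per-scat assignments and rejects."""

    assignments: dict[str, str] = field(default_factory=dict)  # read_id -> scat_id
    rejects: dict[str, str] = field(default_factory=dict)      # read_id -> reason
    trimmed_reads: dict[str, list[SequencingRead]] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Sequence[SequencingRead],
    scheme: TagScheme,
    sample_sheet: Sequence,
    rev_tag_mismatches_allowed: int = 0,
) -> DemuxResult:
    """Assign reads to scats by their forward/reverse tag combination.

    The forward tag must match exactly at position 0 followed by the
    forward primer with at most one mismatch; the read's 3' end must match
    revcomp(reverse_primer) + revcomp(reverse_tag) with at most one
    mismatch in the primer part and ``rev_tag_mismatches_allowed`` in the
    tag part.  Rejection reasons are applied in the order no_forward_tag,
    no_reverse_tag, unknown_pair.  ``sample_sheet`` rows need ``scat_id``,
    ``fwd_tag`` and ``rev_tag`` attributes.
    """
    pair_to_scat: dict[tuple[str, str], str] = {}
    for row in sample_sheet:
        if row.fwd_tag not in scheme.forward_tags:
            raise ConfigurationError(f"sheet names unknown forward tag {row.fwd_tag!r}")
        if row.rev_tag not in scheme.reverse_tags:
            raise ConfigurationError(f"sheet names unknown reverse tag {row.rev_tag!r}")
        pair_to_scat[(row.fwd_tag, row.rev_tag)] = row.scat_id

    fwd_regions = {name: scheme.read_prefix(name) for name in scheme.forward_tags}
    fwd_tag_len = {name: len(t) for name, t in scheme.forward_tags.items()}
    rev_regions = {name: scheme.read_suffix(name) for name in scheme.reverse_tags}
    primer_len = len(scheme.forward_primer)
    rev_primer_len = len(scheme.reverse_primer)

    result = DemuxResult()
    for read in reads:
        fwd_name = None
        for name, region in fwd_regions.items():
            tlen = fwd_tag_len[name]
            if len(read.bases) < len(region):
                continue
            if read.bases[:tlen] != region[:tlen]:
                continue
            if _hamming(read.bases[tlen:len(region)], region[tlen:]) <= 1:
                fwd_name = name
                break
        if fwd_name is None:
            result.rejects[read.read_id] = "no_forward_tag"
            continue

        fwd_cut = len(fwd_regions[fwd_name])
        rev_name = None
        best_mm = None
        for name, region in rev_regions.items():
            rlen = len(region)
            if len(read.bases) < fwd_cut + rlen:
                continue
            tail = read.bases[-rlen:]
            primer_mm = _hamming(tail[:rev_primer_len], region[:rev_primer_len])
            tag_mm = _hamming(tail[rev_primer_len:], region[rev_primer_len:])
            if primer_mm <= 1 and tag_mm <= rev_tag_mismatches_allowed:
                total = primer_mm + tag_mm
                if best_mm is None or total < best_mm:
                    best_mm = total
                    rev_name = name
        if rev_name is None:
            result.rejects[read.read_id] = "no_reverse_tag"
            continue

        scat_id = pair_to_scat.get((fwd_name, rev_name))
        if scat_id is None:
            result.rejects[read.read_id] = "unknown_pair"
            continue

        rev_cut = len(rev_regions[rev_name])
        trimmed = SequencingRead(
            read_id=read.read_id,
            bases=read.bases[fwd_cut : len(read.bases) - rev_cut],
            qualities=read.qualities[fwd_cut : len(read.bases) - rev_cut],
        )
        result.assignments[read.read_id] = scat_id
        result.trimmed_reads.setdefault(scat_id, []).append(trimmed)
    return result


def write_demux_report(result: DemuxResult, path: str | Path) -> None:
    """TSV of every read's disposition (read_id, disposition, scat_id)."""
    with open(path, "w") as fh:
        fh.write("read_id\tdisposition\tscat_id\n")
        for read_id, scat_id in sorted(result.assignments.items()):
            fh.write(f"{read_id}\tassigned\t{scat_id}\n")
        for read_id, reason in sorted(result.rejects.items()):
            fh.write(f"{read_id}\t{reason}\t\n")
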