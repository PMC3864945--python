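"""Dual-tag fusion-primer scheme for scat amplicon libraries.

Each PCR uses one of six forward and one of eight reverse fusion primers;
the 10 nt sample tags sit between the sequencer adapter and the universal
SSU rDNA amplification primer, so a read starts with
``forward_tag + forward_primer`` and ends with
``revcomp(reverse_primer) + revcomp(reverse_tag)``.  The unique (forward,
reverse) tag combination identifies the individual scat within a pooled
sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TagScheme", "default_tag_scheme", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagScheme:
    """Forward/reverse sample tags plus the shared amplification primers."""

    forward_tags: dict[str, str]
    reverse_tags: dict[str, str]
    forward_primer: str
    reverse_primer: str

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("primers must be non-empty")
        for name, tags in (("forward", self.forward_tags), ("reverse", self.reverse_tags)):
            texts = list(tags.values())
            if len(set(texts)) != len(texts):
                raise ValueError(f"duplicate {name} tag sequences")
            if any(not t for t in texts):
                raise ValueError(f"empty {name} tag sequence")

    def read_prefix(self, fwd_name: str) -> str:
        """The expected start of a read tagged with ``fwd_name``."""
        return self.forward_tags[fwd_name] + self.forward_primer

    def read_suffix(self, rev_name: str) -> str:
        """The expected end of a read tagged with ``rev_name``.

        On the forward strand the read terminates with the reverse
        complement of the reverse primer followed by the reverse complement
        of the reverse tag (the tag is 5' of the primer on the reverse
        strand).
        """
        return revcomp(self.reverse_primer) + revcomp(self.reverse_tags[rev_name])


# Tags are the sample-identifying portions of the SSU3'Ion fusion primers
# (between the instrument adapter and the universal primer).
_FORWARD_TAGS = {
    "F_1": "TCAAGCCTGA",
    "F_2": "CGTTAGGTCA",
    "F_3": "TGCCAGGTCA",
    "F_4": "CGAATGGATC",
    "F_5": "TGCCAGGACT",
    "F_6": "CAGGTAAGTC",
}
_REVERSE_TAGS = {
    "R_A": "TCAGGCTTGA",
    "R_B": "CGTAAGTTCA",
    "R_C": "TGCAAGTTCA",
    "R_D": "CGATTGAATC",
    "R_E": "TGCAAGAACT",
    "R_F": "CAGTTAGGTC",
    "R_G": "TCGAACTTAG",
    "R_H": "CTGAAGAACT",
}
_FORWARD_PRIMER = "CACCGCCCGTCGCTACTACCG"      # SSU3'F
_REVERSE_PRIMER = "GGTTCACCTACGGAAACCTTGTTACG"  # SSU3'R


def default_tag_scheme() -> TagScheme:
    """The 6 forward x 8 reverse tag scheme used by the scat assay."""
    return TagScheme(
        forward_tags=dict(_FORWARD_TAGS),
        reverse_tags=dict(_REVERSE_TAGS),
        forward_primer=_FORWARD_PRIMER,
        reverse_primer=_REVERSE_PRIMER,
    )
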