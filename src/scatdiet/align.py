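"""Semi-global pairwise alignment and the identity measure it defines.

Clustering and database matching both score sequence similarity as the
fraction of matching columns in an optimal containment-style semi-global
alignment: unit match score, unit mismatch and gap penalties, where the
shorter sequence must be consumed end to end and only the longer
sequence's terminal overhangs are gap-free (and excluded from the identity
denominator).  Equal-length sequences therefore align globally, while a
sequence and a ragged-ended copy of it (as the length filter leaves
behind) still reach identity 1.0.  Allowing *both* sequences to skip ends
for free would degenerate into local alignment, where unrelated sequences
reach identity 1.0 over a short lucky overlap — useless as a clustering
criterion.

Determinism: arguments are canonically ordered (shorter first, then
lexicographic) so identity is exactly symmetric; the end cell is the
highest-scoring cell of the bottom row, ties preferring the rightmost
cell; traceback prefers diagonal over vertical over horizontal moves.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

__all__ = ["AlignmentStats", "semi_global_align", "pairwise_identity"]

MATCH = 1
MISMATCH = -1
GAP = -1


class AlignmentStats(NamedTuple):
    """Summary of one optimal semi-global alignment of a (rows) vs b (cols)."""

    score: int
    matches: int
    columns: int   # aligned columns; the longer sequence's free overhangs excluded
    paired: int    # columns pairing a base of a with a base of b
    a_span: tuple[int, int]  # half-open interval of a inside the alignment
    b_span: tuple[int, int]
    a_len: int
    b_len: int

    @property
    def identity(self) -> float:
        """Matching columns / aligned columns."""
        return self.matches / self.columns if self.columns else 0.0

    @property
    def coverage_a(self) -> float:
        """Fraction of a's bases aligned against a base of b."""
        return self.paired / self.a_len

    @property
    def coverage_b(self) -> float:
        return self.paired / self.b_len

    @property
    def match_coverage_a(self) -> float:
        """Fraction of a's bases in *matching* columns.

        The operational "does the database account for this seed" measure:
        unrelated random sequences plateau well below it while true (even
        diverged or chimaeric) hits sit high.
        """
        return self.matches / self.a_len

    @property
    def match_coverage_b(self) -> float:
        return self.matches / self.b_len

    def swapped(self) -> "AlignmentStats":
        return AlignmentStats(
            self.score, self.matches, self.columns, self.paired,
            self.b_span, self.a_span, self.b_len, self.a_len,
        )


@lru_cache(maxsize=100_000)
def _align(a: str, b: str) -> AlignmentStats:
    """Core DP; requires (len(a), a) <= (len(b), b)."""
    n, m = len(a), len(b)
    # free gaps before/after b only (row 0 = 0); consuming a against the
    # b-boundary costs like any other gap (column 0 = -i)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = -i
    for i in range(1, n + 1):
        ai = a[i - 1]
        Si = S[i]
        Sp = S[i - 1]
        for j in range(1, m + 1):
            d = Sp[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            u = Sp[j] + GAP
            l = Si[j - 1] + GAP
            best = d
            if u > best:
                best = u
            if l > best:
                best = l
            Si[j] = best

    # a must be fully consumed: end anywhere on the bottom row, the
    # remaining b suffix is a free overhang; ties prefer the rightmost cell
    row = S[n]
    j_end = max(range(m + 1), key=lambda j: (row[j], j))

    i, j = n, j_end
    matches = 0
    columns = 0
    paired = 0
    while i > 0 and j > 0:
        here = S[i][j]
        is_match = a[i - 1] == b[j - 1]
        if here == S[i - 1][j - 1] + (MATCH if is_match else MISMATCH):
            matches += is_match
            paired += 1
            columns += 1
            i -= 1
            j -= 1
        elif here == S[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    # leading a-bases consumed against column 0 are penalized gap columns
    columns += i
    return AlignmentStats(
        score=row[j_end],
        matches=matches,
        columns=columns,
        paired=paired,
        a_span=(0, n),
        b_span=(j, j_end),
        a_len=n,
        b_len=m,
    )


def semi_global_align(a: str, b: str) -> AlignmentStats:
    """Optimal semi-global alignment statistics for two DNA strings."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if (len(a), a) <= (len(b), b):
        return _align(a, b)
    return _align(b, a).swapped()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal semi-global alignment.

    Symmetric, in [0, 1].  The longer sequence's terminal overhangs are
    excluded from the denominator, so e.g. a sequence and its
    1-base-shorter suffix align at identity 1.0, while "AAAA" vs "AAAT"
    gives 0.75.
    """
    return semi_global_align(a, b).identity
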