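"""Minimal amplicon read placement: exact k-mer seeding + ungapped extension.

The screen aligns short reads to a handful of known amplicon references, so
a full aligner is unnecessary.  Reads are anchored by an exact seed k-mer
(tried at the read start and read midpoint, on both strands) and extended
without gaps, counting mismatches.  Two reporting modes match the two
calling strategies:

``single``
    keep only the lowest-mismatch placement; ties across distinct
    placements are discarded as ambiguous (used for single-copy genes).
``report_all``
    keep every placement within the mismatch budget, so a read from a
    conserved region of a duplicated gene is counted once per copy - this
    deliberately reproduces the allele-signal dilution seen for multi-copy
    targets.
"""

from __future__ import annotations

from dataclasses import dataclass

SINGLE = "single"
REPORT_ALL = "report_all"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Placement:
    """One ungapped placement of a read on a reference.

    ``aligned_seq`` is the read oriented to the reference forward strand
    (i.e. reverse-complemented for ``strand == '-'``); quality strings must
    be reversed by the caller for minus-strand placements.
    """

    reference: str
    offset: int  # 0-based start on the reference
    strand: str  # '+' or '-'
    mismatches: int
    aligned_seq: str


def _mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


class AmpliconIndex:
    """Seed index over a reference set for repeated read placement.

    Parameters are plumbing defaults for amplicon data: ``seed_length`` 20
    and ``max_mismatches`` 3 per read.
    """

    def __init__(
        self,
        references: dict[str, str],
        seed_length: int = 20,
        max_mismatches: int = 3,
    ) -> None:
        if seed_length < 1:
            raise ValueError("seed_length must be positive")
        self.references = {r: s.upper() for r, s in references.items()}
        self.seed_length = seed_length
        self.max_mismatches = max_mismatches
        self._index: dict[str, list[tuple[str, int]]] = {}
        for ref, seq in self.references.items():
            for i in range(len(seq) - seed_length + 1):
                self._index.setdefault(seq[i : i + seed_length], []).append((ref, i))

    def _candidates(self, read: str, strand: str):
        k = self.seed_length
        n = len(read)
        anchors = (0, max(0, (n - k) // 2))
        seen: set[tuple[str, int]] = set()
        for a in anchors:
            for ref, i in self._index.get(read[a : a + k], ()):
                off = i - a
                if off < 0 or off + n > len(self.references[ref]):
                    continue
                key = (ref, off)
                if key in seen:
                    continue
                seen.add(key)
                mm = _mismatches(read, self.references[ref][off : off + n], self.max_mismatches)
                if mm <= self.max_mismatches:
                    yield Placement(ref, off, strand, mm, read)

    def map_read(self, read: str, mode: str = SINGLE) -> list[Placement]:
        """Place one read; returns [] for unmapped or (single-mode) ambiguous reads."""
        if mode not in (SINGLE, REPORT_ALL):
            raise ValueError(f"unknown mode {mode!r}")
        read = read.upper()
        if len(read) < self.seed_length:
            return []
        placements = list(self._candidates(read, "+"))
        placements += list(self._candidates(revcomp(read), "-"))
        if not placements:
            return []
        if mode == REPORT_ALL:
            return placements
        best = min(p.mismatches for p in placements)
        top = [p for p in placements if p.mismatches == best]
        return top if len(top) == 1 else []


def map_read(
    read: str,
    references: dict[str, str],
    mode: str = SINGLE,
    seed_length: int = 20,
    max_mismatches: int = 3,
) -> list[Placement]:
    """One-shot convenience wrapper around :class:`AmpliconIndex`."""
    return AmpliconIndex(references, seed_length, max_mismatches).map_read(read, mode)
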