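"""Quality-stratified per-position base counts.

The caller's unit of evidence is "how many reads with base quality >= q show
base B at position p of reference R in library L".  :class:`CountsTensor`
stores, for every (library, reference), an integer array of shape
``(ref_length, 4, 42)`` indexed by position, base (A/C/G/T) and *exact*
Phred quality; counts at a quality cutoff are suffix sums over the last
axis, which makes the cutoff-monotonicity of filtered counts structural.

Counts can be built two ways and must agree on clean data:

* from the internal amplicon mapper (:mod:`tillseq.mapping`), or
* by importing ``samtools mpileup`` text (:func:`parse_mpileup` /
  :func:`counts_from_mpileup`).

Strands are pooled: reverse-strand reads are reverse-complemented before
counting, matching the case-folding of mpileup's ``.``/``,`` notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .mapping import REPORT_ALL, SINGLE, AmpliconIndex
from .simulate import encode_seq

MAX_QUAL = 41
_NQ = MAX_QUAL + 1
BASES = "ACGT"


class PileupParseError(ValueError):
    """Malformed mpileup text."""


class CountsError(ValueError):
    """Inconsistent tensor construction or lookup."""


@dataclass
class PileupColumn:
    """One parsed mpileup column: per-read (base, quality) observations.

    Deletion placeholders (``*``), reference skips and Ns consume a quality
    character but are excluded from base counts; indel insertions attached
    to a preceding base are skipped entirely.
    """

    reference: str
    position: int  # 1-based
    ref_base: str
    bases: list[str]
    quals: list[int]

    @property
    def depth(self) -> int:
        return sum(b in BASES for b in self.bases)

    def counts(self, min_quality: int = 0) -> dict[str, int]:
        out = {b: 0 for b in BASES}
        for b, q in zip(self.bases, self.quals):
            if b in out and q >= min_quality:
                out[b] += 1
        return out


def parse_mpileup(line: str, line_number: int | None = None) -> PileupColumn:
    """Decode one line of ``samtools mpileup`` text.

    ``.``/``,`` count toward the reference base; letters toward the named
    base regardless of case (strands pooled); ``^X`` (read start + mapping
    quality), ``$`` (read end) and ``+n<seq>``/``-n<seq>`` indel blocks are
    skipped.  Raises :class:`PileupParseError` when the base and quality
    columns disagree in length.
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(f"expected >=6 mpileup fields{where}: {line!r}")
    ref, pos_s, ref_base, depth_s, base_str, qual_str = fields[:6]
    ref_base = ref_base.upper()
    bases: list[str] = []
    quals: list[int] = []
    i = 0
    qi = 0
    n = len(base_str)
    while i < n:
        c = base_str[i]
        if c == "^":
            i += 2  # caret + mapping-quality char; no base consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and base_str[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"bad indel block{where}: {base_str[i:]!r}")
            i = j + int(base_str[i + 1 : j])
            continue
        if qi >= len(qual_str):
            raise PileupParseError(f"more bases than qualities{where}")
        q = ord(qual_str[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            bases.append(ref_base)
        elif c.upper() in BASES:
            bases.append(c.upper())
        elif c in "*<>nN":
            bases.append(c)  # consumes quality, never counted
        else:
            raise PileupParseError(f"unexpected pileup character {c!r}{where}")
        quals.append(q)
    if qi != len(qual_str):
        raise PileupParseError(
            f"base/quality length mismatch{where}: {len(qual_str) - qi} leftover qualities"
        )
    return PileupColumn(ref, int(pos_s), ref_base, bases, quals)


class CountsTensor:
    """Per-(library, reference, position) base counts stratified by quality."""

    def __init__(
        self,
        references: dict[str, str],
        libraries: Iterable[str],
        mode: str = SINGLE,
    ) -> None:
        if mode not in (SINGLE, REPORT_ALL):
            raise CountsError(f"unknown counting mode {mode!r}")
        self.references = {r: s.upper() for r, s in references.items()}
        self.libraries = tuple(libraries)
        self.mode = mode
        self.ref_codes = {r: encode_seq(s) for r, s in self.references.items()}
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def _arr(self, library: str, reference: str) -> np.ndarray:
        if library not in self.libraries:
            raise CountsError(f"unknown library {library!r}")
        if reference not in self.references:
            raise CountsError(f"unknown reference {reference!r}")
        key = (library, reference)
        if key not in self._data:
            L = len(self.references[reference])
            self._data[key] = np.zeros((L, 4, _NQ), dtype=np.int64)
        return self._data[key]

    # -- building -----------------------------------------------------------

    def add_batch(
        self,
        library: str,
        reference: str,
        offsets: Iterable[int],
        seqs: list[str],
        quals: list[str],
    ) -> None:
        """Accumulate aligned reads (already oriented to the forward strand).

        All reads in a batch must share one length; qualities are Phred+33
        strings in the same orientation as ``seqs``.
        """
        if not seqs:
            return
        arr = self._arr(library, reference)
        L = arr.shape[0]
        w = len(seqs[0])
        offs = np.asarray(list(offsets), dtype=np.int64)
        codes = encode_seq("".join(seqs)).reshape(len(seqs), w)
        q = (
            np.frombuffer("".join(quals).encode("ascii"), dtype=np.uint8)
            .reshape(len(seqs), w)
            .astype(np.int64)
            - 33
        )
        np.clip(q, 0, MAX_QUAL, out=q)
        pos = offs[:, None] + np.arange(w)
        keep = codes < 4
        flat = (pos[keep] * 4 + codes[keep]) * _NQ + q[keep]
        arr += np.bincount(flat.ravel(), minlength=L * 4 * _NQ).reshape(L, 4, _NQ)

    def add_pileup_column(self, library: str, col: PileupColumn) -> None:
        arr = self._arr(library, col.reference)
        if not 1 <= col.position <= arr.shape[0]:
            raise CountsError(
                f"position {col.position} outside {col.reference} "
                f"(length {arr.shape[0]})"
            )
        for b, q in zip(col.bases, col.quals):
            if b in BASES:
                arr[col.position - 1, BASES.index(b), min(max(q, 0), MAX_QUAL)] += 1

    # -- queries ------------------------------------------------------------

    def counts(self, library: str, reference: str, min_quality: int = 0) -> np.ndarray:
        """(L, 4) base counts at Phred >= ``min_quality``."""
        arr = self._arr(library, reference)
        return arr[:, :, min_quality:].sum(axis=2)

    def depth(self, library: str, reference: str, min_quality: int = 0) -> np.ndarray:
        return self.counts(library, reference, min_quality).sum(axis=1)

    def stacked_counts(self, reference: str, min_quality: int = 0) -> np.ndarray:
        """(n_libraries, L, 4) counts for every library, in library order."""
        return np.stack(
            [self.counts(lib, reference, min_quality) for lib in self.libraries]
        )

    def total_bases(self) -> int:
        return int(sum(a.sum() for a in self._data.values()))

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path, cutoffs: Iterable[int]) -> None:
        """Columnar dump: library, reference, pos, cutoff, A, C, G, T, depth."""
        with open(path, "w") as fh:
            fh.write("library\treference\tpos\tcutoff\tA\tC\tG\tT\tdepth\n")
            for lib in self.libraries:
                for ref in sorted(self.references):
                    if (lib, ref) not in self._data:
                        continue
                    for q in cutoffs:
                        c = self.counts(lib, ref, q)
                        d = c.sum(axis=1)
                        for p in range(c.shape[0]):
                            if d[p] == 0:
                                continue
                            fh.write(
                                f"{lib}\t{ref}\t{p + 1}\t{q}\t"
                                f"{c[p, 0]}\t{c[p, 1]}\t{c[p, 2]}\t{c[p, 3]}\t{d[p]}\n"
                            )


# ---------------------------------------------------------------------------
# builders


class _Accumulator:
    """Buffers aligned reads per (library, reference) and flushes in batches."""

    def __init__(self, tensor: CountsTensor, flush_at: int = 50_000) -> None:
        self.tensor = tensor
        self.flush_at = flush_at
        self._buf: dict[tuple[str, str], tuple[list, list, list]] = {}

    def add(self, library: str, reference: str, offset: int, seq: str, qual: str) -> None:
        offs, seqs, quals = self._buf.setdefault(
            (library, reference), ([], [], [])
        )
        offs.append(offset)
        seqs.append(seq)
        quals.append(qual)
        if len(offs) >= self.flush_at:
            self.flush_key((library, reference))

    def flush_key(self, key) -> None:
        offs, seqs, quals = self._buf.pop(key, ([], [], []))
        if offs:
            self.tensor.add_batch(key[0], key[1], offs, seqs, quals)

    def flush(self) -> None:
        for key in list(self._buf):
            self.flush_key(key)


def counts_from_reads(
    reads_by_library: dict[str, Iterable[tuple[str, str]]],
    references: dict[str, str],
    mode: str = SINGLE,
    seed_length: int = 20,
    max_mismatches: int = 3,
    index: AmpliconIndex | None = None,
) -> CountsTensor:
    """Map barcode-trimmed reads with the internal mapper and count them.

    ``reads_by_library`` maps library id -> iterable of (seq, qual).  Reads
    in one library typically repeat (amplicon data has few distinct start
    positions), so placements are memoized by sequence.
    """
    idx = index or AmpliconIndex(references, seed_length, max_mismatches)
    tensor = CountsTensor(references, reads_by_library.keys(), mode=mode)
    acc = _Accumulator(tensor)
    cache: dict[str, list] = {}
    for lib, reads in reads_by_library.items():
        for seq, qual in reads:
            placements = cache.get(seq)
            if placements is None:
                placements = idx.map_read(seq, mode)
                cache[seq] = placements
            for p in placements:
                q = qual if p.strand == "+" else qual[::-1]
                acc.add(lib, p.reference, p.offset, p.aligned_seq, q)
    acc.flush()
    return tensor


def counts_from_mpileup(
    pileups_by_library: dict[str, object],
    references: dict[str, str],
    mode: str = SINGLE,
) -> CountsTensor:
    """Import per-library ``samtools mpileup`` text (paths or line iterables)."""
    tensor = CountsTensor(references, pileups_by_library.keys(), mode=mode)
    for lib, source in pileups_by_library.items():
        for lineno, line in enumerate(_iter_lines(source), start=1):
            if not line.strip():
                continue
            tensor.add_pileup_column(lib, parse_mpileup(line, line_number=lineno))
    return tensor


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            yield from fh
    else:
        yield from source
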