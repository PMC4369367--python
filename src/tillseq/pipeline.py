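"""Streaming glue: multiplexed read pairs -> demultiplexed, counted evidence.

Keeps memory flat by demultiplexing and counting one batch of read pairs at
a time instead of materializing per-library FASTQ in between; the modular
stages (:mod:`tillseq.demux`, :mod:`tillseq.mapping`, :mod:`tillseq.counts`)
behave identically when run separately on files.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .counts import CountsTensor, _Accumulator
from .demux import DemuxReport, demultiplex_pairs
from .layout import PoolLayout
from .mapping import SINGLE, AmpliconIndex


def count_read_pairs(
    pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    layout: PoolLayout,
    references: dict[str, str],
    mode: str = SINGLE,
    seed_length: int = 20,
    max_mismatches: int = 3,
    min_barcode_quality: float = 10.0,
    chunk_size: int = 50_000,
) -> tuple[CountsTensor, DemuxReport]:
    """Demultiplex, map, and count a stream of barcoded read pairs."""
    index = AmpliconIndex(references, seed_length, max_mismatches)
    tensor = CountsTensor(references, layout.libraries, mode=mode)
    acc = _Accumulator(tensor)
    report = DemuxReport()
    cache: dict[str, list] = {}

    def sink(lib, pair):
        for seq, qual in pair:
            placements = cache.get(seq)
            if placements is None:
                placements = index.map_read(seq, mode)
                cache[seq] = placements
            for p in placements:
                q = qual if p.strand == "+" else qual[::-1]
                acc.add(lib, p.reference, p.offset, p.aligned_seq, q)

    for chunk in _chunks(pairs, chunk_size):
        demultiplex_pairs(
            chunk, layout,
            min_barcode_quality=min_barcode_quality,
            report=report, sink=sink,
        )
    acc.flush()
    return tensor, report


def _chunks(iterable, size) -> Iterator[list]:
    chunk: list = []
    for item in iterable:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk
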