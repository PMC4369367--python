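"""Barcode demultiplexing with mate-pair N repair.

Each mate of a pair starts with the same 5-base inline library barcode.  A
base the sequencer could not call is reported as ``N``; because the barcode
is duplicated across the two mates, an N in one mate can be repaired from
the other.  A pair is assigned only when the two repaired barcodes agree
and match a known library barcode exactly - there is no mismatch rescue
beyond N repair.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .layout import PoolLayout

#: discard reasons tracked by the report
DISCARD_REASONS = ("unknown", "conflict", "unrepairable", "low_quality")


class MalformedReadError(ValueError):
    """A barcode of the wrong length, or desynchronized mates."""


@dataclass
class DemuxReport:
    """Bookkeeping for one demultiplexing run.

    Invariant: ``sum(assigned.values()) + sum(discarded.values()) == total``.
    """

    assigned: Counter = field(default_factory=Counter)
    discarded: Counter = field(default_factory=Counter)
    repaired: int = 0
    total: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def merge(self, other: "DemuxReport") -> None:
        self.assigned.update(other.assigned)
        self.discarded.update(other.discarded)
        self.repaired += other.repaired
        self.total += other.total

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total,
            "assigned": dict(sorted(self.assigned.items())),
            "repaired": self.repaired,
            "discarded": {r: self.discarded.get(r, 0) for r in DISCARD_REASONS},
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("library\tpairs\n")
            for lib, n in sorted(self.assigned.items()):
                fh.write(f"{lib}\t{n}\n")
            for reason in DISCARD_REASONS:
                fh.write(f"discarded:{reason}\t{self.discarded.get(reason, 0)}\n")
            fh.write(f"repaired\t{self.repaired}\n")


def repair_barcode(
    bc1: str, bc2: str, known_barcodes: dict[str, str] | set[str] | frozenset[str]
) -> tuple[str | None, str]:
    """Reconcile the two mates' barcodes and match against the known set.

    Returns ``(barcode, status)`` where status is one of ``ok`` (exact,
    no repair needed), ``repaired`` (an N was filled from the mate), or a
    discard reason ``unknown`` / ``conflict`` / ``unrepairable`` with
    barcode ``None``.  N repair never alters a called (non-N) base; two
    called bases that disagree are a conflict.
    """
    if len(bc1) != len(bc2):
        raise MalformedReadError(f"mate barcodes differ in length: {bc1!r} vs {bc2!r}")
    if isinstance(known_barcodes, dict):
        known = set(known_barcodes.values())
    else:
        known = set(known_barcodes)
    expected_len = len(next(iter(known))) if known else 5
    if len(bc1) != expected_len:
        raise MalformedReadError(f"barcode {bc1!r} is not length {expected_len}")

    merged = []
    for a, b in zip(bc1, bc2):
        if a == b:
            merged.append(a)
        elif a == "N":
            merged.append(b)
        elif b == "N":
            merged.append(a)
        else:
            return None, "conflict"
    bc = "".join(merged)
    if "N" in bc:
        return None, "unrepairable"
    if bc not in known:
        return None, "unknown"
    status = "ok" if bc == bc1 == bc2 else "repaired"
    return bc, status


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
    """Iterate synchronized ((seq, qual), (seq, qual)) mate pairs.

    Raises :class:`MalformedReadError` when the two files desynchronize
    (different read names or lengths).
    """
    import pysam

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        it2 = iter(f2)
        for rec1 in f1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise MalformedReadError("mate files desynchronized: R2 exhausted first")
            n1 = rec1.name.rsplit("/", 1)[0]
            n2 = rec2.name.rsplit("/", 1)[0]
            if n1 != n2:
                raise MalformedReadError(f"desynchronized mates: {rec1.name} vs {rec2.name}")
            yield (rec1.sequence, rec1.quality), (rec2.sequence, rec2.quality)
        if next(it2, None) is not None:
            raise MalformedReadError("mate files desynchronized: R1 exhausted first")


def demultiplex_pairs(
    pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    layout: PoolLayout,
    min_barcode_quality: float = 10.0,
    report: DemuxReport | None = None,
    sink=None,
) -> tuple[dict[str, list], DemuxReport]:
    """Assign read pairs to libraries, trimming barcodes from the output.

    ``sink(library, (r1, r2))`` may be supplied to stream assigned pairs
    elsewhere (e.g. straight into the aligner); otherwise trimmed pairs are
    collected per library and returned.  Pairs whose mean barcode quality
    (over both mates) falls below ``min_barcode_quality`` are discarded as
    ``low_quality`` before any repair is attempted.
    """
    blen = layout.barcode_length
    barcode_to_lib = {bc: lib for lib, bc in layout.barcode_map.items()}
    known = frozenset(barcode_to_lib)
    rep = report if report is not None else DemuxReport()
    out: dict[str, list] = {lib: [] for lib in layout.libraries}

    for (s1, q1), (s2, q2) in pairs:
        rep.total += 1
        if len(s1) < blen or len(s2) < blen:
            raise MalformedReadError("read shorter than barcode")
        bq = [ord(c) - 33 for c in q1[:blen]] + [ord(c) - 33 for c in q2[:blen]]
        if sum(bq) / len(bq) < min_barcode_quality:
            rep.discarded["low_quality"] += 1
            continue
        bc, status = repair_barcode(s1[:blen], s2[:blen], known)
        if bc is None:
            rep.discarded[status] += 1
            continue
        if status == "repaired":
            rep.repaired += 1
        lib = barcode_to_lib[bc]
        rep.assigned[lib] += 1
        trimmed = ((s1[blen:], q1[blen:]), (s2[blen:], q2[blen:]))
        if sink is not None:
            sink(lib, trimmed)
        else:
            out[lib].append(trimmed)
    return out, rep


def demultiplex(
    r1_path,
    r2_path,
    layout: PoolLayout,
    outdir,
    min_barcode_quality: float = 10.0,
) -> DemuxReport:
    """File-level demultiplexing: FASTQ pair in, per-library FASTQ pairs out.

    Writes ``<library>_R1.fastq`` / ``<library>_R2.fastq`` plus
    ``demux_report.tsv`` and ``demux_report.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, tuple] = {}
    counters = {lib: 0 for lib in layout.libraries}

    def sink(lib, pair):
        if lib not in handles:
            handles[lib] = (
                open(outdir / f"{lib}_R1.fastq", "w"),
                open(outdir / f"{lib}_R2.fastq", "w"),
            )
        f1, f2 = handles[lib]
        counters[lib] += 1
        (s1, q1), (s2, q2) = pair
        f1.write(f"@{lib}_{counters[lib]}/1\n{s1}\n+\n{q1}\n")
        f2.write(f"@{lib}_{counters[lib]}/2\n{s2}\n+\n{q2}\n")

    try:
        _, report = demultiplex_pairs(
            iter_fastq_pairs(r1_path, r2_path),
            layout,
            min_barcode_quality=min_barcode_quality,
            sink=sink,
        )
    finally:
        for f1, f2 in handles.values():
            f1.close()
            f2.close()
    report.write_tsv(outdir / "demux_report.tsv")
    report.write_json(outdir / "demux_report.json")
    return report
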