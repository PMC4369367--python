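"""Ground-truthed synthetic data for the pooled-amplicon mutation screen.

Three stages mirror the wet-lab workflow:

1. :func:`simulate_population` plants EMS-style point mutations (dominated by
   G->A / C->T transitions) into a plated population of diploid individuals.
2. :func:`pool_composition` converts planted mutations into per-library
   allele dosages under the two-dimensional pooling arithmetic: a mutant
   allele present on ``z`` chromosomes of one individual contributes
   ``z / (2 * pool_size)`` of the chromosomes in each superpool containing
   that individual.
3. :func:`generate_read_batches` / :func:`generate_read_pairs` emit barcoded
   paired-end reads from each library's allele mixture with Phred-consistent
   substitution errors (per-base error probability ``10**(-Q/10)``).

All randomness flows from a single ``numpy`` generator seeded per call, so
every output is reproducible from its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .layout import PoolLayout

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_BYTE_OF_CODE = np.frombuffer(b"ACGTN", dtype=np.uint8).copy()
_CODE_OF_BYTE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_OF_BYTE[ord(_b)] = _i

#: canonical EMS substitutions as written on the reference strand
CANONICAL = {("G", "A"), ("C", "T")}

TRUTH_COLUMNS = [
    "plate", "row", "col", "reference", "position",
    "ref_base", "alt", "zygosity", "canonical",
]


class SimulationError(ValueError):
    """Bad simulator inputs (empty references, rates outside [0, 1], ...)."""


def encode_seq(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes 0..4."""
    return _CODE_OF_BYTE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_rows(mat: np.ndarray) -> list[str]:
    """(n, w) uint8 code matrix -> list of n strings."""
    n, w = mat.shape
    blob = _BYTE_OF_CODE[mat].tobytes()
    return [blob[i * w : (i + 1) * w].decode("ascii") for i in range(n)]


def _qual_strings(qmat: np.ndarray) -> list[str]:
    n, w = qmat.shape
    blob = (qmat.astype(np.uint8) + 33).tobytes()
    return [blob[i * w : (i + 1) * w].decode("ascii") for i in range(n)]


@dataclass
class ReadModel:
    """Read-emission model for the amplicon sequencer.

    The default 94 bp read length matches the screen's full-length reads and
    includes the 5-base inline library barcode, leaving 89 genomic bases per
    mate.  Base qualities are drawn i.i.d. from a discrete mixture whose
    small low-quality tail makes the quality-filtered background mismatch
    rate fall from ~0.04% at cutoff 10 to ~0.015% at cutoff >=19 - the
    behaviour that makes per-cutoff minimum-percentage thresholds meaningful.
    Substitution errors are Phred-consistent: a base of quality Q is wrong
    with probability ``error_scale * 10**(-Q/10) + context_error_rate``
    (the latter models quality-blind artifacts such as PCR errors and
    defaults to 0).
    """

    read_length: int = 94
    barcode_length: int = 5
    quality_values: tuple[int, ...] = (11, 13, 16, 18, 37, 41)
    quality_probs: tuple[float, ...] = (0.001, 0.0005, 0.006, 0.002, 0.55, 0.4405)
    mean_depth: float = 5000.0
    paired: bool = True
    barcode_n_rate: float = 0.0
    error_scale: float = 1.0
    context_error_rate: float = 0.0
    fragment_range: tuple[int, int] = (160, 260)
    #: share of fragments that are amplicon-terminal.  Fragmentation of an
    #: amplicon molecule always yields the two fragments carrying the
    #: amplicon ends, so coverage does not collapse at the termini.
    terminal_fraction: float = 0.3
    barcode_quality: int = 37

    def __post_init__(self) -> None:
        if not all(2 <= q <= 41 for q in self.quality_values):
            raise SimulationError("quality values must lie in [2, 41]")
        if abs(sum(self.quality_probs) - 1.0) > 1e-9:
            raise SimulationError("quality probabilities must sum to 1")
        if self.read_length <= self.barcode_length:
            raise SimulationError("read_length must exceed barcode_length")

    @property
    def genomic_length(self) -> int:
        """Genomic bases per mate after the inline barcode."""
        return self.read_length - self.barcode_length


# ---------------------------------------------------------------------------
# stage 1: the mutagenized population


def simulate_population(
    layout: PoolLayout,
    references: dict[str, str],
    mutation_rate: float = 1.3e-5,
    canonical_fraction: float = 0.85,
    het_fraction: float = 2 / 3,
    seed: int | None = None,
    unique_sites: bool = False,
) -> pd.DataFrame:
    """Plant EMS-style mutations into every individual of the plated population.

    Each individual accrues ``Poisson(mutation_rate * total_bp)`` mutations at
    uniform positions.  A mutation is canonical (G->A or C->T on the written
    strand) with probability ``canonical_fraction``, in which case it lands on
    a G/C site; otherwise position and substitution are uniform over the
    remaining possibilities.  Zygosity is heterozygous with probability
    ``het_fraction`` (default 2/3, the expectation for a selfed M2
    generation).

    ``unique_sites=True`` additionally forbids two individuals from carrying
    a mutation at the same (reference, position).  At realistic per-site hit
    rates recurrence is negligible anyway; the option restores that regime
    when the rate is compressed to put many mutations into a short region.

    Returns the truth ledger: one row per planted (individual, site) with
    columns ``plate,row,col,reference,position,ref_base,alt,zygosity,canonical``.
    """
    if not references:
        raise SimulationError("references must be non-empty")
    for frac, name in [
        (mutation_rate, "mutation_rate"),
        (canonical_fraction, "canonical_fraction"),
        (het_fraction, "het_fraction"),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise SimulationError(f"{name} must lie in [0, 1], got {frac}")

    rng = np.random.default_rng(seed)
    ref_ids = sorted(references)
    lengths = np.array([len(references[r]) for r in ref_ids])
    total_bp = int(lengths.sum())
    starts = np.concatenate([[0], np.cumsum(lengths)])

    # global site table: (ref index, 1-based position, ref base code)
    all_codes = np.concatenate([encode_seq(references[r]) for r in ref_ids])
    gc_sites = np.flatnonzero((all_codes == _CODE["G"]) | (all_codes == _CODE["C"]))

    individuals = [
        (plate, row, col)
        for plate in range(1, layout.n_plates + 1)
        for row in layout.row_labels
        for col in layout.col_labels
    ]
    n_muts = rng.poisson(mutation_rate * total_bp, size=len(individuals))

    records: list[tuple] = []
    used_sites: set[tuple[str, int]] = set()
    per_indiv_sites: dict[tuple, set[int]] = {}
    for (indiv, k) in zip(individuals, n_muts):
        taken = per_indiv_sites.setdefault(indiv, set())
        planted = 0
        attempts = 0
        while planted < k:
            attempts += 1
            if attempts > 100 * (k + 1):
                warnings.warn("could not place all mutations (references saturated)")
                break
            if rng.random() < canonical_fraction:
                if gc_sites.size == 0:
                    continue
                gpos = int(gc_sites[rng.integers(gc_sites.size)])
                ref_code = int(all_codes[gpos])
                alt = "A" if BASES[ref_code] == "G" else "T"
                canonical = True
            else:
                gpos = int(rng.integers(total_bp))
                ref_code = int(all_codes[gpos])
                choices = [
                    b for b in BASES
                    if b != BASES[ref_code] and (BASES[ref_code], b) not in CANONICAL
                ]
                alt = choices[rng.integers(len(choices))]
                canonical = False
            ridx = int(np.searchsorted(starts, gpos, side="right")) - 1
            ref = ref_ids[ridx]
            pos = int(gpos - starts[ridx]) + 1
            if gpos in taken:
                continue
            if unique_sites and (ref, pos) in used_sites:
                continue
            taken.add(gpos)
            used_sites.add((ref, pos))
            zyg = "het" if rng.random() < het_fraction else "hom"
            records.append(
                (indiv[0], indiv[1], indiv[2], ref, pos, BASES[ref_code], alt, zyg, canonical)
            )
            planted += 1

    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    return truth.sort_values(["reference", "position", "plate", "row", "col"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# stage 2: pooling arithmetic


def pool_composition(truth: pd.DataFrame, layout: PoolLayout) -> pd.DataFrame:
    """Per-library allele dosages implied by the truth ledger.

    Each planted mutation contributes to exactly two libraries: its row
    superpool at dosage ``z / (2 * row_pool_size)`` and its column superpool
    at ``z / (2 * col_pool_size)`` with ``z = 2`` for homozygotes and 1 for
    heterozygotes.  Returns a tidy frame with one row per (mutation, library).
    """
    rows: list[dict] = []
    for rec in truth.itertuples(index=False):
        z = 2 if rec.zygosity == "hom" else 1
        for axis, label, pool in [
            ("row", rec.row, layout.row_pool_size),
            ("column", rec.col, layout.col_pool_size),
        ]:
            rows.append(
                {
                    "reference": rec.reference,
                    "position": rec.position,
                    "ref_base": rec.ref_base,
                    "alt": rec.alt,
                    "zygosity": rec.zygosity,
                    "plate": rec.plate,
                    "row": rec.row,
                    "col": rec.col,
                    "library": layout.library_for(axis, str(label)),
                    "dosage": z / (2 * pool),
                }
            )
    cols = [
        "reference", "position", "ref_base", "alt", "zygosity",
        "plate", "row", "col", "library", "dosage",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# stage 3: read emission


@dataclass
class ReadBatch:
    """A block of barcoded read pairs from one (library, reference)."""

    library: str
    reference: str
    r1_seq: list[str]
    r1_qual: list[str]
    r2_seq: list[str]
    r2_qual: list[str]

    def __len__(self) -> int:
        return len(self.r1_seq)

    def pairs(self) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
        yield from zip(
            zip(self.r1_seq, self.r1_qual), zip(self.r2_seq, self.r2_qual)
        )


def generate_read_batches(
    dosages: pd.DataFrame,
    references: dict[str, str],
    model: ReadModel,
    layout: PoolLayout,
    seed: int | None = None,
    chunk_size: int = 50_000,
    libraries: Iterable[str] | None = None,
) -> Iterator[ReadBatch]:
    """Yield barcoded paired-end reads library by library.

    For each (library, reference) the number of fragments is chosen so mean
    genomic coverage equals ``model.mean_depth``.  Fragments start uniformly
    along the amplicon with lengths uniform over ``model.fragment_range``
    (clipped to the amplicon); mate 1 reads the fragment 5' end on the
    forward strand, mate 2 the 3' end reverse-complemented.  A fragment
    carries a planted mutation with probability equal to that mutation's
    library dosage, so both mates agree.  Sequencing errors and barcode Ns
    are then applied per base.
    """
    rng = np.random.default_rng(seed)
    glen = model.genomic_length
    qvals = np.array(model.quality_values)
    qprobs = np.array(model.quality_probs)
    err_of_q = 10.0 ** (-np.arange(42) / 10.0)

    by_lib_ref: dict[tuple[str, str], list] = {}
    if len(dosages):
        for (lib, ref), grp in dosages.groupby(["library", "reference"]):
            by_lib_ref[(lib, ref)] = [
                (int(p) - 1, _CODE[a], float(d))
                for p, a, d in zip(grp["position"], grp["alt"], grp["dosage"])
            ]

    emit_libs = tuple(libraries) if libraries is not None else layout.libraries
    for lib in emit_libs:
        barcode = layout.barcode_map[lib]
        bc_codes = encode_seq(barcode)
        for ref_id in sorted(references):
            ref_codes = encode_seq(references[ref_id])
            L = ref_codes.size
            if L < glen:
                raise SimulationError(
                    f"reference {ref_id} shorter than genomic read length {glen}"
                )
            n_pairs = int(round(model.mean_depth * L / (2 * glen)))
            if n_pairs == 0:
                warnings.warn(f"depth 0 for {lib}/{ref_id}: emitting no reads")
                continue
            muts = by_lib_ref.get((lib, ref_id), [])
            for lo in range(0, n_pairs, chunk_size):
                n = min(chunk_size, n_pairs - lo)
                yield _emit_chunk(
                    rng, lib, ref_id, ref_codes, bc_codes, muts, n, model,
                    glen, qvals, qprobs, err_of_q,
                )


def _emit_chunk(
    rng, lib, ref_id, ref_codes, bc_codes, muts, n, model, glen, qvals, qprobs, err_of_q
) -> ReadBatch:
    L = ref_codes.size
    fmin, fmax = model.fragment_range
    fmin = max(glen, min(fmin, L))
    fmax = max(fmin, min(fmax, L))
    flen = rng.integers(fmin, fmax + 1, size=n)
    start = (rng.random(n) * (L - flen + 1)).astype(np.int64)
    t = model.terminal_fraction
    if t > 0:
        u = rng.random(n)
        start[u < t / 2] = 0
        right = (u >= t / 2) & (u < t)
        start[right] = (L - flen)[right]
    end = start + flen

    offs = np.arange(glen)
    r1 = ref_codes[start[:, None] + offs]
    r2 = ref_codes[(end - glen)[:, None] + offs]
    # reverse-complement mate 2
    r2 = (3 - r2)[:, ::-1]

    # planted mutations: decided per fragment so mates agree
    for pos0, alt_code, dosage in muts:
        carrier = rng.random(n) < dosage
        if not carrier.any():
            continue
        c1 = pos0 - start
        m1 = carrier & (c1 >= 0) & (c1 < glen)
        r1[np.flatnonzero(m1), c1[m1]] = alt_code
        c2 = end - 1 - pos0
        m2 = carrier & (c2 >= 0) & (c2 < glen)
        r2[np.flatnonzero(m2), c2[m2]] = 3 - alt_code

    out_seq: list[list[str]] = []
    out_qual: list[list[str]] = []
    for mate in (r1, r2):
        q = qvals[rng.choice(qvals.size, size=(n, glen), p=qprobs)]
        p_err = err_of_q[q] * model.error_scale + model.context_error_rate
        if model.error_scale > 0 or model.context_error_rate > 0:
            hit = rng.random((n, glen)) < p_err
            k = int(hit.sum())
            if k:
                mate[hit] = (mate[hit] + rng.integers(1, 4, size=k)) % 4
        # prepend barcode (with optional Ns) and its quality
        bc = np.broadcast_to(bc_codes, (n, bc_codes.size)).copy()
        if model.barcode_n_rate > 0:
            bc[rng.random(bc.shape) < model.barcode_n_rate] = 4
        full = np.concatenate([bc, mate], axis=1)
        fullq = np.concatenate(
            [np.full(bc.shape, model.barcode_quality, dtype=np.int64), q], axis=1
        )
        out_seq.append(decode_rows(full))
        out_qual.append(_qual_strings(fullq))

    return ReadBatch(
        library=lib,
        reference=ref_id,
        r1_seq=out_seq[0],
        r1_qual=out_qual[0],
        r2_seq=out_seq[1],
        r2_qual=out_qual[1],
    )


def generate_read_pairs(
    dosages: pd.DataFrame,
    references: dict[str, str],
    model: ReadModel,
    layout: PoolLayout,
    seed: int | None = None,
) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
    """Flat iterator of ((r1_seq, r1_qual), (r2_seq, r2_qual)) pairs."""
    for batch in generate_read_batches(dosages, references, model, layout, seed):
        yield from batch.pairs()


def write_fastq(
    pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    r1_path,
    r2_path,
    name_prefix: str = "sim",
) -> int:
    """Write paired reads as Phred+33 FASTQ; returns the pair count."""
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for (s1, q1), (s2, q2) in pairs:
            n += 1
            f1.write(f"@{name_prefix}_{n}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name_prefix}_{n}/2\n{s2}\n+\n{q2}\n")
    return n


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_dosages(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index=False)
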