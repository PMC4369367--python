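"""Two-dimensional pool geometry for TILLING-by-sequencing screens.

A mutagenized population is arrayed in ``n_plates`` 96-well plates.  The
plates are stacked into a single "micropool" plate (well A1 of every plate
contributes to micropool well A1, and so on), and the micropool is then
collapsed along each axis: one superpool library per row (containing
``n_cols * n_plates`` individuals) and one per column (``n_rows * n_plates``
individuals).  A rare mutation therefore shows up in exactly one row library
and one column library, and the row x column intersection identifies the
micropool well; the ``n_plates`` individuals stacked at that well remain to
be resolved by genotyping.

With the default 8-plate geometry a row superpool holds 96 individuals and a
column superpool holds 64, so the same mutant allele is ~1.5x more
concentrated in its column library than in its row library.  The exact ratio
(64/96 = 2/3, printed as 0.67) is the *dilution factor* used to bring column
percentages onto the row scale before thresholding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import yaml

ROW = "row"
COLUMN = "column"

_BARCODE_ALPHABET = frozenset("ACGT")


class LayoutError(ValueError):
    """Invalid pooling geometry or barcode table."""


class AxisError(LayoutError):
    """Two libraries from the same pooling axis where one per axis is needed."""


def default_barcodes(n: int, length: int = 5, min_distance: int = 3) -> list[str]:
    """Deterministic barcode set: greedy selection of ``n`` k-mers with
    pairwise Hamming distance >= ``min_distance``.

    The distance-3 spacing means a single sequencing error cannot turn one
    barcode into another, and an N repaired from the mate is unambiguous.
    """
    chosen: list[str] = []
    for kmer in itertools.product("ACGT", repeat=length):
        cand = "".join(kmer)
        if all(_hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise LayoutError(f"cannot construct {n} barcodes of length {length}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class WellAddress:
    """A deconvolved micropool well and its candidate individuals.

    ``candidates`` lists the (plate, well) coordinates stacked at this
    micropool position - one per plate - since superpool sequencing alone
    cannot distinguish between them.
    """

    row: str
    column: str
    candidates: tuple[tuple[int, str], ...]

    @property
    def well(self) -> str:
        return f"{self.row}{self.column}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.well


@dataclass
class PoolLayout:
    """Plate/row/column pooling geometry and the library barcode table.

    Parameters
    ----------
    n_plates
        Number of 96-well plates stacked into the micropool (default 8,
        i.e. 768 individuals).
    row_labels, col_labels
        Well labels; defaults follow the standard 96-well convention
        (rows A-H, columns 1-12).
    barcode_map
        library id -> 5-base barcode.  Libraries are named ``row_A`` ...
        ``row_H`` and ``col_1`` ... ``col_12``.  When omitted a
        deterministic default barcode set is assigned.
    """

    n_plates: int = 8
    row_labels: tuple[str, ...] = tuple("ABCDEFGH")
    col_labels: tuple[str, ...] = tuple(str(i) for i in range(1, 13))
    barcode_map: dict[str, str] = field(default_factory=dict)
    barcode_length: int = 5

    def __post_init__(self) -> None:
        if self.n_plates < 1 or not self.row_labels or not self.col_labels:
            raise LayoutError("layout needs >=1 plate, row, and column")
        self.row_labels = tuple(str(r) for r in self.row_labels)
        self.col_labels = tuple(str(c) for c in self.col_labels)
        if not self.barcode_map:
            codes = default_barcodes(len(self.libraries), self.barcode_length)
            self.barcode_map = dict(zip(self.libraries, codes))
        self.validate()

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    @property
    def n_cols(self) -> int:
        return len(self.col_labels)

    @property
    def row_libraries(self) -> tuple[str, ...]:
        return tuple(f"row_{r}" for r in self.row_labels)

    @property
    def col_libraries(self) -> tuple[str, ...]:
        return tuple(f"col_{c}" for c in self.col_labels)

    @property
    def libraries(self) -> tuple[str, ...]:
        return self.row_libraries + self.col_libraries

    @property
    def row_pool_size(self) -> int:
        """Individuals per row superpool (default 12 x 8 = 96)."""
        return self.n_cols * self.n_plates

    @property
    def col_pool_size(self) -> int:
        """Individuals per column superpool (default 8 x 8 = 64)."""
        return self.n_rows * self.n_plates

    @property
    def n_individuals(self) -> int:
        return self.n_plates * self.n_rows * self.n_cols

    def axis_of(self, library: str) -> str:
        if library in self.row_libraries:
            return ROW
        if library in self.col_libraries:
            return COLUMN
        raise LayoutError(f"unknown library {library!r}")

    def pool_size(self, library: str) -> int:
        return self.row_pool_size if self.axis_of(library) == ROW else self.col_pool_size

    def library_for(self, axis: str, label: str) -> str:
        prefix = {ROW: "row", COLUMN: "col"}[axis]
        lib = f"{prefix}_{label}"
        if lib not in self.barcode_map:
            raise LayoutError(f"no library {lib!r} in layout")
        return lib

    def validate(self) -> None:
        libs = self.libraries
        if set(self.barcode_map) != set(libs):
            raise LayoutError("barcode map must cover exactly the row+column libraries")
        seen: set[str] = set()
        for lib, bc in self.barcode_map.items():
            if len(bc) != self.barcode_length:
                raise LayoutError(f"barcode {bc!r} for {lib} is not length {self.barcode_length}")
            if not set(bc) <= _BARCODE_ALPHABET:
                raise LayoutError(f"barcode {bc!r} for {lib} has bases outside ACGT")
            if bc in seen:
                raise LayoutError(f"duplicate barcode {bc!r}")
            seen.add(bc)

    # -- pooled-fraction arithmetic ----------------------------------------

    def dilution_factor(self) -> Fraction:
        """Column-to-row pool-size ratio as an exact fraction (default 2/3).

        Multiplying a column library's non-reference percentage by this
        factor puts it on the row-library scale, so a single min/max
        threshold applies to both axes.  Presentation rounds to 0.67.
        """
        return Fraction(self.col_pool_size, self.row_pool_size)


def expected_mutant_fraction(pool_size: int, zygosity: str) -> Fraction:
    """Expected percentage of reads carrying a mutant allele in a pool.

    A pool of ``pool_size`` diploid individuals contributes ``2 * pool_size``
    chromosomes; a homozygote carries the allele on 2 of its chromosomes, a
    heterozygote on 1.  Returned as an exact ``Fraction`` on the percentage
    scale (e.g. 100/96 for a homozygote in a 96-individual pool, printed as
    1.04); round only at presentation.
    """
    if pool_size < 1:
        raise LayoutError(f"pool_size must be >= 1, got {pool_size}")
    if zygosity == "hom":
        return Fraction(100, pool_size)
    if zygosity == "het":
        return Fraction(100, 2 * pool_size)
    raise ValueError(f"zygosity must be 'hom' or 'het', got {zygosity!r}")


def deconvolve(row_library: str, column_library: str, layout: PoolLayout) -> WellAddress:
    """Resolve a (row library, column library) hit pair to its micropool well.

    Raises :class:`AxisError` if both libraries sit on the same pooling axis.
    """
    axes = (layout.axis_of(row_library), layout.axis_of(column_library))
    if axes != (ROW, COLUMN):
        raise AxisError(
            f"need one row and one column library, got axes {axes[0]}/{axes[1]}"
        )
    row = row_library.split("_", 1)[1]
    col = column_library.split("_", 1)[1]
    well = f"{row}{col}"
    candidates = tuple((plate, well) for plate in range(1, layout.n_plates + 1))
    return WellAddress(row=row, column=col, candidates=candidates)


def dilution_factor(layout: PoolLayout) -> Fraction:
    """Module-level alias for :meth:`PoolLayout.dilution_factor`."""
    return layout.dilution_factor()


# -- layout file I/O -------------------------------------------------------


def save_layout(layout: PoolLayout, path) -> None:
    doc = {
        "plates": layout.n_plates,
        "rows": list(layout.row_labels),
        "cols": list(layout.col_labels),
        "barcodes": [
            {"library": lib, "axis": layout.axis_of(lib), "barcode": bc}
            for lib, bc in layout.barcode_map.items()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_layout(path) -> PoolLayout:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        barcodes = {e["library"]: e["barcode"] for e in doc.get("barcodes", [])}
        layout = PoolLayout(
            n_plates=int(doc["plates"]),
            row_labels=tuple(str(r) for r in doc["rows"]),
            col_labels=tuple(str(c) for c in doc["cols"]),
            barcode_map=barcodes,
        )
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"malformed layout file {path}: {exc}") from exc
    return layout
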