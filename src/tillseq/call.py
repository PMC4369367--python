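"""Rare-mutation calling from pooled superpool libraries.

Two callers share the same evidence structure (a :class:`~tillseq.counts.CountsTensor`)
and the same uniqueness-plus-deconvolution logic, but differ in the statistic
thresholded:

* :func:`call_single_copy` - for single-copy amplicons.  A candidate at a
  quality cutoff is an alternate base whose non-reference percentage
  (column libraries scaled by the 2/3 dilution factor) falls within
  ``[min%, max%]`` in exactly one row and exactly one column library, and
  which dominates every other non-reference base at the position in both
  hit libraries.  Per-cutoff candidate sets are then partitioned into
  common / high / low quality groups.

* :func:`call_multi_copy` - for multi-copy amplicons counted in
  ``report_all`` mode, where the allele signal is diluted across copies and
  a fixed percentage band is too blunt.  Each library's non-reference
  fraction is instead compared with the mean fraction of the *other*
  libraries on its axis (the variance multiplier); a candidate needs a
  multiplier above the threshold in exactly one row and one column library
  plus a small raw-percentage floor (0.05%).  Sites of fixed divergence
  between gene copies light up every library equally, giving multipliers
  near 1, and are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .counts import CountsTensor
from .layout import PoolLayout, WellAddress, deconvolve
from .mapping import REPORT_ALL

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: per-cutoff minimum non-reference percentage calibrated on the screen's
#: six known single-copy mutants (min quality -> min %)
DEFAULT_MIN_PCT = {
    10: 0.370, 12: 0.370, 14: 0.370, 15: 0.370, 16: 0.360,
    17: 0.190, 18: 0.170, 19: 0.170, 20: 0.135, 21: 0.058,
}


class CallError(ValueError):
    """Misconfigured caller parameters or incompatible counts."""


@dataclass
class SingleCopyParams:
    """Thresholds for the single-copy percentage caller.

    ``min_pct`` maps each quality cutoff to its minimum adjusted
    non-reference percentage; ``max_pct`` (default 5%) rejects common
    polymorphisms and paralog bleed-through; ``dominance_ratio`` requires
    the candidate alternate base to out-count every other non-reference
    base by this factor in both hit libraries.
    """

    min_pct: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_MIN_PCT))
    max_pct: float = 5.0
    dilution: Fraction = Fraction(2, 3)
    dominance_ratio: float = 2.0

    @property
    def cutoffs(self) -> tuple[int, ...]:
        return tuple(sorted(self.min_pct))

    def __post_init__(self) -> None:
        for q, m in self.min_pct.items():
            if not 0 < m < self.max_pct <= 100:
                raise CallError(f"need 0 < min% < max% <= 100 at cutoff {q}")


@dataclass
class MultiCopyParams:
    """Grids for the multi-copy variance-multiplier caller.

    ``multipliers`` spans the full exploration grid (2-20); calibration on
    the screen's known mutants selects working values in the 8-14 range.
    ``epsilon`` guards the background denominator; ``None`` uses one read
    equivalent at the reference's mean depth.
    """

    qualities: tuple[int, ...] = tuple(range(16, 24))
    multipliers: tuple[float, ...] = tuple(range(2, 21))
    min_pct: float = 0.05
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.min_pct <= 0:
            raise CallError("min_pct must be positive")
        if any(m <= 1 for m in self.multipliers):
            raise CallError("variance multipliers must exceed 1")


@dataclass
class CandidateMutation:
    """A called (reference, position, alternate) with its 2D evidence."""

    reference: str
    position: int  # 1-based
    ref_base: str
    alt: str
    row_library: str
    col_library: str
    pct_row: float
    pct_col_raw: float
    pct_col_adj: float
    well: WellAddress
    cutoffs: tuple[int, ...] = ()
    group: str = ""

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.reference, self.position, self.alt)


def nonref_percentages(
    counts: CountsTensor,
    library: str,
    reference: str,
    position: int,
    cutoff: int,
    layout: PoolLayout,
    dilution: Fraction = Fraction(2, 3),
) -> dict[str, dict[str, float]]:
    """Raw and dilution-adjusted percentage of each alternate base at a cell.

    Column-library values are multiplied by the dilution factor so they sit
    on the row-library scale; row-library values are unchanged.  Returns
    ``{alt: {"raw": ..., "adjusted": ...}}``; a depth-0 cell yields ``{}``
    and a log message rather than an error.
    """
    c = counts.counts(library, reference, cutoff)[position - 1]
    depth = int(c.sum())
    if depth == 0:
        logger.info("depth 0 at %s:%s pos %d (cutoff %d); skipped",
                    library, reference, position, cutoff)
        return {}
    scale = float(dilution) if layout.axis_of(library) == "column" else 1.0
    ref_code = int(counts.ref_codes[reference][position - 1])
    out = {}
    for b in range(4):
        if b == ref_code:
            continue
        raw = 100.0 * c[b] / depth
        out[BASES[b]] = {"raw": raw, "adjusted": raw * scale}
    return out


def _percent_arrays(counts, layout, reference, cutoff, dilution):
    """(pct, adj, C, depth, ref_codes, row_idx, col_idx) for one reference."""
    C = counts.stacked_counts(reference, cutoff).astype(float)  # (nlib, L, 4)
    depth = C.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(depth[:, :, None] > 0, 100.0 * C / depth[:, :, None], 0.0)
    libs = counts.libraries
    col_mask = np.array([layout.axis_of(lib) == "column" for lib in libs])
    adj = pct.copy()
    adj[col_mask] *= float(dilution)
    row_idx = np.flatnonzero(~col_mask)
    col_idx = np.flatnonzero(col_mask)
    return pct, adj, C, depth, counts.ref_codes[reference], row_idx, col_idx


def _dominates(c_lib: np.ndarray, alt: int, ref_code: int, ratio: float) -> bool:
    for b in range(4):
        if b in (alt, ref_code):
            continue
        if c_lib[alt] < ratio * c_lib[b]:
            return False
    return True


def _make_candidate(counts, layout, reference, pos0, alt, ref_codes,
                    pct, adj, row_i, col_i) -> CandidateMutation:
    libs = counts.libraries
    row_lib, col_lib = libs[row_i], libs[col_i]
    return CandidateMutation(
        reference=reference,
        position=pos0 + 1,
        ref_base=BASES[int(ref_codes[pos0])],
        alt=BASES[alt],
        row_library=row_lib,
        col_library=col_lib,
        pct_row=float(pct[row_i, pos0, alt]),
        pct_col_raw=float(pct[col_i, pos0, alt]),
        pct_col_adj=float(adj[col_i, pos0, alt]),
        well=deconvolve(row_lib, col_lib, layout),
    )


def call_single_copy(
    counts: CountsTensor,
    params: SingleCopyParams,
    layout: PoolLayout,
) -> dict[int, list[CandidateMutation]]:
    """Run the percentage caller at every configured quality cutoff."""
    if tuple(counts.libraries) != layout.libraries:
        raise CallError("counts libraries do not match layout libraries")
    out: dict[int, list[CandidateMutation]] = {}
    for q in params.cutoffs:
        if q not in params.min_pct:
            raise CallError(f"no min% configured for cutoff {q}")
        found: list[CandidateMutation] = []
        for reference in sorted(counts.references):
            pct, adj, C, depth, ref_codes, row_idx, col_idx = _percent_arrays(
                counts, layout, reference, q, params.dilution
            )
            inband = (
                (adj >= params.min_pct[q])
                & (adj <= params.max_pct)
                & (depth[:, :, None] > 0)
            )
            # the reference base is not a variant
            L = inband.shape[1]
            inband[:, np.arange(L), ref_codes[:L]] = False
            rows_hit = inband[row_idx].sum(axis=0)  # (L, 4)
            cols_hit = inband[col_idx].sum(axis=0)
            for pos0, alt in zip(*np.nonzero((rows_hit == 1) & (cols_hit == 1))):
                pos0, alt = int(pos0), int(alt)
                row_i = int(row_idx[np.flatnonzero(inband[row_idx, pos0, alt])[0]])
                col_i = int(col_idx[np.flatnonzero(inband[col_idx, pos0, alt])[0]])
                rc = int(ref_codes[pos0])
                if not (
                    _dominates(C[row_i, pos0], alt, rc, params.dominance_ratio)
                    and _dominates(C[col_i, pos0], alt, rc, params.dominance_ratio)
                ):
                    continue
                found.append(
                    _make_candidate(counts, layout, reference, pos0, alt,
                                    ref_codes, pct, adj, row_i, col_i)
                )
        out[q] = found
    return out


def group_by_quality(
    per_cutoff: dict[int, list[CandidateMutation]],
    high_min_cutoff: int = 17,
) -> list[CandidateMutation]:
    """Merge per-cutoff candidates and label their quality group.

    ``common``: found at every configured cutoff; ``high``: found only at
    cutoffs >= ``high_min_cutoff``; ``low``: only below it; anything else
    is ``mixed``.
    """
    all_cutoffs = sorted(per_cutoff)
    merged: dict[tuple, CandidateMutation] = {}
    seen_at: dict[tuple, set[int]] = {}
    for q, cands in per_cutoff.items():
        for c in cands:
            key = c.site + (c.row_library, c.col_library)
            merged.setdefault(key, c)
            seen_at.setdefault(key, set()).add(q)
    out = []
    for key, cand in merged.items():
        cuts = sorted(seen_at[key])
        if cuts == all_cutoffs:
            group = "common"
        elif all(q >= high_min_cutoff for q in cuts):
            group = "high"
        elif all(q < high_min_cutoff for q in cuts):
            group = "low"
        else:
            group = "mixed"
        cand.cutoffs = tuple(cuts)
        cand.group = group
        out.append(cand)
    return sorted(out, key=lambda c: (c.reference, c.position, c.alt))


def background_nonref(counts: CountsTensor, cutoff: int) -> float:
    """Mean non-reference percentage over all covered cells at a cutoff.

    This is the sequencing-noise floor against which the per-cutoff minimum
    percentages are set (the screen's working values sit 3-12x above it).
    """
    total = 0.0
    n = 0
    for lib in counts.libraries:
        for ref in sorted(counts.references):
            c = counts.counts(lib, ref, cutoff)
            depth = c.sum(axis=1)
            covered = depth > 0
            if not covered.any():
                continue
            ref_codes = counts.ref_codes[ref][: c.shape[0]]
            ref_counts = c[np.arange(c.shape[0]), ref_codes]
            pct = 100.0 * (depth[covered] - ref_counts[covered]) / depth[covered]
            total += float(pct.sum())
            n += int(covered.sum())
    if n == 0:
        raise CallError("no covered cells at cutoff; cannot compute background")
    return total / n


def call_multi_copy(
    counts: CountsTensor,
    params: MultiCopyParams,
    layout: PoolLayout,
) -> dict[tuple[int, float], list[CandidateMutation]]:
    """Run the variance-multiplier caller over the full (quality, multiplier) grid.

    Requires counts built in ``report_all`` mode.  For a fixed quality the
    multiplier field is computed once and thresholded at each grid value,
    so the candidate sets are naturally nested as the multiplier grows.
    """
    if counts.mode != REPORT_ALL:
        raise CallError("multi-copy calling requires counts built in report_all mode")
    if tuple(counts.libraries) != layout.libraries:
        raise CallError("counts libraries do not match layout libraries")

    out: dict[tuple[int, float], list[CandidateMutation]] = {
        (q, m): [] for q in params.qualities for m in params.multipliers
    }
    for q in params.qualities:
        for reference in sorted(counts.references):
            pct, adj, C, depth, ref_codes, row_idx, col_idx = _percent_arrays(
                counts, layout, reference, q, Fraction(2, 3)
            )
            covered = depth > 0
            if not covered.any():
                continue
            eps = params.epsilon
            if eps is None:
                eps = 100.0 / float(depth[covered].mean())  # one read equivalent
            frac = pct  # percentage scale throughout
            mult = np.zeros_like(frac)
            for axis_idx in (row_idx, col_idx):
                sub = frac[axis_idx]  # (k, L, 4)
                k = len(axis_idx)
                background = (sub.sum(axis=0, keepdims=True) - sub) / (k - 1)
                # epsilon floors the background so a zero-noise simulation
                # cannot produce infinite multipliers
                mult[axis_idx] = sub / np.maximum(background, eps)
            L = frac.shape[1]
            eligible = (frac >= params.min_pct) & (depth[:, :, None] > 0)
            eligible[:, np.arange(L), ref_codes[:L]] = False
            for m in params.multipliers:
                hits = eligible & (mult >= m)
                rows_hit = hits[row_idx].sum(axis=0)
                cols_hit = hits[col_idx].sum(axis=0)
                for pos0, alt in zip(*np.nonzero((rows_hit == 1) & (cols_hit == 1))):
                    pos0, alt = int(pos0), int(alt)
                    row_i = int(row_idx[np.flatnonzero(hits[row_idx, pos0, alt])[0]])
                    col_i = int(col_idx[np.flatnonzero(hits[col_idx, pos0, alt])[0]])
                    out[(q, m)].append(
                        _make_candidate(counts, layout, reference, pos0, alt,
                                        ref_codes, pct, adj, row_i, col_i)
                    )
    return out


def call_multi_copy_at(
    counts: CountsTensor,
    layout: PoolLayout,
    quality: int,
    multiplier: float,
    min_pct: float = 0.05,
    epsilon: float | None = None,
) -> list[CandidateMutation]:
    """Single (quality, multiplier) evaluation of the multi-copy caller."""
    params = MultiCopyParams(
        qualities=(quality,), multipliers=(multiplier,), min_pct=min_pct, epsilon=epsilon
    )
    return call_multi_copy(counts, params, layout)[(quality, multiplier)]


def candidates_to_frame(candidates: list[CandidateMutation]):
    """Tabular view of a candidate list (one row per candidate)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "reference": c.reference,
                "position": c.position,
                "ref": c.ref_base,
                "alt": c.alt,
                "row_library": c.row_library,
                "col_library": c.col_library,
                "pct_row": round(c.pct_row, 4),
                "pct_col_raw": round(c.pct_col_raw, 4),
                "pct_col_adj": round(c.pct_col_adj, 4),
                "cutoffs": ",".join(map(str, c.cutoffs)),
                "group": c.group,
                "well": c.well.well,
            }
            for c in candidates
        ]
    )
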