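"""Parameter calibration against a known-mutant control list.

The screen tunes its callers on mutations whose status is already known:
validated mutations (``status=true``) and positions known to be artifacts
(``status=false``).  Every parameter combination is scored by the percentage
of its predictions that hit known-true entries minus the percentage hitting
known-false entries - predictions matching neither count toward the
denominator only.  The ranking deliberately rewards efficiency (a clean
prediction list) over raw sensitivity.

Percentages are rounded to one decimal before differencing, matching how
such calibration tables are conventionally printed (e.g. 11/16 -> 68.8,
1/16 -> 6.2, difference 62.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

Site = tuple[str, int, str]  # (reference, 1-based position, alt base)


class CalibrationError(ValueError):
    """Unusable control list or empty grids."""


@dataclass
class KnownMutantList:
    """Control sites with known status.

    ``true`` entries are validated mutations; ``false`` entries are known
    artifacts.  Keys are (reference, position, alt); duplicates across the
    two sets are rejected, and at least one true entry is required.
    """

    true: frozenset[Site]
    false: frozenset[Site] = frozenset()
    provenance: str = ""

    def __post_init__(self) -> None:
        self.true = frozenset(self.true)
        self.false = frozenset(self.false)
        if not self.true:
            raise CalibrationError("control list needs at least one status=true entry")
        dup = self.true & self.false
        if dup:
            raise CalibrationError(f"sites listed as both true and false: {sorted(dup)}")

    @classmethod
    def from_tsv(cls, path) -> "KnownMutantList":
        """Load reference/pos/ref/alt/status TSV (status: true|false)."""
        df = pd.read_csv(path, sep="\t")
        true, false = set(), set()
        for rec in df.itertuples(index=False):
            site = (str(rec.reference), int(rec.pos), str(rec.alt))
            (true if str(rec.status).lower() == "true" else false).add(site)
        return cls(true=frozenset(true), false=frozenset(false), provenance=str(path))


@dataclass
class CalibrationRow:
    """One parameter combination's tally against the control list."""

    params: dict
    n_true: int
    n_false: int
    total: int
    true_pct: float = field(init=False)
    false_pct: float = field(init=False)
    difference: float = field(init=False)
    unscorable: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_true + self.n_false > self.total:
            raise CalibrationError("true + false tallies exceed total predicted")
        self.unscorable = self.total == 0
        if self.unscorable:
            self.true_pct = self.false_pct = self.difference = float("nan")
        else:
            # round-half-even at 1 d.p., then difference the rounded values
            self.true_pct = round(100.0 * self.n_true / self.total, 1)
            self.false_pct = round(100.0 * self.n_false / self.total, 1)
            self.difference = round(self.true_pct - self.false_pct, 1)


def score_params(predicted: Iterable[Site], known: KnownMutantList, params: dict | None = None) -> CalibrationRow:
    """Tally a prediction set against the control list."""
    pred = set(predicted)
    return CalibrationRow(
        params=dict(params or {}),
        n_true=len(pred & known.true),
        n_false=len(pred & known.false),
        total=len(pred),
    )


def rank_rows(rows: Sequence[CalibrationRow]) -> list[CalibrationRow]:
    """Sort by difference (desc), ties by n_true (desc) then total (asc).

    Unscorable rows sink to the bottom.
    """
    return sorted(
        rows,
        key=lambda r: (
            r.unscorable,
            -(r.difference if not r.unscorable else float("-inf")),
            -r.n_true,
            r.total,
        ),
    )


def grid_search(
    counts,
    layout,
    known: KnownMutantList,
    mode: str,
    single_params=None,
    multi_params=None,
) -> tuple[list[CalibrationRow], dict[tuple, set[Site]]]:
    """Evaluate a caller over its parameter grid and rank the combinations.

    ``mode='single'`` grids over the configured quality cutoffs (each with
    its own minimum percentage); ``mode='multi'`` over quality x multiplier.
    Returns the ranked rows and the prediction set per parameter key
    (``(cutoff, min_pct)`` or ``(quality, multiplier)``).
    """
    from . import call as _call

    predicted: dict[tuple, set[Site]] = {}
    rows: list[CalibrationRow] = []
    if mode == "single":
        params = single_params or _call.SingleCopyParams()
        if not params.cutoffs:
            raise CalibrationError("empty quality grid")
        per_cutoff = _call.call_single_copy(counts, params, layout)
        for q in params.cutoffs:
            key = (q, params.min_pct[q])
            sites = {c.site for c in per_cutoff[q]}
            predicted[key] = sites
            rows.append(
                score_params(sites, known, {"min_quality": q, "min_pct": params.min_pct[q]})
            )
    elif mode == "multi":
        params = multi_params or _call.MultiCopyParams()
        if not params.qualities or not params.multipliers:
            raise CalibrationError("empty parameter grid")
        grid = _call.call_multi_copy(counts, params, layout)
        for (q, m), cands in grid.items():
            sites = {c.site for c in cands}
            predicted[(q, m)] = sites
            rows.append(
                score_params(
                    sites, known,
                    {"min_quality": q, "multiplier": m, "min_pct": params.min_pct},
                )
            )
    else:
        raise CalibrationError(f"mode must be 'single' or 'multi', got {mode!r}")
    return rank_rows(rows), predicted


def consensus_candidates(
    ranked_rows: Sequence[CalibrationRow],
    predicted: dict[tuple, set[Site]],
    k: int,
) -> set[Site]:
    """Intersection of the prediction sets of the top-k parameter combinations."""
    if k < 1:
        raise CalibrationError("k must be >= 1")
    top = ranked_rows[:k]
    sets = []
    for row in top:
        key = _key_of(row.params)
        sets.append(predicted[key])
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def _key_of(params: dict) -> tuple:
    if "multiplier" in params:
        return (params["min_quality"], params["multiplier"])
    return (params["min_quality"], params["min_pct"])


def rows_to_frame(rows: Sequence[CalibrationRow]) -> pd.DataFrame:
    """Calibration table with one row per parameter combination."""
    return pd.DataFrame(
        [
            {
                **r.params,
                "n_true": r.n_true,
                "true_pct": r.true_pct,
                "n_false": r.n_false,
                "false_pct": r.false_pct,
                "total_predicted": r.total,
                "difference": r.difference,
                "unscorable": r.unscorable,
            }
            for r in rows
        ]
    )
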