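"""Effect annotation, EMS-spectrum classification, and screen-level reporting.

Covers the downstream bookkeeping of a TILLING screen: mapping a called
nucleotide change through a gene model to an amino-acid effect
(silent / missense / nonsense / noncoding), classifying substitutions
against the canonical EMS spectrum (G->A and C->T transitions on the
written strand), converting screen totals into the conventional
"1 SNP per N kb" mutation frequency, and flagging lines whose mutation
spectrum looks like contamination rather than mutagenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd
from Bio.Seq import Seq

from .layout import expected_mutant_fraction

CANONICAL = {("G", "A"), ("C", "T")}


class AnnotationError(ValueError):
    """Invalid gene model or mutation input."""


@dataclass
class GeneModel:
    """Coding-sequence model on an amplicon reference.

    ``cds_intervals`` are ordered, non-overlapping, 1-based closed intervals
    of coding sequence in reference coordinates; their spliced length must
    be divisible by 3.  ``strand`` is the strand the protein is read from
    relative to the written reference.
    """

    reference: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        last_end = 0
        for a, b in ivals:
            if a > b or a <= last_end:
                raise AnnotationError("CDS intervals must be ordered and non-overlapping")
            last_end = b
        self.cds_intervals = ivals
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"spliced CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_intervals)

    def cds_position(self, position: int) -> int | None:
        """0-based position within the spliced CDS, or None if noncoding."""
        offset = 0
        for a, b in self.cds_intervals:
            if a <= position <= b:
                fwd = offset + (position - a)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            offset += b - a + 1
        return None

    def spliced_cds(self, refseq: str) -> str:
        s = "".join(refseq[a - 1 : b] for a, b in self.cds_intervals)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    @classmethod
    def from_bed_row(cls, reference, strand, blocks, protein_id="") -> "GeneModel":
        return cls(reference, strand, tuple(blocks), protein_id)


@dataclass(frozen=True)
class Effect:
    """Predicted consequence of a nucleotide change."""

    kind: str  # silent | missense | nonsense | noncoding
    codon_number: int | None = None  # 1-based amino-acid position
    aa_ref: str | None = None
    aa_alt: str | None = None

    @property
    def aa_change(self) -> str:
        if self.kind == "noncoding" or self.codon_number is None:
            return ""
        return f"{self.aa_ref}{self.codon_number}{self.aa_alt}"


def classify_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    model: GeneModel,
    refseq: str,
) -> Effect:
    """Classify a substitution through the gene model.

    The position is mapped through the CDS intervals (strand-aware) to its
    codon; the codon is translated before and after the substitution.
    Intronic/UTR/upstream positions are ``noncoding``; a substitution whose
    mutant codon is a stop is ``nonsense``.
    """
    if not 1 <= position <= len(refseq):
        raise AnnotationError(f"position {position} outside reference ({len(refseq)} bp)")
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if refseq[position - 1].upper() != ref_base:
        raise AnnotationError(
            f"reference base mismatch at {position}: sequence has "
            f"{refseq[position - 1]!r}, mutation says {ref_base!r}"
        )
    if alt_base == ref_base:
        raise AnnotationError("alt base equals reference base")

    cds_pos = model.cds_position(position)
    if cds_pos is None:
        return Effect(kind="noncoding")

    cds = model.spliced_cds(refseq)
    base_in_cds = ref_base if model.strand == "+" else str(Seq(ref_base).complement())
    if cds[cds_pos] != base_in_cds:
        raise AnnotationError("gene model inconsistent with reference sequence")
    alt_in_cds = alt_base if model.strand == "+" else str(Seq(alt_base).complement())

    codon_idx = cds_pos // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutant = codon[: cds_pos % 3] + alt_in_cds + codon[cds_pos % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_alt == aa_ref:
        kind = "silent"
    elif aa_alt == "*":
        kind = "nonsense"
    else:
        kind = "missense"
    return Effect(kind=kind, codon_number=codon_idx + 1, aa_ref=aa_ref, aa_alt=aa_alt)


def classify_ems(ref_base: str, alt_base: str) -> str:
    """``canonical`` iff the change is G->A or C->T as written on the reference."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise AnnotationError(f"invalid bases {ref_base!r}->{alt_base!r}")
    if alt_base == ref_base:
        raise AnnotationError("alt base equals reference base")
    return "canonical" if (ref_base, alt_base) in CANONICAL else "non-canonical"


def mutation_frequency(
    screened_kb: float, n_mutations: int, n_lines: int
) -> int | None:
    """Screened kb per mutation across the whole population.

    The conventional TILLING summary: (kb screened per line / mutations
    found) x lines screened, i.e. "1 SNP per N kb", rounded half away from
    zero to the nearest kb.  Returns ``None`` when no mutations were found
    (there is no frequency to report, not a division by zero).
    """
    if screened_kb <= 0 or n_lines < 1:
        raise AnnotationError("screened_kb must be positive and n_lines >= 1")
    if n_mutations < 0:
        raise AnnotationError("n_mutations must be >= 0")
    if n_mutations == 0:
        return None
    x = (screened_kb / n_mutations) * n_lines
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def infer_zygosity(row_pct: float, row_pool_size: int) -> tuple[str, bool]:
    """Nearest-expectation zygosity guess from the row-library percentage.

    Returns (zygosity, low_confidence).  Pooled percentages only separate
    hom from het by a factor of two, so any call more than 25% away from
    both expectations is flagged low-confidence.
    """
    hom = float(expected_mutant_fraction(row_pool_size, "hom"))
    het = float(expected_mutant_fraction(row_pool_size, "het"))
    zyg = "hom" if abs(row_pct - hom) < abs(row_pct - het) else "het"
    nearest = hom if zyg == "hom" else het
    return zyg, abs(row_pct - nearest) > 0.25 * nearest


def line_anomaly_report(
    mutations: pd.DataFrame,
    noncanonical_threshold: int = 3,
) -> pd.DataFrame:
    """Per-line mutation tallies with contamination flags.

    Expects a table with at least ``line``, ``ref`` and ``alt`` columns
    (``zygosity`` is used when present).  A line is flagged for manual
    review when it carries at least ``noncanonical_threshold`` changes
    outside the canonical EMS spectrum - in a chemically mutagenized
    population such a cluster looks like seed or pollen contamination
    rather than mutagenesis.
    """
    if mutations.empty:
        return pd.DataFrame(
            columns=["line", "n_mutations", "n_noncanonical", "n_het", "flagged"]
        )
    work = mutations.copy()
    work["canonical"] = [
        classify_ems(r, a) == "canonical" for r, a in zip(work["ref"], work["alt"])
    ]
    rows = []
    for line, grp in work.groupby("line"):
        n_noncanon = int((~grp["canonical"]).sum())
        rows.append(
            {
                "line": line,
                "n_mutations": len(grp),
                "n_noncanonical": n_noncanon,
                "n_het": int((grp["zygosity"] == "het").sum())
                if "zygosity" in grp
                else pd.NA,
                "flagged": n_noncanon >= noncanonical_threshold,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_noncanonical", "line"], ascending=[False, True])
        .reset_index(drop=True)
    )


@dataclass
class ScreenSummary:
    """Screen-level totals and the derived mutation frequencies.

    Frequencies are reported both for the full mutation set and after
    excluding flagged (suspect-contaminant) lines.  The overall exclusion
    removes the flagged lines' non-canonical changes - the changes that
    triggered the flag - while the per-class exclusions remove all of the
    flagged lines' mutations from that class.
    """

    single_copy_kb: float
    multi_copy_kb: float
    n_lines: int
    n_single: int
    n_multi: int
    flagged_lines: tuple[str, ...]
    excluded_overall: int
    excluded_single: int
    excluded_multi: int

    @property
    def total_kb(self) -> float:
        return self.single_copy_kb + self.multi_copy_kb

    @property
    def n_total(self) -> int:
        return self.n_single + self.n_multi

    def frequencies(self) -> dict[str, int | None]:
        return {
            "overall_kb_per_snp": mutation_frequency(
                self.total_kb, self.n_total, self.n_lines
            ),
            "single_copy_kb_per_snp": mutation_frequency(
                self.single_copy_kb, self.n_single, self.n_lines
            ),
            "multi_copy_kb_per_snp": mutation_frequency(
                self.multi_copy_kb, self.n_multi, self.n_lines
            ),
            "overall_kb_per_snp_excl_flagged": mutation_frequency(
                self.total_kb, self.n_total - self.excluded_overall, self.n_lines
            ),
            "single_copy_kb_per_snp_excl_flagged": mutation_frequency(
                self.single_copy_kb, self.n_single - self.excluded_single, self.n_lines
            ),
            "multi_copy_kb_per_snp_excl_flagged": mutation_frequency(
                self.multi_copy_kb, self.n_multi - self.excluded_multi, self.n_lines
            ),
        }


def summarize_screen(
    mutations: pd.DataFrame,
    single_copy_kb: float,
    multi_copy_kb: float,
    n_lines: int,
    extra_known_single: int = 0,
    extra_known_multi: int = 0,
    noncanonical_threshold: int = 3,
) -> ScreenSummary:
    """Build a :class:`ScreenSummary` from a mutation table.

    The table needs ``ref``, ``alt``, ``line`` and ``copy_class``
    (single|multi) columns.  ``extra_known_*`` add control mutations that
    were re-detected but are not rows of the table (they count toward the
    totals but cannot be attributed to flagged lines).
    """
    for col in ("ref", "alt", "line", "copy_class"):
        if col not in mutations.columns:
            raise AnnotationError(f"mutation table lacks required column {col!r}")
    report = line_anomaly_report(mutations, noncanonical_threshold)
    flagged = tuple(report.loc[report["flagged"], "line"]) if len(report) else ()
    in_flagged = mutations["line"].isin(flagged)
    canonical = mutations.apply(
        lambda r: classify_ems(r["ref"], r["alt"]) == "canonical", axis=1
    ) if len(mutations) else pd.Series(dtype=bool)
    single = mutations["copy_class"] == "single"
    return ScreenSummary(
        single_copy_kb=single_copy_kb,
        multi_copy_kb=multi_copy_kb,
        n_lines=n_lines,
        n_single=int(single.sum()) + extra_known_single,
        n_multi=int((~single).sum()) + extra_known_multi,
        flagged_lines=flagged,
        excluded_overall=int((in_flagged & ~canonical).sum()) if len(mutations) else 0,
        excluded_single=int((in_flagged & single).sum()) if len(mutations) else 0,
        excluded_multi=int((in_flagged & ~single).sum()) if len(mutations) else 0,
    )
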