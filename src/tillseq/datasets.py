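"""Published record of the peanut EMS TILLING-by-sequencing screen.

The pipeline in this package was calibrated on a screen of 768 M2 peanut
(*Arachis hypogaea*) lines: 8.5 kb of single-copy amplicon targets (the
allergen genes Ara h 1.01/1.02 and Ara h 2.01/2.02 plus the fatty-acid
desaturases AhFAD2A/B) and 27.6 kb of multi-copy targets (the lipoxygenase
AhLOX7 5'/3' amplicons and the phospholipase-D genes AhPLD1/2).  This
module packages the screen's validated mutation table and headline
constants so that spectrum tallies, per-line anomaly flags and mutation
frequencies can be recomputed from data.

Besides the 20 newly identified mutations tabulated here, six previously
known single-copy mutants were carried as internal controls and re-detected;
they count toward the single-copy total (19) but have no table rows.
"""

from __future__ import annotations

import pandas as pd

#: kb of single-copy amplicon sequence screened per line
SINGLE_COPY_KB = 8.5
#: kb of multi-copy amplicon sequence screened per line
MULTI_COPY_KB = 27.6
#: M2 lines screened (eight 96-well plates)
N_LINES = 768
#: previously known single-copy control mutants re-detected by the screen
PRIOR_KNOWN_SINGLE_COPY = 6

#: calibration tallies reported for the top two multi-copy parameter sets
#: (min quality, multiplier, min variance %, n_true, n_false, total predicted)
TOP_MULTI_COPY_CALIBRATION = (
    (19, 12, 0.05, 11, 1, 16),
    (19, 14, 0.05, 10, 1, 15),
)

_MUTATIONS = [
    # gene, copy_class, position, ref, alt, effect, aa_change, line, amplicon_bp
    ("Arah1.01", "single", 321, "C", "T", "silent", "", "08F213_1", 1865),
    ("Arah1.01", "single", 1524, "C", "T", "missense", "T377I", "07JKEMS167", 1865),
    ("Arah1.01", "single", 1678, "C", "T", "silent", "", "07JKEMS148", 1865),
    ("Arah1.02", "single", 1258, "A", "G", "silent", "", "07JKEMS1125", 1666),
    ("Arah1.02", "single", 72, "G", "T", "missense", "Q24H", "07JKEMS1125", 1666),
    ("Arah1.02", "single", 428, "C", "T", "missense", "P143L", "08F216_1", 1666),
    ("Arah1.02", "single", 644, "C", "A", "missense", "P215H", "08F221_5", 1666),
    ("Arah1.02", "single", 765, "C", "T", "silent", "", "07JKEMS1125", 1666),
    ("Arah1.02", "single", 891, "G", "A", "silent", "", "07JKEMS12", 1666),
    ("Arah1.02", "single", 694, "A", "G", "missense", "I232V", "07JKEMS1125", 1666),
    ("Arah1.02", "single", 742, "A", "C", "missense", "K248Q", "07JKEMS1125", 1666),
    ("AhFAD2B", "single", 632, "C", "T", "missense", "P211L", "08F222_3", 1234),
    # upstream of the start codon; no coordinate reported
    ("Arah2.02", "single", None, "C", "T", "noncoding", "", "08F231_4", 1247),
    ("AhLOX7_3p", "multi", 1508, "T", "C", "missense", "L503P", "07JKEMS169", 1532),
    ("AhLOX7_5p", "multi", 512, "C", "G", "missense", "A171G", "07JKEMS1125", 1714),
    ("AhLOX7_5p", "multi", 525, "A", "G", "missense", "I175M", "07JKEMS1125", 1714),
    ("AhLOX7_5p", "multi", 532, "C", "G", "missense", "L178V", "07JKEMS1125", 1714),
    ("AhPLD1", "multi", 1328, "C", "T", "missense", "S443F", "08F201_4", 1272),
    ("AhPLD1", "multi", 1632, "G", "A", "missense", "M544I", "08F211_5", 1272),
    ("AhPLD2", "multi", 1727, "C", "T", "missense", "P576L", "07JKEMS67", 1500),
]


def validated_mutations() -> pd.DataFrame:
    """The screen's 20 validated newly identified mutations.

    Columns: ``gene, copy_class, position, ref, alt, effect, aa_change,
    line, amplicon_bp``.  The Ara h 2.02 change sits upstream of the start
    codon and carries no reported coordinate (position is <NA>).
    """
    df = pd.DataFrame(
        _MUTATIONS,
        columns=[
            "gene", "copy_class", "position", "ref", "alt",
            "effect", "aa_change", "line", "amplicon_bp",
        ],
    )
    df["position"] = df["position"].astype("Int64")
    return df
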