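import numpy as np
import pandas as pd
import pytest

from tillseq.call import (
    CallError,
    CandidateMutation,
    MultiCopyParams,
    SingleCopyParams,
    background_nonref,
    call_multi_copy,
    call_multi_copy_at,
    call_single_copy,
    group_by_quality,
    nonref_percentages,
)
from tillseq.counts import CountsTensor
from tillseq.layout import PoolLayout
from tillseq.simulate import ReadModel, pool_composition, simulate_population

from conftest import random_reference, trimmed_reads_by_library

CUTOFFS = tuple(SingleCopyParams().cutoffs)


def flat_params(min_pct=0.17, **kw):
    return SingleCopyParams(min_pct={q: min_pct for q in CUTOFFS}, **kw)


def _tensor_with_cell(layout, refs, lib_counts, pos=10, mode="single", base_depth=10_000):
    """Tensor where every library covers `refs` uniformly at `base_depth`
    with the reference base, except explicit (lib, base, count) overrides at
    one position."""
    tensor = CountsTensor(refs, layout.libraries, mode=mode)
    ref = next(iter(refs))
    L = len(refs[ref])
    qual = chr(30 + 33)
    for lib in layout.libraries:
        arr = tensor._arr(lib, ref)
        for p in range(L):
            code = "ACGT".index(refs[ref][p])
            arr[p, code, 30] += base_depth
    for lib, base, count in lib_counts:
        arr = tensor._arr(lib, ref)
        code = "ACGT".index(base)
        ref_code = "ACGT".index(refs[ref][pos - 1])
        arr[pos - 1, code, 30] += count
        arr[pos - 1, ref_code, 30] -= count  # keep depth constant
    return tensor


@pytest.fixture(scope="module")
def refs20():
    rng = np.random.default_rng(21)
    return {"amp": random_reference(rng, 40)}


class TestNonrefPercentages:
    def test_row_library_raw(self, layout, refs20):
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        t = _tensor_with_cell(layout, refs20, [("row_A", alt, 104)])
        pcts = nonref_percentages(t, "row_A", "amp", 10, 30, layout)
        assert pcts[alt]["raw"] == pytest.approx(1.04)
        assert pcts[alt]["adjusted"] == pytest.approx(1.04)

    def test_column_library_adjusted(self, layout, refs20):
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        t = _tensor_with_cell(layout, refs20, [("col_1", alt, 104)])
        pcts = nonref_percentages(t, "col_1", "amp", 10, 30, layout)
        assert pcts[alt]["raw"] == pytest.approx(1.04)
        assert pcts[alt]["adjusted"] == pytest.approx(1.04 * 2 / 3)

    def test_zero_alt_and_zero_depth(self, layout, refs20):
        t = _tensor_with_cell(layout, refs20, [])
        pcts = nonref_percentages(t, "row_A", "amp", 10, 30, layout)
        assert all(v["raw"] == 0.0 for v in pcts.values())
        assert nonref_percentages(t, "row_A", "amp", 10, 35, layout) == {}


class TestCallSingleCopy:
    def _hit(self, layout, refs20, row_count, col_count, alt=None, **extra):
        ref_base = refs20["amp"][9]
        alt = alt or ("A" if ref_base != "A" else "C")
        cells = [("row_B", alt, row_count), ("col_4", alt, col_count)]
        cells += extra.pop("cells", [])
        return _tensor_with_cell(layout, refs20, cells), alt

    def test_clean_hit_called_and_deconvolved(self, layout, refs20):
        # het-like signal: row 0.52%, column 0.78% (adjusted 0.52%)
        t, alt = self._hit(layout, refs20, 52, 78)
        cands = call_single_copy(t, flat_params(), layout)[18]
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.alt, c.well.well) == (10, alt, "B4")
        assert c.pct_col_adj == pytest.approx(c.pct_col_raw * 2 / 3)

    def test_max_percentage_rejects_common_variant(self, layout, refs20):
        t, _ = self._hit(layout, refs20, 600, 900)  # 6% / 9%
        assert call_single_copy(t, flat_params(), layout)[18] == []
        relaxed = flat_params(max_pct=20.0)
        assert len(call_single_copy(t, relaxed, layout)[18]) == 1

    def test_two_row_hits_rejected_as_non_unique(self, layout, refs20):
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        t = _tensor_with_cell(
            layout, refs20,
            [("row_B", alt, 52), ("row_C", alt, 52), ("col_4", alt, 78)],
        )
        assert call_single_copy(t, flat_params(), layout)[18] == []

    def test_dominance_rejects_noisy_position(self, layout, refs20):
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        other = next(b for b in "ACGT" if b not in (ref_base, alt))
        t = _tensor_with_cell(
            layout, refs20,
            [("row_B", alt, 52), ("row_B", other, 40), ("col_4", alt, 78)],
        )
        assert call_single_copy(t, flat_params(), layout)[18] == []
        lax = flat_params(dominance_ratio=1.0)
        assert len(call_single_copy(t, lax, layout)[18]) == 1

    def test_missing_cutoff_config_is_error(self, layout, refs20):
        t, _ = self._hit(layout, refs20, 52, 78)
        with pytest.raises(CallError):
            SingleCopyParams(min_pct={18: 0.0})  # invalid band
        params = flat_params()
        del params.min_pct[18]
        assert 18 not in params.cutoffs  # cutoffs follow the table


class TestGroupByQuality:
    def _cand(self):
        from tillseq.layout import deconvolve

        lay = PoolLayout()
        return CandidateMutation(
            reference="amp", position=1, ref_base="A", alt="G",
            row_library="row_A", col_library="col_1",
            pct_row=0.5, pct_col_raw=0.7, pct_col_adj=0.47,
            well=deconvolve("row_A", "col_1", lay),
        )

    @pytest.mark.parametrize(
        "cutoffs,group",
        [
            (CUTOFFS, "common"),
            ((17, 18, 19, 20), "high"),
            ((17, 18, 19, 20, 21), "high"),
            ((10, 12, 14, 15, 16), "low"),
            ((10, 19), "mixed"),
        ],
    )
    def test_grouping_rule(self, cutoffs, group):
        per_cutoff = {q: ([self._cand()] if q in cutoffs else []) for q in CUTOFFS}
        (merged,) = group_by_quality(per_cutoff)
        assert merged.group == group
        assert merged.cutoffs == tuple(sorted(cutoffs))


class TestBackground:
    def test_error_free_background_is_zero(self, layout):
        rng = np.random.default_rng(22)
        refs = {"amp": random_reference(rng, 40)}
        t = _tensor_with_cell(layout, refs, [])
        assert background_nonref(t, 10) == 0.0

    def test_uniform_error_injection_recovered(self, layout):
        # quality-blind 0.03% error floor -> background ~0.03% at any cutoff
        rng = np.random.default_rng(23)
        refs = {"amp": random_reference(rng, 400)}
        from tillseq.counts import counts_from_reads

        model = ReadModel(mean_depth=900, error_scale=0.0, context_error_rate=3e-4)
        empty = pd.DataFrame(columns=["reference", "position", "ref_base", "alt",
                                      "zygosity", "plate", "row", "col", "library", "dosage"])
        reads = trimmed_reads_by_library(empty, refs, model, layout, seed=24)
        tensor = counts_from_reads(reads, refs)
        bg = background_nonref(tensor, 10)
        n_bases = sum(tensor.depth(lib, "amp", 0).sum() for lib in layout.libraries)
        sigma = 100 * np.sqrt(3e-4 / n_bases)
        assert abs(bg - 0.03) < 3 * sigma


class TestCallMultiCopy:
    def test_requires_report_all_counts(self, layout, refs20):
        t = _tensor_with_cell(layout, refs20, [])
        with pytest.raises(CallError):
            call_multi_copy_at(t, layout, 19, 12)

    def test_multiplier_arithmetic(self, layout, refs20):
        # hit 0.20%, same-axis background 0.0125% -> multiplier 16
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        cells = [("row_B", alt, 32), ("col_4", alt, 32)]
        cells += [(lib, alt, 2) for lib in PoolLayout().libraries
                  if lib not in ("row_B", "col_4")]
        t = _tensor_with_cell(layout, refs20, cells, mode="report_all", base_depth=16_000)
        hits = call_multi_copy_at(t, layout, 30, 12, min_pct=0.05)
        assert [(c.position, c.alt, c.well.well) for c in hits] == [(10, alt, "B4")]
        assert call_multi_copy_at(t, layout, 30, 17, min_pct=0.05) == []

    def test_equal_fractions_rejected(self, layout, refs20):
        ref_base = refs20["amp"][9]
        alt = "A" if ref_base != "A" else "C"
        cells = [(lib, alt, 800) for lib in PoolLayout().libraries]  # 5% everywhere
        t = _tensor_with_cell(layout, refs20, cells, mode="report_all", base_depth=16_000)
        assert call_multi_copy_at(t, layout, 30, 2, min_pct=0.05) == []

    def test_candidate_sets_nested_in_multiplier(self, layout, refs20):
        # modest noise floor in every library, one clear hit per axis
        rng = np.random.default_rng(25)
        cells = []
        for lib in PoolLayout().libraries:
            base = refs20["amp"][9]
            alt = "A" if base != "A" else "C"
            cells.append((lib, alt, int(rng.integers(8, 13))))
        cells += [("row_B", alt, 60), ("col_4", alt, 60)]
        t = _tensor_with_cell(layout, refs20, cells, mode="report_all", base_depth=16_000)
        params = MultiCopyParams(qualities=(30,), multipliers=tuple(range(2, 21)))
        grid = call_multi_copy(t, params, layout)
        prev = None
        for m in params.multipliers:
            cur = {c.site for c in grid[(30, m)]}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_params(self):
        with pytest.raises(CallError):
            MultiCopyParams(multipliers=(1,))
        with pytest.raises(CallError):
            MultiCopyParams(min_pct=0.0)


class TestOnSimulatedScreen:
    def test_planted_mutations_recovered_at_their_wells(self, small_screen, layout):
        truth, _, tensor = small_screen
        grouped = group_by_quality(call_single_copy(tensor, flat_params(), layout))
        called = {(c.reference, c.position, c.alt, c.well.well) for c in grouped}
        planted = {
            (r.reference, r.position, r.alt, f"{r.row}{r.col}")
            for r in truth.itertuples()
        }
        assert called == planted

    def test_oracle_equivalence_with_truth_ledger(self, small_screen, layout):
        # brute-force oracle: planted set restricted to dosages within the
        # [min%, max%] band after dilution adjustment and axis uniqueness
        truth, dosages, tensor = small_screen
        params = flat_params()
        expected = set()
        for (ref, pos, alt), grp in dosages.groupby(["reference", "position", "alt"]):
            ok = 0
            for rec in grp.itertuples():
                pct = 100 * rec.dosage
                if layout.axis_of(rec.library) == "column":
                    pct *= 2 / 3
                ok += params.min_pct[18] <= pct <= params.max_pct
            if ok == 2 and len(grp) == 2:
                expected.add((ref, pos, alt))
        called = {c.site for c in call_single_copy(tensor, params, layout)[18]}
        assert called == expected
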