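import subprocess

import numpy as np
import pytest

from tillseq.counts import (
    CountsError,
    CountsTensor,
    PileupParseError,
    counts_from_mpileup,
    counts_from_reads,
    parse_mpileup,
)
from tillseq.mapping import AmpliconIndex, map_read, revcomp

from conftest import random_reference


class TestMapRead:
    REFS = {
        "r1": "ACGTACGTTAGCAGGCATCGATCGATTACCGGAATTCCGGAGCTAGCTAACCGGTTACGA",
        # r2 shares no 20-mer with r1
        "r2": "TTGACCTGAGGACTATCGCGCCATATGGCCAATTGGCTCTAGACTAGGCATCAGTACGTA",
    }

    def test_exact_substring_single(self):
        read = self.REFS["r1"][10:40]
        (p,) = map_read(read, self.REFS, "single")
        assert (p.reference, p.offset, p.strand, p.mismatches) == ("r1", 10, "+", 0)

    def test_reverse_strand(self):
        read = revcomp(self.REFS["r2"][5:35])
        (p,) = map_read(read, self.REFS, "single")
        assert (p.reference, p.offset, p.strand) == ("r2", 5, "-")
        assert p.aligned_seq == self.REFS["r2"][5:35]

    def test_identical_references_ambiguous_vs_report_all(self):
        refs = {"a": self.REFS["r1"], "b": self.REFS["r1"]}
        read = self.REFS["r1"][:30]
        assert map_read(read, refs, "single") == []
        hits = {p.reference for p in map_read(read, refs, "report_all")}
        assert hits == {"a", "b"}

    def test_best_mismatch_wins_in_single_mode(self):
        # brute-force oracle: enumerate all placements of the read on both
        # references and keep the minimum-mismatch one
        ref_a = self.REFS["r1"]
        ref_b = ref_a[:25] + ("A" if ref_a[25] != "A" else "C") + ref_a[26:]
        refs = {"a": ref_a, "b": ref_b}
        read = ref_a[10:40]  # exact on a, 1 mismatch on b
        best = min(
            ((name, off, sum(x != y for x, y in zip(read, seq[off : off + 30])))
             for name, seq in refs.items()
             for off in range(len(seq) - 29)),
            key=lambda t: t[2],
        )
        (p,) = map_read(read, refs, "single")
        assert (p.reference, p.offset, p.mismatches) == best

    def test_mismatch_budget(self):
        read = "T" * 25
        assert map_read(read, self.REFS, "single") == []

    def test_short_read_unmapped(self):
        assert map_read("ACGT", self.REFS, "single") == []

    def test_seed_error_rescued_by_second_anchor(self):
        read = list(self.REFS["r1"][10:45])
        read[2] = {"A": "C"}.get(read[2], "A")  # break the leading seed
        (p,) = map_read("".join(read), self.REFS, "single")
        assert (p.reference, p.offset, p.mismatches) == ("r1", 10, 1)


class TestParseMpileup:
    def _line(self, bases, quals, ref="amp", pos=10, refbase="A"):
        return f"{ref}\t{pos}\t{refbase}\t{len(quals)}\t{bases}\t{quals}"

    def test_ref_and_alt_bases(self):
        col = parse_mpileup(self._line("..,,tT", "IIIIII"))
        assert col.counts() == {"A": 4, "C": 0, "G": 0, "T": 2}
        assert col.depth == 6

    def test_read_start_and_end_marks(self):
        col = parse_mpileup(self._line("^F..$", "II"))
        assert col.counts() == {"A": 2, "C": 0, "G": 0, "T": 0}

    def test_insertion_block_ignored(self):
        col = parse_mpileup(self._line(".+2AT.,", "III"))
        assert col.counts()["A"] == 3 and col.depth == 3

    def test_deletion_placeholder_consumes_quality(self):
        col = parse_mpileup(self._line("..*", "III"))
        assert col.depth == 2 and col.counts()["A"] == 2

    def test_quality_filtering(self):
        col = parse_mpileup(self._line(".t", "I$"))  # Q40, Q3
        assert col.counts(min_quality=10) == {"A": 1, "C": 0, "G": 0, "T": 0}

    def test_length_mismatch_raises_with_line_number(self):
        with pytest.raises(PileupParseError, match="line 7"):
            parse_mpileup(self._line("...", "II"), line_number=7)

    def test_unexpected_character(self):
        with pytest.raises(PileupParseError):
            parse_mpileup(self._line(".?.", "III"))


class TestCountsTensor:
    def _tensor(self):
        refs = {"amp": "ACGTACGTACGTACGTACGT"}
        t = CountsTensor(refs, ["row_A", "col_1"])
        return refs, t

    def test_identical_counts_when_all_qualities_high(self):
        refs, t = self._tensor()
        t.add_batch("row_A", "amp", [0, 0], [refs["amp"][:10]] * 2, ["I" * 10] * 2)
        assert (t.counts("row_A", "amp", 10) == t.counts("row_A", "amp", 20)).all()

    def test_quality_cutoff_excludes_low_bases(self):
        refs, t = self._tensor()
        t.add_batch("row_A", "amp", [0], [refs["amp"][:4]], [chr(15 + 33) * 4])
        assert t.depth("row_A", "amp", 10)[0] == 1
        assert t.depth("row_A", "amp", 20)[0] == 0

    def test_depth_is_base_sum(self):
        refs, t = self._tensor()
        t.add_batch("row_A", "amp", [2, 5], ["GTAC", "GTAC"], ["IIII", "HHHH"])
        c = t.counts("row_A", "amp", 0)
        assert (t.depth("row_A", "amp", 0) == c.sum(axis=1)).all()

    def test_monotone_in_cutoff_random_batches(self):
        refs, t = self._tensor()
        rng = np.random.default_rng(0)
        for _ in range(20):
            off = int(rng.integers(0, 10))
            seq = "".join(rng.choice(list("ACGT"), 8))
            qual = "".join(chr(int(q) + 33) for q in rng.integers(2, 42, 8))
            t.add_batch("row_A", "amp", [off], [seq], [qual])
        prev = t.counts("row_A", "amp", 0)
        for q in range(1, 42):
            cur = t.counts("row_A", "amp", q)
            assert (cur <= prev).all()
            prev = cur

    def test_unknown_keys_rejected(self):
        _, t = self._tensor()
        with pytest.raises(CountsError):
            t.counts("row_Z", "amp", 0)
        with pytest.raises(CountsError):
            t.counts("row_A", "nope", 0)

    def test_tsv_dump(self, tmp_path):
        refs, t = self._tensor()
        t.add_batch("row_A", "amp", [0], ["ACGT"], ["IIII"])
        out = tmp_path / "counts.tsv"
        t.to_tsv(out, cutoffs=[10, 20])
        lines = out.read_text().splitlines()
        assert lines[0].startswith("library\treference")
        assert len(lines) == 1 + 2 * 4  # 4 covered positions x 2 cutoffs


class TestCountsFromReads:
    def test_simulated_mean_depth_matches_model(self, small_screen, layout, small_refs):
        _, _, tensor = small_screen
        # error-free reads all map, so mean coverage equals the depth model
        d = tensor.depth("row_A", "ampA", 0)
        assert abs(d.mean() - 2500) / 2500 < 0.02

    def test_report_all_counts_conserved_region_twice(self):
        rng = np.random.default_rng(3)
        base = random_reference(rng, 120)
        refs = {"c1": base, "c2": base[:60] + ("A" if base[60] != "A" else "C") + base[61:]}
        read = base[10:50]  # conserved region
        tensor_all = counts_from_reads(
            {"lib": [(read, "I" * 40)]}, refs, mode="report_all"
        )
        assert tensor_all.depth("lib", "c1", 0).sum() == 40
        assert tensor_all.depth("lib", "c2", 0).sum() == 40
        tensor_single = counts_from_reads({"lib": [(read, "I" * 40)]}, refs, mode="single")
        total = (
            tensor_single.depth("lib", "c1", 0).sum()
            + tensor_single.depth("lib", "c2", 0).sum()
        )
        assert total == 0  # ambiguous in single mode


class TestMpileupImport:
    def test_round_trip_against_samtools(self, tmp_path):
        # toy reads -> internal counts; same reads as BAM -> samtools mpileup
        # -> imported counts; the two tensors must agree exactly
        import pysam

        rng = np.random.default_rng(5)
        ref = random_reference(rng, 80)
        refs = {"amp": ref}
        alt = "A" if ref[30] != "A" else "G"
        reads = [
            (ref[0:40], "".join(chr(int(q) + 33) for q in rng.integers(20, 41, 40))),
            (ref[20:60], "I" * 40),
            (ref[10:50][:20] + alt + ref[31:50], "J" * 40),  # alt at position 31
            (revcomp(ref[35:75]), "K" * 40),
        ]
        internal = counts_from_reads({"lib": reads}, refs, mode="single")

        fasta = tmp_path / "ref.fa"
        fasta.write_text(f">amp\n{ref}\n")
        pysam.faidx(str(fasta))
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "amp", "LN": len(ref)}]}
        bam = tmp_path / "reads.bam"
        idx = AmpliconIndex(refs)
        with pysam.AlignmentFile(bam, "wb", header=header) as fh:
            for i, (seq, qual) in enumerate(reads):
                (p,) = idx.map_read(seq, "single")
                a = pysam.AlignedSegment()
                a.query_name = f"read{i}"
                a.query_sequence = p.aligned_seq
                a.flag = 0 if p.strand == "+" else 16
                a.reference_id = 0
                a.reference_start = p.offset
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    qual if p.strand == "+" else qual[::-1]
                )
                fh.write(a)
        sorted_bam = tmp_path / "sorted.bam"
        pysam.sort("-o", str(sorted_bam), str(bam))
        pysam.index(str(sorted_bam))
        out = subprocess.run(
            ["samtools", "mpileup", "-B", "-Q", "0", "-d", "100000",
             "-f", str(fasta), str(sorted_bam)],
            capture_output=True, text=True, check=True,
        )
        imported = counts_from_mpileup({"lib": out.stdout.splitlines()}, refs)
        for q in (0, 20, 35):
            np.testing.assert_array_equal(
                internal.counts("lib", "amp", q), imported.counts("lib", "amp", q)
            )
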