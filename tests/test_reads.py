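"""Read simulation, assignment, methylation calling and conversion correction."""

import numpy as np
import pytest
from scipy import stats as sps

from epiage.reads import (
    AlignedRead,
    ConversionError,
    ReadRecord,
    assign_reads,
    call_methylation,
    conversion_rate,
    correct_conversion,
    quantify,
    read_fastq,
    simulate_reads,
    write_fastq,
    write_sam,
)


def _target_calls(calls, marker):
    return calls[(calls["marker"] == marker) & calls["is_target"]].iloc[0]


class TestSimulateReads:
    def test_fully_methylated_fully_converted_all_c(self, panel):
        batch = simulate_reads(panel, {"cg19761273": 1.0}, n_fragments=50,
                               conversion_rate=1.0, seed=1)
        amp = panel.amplicons["cg19761273"]
        for rec in batch:
            if rec.mate == 1:
                for off in amp.cpg_offsets:
                    if off < len(rec.sequence):
                        assert rec.sequence[off] == "C"

    def test_c_fraction_within_exact_binomial_ci(self, panel):
        beta, n = 0.7, 1000
        batch = simulate_reads(panel, {"cg19761273": beta}, n_fragments=n,
                               conversion_rate=1.0, seed=2)
        amp = panel.amplicons["cg19761273"]
        off = amp.target_offset
        c = sum(1 for r in batch if r.mate == 1 and r.sequence[off] == "C")
        lo, hi = sps.binom.ppf([0.005, 0.995], n, beta)
        assert lo <= c <= hi

    def test_control_conversion_within_binomial_ci(self, panel):
        rate, n = 0.95, 1000
        batch = simulate_reads(panel, {"cg19761273": 0.5}, n_fragments=n,
                               conversion_rate=rate, seed=3)
        amp = panel.amplicons["cg19761273"]
        controls = [o for o in amp.control_offsets if o < 150]
        t = total = 0
        for r in batch:
            if r.mate != 1:
                continue
            for off in controls:
                total += 1
                t += r.sequence[off] == "T"
        lo, hi = sps.binom.ppf([0.005, 0.995], total, rate)
        assert lo <= t <= hi

    def test_deterministic_given_seed(self, panel):
        a = simulate_reads(panel, {"cg27544190": 0.4}, n_fragments=20, seed=7)
        b = simulate_reads(panel, {"cg27544190": 0.4}, n_fragments=20, seed=7)
        assert a == b

    def test_invalid_rates_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate_reads(panel, {"cg19761273": 0.5}, conversion_rate=1.5)
        with pytest.raises(ValueError):
            simulate_reads(panel, {"cg19761273": 0.5}, seq_error_rate=-0.1)


class TestAssignReads:
    def test_error_free_reads_fully_assigned(self, panel):
        batch = simulate_reads(panel, {"cg19761273": 0.5}, n_fragments=200,
                               conversion_rate=0.98, seed=4)
        assignment = assign_reads(batch, panel)
        assert not assignment.unassigned
        assert set(assignment.by_marker) == {"cg19761273"}
        assert len(assignment.by_marker["cg19761273"]) == len(batch)

    def test_one_percent_error_reads_mostly_assigned_correctly(self, panel):
        # 10,000 reads across all 16 markers with 1% substitution error
        true = {m: 0.5 for m in panel.amplicons}
        batch = simulate_reads(panel, true, n_fragments=312,
                               conversion_rate=0.99, seq_error_rate=0.01, seed=5)
        assignment = assign_reads(batch, panel)
        correct = sum(
            1
            for marker, reads in assignment.by_marker.items()
            for read in reads
            if read.read_id.split(":")[1] == marker
        )
        assert correct / len(batch) >= 0.99

    def test_random_sequences_unassigned(self, panel):
        rng = np.random.default_rng(6)
        batch = [
            ReadRecord(f"rnd{i}", 1, "".join(rng.choice(list("ACGT"), 150)), "I" * 150)
            for i in range(20)
        ]
        assignment = assign_reads(batch, panel)
        assert len(assignment.unassigned) == 20

    def test_empty_batch_empty_result(self, panel):
        assignment = assign_reads([], panel)
        assert assignment.by_marker == {} and assignment.unassigned == []


class TestCallMethylation:
    def _amp(self, panel):
        return panel.amplicons["cg27544190"]  # 106 bp, single-read coverage

    def test_counts_and_threshold(self, panel):
        amp = self._amp(panel)
        off = amp.target_offset
        ref = amp.reference_seq
        reads = []
        for i in range(1000):
            base = "C" if i < 700 else "T"
            seq = ref[:off] + base + ref[off + 1:]
            reads.append(AlignedRead(f"r{i}", 1, seq, 0, None, 0))
        calls = call_methylation(reads, amp, min_reads=1000)
        row = calls[calls["offset"] == off].iloc[0]
        assert row["c_count"] == 700 and row["t_count"] == 300
        assert row["raw_beta"] == pytest.approx(0.7)
        assert row["coverage"] == 1000 and row["pass_coverage"]

    def test_999_reads_fail_coverage_boundary(self, panel):
        amp = self._amp(panel)
        reads = [AlignedRead(f"r{i}", 1, amp.reference_seq, 0, None, 0)
                 for i in range(999)]
        calls = call_methylation(reads, amp, min_reads=1000)
        assert not calls["pass_coverage"].any()

    def test_zero_reads_undefined_beta(self, panel):
        amp = self._amp(panel)
        calls = call_methylation([], amp)
        assert calls["raw_beta"].isna().all()
        assert (calls["coverage"] == 0).all()

    def test_mate_overlap_counted_once_first_mate_wins(self, panel):
        amp = self._amp(panel)
        off = amp.target_offset
        ref = amp.reference_seq
        seq_c = ref[:off] + "C" + ref[off + 1:]
        seq_t = ref[:off] + "T" + ref[off + 1:]
        reads = [
            AlignedRead("frag0", 1, seq_c, 0, None, 0),
            AlignedRead("frag0", 2, seq_t, 0, None, 0),  # overlaps, must not count
            AlignedRead("frag1", 2, seq_t, 0, None, 0),  # mate 2 only: counts
        ]
        calls = call_methylation(reads, amp, min_reads=1)
        row = calls[calls["offset"] == off].iloc[0]
        assert row["c_count"] == 1 and row["t_count"] == 1
        assert row["coverage"] == 2

    def test_n_bases_go_to_other_count(self, panel):
        amp = self._amp(panel)
        off = amp.target_offset
        seq = amp.reference_seq[:off] + "N" + amp.reference_seq[off + 1:]
        calls = call_methylation([AlignedRead("r0", 1, seq, 0, None, 0)], amp,
                                 min_reads=1)
        row = calls[calls["offset"] == off].iloc[0]
        assert row["other_count"] == 1 and row["coverage"] == 0

    def test_counting_conservation(self, panel):
        amp = self._amp(panel)
        batch = simulate_reads(panel, {amp.cpg_id: 0.3}, n_fragments=150,
                               conversion_rate=0.97, seq_error_rate=0.01, seed=8)
        assignment = assign_reads(batch, panel)
        calls = call_methylation(assignment.by_marker[amp.cpg_id], amp, min_reads=1)
        # every offset observation lands in exactly one of c/t/other
        n_fragments = 150  # both mates overlap fully on a 106-bp amplicon
        total = calls["c_count"] + calls["t_count"] + calls["other_count"]
        assert (total == n_fragments).all()


class TestConversion:
    def test_all_t_controls_rate_one(self, panel):
        amp = panel.amplicons["cg27544190"]
        reads = [AlignedRead(f"r{i}", 1, amp.reference_seq, 0, None, 0)
                 for i in range(50)]
        calls = call_methylation(reads, amp, min_reads=1)
        assert conversion_rate(calls) == 1.0

    def test_partial_conversion_fraction(self, panel):
        amp = panel.amplicons["cg27544190"]
        off = amp.control_offsets[0]
        ref = amp.reference_seq
        fail = ref[:off] + "C" + ref[off + 1:]
        n_ctrl = len(amp.control_offsets)
        # 2 unconverted control observations out of 100 reads * n_ctrl controls
        reads = [AlignedRead(f"r{i}", 1, fail if i < 2 else ref, 0, None, 0)
                 for i in range(100)]
        calls = call_methylation(reads, amp, min_reads=1)
        assert conversion_rate(calls) == pytest.approx(1 - 2 / (100 * n_ctrl))

    def test_no_controls_raises(self, panel):
        amp = panel.amplicons["cg27544190"]
        calls = call_methylation([], amp)
        with pytest.raises(ConversionError, match="no conversion controls"):
            conversion_rate(calls)

    @pytest.mark.parametrize(
        "raw, rate, expected",
        [
            (0.5, 1.0, 0.5),  # perfect conversion: identity
            (0.01, 0.99, 0.0),  # observed equals the conversion-failure floor
            (0.5 + (1 - 0.96) * 0.5, 0.96, 0.5),  # forward model inverted
        ],
    )
    def test_correct_conversion_values(self, raw, rate, expected):
        assert correct_conversion(raw, rate) == pytest.approx(expected, abs=1e-12)

    def test_rate_at_most_half_refused(self):
        with pytest.raises(ConversionError, match="assay failure"):
            correct_conversion(0.5, 0.5)

    def test_correction_monotone_in_raw_beta(self):
        grid = np.linspace(0, 1, 101)
        corrected = [correct_conversion(r, 0.97) for r in grid]
        assert all(b >= a for a, b in zip(corrected, corrected[1:]))


class TestQuantifyAndIO:
    def test_quantify_end_to_end_rows(self, panel):
        batch = simulate_reads(panel, {"cg19761273": 0.6, "cg06493994": 0.2},
                               n_fragments=300, conversion_rate=0.98, seed=9)
        calls = quantify(batch, panel, min_reads=200)
        assert set(calls["marker"]) == {"cg19761273", "cg06493994"}
        row = _target_calls(calls, "cg19761273")
        assert row["pass_coverage"]
        assert row["corrected_beta"] == pytest.approx(0.6, abs=0.06)
        assert 0.95 < row["conversion_rate"] <= 1.0

    def test_per_read_rate_close_to_pooled(self, panel):
        batch = simulate_reads(panel, {"cg19761273": 0.5}, n_fragments=400,
                               conversion_rate=0.97, seed=10)
        pooled = quantify(batch, panel, min_reads=1)
        per_read = quantify(batch, panel, min_reads=1, per_read_rate=True)
        assert (_target_calls(pooled, "cg19761273")["conversion_rate"]
                == pytest.approx(
                    _target_calls(per_read, "cg19761273")["conversion_rate"],
                    abs=0.01))

    def test_fastq_round_trip(self, panel, tmp_path):
        batch = simulate_reads(panel, {"cg27544190": 0.5}, n_fragments=10, seed=11)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        write_fastq(batch, r1, r2)
        loaded = read_fastq(r1, r2)
        assert sorted(loaded) == sorted(batch)

    def test_sam_output_parses_with_pysam(self, panel, tmp_path):
        import pysam

        batch = simulate_reads(panel, {"cg27544190": 0.5}, n_fragments=5, seed=12)
        assignment = assign_reads(batch, panel)
        path = tmp_path / "out.sam"
        write_sam(assignment, panel, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            records = list(sam)
        assert len(records) == 10
        assert all(rec.reference_name == "cg27544190" for rec in records)
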