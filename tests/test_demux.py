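"""Sample sheets and dual-index demultiplexing."""

import gzip
import itertools

import pytest

from hamdex import fastq
from hamdex.demux import (
    DemuxPolicy,
    ReadRecord,
    SampleSheet,
    demux_run,
    parse_sample_sheet,
    read_run,
    reverse_complement,
)
from hamdex.sim import ErrorProfile, generate_run, simulate_records

HI = fastq.phred_to_string([37] * 8)


def make_read(rid, i7, i5, q1=HI, q2=HI):
    return ReadRecord(
        read_id=rid,
        sequence="ACGT" * 10,
        qualities=fastq.phred_to_string([37] * 40),
        index1_seq=i7,
        index1_quals=q1,
        index2_seq=i5,
        index2_quals=q2,
    )


def flip(seq, p):
    return seq[:p] + ("A" if seq[p] != "A" else "C") + seq[p + 1 :]


class TestSampleSheet:
    def test_parse_well_formed(self, tmp_path, index96):
        path = tmp_path / "sheet.csv"
        path.write_text(
            "sample_id,i7,i5\n"
            f"s1,{index96.indices[0]},{index96.indices[1]}\n"
            f"s2,{index96.indices[2]},{index96.indices[3]}\n"
        )
        sheet = parse_sample_sheet(path)
        assert len(sheet) == 2
        sheet.validate_against(index96, index96)

    def test_duplicate_pair_rejected(self, tmp_path, index96):
        path = tmp_path / "sheet.csv"
        i7, i5 = index96.indices[0], index96.indices[1]
        path.write_text(f"sample_id,i7,i5\ns1,{i7},{i5}\ns2,{i7},{i5}\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_sample_sheet(path)

    def test_non_acgt_index_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            SampleSheet(samples=(("s1", "ACGTACGN", "ACGTACGT"),))

    def test_full_plate_pair_capacity(self, index96):
        # 96 x 96 = 9216 distinct dual-index pairs
        sheet = SampleSheet(
            samples=tuple(
                (f"s{i:04d}", i7, i5)
                for i, (i7, i5) in enumerate(
                    itertools.product(index96.indices, index96.indices)
                )
            )
        )
        assert len(sheet) == 9216
        assert len(sheet.pair_to_sample) == 9216

    def test_foreign_index_fails_validation(self, index96):
        sheet = SampleSheet(samples=(("s1", "ACGTACGT", index96.indices[0]),))
        if "ACGTACGT" not in index96.indices:
            with pytest.raises(ValueError, match="not in index set"):
                sheet.validate_against(index96, index96)


class TestDemuxRun:
    def test_error_free_reads_all_exact(self, small_sheet, index96):
        sid, i7, i5 = small_sheet.samples[0]
        reads = [make_read(f"r{i}", i7, i5) for i in range(10)]
        stats = demux_run(reads, small_sheet, index96, index96)
        assert stats.per_sample[sid]["total"] == 10
        assert stats.per_sample[sid]["exact_both"] == 10
        assert stats.conserves_counts()

    def test_single_error_corrected_assignment(self, small_sheet, index96):
        sid, i7, i5 = small_sheet.samples[1]
        reads = [make_read("r0", flip(i7, 2), i5)]
        stats = demux_run(
            reads, small_sheet, index96, index96, policy=DemuxPolicy(q_min=0)
        )
        assert stats.per_sample[sid]["corrected_any"] == 1

    def test_double_error_gives_index1_fail(self, small_sheet, index96):
        _, i7, i5 = small_sheet.samples[0]
        bad = flip(flip(i7, 0), 4)
        stats = demux_run(
            [make_read("r0", bad, i5)],
            small_sheet,
            index96,
            index96,
            policy=DemuxPolicy(q_min=0),
        )
        assert stats.undetermined["index1_fail"] == 1

    def test_low_quality_reason_takes_precedence(self, small_sheet, index96):
        _, i7, i5 = small_sheet.samples[0]
        low = fastq.phred_to_string([5] * 8)
        stats = demux_run(
            [make_read("r0", flip(i7, 1), i5, q1=low)],
            small_sheet,
            index96,
            index96,
            policy=DemuxPolicy(q_min=20),
        )
        assert stats.undetermined["low_quality"] == 1

    def test_pair_not_in_sheet(self, small_sheet, index96):
        # valid indices, but a pair no sample uses
        _, i7, _ = small_sheet.samples[0]
        _, _, i5 = small_sheet.samples[2]
        stats = demux_run(
            [make_read("r0", i7, i5)], small_sheet, index96, index96
        )
        assert stats.undetermined["pair_not_in_sheet"] == 1

    def test_strict_policy_rejects_any_mismatch(self, small_sheet, index96):
        sid, i7, i5 = small_sheet.samples[0]
        reads = [make_read("r0", i7, i5), make_read("r1", flip(i7, 3), i5)]
        stats = demux_run(
            reads, small_sheet, index96, index96, policy=DemuxPolicy(max_mismatch=0)
        )
        assert stats.per_sample[sid]["total"] == 1
        assert stats.undetermined_reads == 1

    def test_order_independence_of_stats(self, small_sheet, index96):
        profile = ErrorProfile(per_position_rate=0.02, seed=3)
        records, _ = simulate_records(small_sheet, 400, profile)
        fwd = demux_run(records, small_sheet, index96, index96)
        rev = demux_run(list(reversed(records)), small_sheet, index96, index96)
        assert fwd.to_dict() == rev.to_dict()

    def test_rc_index2_option(self, small_sheet, index96):
        sid, i7, i5 = small_sheet.samples[0]
        reads = [make_read("r0", i7, reverse_complement(i5))]
        stats = demux_run(
            reads,
            small_sheet,
            index96,
            index96,
            policy=DemuxPolicy(rc_index2=True),
        )
        assert stats.per_sample[sid]["exact_both"] == 1


class TestFastqRoundTrip:
    def test_run_files_demux_end_to_end(self, small_sheet, index96, tmp_path):
        profile = ErrorProfile(per_position_rate=0.0, seed=1)
        paths, truth = generate_run(small_sheet, 60, profile, tmp_path / "run")
        reads = read_run(paths.r1, i1=paths.i1, i2=paths.i2)
        outdir = tmp_path / "demux"
        stats = demux_run(reads, small_sheet, index96, index96, outdir=outdir)
        assert stats.total_reads == 60
        assert stats.assigned_reads == 60
        # per-sample FASTQ outputs hold exactly the assigned reads
        written = 0
        for sid in small_sheet.sample_ids():
            f = outdir / f"{sid}.fastq.gz"
            if f.exists():
                written += sum(1 for _ in fastq.read_fastq(f))
        assert written == 60
        assert not (outdir / "undetermined.fastq.gz").exists()

    def test_header_dialect(self, small_sheet, index96, tmp_path):
        sid, i7, i5 = small_sheet.samples[0]
        r1 = tmp_path / "r1.fastq"
        r1.write_text(
            f"@read1 1:N:0:{i7}+{i5}\n{'A' * 20}\n+\n{'I' * 20}\n"
        )
        reads = list(read_run(r1, indexes_in_header=True))
        assert reads[0].index1_seq == i7
        stats = demux_run(reads, small_sheet, index96, index96)
        assert stats.per_sample[sid]["total"] == 1

    def test_truncated_index_file_raises(self, small_sheet, index96, tmp_path):
        _, i7, i5 = small_sheet.samples[0]
        r1 = tmp_path / "r1.fastq"
        i1 = tmp_path / "i1.fastq"
        i2 = tmp_path / "i2.fastq"
        r1.write_text("@r0\nAAAA\n+\nIIII\n@r1\nAAAA\n+\nIIII\n")
        i1.write_text(f"@r0\n{i7}\n+\n{HI}\n")
        i2.write_text(f"@r0\n{i5}\n+\n{HI}\n")
        with pytest.raises(ValueError, match="truncated at record 1"):
            list(read_run(r1, i1=i1, i2=i2))
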