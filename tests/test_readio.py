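"""Input formats, the anchored primer rule, and pair merging."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crispamp import ReadPair, match_and_trim_primer, merge_pair, read_sequences, revcomp
from crispamp.readio import MERGED, REJECTED_OVERLAP, read_fastq_pair
from crispamp.reference import FSHR_FWD_PRIMER, FSHR_REV_PRIMER


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


class TestReadSequences:
    def test_fastq_round_trip(self, tmp_path):
        path = tmp_path / "one.fastq"
        _write_fastq(path, [("r1", "ACGTACGT", [30] * 8)])
        ((rid, seq, qual),) = list(read_sequences(path, "fastq"))
        assert rid == "r1" and seq == "ACGTACGT"
        assert len(seq) == len(qual) and qual == tuple([30] * 8)

    def test_gzip_fastq(self, tmp_path):
        path = tmp_path / "one.fastq.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("@r1\nACGT\n+\nIIII\n")
        ((_, seq, qual),) = list(read_sequences(path, "fastq"))
        assert seq == "ACGT" and qual == (40, 40, 40, 40)

    def test_bundled_tsv_counts(self, allele_records):
        """The bundled cohort table has 46 allele rows over 36 fish."""
        assert len(allele_records) == 46
        assert len({sid for sid, _ in allele_records}) == 36

    def test_unequal_pair_counts_error(self, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(r1, [(f"r{i}", "ACGT", [30] * 4) for i in range(3)])
        _write_fastq(r2, [(f"r{i}", "ACGT", [30] * 4) for i in range(2)])
        with pytest.raises(ValueError, match="more records"):
            list(read_fastq_pair(r1, r2))

    def test_mate_id_mismatch_error(self, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(r1, [("a", "ACGT", [30] * 4)])
        _write_fastq(r2, [("b", "ACGT", [30] * 4)])
        with pytest.raises(ValueError, match="mate id mismatch"):
            list(read_fastq_pair(r1, r2))

    def test_unsupported_format(self):
        with pytest.raises(ValueError, match="unsupported"):
            read_sequences("x", "bam")


class TestPrimerRule:
    def test_exact_prefix_trimmed(self):
        m = match_and_trim_primer(FSHR_FWD_PRIMER + "ACGT", FSHR_FWD_PRIMER)
        assert m.accepted and m.trimmed == "ACGT" and m.n_mismatch == 0

    def test_one_mismatch_allowed(self):
        mutated = "T" + FSHR_FWD_PRIMER[1:]
        m = match_and_trim_primer(mutated + "GGGG", FSHR_FWD_PRIMER, max_mismatch=1)
        assert m.accepted and m.trimmed == "GGGG" and m.n_mismatch == 1

    def test_two_mismatches_rejected(self):
        mutated = "TT" + FSHR_FWD_PRIMER[2:]
        m = match_and_trim_primer(mutated + "GGGG", FSHR_FWD_PRIMER, max_mismatch=1)
        assert not m.accepted and m.n_mismatch == 2

    def test_n_counts_as_mismatch(self):
        seq = "NN" + FSHR_FWD_PRIMER[2:] + "AA"
        assert not match_and_trim_primer(seq, FSHR_FWD_PRIMER).accepted

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=12, max_size=40),
        primer=st.text(alphabet="ACGT", min_size=4, max_size=10),
        max_mm=st.integers(min_value=0, max_value=3),
    )
    def test_acceptance_equals_brute_hamming(self, seq, primer, max_mm):
        """Acceptance is exactly the Hamming-ball membership of the 5'
        prefix (anchored, no shifts), per a direct base-by-base count."""
        brute = sum(
            a != b or a == "N" for a, b in zip(seq[: len(primer)], primer)
        )
        assert match_and_trim_primer(seq, primer, max_mm).accepted == (brute <= max_mm)


def _pair_from(amplicon, read_len, qual=40):
    quals = tuple([qual] * read_len)
    return ReadPair("p", amplicon[:read_len], revcomp(amplicon)[:read_len], quals, quals)


class TestMergePair:
    def test_error_free_pairs_reconstruct_every_cohort_allele(
        self, allele_records, amplicon_ref
    ):
        """Embedding each cohort allele in the full amplicon and merging
        error-free 150-nt mates recovers the amplicon exactly."""
        from crispamp.reference import FSHR_EXON2_WT

        lo = len(amplicon_ref.fwd_primer)
        wt_at = amplicon_ref.sequence.index(FSHR_EXON2_WT)
        prefix = amplicon_ref.sequence[:wt_at]
        suffix = amplicon_ref.sequence[wt_at + len(FSHR_EXON2_WT) :]
        for allele in sorted({seq for _, seq in allele_records}):
            amplicon = prefix + allele + suffix
            trimmed = ReadPair(
                "p",
                amplicon[lo : lo + 130],
                revcomp(amplicon)[len(amplicon_ref.rev_primer) : len(amplicon_ref.rev_primer) + 130],
                tuple([40] * 130),
                tuple([40] * 130),
            )
            merged = merge_pair(trimmed)
            assert merged.status == MERGED
            assert merged.seq == amplicon[lo : len(amplicon) - len(amplicon_ref.rev_primer)]
            assert merged.n_overlap_mismatch == 0

    def test_higher_quality_base_wins_in_overlap(self):
        amplicon = "A" * 20 + "C" * 20 + "G" * 20
        r1 = amplicon[:40]
        r2 = revcomp(amplicon)[:40]
        # corrupt one forward base inside the overlap, with low quality
        r1 = r1[:30] + "T" + r1[31:]
        q1 = [10 if i == 30 else 40 for i in range(40)]
        pair = ReadPair("p", r1, r2, tuple(q1), tuple([40] * 40))
        merged = merge_pair(pair, min_overlap=10)
        assert merged.status == MERGED
        assert merged.seq == amplicon
        assert merged.n_overlap_mismatch == 1

    def test_quality_tie_takes_forward_base(self):
        amplicon = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        r1 = amplicon[:24]
        r2 = revcomp(amplicon)[:24]
        r1 = r1[:20] + ("A" if r1[20] != "A" else "C") + r1[21:]
        pair = ReadPair("p", r1, r2, tuple([30] * 24), tuple([30] * 24))
        merged = merge_pair(pair, min_overlap=8, max_overlap_mismatch_rate=0.2)
        assert merged.status == MERGED
        assert merged.seq[20] == r1[20]

    def test_short_overlap_rejected(self):
        amplicon = "ATCGGCTAAGCTTGCACGTGAGTCCTAGGATCCATGCCGTA" * 2
        pair = _pair_from(amplicon, 45)  # true overlap 2*45-82 = 8
        assert merge_pair(pair, min_overlap=30).status == REJECTED_OVERLAP

    def test_n_never_wins_over_called_base(self):
        amplicon = "A" * 20 + "C" * 20 + "G" * 20
        r1 = amplicon[:40]
        r1 = r1[:35] + "N" + r1[36:]
        pair = ReadPair(
            "p", r1, revcomp(amplicon)[:40], tuple([40] * 40), tuple([2] * 40)
        )
        merged = merge_pair(pair, min_overlap=10)
        assert "N" not in merged.seq

    def test_swap_and_complement_symmetry(self):
        """Merging (R2, R1) as if strands were exchanged yields the
        reverse complement of the (R1, R2) consensus for error-free
        pairs."""
        rng = np.random.default_rng(3)
        amplicon = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        pair = _pair_from(amplicon, 60)
        swapped = ReadPair("p", pair.rev_seq, pair.fwd_seq, pair.rev_qual, pair.fwd_qual)
        m1, m2 = merge_pair(pair), merge_pair(swapped)
        assert m1.status == m2.status == MERGED
        assert m2.seq == revcomp(m1.seq)
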