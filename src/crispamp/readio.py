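"""Sequence input, the anchored primer rule, and read-pair merging.

Amplicon reads must contain their primer at the very 5' end (no shifts, no
indels) within a configurable Hamming distance, 1 mismatch by default.
Accepted mates are merged into a single per-read amplicon sequence by
scanning all overlap offsets, keeping the one with the most matching
bases, and calling the consensus base with the higher Phred score inside
the overlap.

FASTQ/FASTA parsing goes through Biopython; gzip is handled
transparently. Bare allele sequences (FASTA, or TSV with sample_id and
sequence columns) bypass merging entirely.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from numba import njit

from .reference import revcomp

MERGED = "merged"
REJECTED_PRIMER = "rejected_primer"
REJECTED_OVERLAP = "rejected_overlap"


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: tuple[int, ...]
    rev_qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: tuple[int, ...]
    n_overlap: int
    n_overlap_mismatch: int
    status: str


@dataclass(frozen=True)
class PrimerMatch:
    accepted: bool
    trimmed: str
    n_mismatch: int


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> Iterator[Tuple[str, str, tuple]]:
    """Yield (id, seq, qual) records from a (possibly gzipped) FASTQ file."""
    index = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper(), tuple(
                    rec.letter_annotations["phred_quality"]
                )
                index += 1
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ record at index {index}: {exc}") from exc


def read_fastq_pair(r1_path, r2_path) -> Iterator[ReadPair]:
    """Yield mated :class:`ReadPair` records from two FASTQ files.

    Mates must appear in the same order with matching ids (ignoring a
    trailing ``/1``/``/2``); unequal record counts are an error.
    """
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    index = 0
    for rec1 in it1:
        rec2 = next(it2, None)
        if rec2 is None:
            raise ValueError(f"record {index}: {r1_path} has more records than {r2_path}")
        id1, id2 = rec1[0].removesuffix("/1"), rec2[0].removesuffix("/2")
        if id1 != id2:
            raise ValueError(f"record {index}: mate id mismatch ({rec1[0]!r} vs {rec2[0]!r})")
        yield ReadPair(id1, rec1[1], rec2[1], rec1[2], rec2[2])
        index += 1
    if next(it2, None) is not None:
        raise ValueError(f"record {index}: {r2_path} has more records than {r1_path}")


def read_bare_sequences(path, format: str) -> List[Tuple[str, str]]:
    """Read (sample_id, sequence) records from FASTA or TSV.

    TSV files need ``sample_id`` and ``sequence`` columns; one sample may
    span several rows (one per allele).
    """
    if format == "fasta":
        with _open_text(path) as fh:
            return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"sample_id", "sequence"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
        return [(row.sample_id, row.sequence.upper()) for row in df.itertuples()]
    raise ValueError(f"unsupported bare-sequence format {format!r}")


def read_sequences(path, format: str):
    """Dispatch on input format.

    ``fastq-pair`` expects ``path`` to be a (R1, R2) tuple and yields
    :class:`ReadPair`; ``fastq`` yields (id, seq, qual); ``fasta`` and
    ``tsv`` return (sample_id, sequence) records that bypass merging.
    """
    if format == "fastq-pair":
        r1, r2 = path
        return read_fastq_pair(r1, r2)
    if format == "fastq":
        return read_fastq(path)
    if format in {"fasta", "tsv"}:
        return read_bare_sequences(path, format)
    raise ValueError(f"unsupported format {format!r}")


def match_and_trim_primer(seq: str, primer: str, max_mismatch: int = 1) -> PrimerMatch:
    """Anchored primer check: Hamming distance on the equal-length 5' prefix.

    N counts as a mismatch. On acceptance the primer prefix is removed;
    rejection is a return status, not an error.
    """
    if len(primer) >= len(seq):
        raise ValueError("primer must be shorter than the read")
    mism = sum(
        1 for a, b in zip(seq[: len(primer)], primer) if a != b or a == "N" or b == "N"
    )
    if mism <= max_mismatch:
        return PrimerMatch(True, seq[len(primer) :], mism)
    return PrimerMatch(False, "", mism)


@njit(cache=True)
def _best_overlap(a, b, min_overlap, max_mismatch_rate):  # pragma: no cover
    """Admissible offset of b against a with the most matching bases.

    Only offsets whose overlap meets ``min_overlap`` and whose mismatch
    rate stays within ``max_mismatch_rate`` compete (4 encodes N, which
    never matches); among those the one with the most matching bases
    wins, ties going to the longer overlap.
    """
    best_o, best_matches, best_ov, best_mism = -1, -1, 0, 0
    for o in range(0, len(a) - min_overlap + 1):
        ov = min(len(a) - o, len(b))
        matches = 0
        for k in range(ov):
            if a[o + k] == b[k] and a[o + k] != 4:
                matches += 1
        if ov - matches > max_mismatch_rate * ov:
            continue
        if matches > best_matches:
            best_o, best_matches, best_ov = o, matches, ov
            best_mism = ov - matches
    return best_o, best_ov, best_mism


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 30,
    max_overlap_mismatch_rate: float = 0.1,
) -> MergedRead:
    """Merge a primer-trimmed pair into one amplicon-oriented consensus.

    The reverse mate is reverse-complemented, the overlap offset with the
    most matching bases is chosen, and within the overlap the base with
    the higher Phred score wins (tie: forward base; an N never wins over a
    called base). Qualities inside the overlap are the per-position
    maximum. Pairs with no admissible overlap get status
    ``rejected_overlap``.
    """
    from .align import encode  # shared base encoding

    r2 = revcomp(pair.rev_seq)
    q2 = pair.rev_qual[::-1]
    r1, q1 = pair.fwd_seq, pair.fwd_qual
    if min(len(r1), len(r2)) < min_overlap:
        return MergedRead(pair.id, "", (), 0, 0, REJECTED_OVERLAP)

    o, ov, mism = _best_overlap(
        encode(r1), encode(r2), min_overlap, max_overlap_mismatch_rate
    )
    if o < 0:
        return MergedRead(pair.id, "", (), 0, 0, REJECTED_OVERLAP)

    seq = list(r1[:o])
    qual = list(q1[:o])
    for k in range(ov):
        b1, b2 = r1[o + k], r2[k]
        p1, p2 = q1[o + k], q2[k]
        if b1 == "N" and b2 != "N":
            seq.append(b2)
        elif b2 == "N" and b1 != "N":
            seq.append(b1)
        elif p2 > p1:
            seq.append(b2)
        else:
            seq.append(b1)
        qual.append(max(p1, p2))
    if ov < len(r2):  # reverse mate extends past the forward read
        seq.extend(r2[ov:])
        qual.extend(q2[ov:])
    else:  # reverse mate contained in the forward read
        seq.extend(r1[o + ov :])
        qual.extend(q1[o + ov :])
    return MergedRead(pair.id, "".join(seq), tuple(qual), ov, mism, MERGED)
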