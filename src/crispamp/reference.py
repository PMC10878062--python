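"""Reference amplicon records.

An :class:`AmpliconReference` bundles everything downstream stages need to
interpret an amplicon: the reference sequence itself, the PCR primer pair
(as synthesized, i.e. the reverse primer matches the reverse strand), the
CRISPR protospacer coordinates, and optional reading-frame metadata used to
translate indel calls into protein consequences.

Two ready-made references for the Atlantic salmon *fshr* exon-2 target are
provided: the published 72-nt wild-type segment used for bare-allele
genotyping, and a synthetic full-length PCR amplicon (real primers and
target segment, synthetic flanking filler) used by the read simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """A reference amplicon with target-site and frame metadata.

    Parameters
    ----------
    name
        Text label used in reports and VCF contig lines.
    sequence
        Uppercase DNA over {A,C,G,T}. For a full PCR product this includes
        the primer sites; for a trimmed segment the primers may be absent
        (and should then be passed as empty strings).
    fwd_primer, rev_primer
        Primer pair as synthesized. When non-empty and ``sequence`` is the
        full amplicon, ``fwd_primer`` must be its prefix and the reverse
        complement of ``rev_primer`` its suffix.
    target_start, target_end
        0-based half-open protospacer coordinates on ``sequence``.
    target_strand
        ``"+"`` or ``"-"``: strand of the protospacer relative to
        ``sequence``.
    frame_offset
        Codon phase of position 0: index of the first base of the first
        complete codon within ``sequence`` (0, 1 or 2), or ``None`` when
        unknown. Required for protein-consequence calls.
    aa_numbering_offset
        Protein residue number assigned to reference codon 0 (the codon
        starting at ``frame_offset``). ``None`` means number from 1.
    cds_upstream, cds_downstream
        Optional CDS context flanking ``sequence``, reserved for
        translations that cross the segment boundary.
    """

    name: str
    sequence: str
    fwd_primer: str = ""
    rev_primer: str = ""
    target_start: int = 0
    target_end: int = 0
    target_strand: str = "+"
    frame_offset: Optional[int] = None
    aa_numbering_offset: Optional[int] = None
    cds_upstream: str = ""
    cds_downstream: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"reference sequence has non-DNA characters: {sorted(bad)}")
        if not (0 <= self.target_start <= self.target_end <= len(self.sequence)):
            raise ValueError("target coordinates out of bounds")
        if self.target_strand not in {"+", "-"}:
            raise ValueError("target_strand must be '+' or '-'")
        if self.frame_offset is not None and self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.fwd_primer and not self.sequence.startswith(self.fwd_primer):
            raise ValueError("fwd_primer is not a prefix of the amplicon sequence")
        if self.rev_primer and not self.sequence.endswith(revcomp(self.rev_primer)):
            raise ValueError("revcomp(rev_primer) is not a suffix of the amplicon sequence")

    @property
    def inner_sequence(self) -> str:
        """Sequence between (and excluding) the primer sites.

        Primer-trimmed merged reads are aligned against this segment.
        """
        start = len(self.fwd_primer)
        end = len(self.sequence) - len(self.rev_primer)
        return self.sequence[start:end]

    @property
    def target_sequence(self) -> str:
        """Protospacer on its own strand."""
        seg = self.sequence[self.target_start : self.target_end]
        return seg if self.target_strand == "+" else revcomp(seg)


# The published wild-type exon-2 segment spanning the CRISPR target site.
FSHR_EXON2_WT = (
    "GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT"
)

# gRNA protospacer, a reverse-strand match of FSHR_EXON2_WT[36:56].
FSHR_GRNA = "GGAGGTTGGTGAAGGCTTCT"

# Amplicon PCR primers (target-specific 3' parts, adapters removed).
FSHR_FWD_PRIMER = "GCTGTATCGTTCCCAGCAAT"
FSHR_REV_PRIMER = "CGTTCCTAAGGAGACAAACCA"

# Fixed synthetic filler placed between the primer sites and the published
# segment so that the simulator has a realistically sized (250 bp) product.
# These flanks are synthetic: the study's full amplicon sequence outside the
# printed segment is not public.
_PAD_LEFT = (
    "TCAGGTACGCTAAGTCCATGGATTCGACCTGTAACGGTCATACGGAGTTC"
    "CTAGCAATGGTCAGTACGAT"
)
_PAD_RIGHT = (
    "GATCCGTTAGCACTGGAATCCGTATGCAAGGTTCACTAGGCTTAACGGTA"
    "CCATGAGTCAATCGGAT"
)


def fshr_exon2_reference() -> AmpliconReference:
    """The published *fshr* exon-2 wild-type segment (72 nt).

    Frame metadata places codon boundaries so that the common in-frame
    del3 allele deletes the single glutamate codon reported at residue 72
    of the Fshr protein; see docs/methods.md for how the phase and
    numbering offset are anchored.
    """
    return AmpliconReference(
        name="fshr_exon2",
        sequence=FSHR_EXON2_WT,
        target_start=36,
        target_end=56,
        target_strand="-",
        frame_offset=1,
        aa_numbering_offset=60,
    )


def fshr_synthetic_amplicon() -> AmpliconReference:
    """Synthetic 250-bp *fshr* PCR product for read simulation.

    Real primers and published target segment, synthetic flanking filler.
    Frame metadata is left unset: protein-level calls use
    :func:`fshr_exon2_reference`.
    """
    seq = (
        FSHR_FWD_PRIMER
        + _PAD_LEFT
        + FSHR_EXON2_WT
        + _PAD_RIGHT
        + revcomp(FSHR_REV_PRIMER)
    )
    offset = len(FSHR_FWD_PRIMER) + len(_PAD_LEFT)
    return AmpliconReference(
        name="fshr_amplicon",
        sequence=seq,
        fwd_primer=FSHR_FWD_PRIMER,
        rev_primer=FSHR_REV_PRIMER,
        target_start=offset + 36,
        target_end=offset + 56,
        target_strand="-",
    )
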