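"""Edit extraction, indel classification and protein consequences.

From a global alignment each contiguous gap run becomes one deletion or
insertion edit and each run of mismatch columns one substitution edit,
with positions reported on the ungapped reference (0-based). Indels are
canonically left-realigned, so the same variant always gets the same
coordinates and name regardless of where the aligner placed the gap.

Classification follows the net indel length: no insertion/deletion edits
means ``no_indel`` (substitution-only alleles count as wild-type class for
genotyping), a net length divisible by 3 means ``in_frame``, anything else
``frameshift``. Substitutions never affect the class or the allele name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

from Bio.Seq import Seq

from .align import PairwiseAlignment, ScoringScheme, global_align
from .reference import AmpliconReference

NO_INDEL = "no_indel"
IN_FRAME = "in_frame"
FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class Edit:
    """One edit on the reference.

    ``ref_pos`` is 0-based; for an insertion it is the reference position
    before which ``alt_seq`` is inserted.
    """

    kind: str  # deletion | insertion | substitution
    ref_pos: int
    length: int
    alt_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"deletion", "insertion", "substitution"}:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("edit length must be >= 1")
        if self.kind in {"insertion", "substitution"} and len(self.alt_seq) != self.length:
            raise ValueError("alt_seq length must equal edit length")

    @property
    def token(self) -> str:
        return {"deletion": "del", "insertion": "ins", "substitution": "sub"}[self.kind] + str(
            self.length
        )


@dataclass(frozen=True)
class AlleleCall:
    """One allele's edits relative to the reference, with its class."""

    seq: str
    edits: tuple[Edit, ...]
    net_indel: int
    indel_class: str
    identical_to_wt: bool
    name: str
    align_score: int


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str  # none | residue_deletion | residue_insertion | missense | frameshift
    aa_position: Optional[int] = None
    detail: str = ""


def extract_edits(alignment: PairwiseAlignment) -> List[Edit]:
    """Turn alignment columns into a sorted, left-realigned edit list.

    Raises ``ValueError`` on malformed alignments (a column gapped in both
    rows, or gapped strings of unequal length).
    """
    aq, ar = alignment.aligned_query, alignment.aligned_ref
    if len(aq) != len(ar):
        raise ValueError("malformed alignment: rows differ in length")
    edits: List[Edit] = []
    ref_pos = 0
    i = 0
    n = len(aq)
    while i < n:
        if aq[i] == "-" and ar[i] == "-":
            raise ValueError(f"malformed alignment: column {i} gapped in both rows")
        if aq[i] == "-":  # deletion from the reference
            j = i
            while j < n and aq[j] == "-":
                if ar[j] == "-":
                    raise ValueError(f"malformed alignment: column {j} gapped in both rows")
                j += 1
            edits.append(Edit("deletion", ref_pos, j - i))
            ref_pos += j - i
            i = j
        elif ar[i] == "-":  # insertion relative to the reference
            j = i
            while j < n and ar[j] == "-":
                if aq[j] == "-":
                    raise ValueError(f"malformed alignment: column {j} gapped in both rows")
                j += 1
            edits.append(Edit("insertion", ref_pos, j - i, aq[i:j]))
            i = j
        elif aq[i] != ar[i]:  # run of substitution columns -> one edit
            j = i
            while j < n and aq[j] != "-" and ar[j] != "-" and aq[j] != ar[j]:
                j += 1
            edits.append(Edit("substitution", ref_pos, j - i, aq[i:j]))
            ref_pos += j - i
            i = j
        else:
            ref_pos += 1
            i += 1
    return _left_realign(edits, alignment.ref)


def _left_realign(edits: List[Edit], ref: str) -> List[Edit]:
    """Shift each indel maximally to the left without crossing other edits."""
    out: List[Edit] = []
    for edit in sorted(edits, key=lambda e: (e.ref_pos, e.kind)):
        bound = 0
        if out:
            prev = out[-1]
            bound = prev.ref_pos if prev.kind == "insertion" else prev.ref_pos + prev.length
        if edit.kind == "deletion":
            p = edit.ref_pos
            while p > bound and ref[p - 1] == ref[p + edit.length - 1]:
                p -= 1
            edit = replace(edit, ref_pos=p)
        elif edit.kind == "insertion":
            p, alt = edit.ref_pos, edit.alt_seq
            while p > bound and ref[p - 1] == alt[-1]:
                alt = alt[-1] + alt[:-1]
                p -= 1
            edit = replace(edit, ref_pos=p, alt_seq=alt)
        out.append(edit)
    return out


def apply_edits(ref: str, edits: Sequence[Edit]) -> str:
    """Reconstruct the query implied by ``edits`` applied to ``ref``."""
    parts: List[str] = []
    pos = 0
    for edit in sorted(edits, key=lambda e: (e.ref_pos, e.kind != "insertion")):
        if edit.ref_pos < pos:
            raise ValueError("edits overlap")
        parts.append(ref[pos : edit.ref_pos])
        if edit.kind == "deletion":
            pos = edit.ref_pos + edit.length
        elif edit.kind == "substitution":
            parts.append(edit.alt_seq)
            pos = edit.ref_pos + edit.length
        else:
            parts.append(edit.alt_seq)
            pos = edit.ref_pos
    parts.append(ref[pos:])
    return "".join(parts)


def _allele_name(edits: Sequence[Edit], identical_to_wt: bool) -> str:
    indels = [e for e in edits if e.kind != "substitution"]
    if indels:
        return "+".join(e.token for e in indels)
    return "wt" if identical_to_wt else "sub"


def classify_allele(
    edits: Sequence[Edit], ref_seq: str, query: str, align_score: int = 0
) -> AlleleCall:
    """Classify one allele from its edit list.

    The class depends only on the net indel length (insertions minus
    deletions); substitutions are recorded but never change the class or
    the canonical name.
    """
    ins = sum(e.length for e in edits if e.kind == "insertion")
    dels = sum(e.length for e in edits if e.kind == "deletion")
    net = ins - dels
    if ins == 0 and dels == 0:
        indel_class = NO_INDEL
    elif net % 3 == 0:
        indel_class = IN_FRAME
    else:
        indel_class = FRAMESHIFT
    identical = query == ref_seq
    return AlleleCall(
        seq=query,
        edits=tuple(edits),
        net_indel=net,
        indel_class=indel_class,
        identical_to_wt=identical,
        name=_allele_name(edits, identical),
        align_score=align_score,
    )


def call_allele(
    query: str, ref: AmpliconReference | str, scoring: ScoringScheme | None = None
) -> AlleleCall:
    """Align one allele sequence to the reference and classify it."""
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    aln = global_align(query, ref_seq, scoring)
    return classify_allele(extract_edits(aln), ref_seq, query, aln.score)


def _translate_in_frame(seq: str, frame_offset: int) -> str:
    coding = seq[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def protein_consequence(call: AlleleCall, ref: AmpliconReference) -> ProteinConsequence:
    """Protein-level consequence of an allele on the reference translation.

    Requires ``ref.frame_offset``. Residue numbers are
    ``aa_numbering_offset + codon index`` (numbering from 1 when no offset
    is configured), which lets a trimmed amplicon segment report positions
    in full-protein coordinates.
    """
    if ref.frame_offset is None:
        raise ValueError(
            "frame_offset is not configured on the reference; set it (and "
            "aa_numbering_offset for protein numbering) to request protein consequences"
        )
    offset = ref.aa_numbering_offset if ref.aa_numbering_offset is not None else 1

    if not call.edits:
        return ProteinConsequence("none")

    if call.indel_class == FRAMESHIFT:
        first = min(e.ref_pos for e in call.edits if e.kind != "substitution")
        codon = max(0, (first - ref.frame_offset)) // 3
        return ProteinConsequence("frameshift", offset + codon, "reading frame disrupted")

    p_ref = _translate_in_frame(ref.sequence, ref.frame_offset)
    p_alt = _translate_in_frame(call.seq, ref.frame_offset)
    a = 0
    while a < min(len(p_ref), len(p_alt)) and p_ref[a] == p_alt[a]:
        a += 1
    b = 0
    while (
        b < min(len(p_ref), len(p_alt)) - a
        and p_ref[len(p_ref) - 1 - b] == p_alt[len(p_alt) - 1 - b]
    ):
        b += 1
    lost = p_ref[a : len(p_ref) - b]
    gained = p_alt[a : len(p_alt) - b]

    if len(p_alt) < len(p_ref):
        detail = lost if not gained else f"{lost}>{gained}"
        return ProteinConsequence("residue_deletion", offset + a, detail)
    if len(p_alt) > len(p_ref):
        detail = gained if not lost else f"{lost}>{gained}"
        return ProteinConsequence("residue_insertion", offset + a, detail)
    if lost:
        return ProteinConsequence("missense", offset + a, f"{lost}>{gained}")
    return ProteinConsequence("none")


def edits_to_vcf_records(ref: AmpliconReference, call: AlleleCall) -> List[tuple]:
    """Edits as (CHROM, POS, REF, ALT) with 1-based, anchor-base indels."""
    records = []
    seq = ref.sequence
    for e in call.edits:
        if e.kind == "substitution":
            records.append((ref.name, e.ref_pos + 1, seq[e.ref_pos : e.ref_pos + e.length], e.alt_seq))
        elif e.kind == "deletion":
            if e.ref_pos == 0:  # no left anchor: anchor on the following base
                records.append((ref.name, 1, seq[: e.length + 1], seq[e.length]))
            else:
                p = e.ref_pos - 1
                records.append((ref.name, p + 1, seq[p : e.ref_pos + e.length], seq[p]))
        else:
            if e.ref_pos == 0:
                records.append((ref.name, 1, seq[0], e.alt_seq + seq[0]))
            else:
                p = e.ref_pos - 1
                records.append((ref.name, p + 1, seq[p], seq[p] + e.alt_seq))
    return records


def write_vcf(path, ref: AmpliconReference, calls: Iterable[tuple[str, AlleleCall]]) -> None:
    """Write per-sample allele edits as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={len(ref.sequence)}>\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        fh.write('##INFO=<ID=ALLELE,Number=1,Type=String,Description="Canonical allele name">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for sample_id, call in calls:
            for chrom, pos, r, a in edits_to_vcf_records(ref, call):
                fh.write(
                    f"{chrom}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t"
                    f"SAMPLE={sample_id};ALLELE={call.name}\n"
                )
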