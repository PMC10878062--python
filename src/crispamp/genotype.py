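"""Per-sample allele tables, founder mosaicism and diploid genotype calls.

A founder (F0) fish injected at the one-cell stage is a mosaic: its fin
clip yields many alleles at uneven proportions. Its offspring (F1) carry
at most two germline alleles at roughly 50/50. Both situations reduce to
an allele-frequency table; the difference is only how many alleles clear
the genotype threshold.

Genotype labels follow the conventional class-pair notation where the
wild-type class means "no indel" (substitution-only alleles included):

====================  =========
allele classes        label
====================  =========
frameshift/frameshift ``-/-``
in_frame/in_frame     ``if/if``
in_frame/frameshift   ``if/fs``
in_frame/no_indel     ``if/wt``
frameshift/no_indel   ``fs/wt``
no_indel/no_indel     ``+/+``
====================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .calls import FRAMESHIFT, IN_FRAME, NO_INDEL, AlleleCall

MOSAIC = "mosaic"
NO_CALL = "no_call"

_CLASS_PAIR_LABELS: Dict[Tuple[str, str], str] = {
    (FRAMESHIFT, FRAMESHIFT): "-/-",
    (IN_FRAME, IN_FRAME): "if/if",
    (IN_FRAME, FRAMESHIFT): "if/fs",
    (IN_FRAME, NO_INDEL): "if/wt",
    (FRAMESHIFT, NO_INDEL): "fs/wt",
    (NO_INDEL, NO_INDEL): "+/+",
}
# class precedence used to canonicalize unordered pairs
_CLASS_ORDER = {IN_FRAME: 0, FRAMESHIFT: 1, NO_INDEL: 2}


def class_pair_label(class1: str, class2: str) -> str:
    """Genotype label for an unordered pair of allele classes."""
    pair = tuple(sorted((class1, class2), key=_CLASS_ORDER.__getitem__))
    return _CLASS_PAIR_LABELS[pair]


@dataclass(frozen=True)
class AlleleRow:
    allele: AlleleCall
    read_count: int
    frequency: float


@dataclass(frozen=True)
class AlleleTable:
    """Retained alleles of one sample, sorted by descending read count."""

    sample_id: str
    rows: tuple[AlleleRow, ...]
    total_reads: int
    dropped_reads: int = 0
    dropped_alleles: int = 0

    def __post_init__(self) -> None:
        if self.rows:
            total = sum(r.frequency for r in self.rows)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class MosaicProfile:
    sample_id: str
    wt_fraction: float
    class_fractions: Dict[str, float]
    name_fractions: Dict[str, float]


@dataclass(frozen=True)
class SampleGenotype:
    sample_id: str
    allele1: Optional[AlleleCall]
    allele2: Optional[AlleleCall]
    label: str
    allele_fractions: tuple[float, ...]
    single_allele_call: bool = False


def tally_alleles(
    calls: Iterable[AlleleCall],
    min_count: int = 5,
    min_frequency: float = 0.01,
    sample_id: str = "",
) -> AlleleTable:
    """Collapse identical allele sequences and drop sequencing noise.

    Alleles below ``min_count`` reads or ``min_frequency`` of the sample
    are removed and the remaining frequencies renormalized; the dropped
    mass is reported on the table, never silently discarded.
    """
    calls = list(calls)
    if not calls:
        raise ValueError(f"sample {sample_id!r}: no alleles to tally")
    by_seq: Dict[str, List[AlleleCall]] = {}
    for call in calls:
        by_seq.setdefault(call.seq, []).append(call)
    total = len(calls)
    kept: List[Tuple[AlleleCall, int]] = []
    dropped_reads = 0
    dropped_alleles = 0
    for seq, group in by_seq.items():
        count = len(group)
        if count >= min_count and count / total >= min_frequency:
            kept.append((group[0], count))
        else:
            dropped_reads += count
            dropped_alleles += 1
    if not kept:
        raise ValueError(
            f"sample {sample_id!r}: all {len(by_seq)} alleles fell below the "
            f"noise thresholds (min_count={min_count}, min_frequency={min_frequency})"
        )
    kept.sort(key=lambda item: (-item[1], item[0].seq))
    retained = sum(count for _, count in kept)
    rows = tuple(
        AlleleRow(call, count, count / retained) for call, count in kept
    )
    return AlleleTable(sample_id, rows, total, dropped_reads, dropped_alleles)


def mosaic_profile(table: AlleleTable) -> MosaicProfile:
    """Per-class and per-name variant fractions of one sample.

    The observed frequencies are the maximum-likelihood estimates of the
    underlying multinomial proportions, so no further estimation step is
    needed.
    """
    if not table.rows:
        raise ValueError("empty allele table")
    class_fr = {NO_INDEL: 0.0, IN_FRAME: 0.0, FRAMESHIFT: 0.0}
    name_fr: Dict[str, float] = {}
    wt = 0.0
    for row in table.rows:
        class_fr[row.allele.indel_class] += row.frequency
        name_fr[row.allele.name] = name_fr.get(row.allele.name, 0.0) + row.frequency
        if row.allele.identical_to_wt:
            wt += row.frequency
    return MosaicProfile(table.sample_id, wt, class_fr, name_fr)


def call_genotype(
    table: AlleleTable,
    min_allele_fraction: float = 0.20,
    max_alleles: int = 2,
) -> SampleGenotype:
    """Call a diploid genotype from an allele table.

    Alleles at frequency >= ``min_allele_fraction`` are genotype alleles:
    exactly one means homozygous (the allele is duplicated and the call is
    flagged as single-allele, since large-deletion dropout cannot be
    excluded), exactly two means heterozygous, more than ``max_alleles``
    yields the ``mosaic`` label, none yields ``no_call``.
    """
    major = [row for row in table.rows if row.frequency >= min_allele_fraction]
    fracs = tuple(row.frequency for row in major)
    if not major:
        return SampleGenotype(table.sample_id, None, None, NO_CALL, fracs)
    if len(major) > max_alleles:
        return SampleGenotype(table.sample_id, None, None, MOSAIC, fracs)
    if len(major) == 1:
        allele = major[0].allele
        label = class_pair_label(allele.indel_class, allele.indel_class)
        return SampleGenotype(table.sample_id, allele, allele, label, fracs, True)
    a1, a2 = major[0].allele, major[1].allele
    label = class_pair_label(a1.indel_class, a2.indel_class)
    return SampleGenotype(table.sample_id, a1, a2, label, fracs)


def genotype_frame(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    """Genotype calls as a tidy table (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in genotypes],
            "allele1": [g.allele1.name if g.allele1 else "" for g in genotypes],
            "allele2": [g.allele2.name if g.allele2 else "" for g in genotypes],
            "label": [g.label for g in genotypes],
            "single_allele_call": [g.single_allele_call for g in genotypes],
        }
    )


def summarize_cohort(
    genotypes: Sequence[SampleGenotype], phenotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Join genotype calls with a phenotype table and tally the cohort.

    Returns the per-fish joined table, a genotype x sampling-month x
    maturity contingency table of counts, and the list of sample ids
    present on only one side of the join (reported, not fatal).
    """
    geno = genotype_frame(genotypes)
    pheno = phenotypes.copy()
    pheno["sample_id"] = pheno["sample_id"].astype(str)
    joined = geno.merge(pheno, on="sample_id", how="inner")
    unmatched = sorted(
        set(geno.sample_id).symmetric_difference(set(pheno.sample_id))
    )
    counts = (
        joined.groupby(["label", "sampling_month", "maturity"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
    return joined, counts, unmatched
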