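"""End-to-end orchestration: configuration, pipelines and run artifacts.

The genotyping pipeline chains the stages: primer check and trim on each
mate, pair merging, global alignment of the consensus to the inner
reference segment, edit extraction and classification, noise-filtered
allele tallying, and diploid genotype calling. Bare allele sequences
(FASTA/TSV) enter the same chain after the merging stage, with the
read-count noise filter disabled (each row is a curated allele, not a
read).

Every run writes a manifest recording the package version, thresholds,
seed and input digests, so outputs are reproducible byte-for-byte from
(config, inputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .align import ScoringScheme
from .calls import AlleleCall, call_allele, write_vcf
from .genotype import (
    AlleleTable,
    SampleGenotype,
    call_genotype,
    class_pair_label,
    genotype_frame,
    summarize_cohort,
    tally_alleles,
)
from .phenostats import compare_groups, maturity_by_genotype
from .readio import MERGED, ReadPair, match_and_trim_primer, merge_pair, read_sequences
from .reference import (
    AmpliconReference,
    fshr_exon2_reference,
    fshr_synthetic_amplicon,
)
from .simulate import (
    SimTruth,
    simulate_f0_cohort,
    simulate_f1_cross,
    simulate_reads,
    truth_frame,
    write_fastq_pair,
)


@dataclass
class RunConfig:
    """All pipeline thresholds and run settings in one serializable place."""

    max_primer_mismatch: int = 1
    min_overlap: int = 30
    max_overlap_mismatch_rate: float = 0.1
    min_count: int = 5
    min_frequency: float = 0.01
    min_allele_fraction: float = 0.20
    max_alleles: int = 2
    match: int = 2
    mismatch: int = -3
    gap_open: int = -8
    gap_extend: int = -1
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.max_primer_mismatch <= 5:
            raise ValueError("max_primer_mismatch must be in [0, 5]")
        if not 0 < self.min_allele_fraction <= 0.5:
            raise ValueError("min_allele_fraction must be in (0, 0.5]")
        if not 0 <= self.max_overlap_mismatch_rate <= 1:
            raise ValueError("max_overlap_mismatch_rate must be in [0, 1]")
        if not 0 <= self.min_frequency < 1:
            raise ValueError("min_frequency must be in [0, 1)")
        self.scoring  # validate scoring parameters

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    n_pairs: int
    n_primer_fail: int
    n_overlap_fail: int
    n_merged: int


def genotype_read_pairs(
    sample_id: str,
    pairs: Iterable[ReadPair],
    ref: AmpliconReference,
    config: RunConfig | None = None,
    cache: Optional[Dict[str, AlleleCall]] = None,
) -> Tuple[AlleleTable, SampleGenotype, SampleMetrics]:
    """Run one sample's read pairs through the full genotyping chain."""
    config = config or RunConfig()
    cache = {} if cache is None else cache
    inner = ref.inner_sequence
    n_pairs = n_primer_fail = n_overlap_fail = 0
    calls: List[AlleleCall] = []
    for pair in pairs:
        n_pairs += 1
        m1 = match_and_trim_primer(pair.fwd_seq, ref.fwd_primer, config.max_primer_mismatch)
        m2 = match_and_trim_primer(pair.rev_seq, ref.rev_primer, config.max_primer_mismatch)
        if not (m1.accepted and m2.accepted):
            n_primer_fail += 1
            continue
        trimmed = ReadPair(
            pair.id,
            m1.trimmed,
            m2.trimmed,
            pair.fwd_qual[len(ref.fwd_primer) :],
            pair.rev_qual[len(ref.rev_primer) :],
        )
        merged = merge_pair(trimmed, config.min_overlap, config.max_overlap_mismatch_rate)
        if merged.status != MERGED:
            n_overlap_fail += 1
            continue
        call = cache.get(merged.seq)
        if call is None:
            call = call_allele(merged.seq, inner, config.scoring)
            cache[merged.seq] = call
        calls.append(call)
    if not calls:
        raise ValueError(
            f"sample {sample_id!r}: no read pair survived primer/overlap checks "
            f"({n_pairs} pairs, {n_primer_fail} primer failures, {n_overlap_fail} overlap failures)"
        )
    table = tally_alleles(calls, config.min_count, config.min_frequency, sample_id)
    genotype = call_genotype(table, config.min_allele_fraction, config.max_alleles)
    metrics = SampleMetrics(
        sample_id, n_pairs, n_primer_fail, n_overlap_fail, n_pairs - n_primer_fail - n_overlap_fail
    )
    return table, genotype, metrics


def genotype_bare_sequences(
    records: Sequence[Tuple[str, str]],
    ref: AmpliconReference,
    config: RunConfig | None = None,
) -> Tuple[Dict[str, AlleleTable], List[SampleGenotype]]:
    """Genotype samples given curated allele sequences (one row per allele).

    One row means a homozygote, two rows a heterozygote. The read-count
    noise filter does not apply (min_count 1, min_frequency 0).
    """
    if not records:
        raise ValueError("no input sequences")
    config = config or RunConfig()
    by_sample: Dict[str, List[str]] = {}
    for sample_id, seq in records:
        by_sample.setdefault(str(sample_id), []).append(seq)
    cache: Dict[str, AlleleCall] = {}
    tables: Dict[str, AlleleTable] = {}
    genotypes: List[SampleGenotype] = []
    for sample_id, seqs in by_sample.items():
        calls = []
        for seq in seqs:
            call = cache.get(seq)
            if call is None:
                call = call_allele(seq, ref.sequence, config.scoring)
                cache[seq] = call
            calls.append(call)
        table = tally_alleles(calls, min_count=1, min_frequency=0.0, sample_id=sample_id)
        tables[sample_id] = table
        genotypes.append(call_genotype(table, config.min_allele_fraction, config.max_alleles))
    return tables, genotypes


def allele_table_frame(tables: Dict[str, AlleleTable]) -> pd.DataFrame:
    rows = []
    for sample_id, table in tables.items():
        for row in table.rows:
            rows.append(
                {
                    "sample_id": sample_id,
                    "allele_seq": row.allele.seq,
                    "name": row.allele.name,
                    "net_indel": row.allele.net_indel,
                    "class": row.allele.indel_class,
                    "edits": ";".join(e.token for e in row.allele.edits) or ".",
                    "count": row.read_count,
                    "frequency": row.frequency,
                }
            )
    return pd.DataFrame(rows)


def true_genotype_labels(
    truths: Sequence[SimTruth], ref: AmpliconReference, config: RunConfig | None = None
) -> Dict[str, str]:
    """Class-pair genotype labels implied by simulation truth alleles."""
    config = config or RunConfig()
    inner_cache: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    lo, hi = len(ref.fwd_primer), -len(ref.rev_primer) or None
    for truth in truths:
        classes = []
        seqs = [seq for _, seq in truth.alleles]
        if len(seqs) == 1:
            seqs = seqs * 2
        for seq in seqs[:2]:
            inner = seq[lo:hi]
            cls = inner_cache.get(inner)
            if cls is None:
                cls = call_allele(inner, ref.inner_sequence, config.scoring).indel_class
                inner_cache[inner] = cls
            classes.append(cls)
        labels[truth.sample_id] = class_pair_label(*classes)
    return labels


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, inputs: Dict[str, str], extra: dict) -> None:
    manifest = {
        "tool": "crispamp",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": inputs,
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_genotype(
    config: RunConfig,
    ref: AmpliconReference,
    r1: Optional[str] = None,
    r2: Optional[str] = None,
    alleles: Optional[str] = None,
    sample_id: str = "sample",
    vcf: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Genotype one FASTQ pair or a bare-allele table; write TSV outputs.

    Writes ``alleles.tsv``, ``genotypes.tsv``, ``metrics.tsv`` (read input
    only), an optional per-allele VCF, and ``manifest.json`` under
    ``config.out_dir``. Returns the tables as DataFrames.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: Dict[str, str] = {}
    metrics_df = None
    if alleles is not None:
        fmt = "fasta" if str(alleles).endswith((".fa", ".fasta", ".fa.gz", ".fasta.gz")) else "tsv"
        records = list(read_sequences(alleles, fmt))
        if not records:
            raise ValueError(f"{alleles}: no sequences found")
        tables, genotypes = genotype_bare_sequences(records, ref, config)
        inputs[str(alleles)] = _sha256(alleles)
    elif r1 is not None and r2 is not None:
        pairs = read_sequences((r1, r2), "fastq-pair")
        table, genotype, metrics = genotype_read_pairs(sample_id, pairs, ref, config)
        tables, genotypes = {sample_id: table}, [genotype]
        metrics_df = pd.DataFrame([dataclasses.asdict(metrics)])
        inputs[str(r1)] = _sha256(r1)
        inputs[str(r2)] = _sha256(r2)
    else:
        raise ValueError("provide either alleles=, or both r1= and r2=")

    allele_df = allele_table_frame(tables)
    geno_df = genotype_frame(genotypes)
    allele_df.to_csv(out_dir / "alleles.tsv", sep="\t", index=False)
    geno_df.to_csv(out_dir / "genotypes.tsv", sep="\t", index=False)
    result = {"alleles": allele_df, "genotypes": geno_df}
    if metrics_df is not None:
        metrics_df.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        result["metrics"] = metrics_df
    if vcf:
        calls = [
            (sid, row.allele)
            for sid, table in tables.items()
            for row in table.rows
        ]
        write_vcf(out_dir / "alleles.vcf", ref, calls)
    _write_manifest(out_dir, config, inputs, {"n_samples": len(tables)})
    return result


def run_simulate(config: RunConfig, scenario: dict, ref: Optional[AmpliconReference] = None):
    """Simulate a scenario and write FASTQ pairs plus a truth table.

    The scenario mapping needs a ``kind`` ("f0_cohort" or "f1_cross") and
    the corresponding simulator arguments; validation errors name the
    missing field.
    """
    ref = ref or fshr_synthetic_amplicon()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = scenario.get("kind")
    if kind is None:
        raise ValueError("scenario is missing required field 'kind'")
    common = {
        k: scenario[k] for k in ("n_reads", "read_len", "error_rate") if k in scenario
    }
    if kind == "f0_cohort":
        from .simulate import default_allele_pool

        for fieldname in ("n_fish", "dirichlet_concentration"):
            if fieldname not in scenario:
                raise ValueError(f"scenario is missing required field {fieldname!r}")
        pool = scenario.get("allele_pool") or default_allele_pool(ref)
        truths = simulate_f0_cohort(
            scenario["n_fish"],
            scenario["dirichlet_concentration"],
            pool,
            seed=config.seed,
            **common,
        )
    elif kind == "f1_cross":
        for fieldname in ("parent1_gametes", "parent2_gametes", "n_offspring"):
            if fieldname not in scenario:
                raise ValueError(f"scenario is missing required field {fieldname!r}")
        truths = simulate_f1_cross(
            scenario["parent1_gametes"],
            scenario["parent2_gametes"],
            scenario["n_offspring"],
            seed=config.seed,
            **common,
        )
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    for truth in truths:
        pairs = simulate_reads(truth, ref)
        write_fastq_pair(
            pairs,
            out_dir / f"{truth.sample_id}_R1.fastq.gz",
            out_dir / f"{truth.sample_id}_R2.fastq.gz",
        )
    tf = truth_frame(truths)
    tf.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    _write_manifest(out_dir, config, {}, {"scenario": {k: str(v) for k, v in scenario.items()}})
    return truths


def run_stats(
    config: RunConfig,
    phenotypes: pd.DataFrame,
    genotypes: Optional[pd.DataFrame] = None,
    variables: Sequence[str] = ("gsi", "plasma_11kt"),
) -> Dict[str, pd.DataFrame]:
    """Group comparisons per variable by genotype, plus maturity tallies.

    ``phenotypes`` needs ``sample_id``, ``genotype`` (or a genotype table
    to join on), ``maturity`` and ``sampling_month``; numeric columns
    named in ``variables`` are compared between genotype groups when
    present.
    """
    df = phenotypes.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if genotypes is not None:
        geno = genotypes.copy()
        geno["sample_id"] = geno["sample_id"].astype(str)
        df = df.drop(columns=[c for c in ("genotype",) if c in df]).merge(
            geno[["sample_id", "label"]].rename(columns={"label": "genotype"}),
            on="sample_id",
            how="inner",
        )
    if "genotype" not in df:
        raise ValueError("no genotype column available after join")

    tallies = maturity_by_genotype(df)
    reports = []
    for var in variables:
        if var not in df:
            continue
        sub = df.dropna(subset=[var])
        groups = {
            str(label): grp[var].to_numpy()
            for label, grp in sub.groupby("genotype")
            if len(grp) >= 2
        }
        if len(groups) < 2:
            continue
        res = compare_groups(groups, adjust="holm")
        reports.append(
            {
                "variable": var,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "groups": ",".join(f"{k}(n={v})" for k, v in res.group_sizes.items()),
            }
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_df = pd.DataFrame(reports)
    tallies.to_csv(out_dir / "maturity_by_genotype.tsv", sep="\t", index=False)
    report_df.to_csv(out_dir / "group_tests.tsv", sep="\t", index=False)
    return {"tests": report_df, "maturity": tallies}
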