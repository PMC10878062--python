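"""Bundled example data: the *fshr* exon-2 F1 genotyping cohort.

Two small published tables ship with the package: the per-fish exon-2
allele sequences of the sequenced F1 fish (one row per allele; a single
row means a homozygote) and the matching phenotype table (sampling month,
maturity, reported genotype and mutation labels). Together with
:func:`crispamp.reference.fshr_exon2_reference` they exercise the whole
genotyping chain without any sequencing run.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("crispamp").joinpath("data", name)


def load_f1_alleles() -> pd.DataFrame:
    """Per-fish allele sequences (columns: sample_id, sequence)."""
    with resources.as_file(_data_path("fshr_f1_alleles.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def load_f1_phenotypes() -> pd.DataFrame:
    """Per-fish phenotype table (sampling month, maturity, genotype labels)."""
    with resources.as_file(_data_path("fshr_f1_phenotypes.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def f1_allele_records() -> list[tuple[str, str]]:
    """Allele rows as (sample_id, sequence) pairs for the pipeline."""
    df = load_f1_alleles()
    return list(df.itertuples(index=False, name=None))
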