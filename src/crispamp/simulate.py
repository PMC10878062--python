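"""Synthetic alleles, reads and cohorts with known ground truth.

The study design this emulates: founder (F0) fish are mosaics carrying
many edited alleles at uneven proportions (drawn here from a Dirichlet
over an allele pool, wild type included, with pool weights defaulting to
the variant prevalences observed in the source cohort); F1 offspring are
diploid, inheriting one germline allele from each parent, so their reads
split roughly 50/50 between two alleles. Sequencing noise is i.i.d.
substitution error at a configurable per-base rate; indel errors are not
modelled (they are orders of magnitude rarer on the MiSeq platform and
are handled by the genotyping noise filter).

All randomness derives from a single seed through
``numpy.random.SeedSequence`` spawning, so any stage can be re-run in
isolation and outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calls import Edit, apply_edits
from .readio import ReadPair
from .reference import AmpliconReference, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EditSpec:
    """Recipe for one synthetic allele edit on the reference."""

    kind: str  # deletion | insertion | substitution
    position: int
    length: int
    bases: str = "random"  # explicit DNA, or "random"


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    alleles: tuple[tuple[str, str], ...]  # (allele name, full sequence)
    proportions: tuple[float, ...]
    n_reads: int = 1000
    read_len: int = 150
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("allele proportions must sum to 1")
        if len(self.proportions) != len(self.alleles):
            raise ValueError("one proportion per allele required")


def _spawn(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_allele(ref: AmpliconReference, specs: EditSpec | Sequence[EditSpec], seed: int = 0) -> str:
    """Apply edit specs to the reference sequence, deterministically.

    Random inserted/substituted bases are drawn from the seed; a
    substitution is guaranteed to differ from the reference base.
    """
    if isinstance(specs, EditSpec):
        specs = [specs]
    rng = np.random.Generator(np.random.PCG64(seed))
    edits: List[Edit] = []
    for spec in specs:
        if spec.kind == "deletion":
            if spec.position + spec.length > len(ref.sequence):
                raise ValueError("deletion extends past the reference")
            edits.append(Edit("deletion", spec.position, spec.length))
            continue
        if spec.position > len(ref.sequence):
            raise ValueError("edit position outside the reference")
        if spec.bases == "random":
            alt = _random_dna(rng, spec.length)
            if spec.kind == "substitution":
                alt = "".join(
                    "ACGT"[("ACGT".index(b) + 1) % 4] if b == r else b
                    for b, r in zip(alt, ref.sequence[spec.position : spec.position + spec.length])
                )
        else:
            alt = spec.bases
        edits.append(Edit(spec.kind, spec.position, spec.length, alt))
    return apply_edits(ref.sequence, sorted(edits, key=lambda e: e.ref_pos))


def _add_errors(seq_codes: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq_codes
    hits = np.nonzero(rng.random(len(seq_codes)) < rate)[0]
    if len(hits) == 0:
        return seq_codes
    out = seq_codes.copy()
    # substitute with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=len(hits))
    base_idx = np.searchsorted(_BASES, out[hits])
    out[hits] = _BASES[(base_idx + shift) % 4]
    return out


def simulate_reads(truth: SimTruth, ref: AmpliconReference) -> List[ReadPair]:
    """Draw paired reads from a sample's true allele mixture.

    Read counts per allele are multinomial in the true proportions; R1 is
    the 5' ``read_len`` of the allele amplicon, R2 the 5' ``read_len`` of
    its reverse complement, so both carry their primer at the 5' end.
    Base qualities are constant at the Phred equivalent of the error rate.
    """
    if truth.read_len > min(len(seq) for _, seq in truth.alleles):
        raise ValueError("read_len exceeds an allele amplicon length")
    if not 0 <= truth.error_rate <= 0.05:
        raise ValueError("error rate must be in [0, 0.05]")
    rng_counts, rng_err = _spawn(truth.seed, 2)
    counts = rng_counts.multinomial(truth.n_reads, truth.proportions)
    qual = 40 if truth.error_rate == 0 else min(40, round(-10 * np.log10(truth.error_rate)))
    quals = tuple([qual] * truth.read_len)
    pairs: List[ReadPair] = []
    idx = 0
    for (name, seq), count in zip(truth.alleles, counts):
        fwd = np.frombuffer(seq[: truth.read_len].encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(seq)[: truth.read_len].encode(), dtype=np.uint8)
        for _ in range(count):
            r1 = _add_errors(fwd, rng_err, truth.error_rate)
            r2 = _add_errors(rev, rng_err, truth.error_rate)
            pairs.append(
                ReadPair(
                    f"{truth.sample_id}:{idx}",
                    r1.tobytes().decode(),
                    r2.tobytes().decode(),
                    quals,
                    quals,
                )
            )
            idx += 1
    return pairs


def write_fastq_pair(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    """Write mates to two FASTQ files (gzipped when the path ends in .gz)."""

    def _open(path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for pair in pairs:
            q1 = "".join(chr(q + 33) for q in pair.fwd_qual)
            q2 = "".join(chr(q + 33) for q in pair.rev_qual)
            f1.write(f"@{pair.id}/1\n{pair.fwd_seq}\n+\n{q1}\n")
            f2.write(f"@{pair.id}/2\n{pair.rev_seq}\n+\n{q2}\n")


def truth_frame(truths: Sequence[SimTruth]) -> pd.DataFrame:
    """Truth tables as a tidy DataFrame (one row per sample x allele)."""
    rows = []
    for t in truths:
        for (name, _), prop in zip(t.alleles, t.proportions):
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "allele": name,
                    "proportion": prop,
                    "n_reads": t.n_reads,
                    "error_rate": t.error_rate,
                    "seed": t.seed,
                }
            )
    return pd.DataFrame(rows)


# Default F0 allele pool: the distinct edit structures seen in the source
# cohort's founder fin clips, placed at the CRISPR cut site, with pool
# weights matching the reported cohort mean prevalences (wild type 16.5%,
# del3 47.7%, the remainder split over the frameshift/other structures).
_F0_POOL_SPECS: Dict[str, Tuple[EditSpec, ...]] = {
    "del3": (EditSpec("deletion", 0, 3),),
    "del1": (EditSpec("deletion", 0, 1),),
    "del8": (EditSpec("deletion", 0, 8),),
    "del14": (EditSpec("deletion", 0, 14),),
    "del17": (EditSpec("deletion", 0, 17),),
    "ins7": (EditSpec("insertion", 0, 7),),
    "ins8": (EditSpec("insertion", 0, 8),),
    "ins17": (EditSpec("insertion", 0, 17),),
}


def default_allele_pool(ref: AmpliconReference, seed: int = 20) -> Dict[str, str]:
    """Named allele sequences (wild type included) for cohort simulation.

    Indels are anchored at the expected Cas9 cut site, 3 bp from the
    PAM-proximal end of the protospacer.
    """
    if ref.target_strand == "-":
        cut = ref.target_start + 3
    else:
        cut = ref.target_end - 3
    pool = {"wt": ref.sequence}
    for i, (name, specs) in enumerate(_F0_POOL_SPECS.items()):
        shifted = [
            EditSpec(s.kind, cut + s.position, s.length, s.bases) for s in specs
        ]
        pool[name] = make_allele(ref, shifted, seed=seed + i)
    return pool


def default_pool_weights(pool: Dict[str, str]) -> Dict[str, float]:
    """Pool-mean proportions: wt 0.165, del3 0.477, rest uniform."""
    others = [k for k in pool if k not in {"wt", "del3"}]
    weights = {"wt": 0.165, "del3": 0.477}
    for k in others:
        weights[k] = (1.0 - 0.165 - 0.477) / len(others)
    return weights


def simulate_f0_cohort(
    n_fish: int,
    dirichlet_concentration: float,
    allele_pool: Dict[str, str],
    seed: int,
    pool_weights: Optional[Dict[str, float]] = None,
    n_reads: int = 1000,
    read_len: int = 150,
    error_rate: float = 0.001,
) -> List[SimTruth]:
    """Mosaic founder cohort: per-fish proportions ~ Dirichlet over the pool.

    The Dirichlet parameters are ``concentration * pool_weights``, so the
    concentration controls fish-to-fish variability while the pool
    weights set the cohort mean; as concentration -> infinity every fish
    approaches the pool-mean proportions.
    """
    if not allele_pool:
        raise ValueError("allele pool must be non-empty")
    weights = pool_weights or default_pool_weights(allele_pool)
    names = list(allele_pool)
    alpha = np.array([weights[n] for n in names]) * dirichlet_concentration
    ss = np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_fish + 1)[1:]]
    truths = []
    for i in range(n_fish):
        props = rng.dirichlet(alpha)
        props = props / props.sum()
        truths.append(
            SimTruth(
                sample_id=f"F0_{i:03d}",
                alleles=tuple((n, allele_pool[n]) for n in names),
                proportions=tuple(props),
                n_reads=n_reads,
                read_len=read_len,
                error_rate=error_rate,
                seed=child_seeds[i],
            )
        )
    return truths


def simulate_f1_cross(
    parent1_gametes: Dict[str, Tuple[str, float]],
    parent2_gametes: Dict[str, Tuple[str, float]],
    n_offspring: int,
    seed: int,
    n_reads: int = 1000,
    read_len: int = 150,
    error_rate: float = 0.001,
) -> List[SimTruth]:
    """Diploid offspring of two parents with known germline allele pools.

    Each gamete pool maps allele name -> (sequence, transmission
    probability). Every offspring draws one allele per parent
    independently and its reads split 50/50 between the two (identical
    alleles collapse to a single homozygous allele).
    """
    for pool in (parent1_gametes, parent2_gametes):
        total = sum(p for _, p in pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("gamete transmission probabilities must sum to 1")
    ss = np.random.SeedSequence(seed)
    spawned = ss.spawn(n_offspring + 1)
    rng = np.random.Generator(np.random.PCG64(spawned[0]))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in spawned[1:]]
    names1, names2 = list(parent1_gametes), list(parent2_gametes)
    p1 = np.array([parent1_gametes[n][1] for n in names1])
    p2 = np.array([parent2_gametes[n][1] for n in names2])
    truths = []
    for i in range(n_offspring):
        a1 = names1[rng.choice(len(names1), p=p1)]
        a2 = names2[rng.choice(len(names2), p=p2)]
        seq1, seq2 = parent1_gametes[a1][0], parent2_gametes[a2][0]
        if seq1 == seq2:
            alleles = ((a1, seq1),)
            props = (1.0,)
        else:
            alleles = ((a1, seq1), (a2, seq2))
            props = (0.5, 0.5)
        truths.append(
            SimTruth(
                sample_id=f"F1_{i:03d}",
                alleles=alleles,
                proportions=props,
                n_reads=n_reads,
                read_len=read_len,
                error_rate=error_rate,
                seed=child_seeds[i],
            )
        )
    return truths
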