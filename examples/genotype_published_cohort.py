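"""Genotype the bundled F1 cohort from its printed allele sequences.

Loads the per-fish exon-2 allele table shipped with the package (one row
per sequenced allele; a single row means a homozygote), aligns every
allele to the wild-type segment, classifies indels, and calls diploid
genotypes. The printed counts are the cohort composition: fish with two
frameshift alleles (-/-) have lost receptor function, if/if fish carry
the 3-nt in-frame deletion on both alleles, and mixed fish pair an
in-frame allele with a frameshift or wild-type allele.
"""

import collections

from crispamp import fshr_exon2_reference, genotype_bare_sequences, protein_consequence
from crispamp.datasets import f1_allele_records

ref = fshr_exon2_reference()
records = f1_allele_records()
tables, genotypes = genotype_bare_sequences(records, ref)

print(f"{len(records)} allele sequences from {len(tables)} fish")
counts = collections.Counter(g.label for g in genotypes)
for label in ("-/-", "if/if", "if/fs", "if/wt"):
    print(f"  {label:6s} {counts[label]:3d} fish")

# the in-frame allele shared by every if/if fish, at the protein level
ifif = next(g for g in genotypes if g.label == "if/if")
consequence = protein_consequence(ifif.allele1, ref)
print(
    f"\nif/if allele '{ifif.allele1.name}': net indel {ifif.allele1.net_indel} nt, "
    f"{consequence.kind} of residue {consequence.detail} at position {consequence.aa_position}"
)
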