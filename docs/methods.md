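# Methods

## Problem setting

CRISPR-Cas9 injection at the one-cell stage produces founder (F0) fish
that are genetic mosaics: editing happens independently in different
early blastomeres, so a fin clip contains many alleles at uneven
proportions, usually with a small wild-type remainder. F1 offspring
inherit at most two germline alleles and behave as ordinary diploids.
Both situations are genotyped from the same data type — deep-sequenced
PCR amplicons spanning the target site — and reduce to an
allele-frequency table per fish. The biological readout in the source
programme is whether *fshr* (the follicle-stimulating hormone receptor
gene of Atlantic salmon) retains its reading frame: fish with two
frameshift alleles fail to enter puberty, while the common 3-nt
in-frame deletion preserves partial receptor function.

## Read model

Reads must contain their primer at the very 5′ end. The check is
anchored at position 0 and allows substitutions only (Hamming distance
on the equal-length prefix, ≤1 mismatch by default, N counting as a
mismatch): this is the strictest deterministic reading of a
"primer present in the 5′ end" rule and makes acceptance exactly a
Hamming-ball membership, which the tests verify against a brute-force
scan. Failing reads are tallied in run metrics, never silently dropped.

Merging reverse-complements the reverse mate and scans every overlap
offset; only offsets with overlap ≥ `min_overlap` (default 30 nt) and
mismatch rate ≤ `max_overlap_mismatch_rate` (default 0.1) are
admissible, and among those the one with the most matching bases wins
(ties to the longer overlap). Restricting the scan to admissible
offsets matters: maximizing raw matches alone lets a long, low-identity
spurious overlap outscore a short error-free one on insertion alleles.
Within the overlap the base with the higher Phred score is taken (tie →
forward base, recorded as a fixed convention; an N never beats a called
base) and the quality is the per-position maximum. No assembler
parameters were published for the source data; these defaults merge
every bundled allele (net indels up to ±17 nt) with 150-nt reads on the
250-nt synthetic amplicon and 300-nt reads on real-scale products.

## Alignment

Alleles are placed by end-to-end (global) pairwise alignment with
affine gap penalties, computed with the three-state Gotoh recurrence
(match/mismatch, gap-in-query, gap-in-reference) and full traceback;
the inner loops are numba-compiled. A multiple-sequence aligner was
used in the source pipeline; a bespoke pairwise aligner is used here
because each read is independently compared to one reference and the
stage's only job is edit extraction, which a pairwise optimum defines
completely. Scoring defaults (+2 match, −3 mismatch, −8 gap open, −1
gap extend; a length-*L* gap costs open + (L−1)·extend) favour one
contiguous indel over scattered gaps, matching how CRISPR repair
outcomes are conventionally written. Tie-breaking is deterministic:
diagonal over gap states, gap-in-query over gap-in-reference, gap
extension over re-opening. Scores are verified against a cubic
dynamic-programming oracle that enumerates every gap length with no
affine machinery (1000 seeded instances ≤40 nt), and cross-checked
against Biopython's independent affine aligner.

Edit extraction converts gap runs to deletion/insertion edits and
mismatch runs to substitution edits, then left-realigns every indel
maximally (shifting a gap left while the flanking base re-matches,
without crossing a neighbouring edit). Left realignment makes
coordinates and names canonical even where the optimum placement is
ambiguous (the del3 gap can sit at three positions; it is always
reported at reference offset 36). Applying the edit list to the
reference must reconstruct the query byte-exactly; this round-trip is
tested for all 46 bundled alleles and by property tests.

## Classification and naming

Class is a function of the net indel length alone: `no_indel` when no
indel edits exist, `in_frame` when the net length is a nonzero multiple
of 3, `frameshift` otherwise. Substitutions never affect class or name
— forced by the bundled cohort, where one fish pairs del3 with a
substitution-only allele and is recorded as if/wt. Names are the
ordered indel tokens (`del3`, `ins8`, `del1+ins8`, …), `wt` for a
sequence identical to the reference and `sub` for substitution-only
alleles. The frameshift rule is validated against an independent
translation oracle: for every single deletion of length 1–60, the class
equals whether the translated downstream peptide changes.

Protein consequences require the reference's codon phase
(`frame_offset`) and optionally a residue-numbering offset. The exon-2
segment's phase is not derivable from the segment itself; the bundled
reference carries `frame_offset=1` and `aa_numbering_offset=60`, the
unique values consistent with the published protein coordinates of the
del3 variant (loss of the glutamate codon at residue 72). With a
configured frame, in-frame consequences are computed by translating
reference and allele and diffing the peptides (common prefix/suffix);
frameshifts report the codon of the first indel.

## Genotyping

Identical sequences are collapsed; alleles below `min_count` = 5 reads
or `min_frequency` = 1% are treated as sequencing noise, removed, and
reported as dropped mass. Alleles at ≥ `min_allele_fraction` = 20% of
retained reads are genotype alleles: exactly one → homozygote (flagged
`single_allele_call`, since dropout of a large-deletion allele cannot
be excluded), two → heterozygote, more → `mosaic`, none → `no_call`.
The source study published no depth or cutoff values; these defaults
are declared choices such that 50/50 diploid alleles always pass and
i.i.d. substitution-error alleles at MiSeq-like rates essentially never
do, and all of them are configurable and logged in the run manifest.
Mosaic profiles report per-class and per-name read fractions; the
observed frequencies are the maximum-likelihood multinomial estimates,
so no further estimation is performed. Bare-allele inputs (curated
sequences rather than reads) bypass the count-based noise filter.

## Phenotype statistics

GSI = gonad weight × 100 / body weight (percent); relative expression
2^−((Ct_target − Ct_ref) − ΔCt_calibrator). Two-group comparisons use
an unpaired equal-variance t test only when both groups have n ≥ 8 and
pass the D'Agostino–Pearson omnibus normality test at α = 0.05;
otherwise the two-sided Mann–Whitney test. "Too few to test for
normality" is implemented as: either group with n < 8 skips the gate
and goes nonparametric. For groups of ≤7 per side the Mann–Whitney p
is exact, enumerating all C(n₁+n₂, n₁) assignments of the pooled
observed values (valid under ties; the two-sided p counts assignments
with |U − n₁n₂/2| at least as large as observed); larger groups use the
tie-corrected normal approximation. Multi-group comparisons use
Kruskal–Wallis followed by Dunn's pairwise z tests with tie correction;
the multiplicity adjustment was not named in the source description, so
Holm is used (configurable). For two groups Dunn's z² equals the
tie-corrected Kruskal–Wallis H, which the tests exploit as an
independent check of the rank-variance formula.

## Simulator

The generator emulates the study conditions: a 250-bp amplicon (real
primers and published 72-nt target segment, synthetic flanking filler,
since the full product sequence outside the printed segment is not
public), founder allele proportions drawn from a Dirichlet whose mean
is the reported cohort composition (16.5% wild type, 47.7% del3, the
remainder split over the other observed edit structures), Mendelian F1
crosses with independent per-parent transmission, 150-nt paired reads
with the primer at each 5′ end, and i.i.d. substitution errors at 0.1%
per base by default with constant Phred qualities at the matching
error probability. It does not model PCR amplification bias, chimeras,
indel sequencing errors, quality miscalibration or index hopping —
passing recovery tests therefore shows correctness of the analysis
under multinomial sampling and substitution noise, not robustness to
those artefacts. All randomness derives from one seed via
`SeedSequence` spawning; outputs are bit-reproducible given (config,
seed).

## Validation scale and numerical choices

The heavier checks run at deliberately chosen sizes: alignment oracle
agreement on 1000 random pairs ≤40 nt; founder-recovery at 5000 reads
(binomial SE ≈ 0.007, tolerance ±0.03); F1 recovery on 100 offspring ×
500 read pairs at 0.1% error (≥99% of calls must equal truth);
Mendelian class frequencies on 400 offspring within 3 binomial SE;
Kruskal–Wallis type-I error over 1000 null simulations within 0.05 ±
0.02. Frequencies are exact rational counts until the final division;
allele tables assert Σfrequency = 1 within 1e-9. Degenerate inputs
(empty samples, all-noise samples, single-group comparisons, groups of
one observation, malformed alignments, out-of-bounds edits) raise
errors naming the offending sample or field.

## Known limitations

- Genotypes are called per amplicon; alleles are not phased across
  amplicons and large deletions removing a primer site present as
  homozygosity of the surviving allele.
- Protein numbering depends on user-supplied CDS context; for
  references other than the bundled one, `frame_offset` and
  `aa_numbering_offset` must be configured before protein consequences
  are requested.
- The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and is
  restricted to ≤7 observations per side by design.
- Composite alleles (several indels plus substitutions) are classified
  by net indel length and named by their ordered indel tokens; manual
  labels of such alleles in external tables may tokenize differently
  even when length and class agree.
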