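# Methods

## Problem and approach

T-cell receptor (TCR) chains are assembled somatically by V(D)J
recombination: a V and a J gene segment are joined after exonucleolytic
trimming of the V 3' and J 5' ends, with non-templated nucleotides
inserted between them. A sequencing read of a rearranged chain therefore
cannot be mapped back to the germline by ordinary alignment of the whole
molecule; what identifies the rearrangement is (i) which V and J were
used and (ii) what happened at the junction.

`tcrtag` classifies each read by exact multi-keyword search for short
germline-identifying **tags** — one substring per V and J gene (or per
indistinguishable subfamily), chosen so it occurs nowhere else in the
reference set. All tags are searched simultaneously with an Aho–Corasick
keyword trie, flattened into a dense transition table, so a read is
classified in a single left-to-right pass, linear in read length and
independent of the number of tags. A read with exactly one V tag followed
by exactly one J tag is reduced to the **five-part classifier**
(V, J, nV deletions, nJ deletions, insert), a lossless encoding of the
rearrangement given the references; anything else is a no-call with a
reason code (`no_v`, `no_j`, `multiple_v`, `multiple_j`,
`order_violation`).

### Deletion counting and canonical form

From the V tag end, read and germline are walked in parallel toward the
gene 3' end; the first mismatch (or sequence end) terminates the walk and
the remaining germline bases count as deleted. The J side is symmetric,
walking leftward, and is forbidden from crossing the V walk's end point.
The insert is the read segment strictly between the two walks.

The decomposition of a junction into (deletions, insert) is not unique:
a boundary nucleotide that coincides with the next germline base can be
attributed to either side. The walk above resolves this deterministically
by maximizing V-side germline attribution first, then J-side. The same
rule is applied by `canonical_classifier` when the simulator records
ground truth, so reconstruct → annotate round-trips are exactly
idempotent and classifier equality is well defined.

## Germline references and tag placement

Tags are length 20 nt by default. V tags are placed as close to the 3'
end as uniqueness allows, J tags as close to the 5' end, so that the
inter-tag window brackets the junction; a **guard** keeps each tag clear
of the junction-proximal bases that recombination may delete (bundled
set: 20 nt on the V side, 16 nt on the J side), and a **window** bounds
how far from the junction a tag may sit (60 nt on the V side), since real
reads cover a limited stretch of the V gene.

Within those constraints some V subfamilies (TRBV6-1/6-2/6-3,
TRBV12-1/12-2 in the human beta locus) are identical: no tag can separate
them. In `group` mode such genes share one tag assigned to the group's
first member, and calls on any member are reported as that
representative. This is deliberate and mirrors the behaviour of
tag-based TCR annotation on the real locus; it is the dominant source of
V-level mis-assignment, and it barely affects the junction because the
members agree near the conserved cysteine.

The bundled reference is a **fully synthetic** TRB-like locus (41 V of
300 nt, 13 J of 62 nt; generated by `scripts/make_germline_fixture.py`
under a fixed seed). It is not IMGT material; it reproduces the
structural features that matter for evaluation: leaderless in-frame V
regions with the conserved 2nd-CYS codon 15 nt from the 3' end, CDR1/CDR2
codon-aligned spans, J regions with the conserved J-PHE codon 26 nt in,
and the two ambiguous V subfamilies above. One subfamily member
(TRBV6-3) additionally differs from its representative *between* the tag
window and the conserved cysteine, so its reads are mis-reconstructed
around the junction — the mechanism that keeps junction accuracy above,
but not equal to, 100% of the correctly-tagged fraction.

## UMI error correction

Each cDNA molecule carries a 12 nt unique molecular identifier (UMI,
"barcode"), read as two 6-mers flanking a fixed 4 nt spacer on the second
read (layout configurable via specs like `N6S4N6`). After annotation:

1. reads are grouped by exact barcode;
2. groups are compared pairwise: if the barcodes are within `th_bc`
   (Levenshtein distance, default 2) **and** the groups' most frequent
   inter-tag sequences are within `th_tcr` (percentage Levenshtein
   distance = 100·d/max(len), default 10%), the groups merge;
3. merging repeats in sweeps until a fixed point (cap 10 sweeps).

Comparison order is deterministic — descending group size, then barcode
lexicographic — and the larger cluster absorbs the smaller, keeping its
barcode; the dominant sequence is recomputed after every merge, with ties
broken toward the lexicographically smallest sequence. Largest-first
ordering makes abundant true molecules absorb their error satellites,
which is the algorithm's purpose. Each final cluster estimates one
pre-PCR molecule; per distinct consensus classifier the output reports
the **TCR count** (number of clusters) and **BC count** (mean cluster
size in reads).

Defaults `th_bc = 2`, `th_tcr = 10` merge one-to-two UMI errors and up to
~10% sequence error without bridging unrelated molecules: random 12-mer
UMIs are almost never within distance 2, and unrelated junctions differ
far beyond 10%.

*Complexity.* Pairwise comparison over all groups is quadratic, so when
`th_tcr` < 25% groups are compared only within buckets sharing the (V, J)
call of their dominant sequence. Two in-window sequences with different
V or J calls must differ by at least one whole 20 nt tag, which exceeds
`th_tcr`·len for windows of the sizes the tag geometry produces, so at
the default thresholds the restriction cannot change the result; it is
disabled for `th_tcr` ≥ 25.

*Caveat.* The clustering is a greedy fixed-point procedure; output
invariance under input read order is asserted on test fixtures, not
guaranteed in general (ties between equal-sized groups are broken by
barcode, which makes the implementation deterministic for any fixed
input multiset).

## Junction, productivity and AIRR output

The full nucleotide sequence is reconstructed from the classifier
(germline V minus its deletions + insert + germline J minus its
deletions). The **junction** runs from the conserved cysteine codon
(germline-annotated position on V) through the conserved phenylalanine
codon (germline-annotated position on J), inclusive; it is undefined when
either conserved codon was (partly) deleted. A rearrangement is
**productive** iff the junction exists, its length is a multiple of 3,
its translation starts with C and ends with F, and the V-frame
translation contains no stop codon through the junction.

Output is an AIRR Community Rearrangement TSV: one row per unique DNA
sequence (so the same amino-acid junction may appear in several rows),
all required schema fields present (alignment/cigar fields empty — this
tool does not align), non-productive rows included by default, plus
custom columns `decombinator_id` (the five-part classifier), `cdr1_aa`,
`cdr2_aa`, `sequence_aa` and `bc_count`. A leading `#` comment pins the
schema version and the tag-set checksum for provenance. `rev_comp` is
reported `F`: orientation is resolved at annotation and the intermediate
format does not carry the flag per read. D genes are not tagged;
`d_call` is empty, and alleles are not distinguished.

## Simulator (study conditions)

The generator is a deliberately simple surrogate for a learned
recombination model: V and J uniform (frequency tables accepted),
deletions geometric (mean 4 nt, truncated at 14), insert length
Poisson (mean 6 nt) with uniform composition, sequences deduplicated,
classifiers recorded in canonical form. Per-TCR pre-PCR molecule counts
are 1 + Poisson(2.7) (mean ≈ 3.7 molecules, ≈ 7% singletons) — a narrow
clone-size range representative of a small blood-draw library, chosen
once together with the error rates below so that the expected evaluation
operating point matches the published benchmark regime, and frozen.

PCR: 3 doubling rounds; each duplication acquires independent per-base
substitutions at 8.5·10⁻⁵ /base/duplication which propagate to
descendants. Sequencing: every final copy becomes a read pair with
independent per-base substitutions at 10⁻³ on both the TCR read and the
UMI read; quality strings are flat at the matching Phred score. UMIs are
drawn uniformly at random; collisions are allowed (and stress the
clustering). With the defaults a 10,000-TCR run produces ≈ 37,000
molecules and ≈ 295,000 read pairs, which keeps the full chain under
half a minute on one core.

The closed-form calibration behind the defaults: a cluster's consensus
goes wrong essentially only when a **first-round** PCR error lands in the
junction-proximal, non-tag part of the inter-tag window (expected length
ℓ ≈ 34 nt) and the mutant lineage wins the within-cluster majority vote
(probability ≈ ½ by symmetry). Expected spurious survivors ≈
N_molecules · ℓ · e_pcr ≈ 110, and a true sequence is lost when all its
molecules go wrong — dominated by singletons, ≈ n₁ · ℓ · e_pcr ≈ 2.
Sequencing errors, by contrast, are corrected almost completely: a UMI
error creates a satellite group that merges back (distance 1–2), and a
TCR-read error is outvoted inside its cluster.

What the simulator does **not** emulate: learned V/J usage and
position-dependent trimming profiles, indel sequencing errors
(substitution-only), quality-dependent error profiles, chimeras, and
multi-sample index hopping. Passing the benchmark therefore shows the
correction machinery behaves as designed under substitution noise with
realistic redundancy — not that real-library artefacts beyond that model
are handled.

## Scoring

*Annotation accuracy* is the fraction of one-error-free-read-per-TCR
whose five-part classifier equals the generator's (no-calls count as
wrong); *junction accuracy* compares the junction **nucleotide** string
implied by the called classifier against the truth (None-safe, and
well-defined for out-of-frame rearrangements, unlike an amino-acid
comparison).

*Collapse recovery* is scored against the annotation of the error-free
pre-PCR sequences themselves (`annotate_truth`): the collapse stage
corrects PCR/sequencing error, so its reference is what the annotator
would emit with zero noise — otherwise the (designed) subfamily tag
ambiguity would dominate the count. Recovered = truth classifiers present
in the collapsed output; spurious = output classifiers absent from truth;
abundance fidelity is the Pearson r between pre-PCR molecule counts and
reported TCR counts over the recovered classifiers.

## Demultiplexing

Dual sample indices are parsed from the Illumina-style header comment
(`...:I1+I2`). A record is assigned to the unique sample with both
indices within `max_mismatch` (default 1) substitutions; zero or multiple
candidates go to `undetermined`. Sample sheets whose index pairs are
within 2·`max_mismatch` total mismatches are rejected at load.

## Numerical and degenerate-input choices

- Tag matching is exact (no mismatch rescue); a tag hit in the read is
  trusted absolutely, and any repetition of a tag is a conservative
  `multiple_*` no-call.
- Edit distances are computed with edlib (global alignment mode);
  empty-vs-empty is 0, empty-vs-s is len(s); `percent_levenshtein`
  rejects empty input.
- `group_by_barcode` of no reads is an empty list; an empty FASTQ pair
  yields a header-only AIRR file and zeroed statistics.
- Geometric deletions use p = 1/(1+mean); truncation at 14 nt keeps tags
  and both conserved codons recoverable by construction of the bundled
  geometry (guards ≥ cap + 2).
- All pipeline randomness lives in the simulator and is driven by one
  integer seed; annotation, collapse and translation are deterministic.

## Evaluation problem sizes

The benchmark tests and the acceptance script use 10,000 ground-truth
TCRs (the published evaluation's n) for both chains; unit and property
tests use 50–500-TCR repertoires and a 5-gene toy locus. A full
10,000-TCR collapse chain runs in ≈ 20 s on one core.
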