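# Methods

This note documents the models, rules and numerical choices behind
`utrdissect`, in the order data flows through the pipeline, and states what
the synthetic-data experiments do and do not demonstrate.

## Coordinate conventions

All positions are 0-based and all intervals half-open `[start, end)`
(BED-compatible). A Cas9 cut is a *between-base* coordinate: the 0-based
position of the first reference base 3′ of the blunt cut. The polyA site is
one past the last transcribed base.

## Reference model and polyA signal

The reference is a single short amplicon sequence over {A,C,G,T} (RNA input
is uppercased and U→T normalized; anything else is a hard error naming the
offending position). The canonical polyadenylation signal AATAAA is searched
with the whole hexamer constrained to lie 10–35 nt upstream of the polyA
site: start *s* must satisfy `site − 35 ≤ s` and `s + 6 ≤ site − 10`. This
containment reading is the strictest interpretation of "present between 10
and 35 nt upstream" and is deliberate. When several hexamers qualify, the
5′-most is chosen: it maximizes the sequence left between the distal cut and
the signal, matching the design goal of excising as much UTR as possible
while sparing polyadenylation. When no canonical hexamer exists the pipeline
does **not** predict alternative signals; the user must supply the signal
coordinate (config key `polya_signal_start`), e.g. from an external
polyA-signal predictor.

## Guide enumeration and dual-guide design

Guide enumeration is plain NGG-PAM scanning of both strands: every position
where a 20-nt protospacer plus NGG fits inside the reference yields exactly
one site; no uniqueness, GC or synthesis filters are applied. The cut sits
between protospacer positions 17/18 (3 bp 5′ of the PAM) — standard SpCas9
blunt-cut geometry, needed as a coordinate anchor by the simulator.

The dual-guide excision pair is chosen to maximize the excised span subject
to the placement rules: the proximal guide is on the antisense strand with
its PAM inside the UTR (so neither PAM nor cut touches coding sequence or
the stop codon), taking the smallest valid cut position; the distal guide is
on the sense strand with its PAM entirely 5′ of the polyA signal, taking the
largest valid cut position. Either side lacking a candidate is an error
naming the side.

## Synthetic screen generator

The generator emulates a 64-guide screen of a ~781-nt AT-rich 3′-UTR with
paired DNA (genomic) and RNA (cDNA) amplicon libraries.

**Reference.** Background bases are drawn AT-rich (default GC 0.15); every
accidental GG/CC dinucleotide is then scrubbed and exactly 64 PAMs are
planted at even spacing (small jitter) on alternating strands, so guide
enumeration finds exactly the planted landscape. A canonical AATAAA is
planted 25–31 nt upstream of the polyA site (the reference end).

**Alleles.** 1,500 allele draws are taken around the cut sites: each draw is
a single-cut deletion with length from a geometric-like distribution
(mode 5, decay 0.75 per nt, support 1–40) placed uniformly so the interval
contains or abuts the cut, or with probability 0.05 a dual-cut excision
spanning two cut positions. Duplicates collapse; this yields on the order of
1,100–1,200 distinct deletions, matching the scale a 64-guide screen reports
(≈1,176 analyzable deletions), with the 1–2 nt and ≥30 nt tails present to
exercise the filters. The intact allele keeps fraction 0.5 of the
population; deletion-allele frequencies are symmetric-Dirichlet within the
rest. The true indel spectrum of Cas9 repair is not modeled (no
microhomology bias, no insertions); the spectrum only needs to populate the
analysis window and the filter-rejected tails.

**Expression effects.** Ground truth is a set of non-overlapping effect
regions with positive multipliers: any allele whose deletion overlaps a
region has its RNA abundance multiplied (multiplier > 1 ≈ removal of a
destabilizing element; < 1 ≈ removal of a transcription-promoting element).
RNA relative abundance of an allele = DNA frequency × baseline ratio ×
product of overlapped multipliers.

**Output modes.** `simulate_reads` emits 150-nt proper mate pairs (insert
~N(300, 40) clipped to [150, allele length]) as truth-aligned SAM — the
allele's deletion appears as a D CIGAR operation — plus FASTQ, with
per-base substitution errors (default 10⁻³); the truth SAM lets the whole
pipeline run without an external aligner while FASTQ preserves the option of
using one. Default depths are 10⁵ DNA / 5.6·10⁴ RNA fragments, preserving
the ~80:45 library-depth ratio of a deep screen at desk scale.
`simulate_counts` skips reads entirely and draws multinomial per-allele
fragment counts for each library; the large statistical experiments (null
error rates, parameter recovery) use this mode, since read-level detail is
exercised separately by the CIGAR-oracle comparison. Read-level counting
differs slightly from count-level in that fragments whose reads miss the
deletion junction are classified reference; this biases per-allele counts
low by a length-independent factor and is irrelevant to ratio statistics.

Sequencing errors are substitutions only; spurious 1–2 nt deletions (what
the length-1–2 filter exists for) can be injected explicitly in tests via
the allele model's out-of-range lengths.

## Deletion calling

CIGAR walking: M/=/X advance reference and read, I and S advance the read
only, D and N advance the reference only; each D (or N — amplicon
alignments should not contain splices, but aligners can emit N; treated as
D and then subject to the normal length filters) produces a call with its
reference start, length and the read-base offsets of the junction from both
read ends (soft-clipped bases count as read bases). H/P operations discard
the record.

Read-level filters, in order: 1–2 nt calls are dropped as likely sequencing
errors (the read is kept and may still be reference); more than one
remaining call discards the read (multi-deletion); a junction < 8 nt from
either read end discards it (edge-proximal); length ≥ 30 discards it.

Mate reconciliation (fragment-level counting — an allele exists once per
molecule, so a deletion seen by both mates counts once): both reference →
reference; agreeing deletions → that deletion; disagreeing deletions →
discarded (mate-conflict; conflicting mates indicate chimeras or alignment
error — conservative choice, the rule is ours); a deletion plus a reference
mate whose aligned span fully covers the deletion locus without showing it →
mate-conflict, otherwise the deletion stands; any discarded mate discards
the fragment; both mates unmapped → discarded. A fragment with no qualifying
deletion is reference regardless of how much of the UTR its mates cover
(uncovered regions are assumed deletion-free); per-position denominators use
distinct deletions only, so partial coverage of reference fragments does not
bias the map. Deletions are grouped by the aligner's reported coordinates;
no left-alignment normalization is applied before grouping.

## Ratio quantification

Distinct deletion = unique (start, length); r = RNA fragments / DNA
fragments; reference ratio = the same ratio over reference-classified
fragments; normalized r = r / reference ratio; total r = ΣRNA/ΣDNA over
retained deletions. The abundance filter retains an allele only when
`count/total > 6.5·10⁻⁷` **in both libraries** (the boundary itself is
eliminated, matching "≤ … eliminated" semantics; comparisons are done as
`count × 10⁷ > 6.5 × total` to avoid float-boundary surprises). Per-library
application is the default because r needs a reliable numerator and
denominator; an alternative absolute-minimum mode (> 16 DNA and > 8 RNA
fragments) is available via `abundance_mode = "absolute"`. RNA-only alleles
are excluded (r undefined) rather than assigned infinite r. The length
window 3–29 nt is applied at the same step.

The pilot-style single-element analysis classifies each deletion against a
known element interval: fully inside; a proper superset (the whole element
plus some flank); or disjoint (control). Boundary-straddling deletions
belong to no class and are excluded — strict containment on both sides is
our rule for an inherently ambiguous definition. The top 9 per class by DNA
fragment count (abundance of an allele in the population is a DNA property)
are compared control-vs-element with a two-sided Mann–Whitney test; at these
group sizes the exact null is always used when tie-free.

## Per-position inference

A deletion "involves" position *i* iff *i* lies inside the half-open deleted
interval — junction-adjacent undeleted bases are excluded. Positions
involved in fewer than 4 retained distinct deletions are not analyzed.

*Bootstrap:* percentile bootstrap of the median over the deletions at the
position (B = 10,000 for standalone use; the map's default is B = 1,000,
which at the screen sizes used here changes CI endpoints by < 1 % while
keeping a full 781-position map under a second). The resampling unit is the
distinct deletion: reads within an allele are not exchangeable units of r.

*Testing:* two-sided Mann–Whitney of r at the position versus r of all other
retained deletions; exact enumeration when min(n₁, n₂) ≤ 8 with no ties
(small per-position groups are exactly where the normal approximation is
poor), otherwise the tie- and continuity-corrected normal approximation.
Bonferroni correction uses the family of positions actually analyzed —
tests never performed are not part of the family. Two-sided throughout,
since real elements act in both directions. Adjacent significant positions
merge into half-open BED intervals.

Determinism: one seeded generator drives all bootstrap resampling in
position order, so a (inputs, config, seed) triple reproduces every output
byte-for-byte.

## Assay formulas

Reporter effect, decay fraction (t₄/t₀), new-transcription ratio and
enhancer activity are ratio statistics over replicate tables of normalized
qPCR-style levels; normalization by the control is division by the control
*mean* (replicates are not paired across conditions, except decay, which
pairs timepoints within replicate). Summaries are mean ± sample s.d.
Presentation conventions: a transcription ratio of 0.18 is "an 82 %
reduction"; enhancer activity is also reported as fold change over the
minimal-promoter-only control mean. Replicate-level significance tests
(two-sided t, Dunnett) are thin pass-throughs to standard routines. ΔΔCt
conversion from raw Ct values is out of scope; inputs are expression-scale
levels.

## Validation experiments and their scope

The statistical suite (see `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs at these problem sizes, chosen to give stable
rates at interactive runtimes: read-level oracle comparison on 1,000
error-free fragments; 200 random exact-test instances; 1,000 bootstrap
coverage replicates at n = 30; 100 null screens and 20 planted-element
screens at 10⁵ DNA fragments each (count mode). Under these conditions the
pipeline recovers planted elements with the correct effect direction,
maintains ~5 % per-position type-I error and ≥95 % familywise control, and
its CIs cover at ~95 %.

What passing these experiments does **not** show: robustness to alignment
artifacts (the truth SAM has no mismapping, no soft-clip ambiguity, no
left-shift degeneracy in repeats), to PCR amplification or UMI-less
duplicate bias, to non-uniform guide efficiency, or to a realistic Cas9
repair spectrum. Real screens should treat the map's significant intervals
as candidates for single-guide validation, not as calibrated effect sizes.

## Known limitations

* Overlapping deletions blur element boundaries: a significant interval
  extends over every position whose covering deletion set is shifted, so
  recovered intervals are wider than (and need not be centered on) the true
  element.
* The Mann–Whitney "elsewhere" group includes neighboring positions'
  deletions, so adjacent positions' tests are strongly dependent; Bonferroni
  is conservative under this dependence.
* No FDR alternative is wired in as default, and no spatial smoothing or
  deconvolution of overlapping deletion effects is attempted.
* The abundance threshold's original per-library/pooled interpretation is
  ambiguous in the field; both supported modes are documented above.
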