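# Methods

This note documents the models and conventions behind `poppystr`: what each
stage computes, the choices made where more than one defensible convention
exists, and what the synthetic-data generators do and do not emulate.

## Perfect-repeat mining

A microsatellite locus is a maximal run of a primitive (non-periodic) motif
of length 2–6 nt. Runs are found per period by comparing each base with the
base one period earlier; `N` and any non-ACGT character break runs (non-ACGTN
input is rejected), lowercase is uppercased, and mononucleotide runs are
never reported. Reporting is at the shortest period: an `(AG)×12` run is one
dinucleotide locus, never `(AGAG)×6` — guaranteed by requiring the motif to
be primitive.

**Canonical phase.** When a maximal periodic stretch is not an exact
multiple of the period (e.g. `T·AGAT×7`, 29 bp at period 4), several
placements of the full-copy run exist. The scanner reports the placement
whose motif is the lexicographically smallest rotation (here `AGAT` starting
after the partial base), which is unique because primitive rotations are
pairwise distinct. Coordinates are 1-based and inclusive on the forward
strand.

`canonical_motif` maps a motif to the lexicographically smallest string over
all rotations of itself and its reverse complement, so `GATA`, `ATAG` and
`ATCT` aggregate into one class for composition summaries.

**Candidate selection** uses repeat-number windows per motif length
(trinucleotide NR ∈ [10, 15]; tetranucleotide NR ≥ 7; penta/hexanucleotide
NR ≥ 8; dinucleotides excluded) and, by default, requires placement on a
named chromosome. **Uniqueness** is judged on 12-column tabular alignment
hits with three predicates: at most `max_significant_hits` hits below the
significance e-value, at most `max_high_cover_hits` hits at ≥ the high-cover
fraction, and a best-vs-second-best bitscore gap. The numeric defaults
(1e-10, 80 %, 1, 1, 10 bits) are this package's documented stand-ins; the
procedure they implement was published without its trained thresholds. A
candidate with no hit at all is treated as malformed input, since a correct
alignment always contains the self-hit.

**Inter-locus distance**: same-chromosome pairs closer than 50 Mb are
flagged `possible linkage` (a conservative 1 cM ≈ 1 Mb reading);
different-chromosome pairs are independent. **Primer cross-dimer score**:
the longest contiguous Watson–Crick complementary window over all ungapped
antiparallel offsets of one primer against the other — a deliberately simple
AutoDimer-style screen whose score equals primer length for a primer against
its own reverse complement. Multiplex design practice keeps co-amplified
pairs at score ≤ 5.

## Allele nomenclature

A marker reference is `upstream flank + repeat structure + downstream
flank` (+ an optional 7 bp pig-tail accounted in fragment size only). An
amplicon is decomposed by choosing the two boundary positions that minimize
the joint cost of

1. aligning the reference upstream flank to the amplicon prefix,
2. tiling the middle with the reference motifs, and
3. aligning the downstream flank to the suffix.

Alignment cost is lexicographic: edited bases first, then contiguous edit
blocks (each opened mismatch/insertion/deletion run costs one block). The
block term makes the edit script canonical where plain edit distance is
ambiguous — one 10 bp deletion beats an equal-cost split into two gaps.
Untiled middle bases cost slightly more than flank-aligned bases, so
boundary bases go to the flanks on ties and `x` counts only interior
interruptions; among residual ties the leftmost and largest repeat region
wins. Middle tiling minimizes (interruption bases, interruption blocks) with
the longest uninterrupted leading run as final tie-break, consistent with
the longest-uninterrupted-sequence view of repeat structure; a genuinely
ambiguous tiling raises an error listing the co-optimal structures. The
decomposition always reconstructs the amplicon exactly.

**Flank-variant coordinates.** Position 1 is the base immediately adjacent
to the repeat region, counting away from it (upstream 5′-ward, downstream
3′-ward); a length-L variant at position p spans offsets p … p+L−1 and its
sequence is written 5′→3′. Indels are canonicalized by sliding toward the
repeat boundary: the smallest position yielding the same edited flank.
Descriptors are printed D-side first, ascending position, joined by `; `.

**Conventions.** Repeat-based naming: `n.x` from the structure alone;
flanking indels never shift it. Size-based naming: the designation encodes
motif_len·n + x plus the net signed flanking indel length, in motif units —
and raises a negative-numbering error when deletions exceed the repeat
region, which is the main argument for the repeat-based convention.
Shorthand rewrites descriptors whose sequence exceeds `max_seq_len`
(default 5, so 2 bp `TCdel` stays verbatim while 8–10 bp deletions become
`U25-8del` style) as side+position+`-`+length+kind; it is idempotent and,
for deletions and substitutions, invertible given the reference. SID labels
are base-26 uppercase encodings of a SHA-256 digest of the uppercased
sequence, truncated to 4 letters; a registry detects digest collisions
(forcing a longer label) and reports whether 3-letter prefixes are unique
panel-wide. This scheme is deterministic and documented but is not claimed
to match any externally published SID catalogue.

**Identifiability limit.** A flanking indel that reproduces motif-like
sequence at the repeat boundary is genuinely ambiguous: the same amplicon
string is explained by a different repeat count with fewer edited bases,
and the parser, by parsimony, prefers that explanation. This is the
flanking-indel "masking" effect inherent to sequence data, not a parser
artifact; round-trip recovery of simulated variants is therefore exact for
variants clear of the boundary (position ≥ ~6) whose sequences contain no
motif copy, and the test suite samples accordingly.

**Null-allele diagnosis** aligns the forward primer (and the reverse
complement of the reverse primer) into an extended amplicon spanning both
sites (edlib infix alignment) and reports substitutions by offset from the
primer 3′ end plus any indel overlapping the site; substitutions within the
3′-terminal four bases, and all indels, are classed high-severity.

## CE genotyping

Thresholding only flags sub-threshold peaks (200 rfu default); downstream
consumers decide what to drop. Ladders are composed by greedy set cover over
samples (most uncovered alleles first, ties by sample id); inventory alleles
carried by no sample are listed as missing and excluded from the bins. Bins
are ±0.4 bp around per-allele centers — the conventional default binning
range — and a ladder is rejected if adjacent centers are within twice the
half-width. Peaks are matched to markers by dye (and assay, when present:
multiplex assays are separate injections). A passing peak one repeat unit
below a taller called allele is filtered as stutter when its height ratio is
at most the marker's filter threshold (mean + 3·SD from validation data,
0.15 fallback); forward stutters are classified but never auto-filtered.
Zero surviving alleles is a locus dropout; one is a homozygote, with an
allelic-dropout suspicion flag when the sample's dose metadata is below
0.5 ng — the hom/dropout distinction is undecidable from a single profile,
so it is a flag, not a decision. Stutter classification matches sub-peaks to
expected positions (n−k, n−2k, n+k with k = one repeat unit; n−2/3/4 bp for
markers configured with the 1-bp series) within 0.5 bp, and never types a
peak taller than its parent as backward stutter. Sizing precision reports
per-allele sample SDs over repeated ladder injections, their mean, SEM
(SD of the per-allele SDs / √n), extremes, and flags alleles with
3·SD > half-width.

## Validation metrics

Codominant normalization precedes the balance metrics: heterozygote peak
heights are averaged, homozygote heights halved. IELB divides each locus
height by the profile's assay mean, so the mean IELB of a complete profile
is exactly 1 — per-locus IELB structure emerges only when pooling across
samples, which is the default mode (a complete-profile-only mode is also
provided). ICB is min/max within a dye channel; a single-locus channel
returns 1.0 with an explicit flag. Hb is oriented by allele size
(HMW/LMW) and can exceed 1, carrying directionality of preferential
amplification; Hb′ = min(Hb, 1/Hb) is bounded by 1. All three are invariant
under a global rfu gain. Heterozygote-balance outliers are flagged by the
1.5·IQR boxplot rule on Hb′ per marker — flagged, never silently removed.
Stutter summaries report mean/median/SD/min/max and the mean + 3·SD filter
threshold per marker × type; the allele-size trend is a least-squares slope
on per-allele mean ratios (not raw observations). Alleles with no observed
stutter are absent from the summaries, which biases group means upward;
this is reported as is. Sensitivity reports classify calls against truth
(or a high-dose reference): true heterozygote called homozygous = allelic
dropout, no called allele = locus dropout, full profile = all loci called.
Cross-reactivity counts each marker once per non-target taxon and
separately notes markers whose passing signal stays within 1.5× the
analytical threshold.

## Population analysis

Genotypes live in a wide sample × marker matrix of `a1/a2` cells. N_al
counts distinct labels; H_Obs is the heterozygous fraction of non-missing
samples. Identity analysis reports pairs identical at every co-typed
marker; missing markers cannot mismatch but are counted, and pairs with
fewer than 20 co-typed markers are flagged low-confidence. Null-allele loci
enter as missing, since profile data cannot distinguish a null from
amplification failure. Two varieties are indistinguishable iff any
cross-variety 0-mismatch pair exists; indistinguishable groups are connected
components of that graph, and the number of distinguishable units is the
component count. PCA uses 0/1/2 allele-dosage columns, centered and
unscaled by default (dosage columns have comparable variance; scaling is
switchable), with the sign of each component fixed so its
largest-magnitude loading is positive. UPGMA runs on Euclidean distances
over the first three principal components with a deterministic tie-break
(merge the lexicographically smallest member pair); it is implemented
directly so the tie-break is exact, and cross-checked against SciPy's
average linkage in the tests. Flat clusters cut the tree at four groups by
default, matching the four use categories (culinary, dual, pharmaceutical,
ornamental). Mislabel screening compares each sample's distance to its own
variety's leave-one-out centroid against other centroids in score space; a
configurable margin (plus a 1e-8 numerical tolerance) controls strictness,
and varieties with fewer than two samples are skipped.

## Synthetic data

The generators emulate the study conditions rather than the instrument:

* **Genomes**: i.i.d. background at a given GC fraction with planted
  perfect repeats; flanking bases are resampled so each planted run is
  maximal, and an optional scrub pass disrupts background runs reaching the
  search thresholds so planted loci are recoverable with precision =
  recall = 1.
* **Varieties**: inbred lines as per-variety allele pools; plants are
  homozygous for a pool allele except with probability
  `residual_het_rate` (default 0.076, a typical mean observed
  heterozygosity for registered poppy varieties), so realized H_Obs is
  binomial around the rate. An engineered 36-variety dataset fixes
  single-allele pools within designated indistinguishable groups (sizes 4
  and 2), gives every other variety a unique two-marker allele signature,
  and plants two mislabelled samples whose profiles sit near — but not
  identical to — their true variety.
* **CE profiles**: per allele copy, lognormal heights (median 2000 rfu,
  log-SD 0.25 at the 1.25 ng reference dose), multiplied by dye gain and
  dose, with log-height falling 0.002 per bp of fragment size (drives the
  observed heterozygote imbalance without claiming its mechanism). Height
  dispersion grows as (ref_dose/dose)^0.5, the stochastic few-template-copy
  effect that degrades Hb′ at low input. Dropout acts per allele copy with
  probability 1/(1 + (dose/d50)^slope) — logistic in log2(dose), d50 =
  0.2 ng, slope 2 by default; losing one copy of a heterozygote is an
  allelic dropout, losing both a locus dropout. No quantitative dropout-dose
  law is published for this system; the logistic form is this module's
  choice, exposed as configuration. Stutter ratios are linear in parent
  repeat number per type (backward default 0.02 + 0.004·NR) and stutter
  height is exactly ratio × parent height before sizing noise; two
  pentanucleotide markers emit the 1-bp series. Sizes get Gaussian noise
  (0.06 bp SD, matching reported ladder sizing SDs); sub-threshold peaks
  are flagged, never deleted. Every peak carries exactly one provenance
  record, and all randomness derives from one seed with per-sample
  sub-streams.

Not modeled (and hence not validated by passing tests): continuous
electropherogram traces, pull-up/spectral bleed, off-scale clipping, PCR
inhibitors, size-standard curve fitting, and degraded/mixed-source samples.
Real data also exhibit isoallele-driven bimodal stutter clouds and
non-linear allele-specific stutter, which the linear stutter model does not
produce.

## Problem sizes and determinism

The test suite exercises the miner against an exhaustive oracle on 200
random sequences of 0.5–5 kb; balance identities on 1,000 simulated
profiles; stutter-slope recovery on >1,000 classified stutters (15 %
tolerance); dropout-d50 recovery on ~513 heterozygous loci per dose over
the five-point dilution ladder (20 % tolerance); sizing-SD recovery on 151
alleles × 10 injections within χ² sampling bounds; and the discrimination
rehearsal on 36 varieties × 4–9 plants. All stochastic tests run under
fixed seeds; `scripts/acceptance.py` derives every random input from its
`--seed` argument, and its reported designations are invariant across
seeds because the constructed references pin only the bases the worked
examples require.
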