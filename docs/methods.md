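# Methods

## Scope and model

`zfnscreen` covers the computational path of a designer-nuclease (ZFN or
TALEN) knockout campaign in zebrafish: candidate-site enumeration and
vetting, activity assessment from cloned somatic amplicons, and pooled
fluorescent-PCR founder screening. The wet-lab boundary is deliberate:
inputs are sequences (FASTA) and fragment-analysis peak tables (CSV of
well, size in bp, height); chromatogram processing, primer design and
instrument operation are out of scope.

## Target sites and off-target search

A composite site is `[left half-site][spacer][right half-site]` on the
plus strand, half-sites 9–18 nt, spacer 5–7 bp by default (configurable to
21 bp for TALEN-style geometries). Candidate enumeration is an exhaustive
window scan of the CDS, optionally restricted to starts in the first half
of the open reading frame (frameshifts there truncate most of the
protein).

Off-target counting is exact Hamming matching: every window on both
strands within `k` mismatches of the query is reported, with 0-based
half-open coordinates (minus-strand matches at their plus-strand
location). Gapped (indel-tolerant) matching is intentionally not offered.
Choices that matter:

* `N` in genome or query counts as a mismatch to everything — conservative
  for uniqueness assessment.
* Windows running off a contig end are not reported; ordering is (contig,
  start, `+` before `-`).
* The scan is a vectorised per-query-position comparison over all windows
  (O(G·L) with numpy constants), so genomes of tens of kb are instant; no
  index is built. It is validated against an independent pure-python
  brute-force oracle in the tests.
* Default vetting scans each half-site independently; the paired scan
  (`offtargets-paired`) is a separate mode reporting loci where two
  half-site matches converge across a spacer in range. With homodimers
  enabled it also reports LL and RR arrangements — a left-site plus-strand
  match facing a left-site minus-strand match, etc. — the configurations
  obligate-heterodimeric FokI variants are engineered to suppress. The
  per-half budget applies to each half independently; both a per-half and
  a composite reading of a total mismatch budget are thereby available
  (scan the composite as a single query for the latter).

The SNP pre-screen takes same-length amplicon sequences from several
individuals of the injection line (eight is typical), locates the
composite site, and reports polymorphic columns within it. Only variants
inside a half-site fail the site; spacer variants are reported but pass,
since a zinc-finger contact is not disrupted by them. Whether a
spacer-only variant should disqualify a site is genuinely open; the pass
rule is explicit and the variant list lets a user apply a stricter policy.

## Clone classification

Each clone is globally aligned to the wild-type amplicon with biopython's
`PairwiseAligner` (match +1, mismatch −2, gap open −5, gap extend −1; the
first gap base costs the open score, each further base the extend score).
Alignment columns are classed match/mismatch/gap; maximal runs of
non-match columns form difference segments, and segments separated by at
most `merge_dist` (default 10) matching columns are merged into one event.
This absorption step matters: an NHEJ junction that replaces wild-type
bases ("complex" event) is represented by an optimal alignment as
mismatch columns beside a single gap, never as two adjacent gaps, so
without merging every complex event would be miscalled as an indel plus
point mutations. The price is that a genuine isolated substitution within
`merge_dist` of an indel is folded into the event; at a nuclease cut site
that reading is usually the right one, and `merge_dist` is a parameter.

Pure indels are then left-aligned (shifted maximally 5′ through their
microhomology run), following variant-normalisation practice. An event
counts as a lesion when any of its microhomology-equivalent placements
overlaps the cut window (callers typically pass the spacer interval).
Substitution-only clones and events outside the window are scored
wild-type for the lesion frequency — the assay scores in/dels, and PCR or
sequencing errors would otherwise inflate the estimate — but are recorded
in the call's warnings. A duplication is an insertion identical to the
adjacent wild-type copy; after left-alignment the template copy sits 3′ of
the insertion point (equivalently 5′ at the rightmost placement), so both
flanks are checked.

Degenerate case: a "complex" event whose inserted bases equal the ends of
the deleted run is sequence-identical to a shorter pure indel and is
called as such; the simulator never generates these (see below). Complex
events with equal insertion and deletion lengths are likewise
sequence-identical to substitution runs and are not generated.

## Frequency statistics

* Lesion frequency: 100·mutant/total, reported to one decimal, with a 95%
  Wilson score interval (statsmodels); Wilson rather than Wald because
  clone counts are small and p̂ is often near 0 or 1. Published tables of
  this kind mix integer and one-decimal precision; this package always
  prints one decimal.
* Detection power 1 − (1−p)ⁿ and its inverse `min_clones` =
  ⌈log(1−confidence)/log(1−p)⌉ (verified by stepping the power function).
* Transmission: lower bound 100·k/(s·m); MLE 100·(1 − (1 − k/m)^(1/s))
  from inverting the pool-positive probability q = 1 − (1−p)^s at the
  binomial MLE q̂ = k/m; CI by transforming an exact Clopper–Pearson
  interval on (k, m). The MLE is slightly convex in q̂, so its mean sits a
  few percent above p at these pool sizes — within the 15% calibration
  band the tests enforce. Failed wells (no wild-type-sized peak) are
  excluded from both k and m, since the wild-type allele is always present
  in an outcross and its absence means amplification failure, not biology.
* Alleles are keyed by net length change only: capillary sizing cannot
  separate same-size alleles of different sequence; sequence-level
  disambiguation belongs to the clone-sequencing side.

## Peak calling

Defaults: `size_tol` 0.5 bp (capillary sizing accuracy), `min_rel_height`
0.05 of total well signal (noise floor; instrument-dependent and
configurable). Carrier estimate `round(height/total · 2s)` clamped to
[1, s]; with noise-free heights proportional to allele counts this is
exact for every pool (a tested invariant). Single-fish genotyping is the
s = 1 case with a heterozygote band of 0.3–0.7 mutant fraction; more than
one mutant peak in a fin clip, or a fraction outside the band, is flagged
for review rather than called.

`merge_plus_a` folds (x, x+1) peak pairs with the smaller peak at x+1 into
x. It is idempotent and conserves total signal. It cannot rescue a true
+1 insertion allele, whose peak coincides with the wild-type +A shadow —
which is exactly why PIG-tailed reverse primers, which drive adenylation
to completion and remove the artifact at the bench, are the preferred
solution; the merge is a fallback for legacy data.

## Synthetic data

The generators define the regimes the pipeline is tested in:

* Loci: random contig with the composite site embedded; amplicon length
  uniform in 230–350 bp with the site centred within ±10% of the midpoint
  (standard sizing-PCR design).
* Indel spectrum defaults (stylised, since only qualitative facts are
  established for ZFN lesions): insertion 0.45 / deletion 0.45 / complex
  0.10; insertion sizes 1–10 bp with the mode at 4 and 60% of insertions
  duplicating the adjacent 5′ wild-type bases (the classic +4 duplication);
  deletion sizes truncated-geometric (decay 0.90) to 60 bp, so large
  deletions outweigh large insertions; complex events draw both sizes with
  insertion bases resampled so the event cannot reduce to a pure indel.
  All overridable.
* Clone sets: Bernoulli(lesion_freq) per clone, mutant alleles uniform.
* Founder screens: per embryo at most one heterozygous allele (outcross),
  wells of 2s alleles, peak height = allele count × gain × lognormal(mean
  1, cv) — the simplest positive multiplicative noise, not a claim about
  instrument physics. The +A artifact splits each peak between x and x+1
  at a shadow/parent ratio uniform in [0.3, 0.7]; the split conserves
  signal, so merging restores the artifact-free table exactly. Genotypes
  are drawn from a dedicated RNG stream so noise/artifact settings do not
  perturb them. Everything is a pure function of (arguments, seed).

What passing tests on these simulations do **not** show: robustness to
PCR amplification bias, allele dropout, stutter beyond the +A form,
sizing drift, or cross-contamination — none of which are modelled.

## Problem sizes and numerical notes

The test and acceptance workloads use genome scans up to 50 kb, 10⁴
simulated alleles for the classification round-trip, 1,000 replicates for
Wilson-coverage checks and 300–500 replicates per frequency for MLE
calibration; these sizes make the statistical assertions stable across
seeds while the whole suite runs in well under a minute. Alignment
tie-breaking never affects calls because placement is re-normalised by
explicit left-alignment; interval arithmetic is 0-based half-open
internally with 1-based positions only in human-readable reports; the
one-decimal rounding of the lesion percentage is clamped into its CI at
the extremes.

## The workflow runner

`zfnscreen run` executes stages in campaign order (sites → off-targets →
lesions → screen) from one YAML config, writes TSV/JSON artifacts, a
Markdown report that states the go/no-go reading (clear activity →
proceed to founders, none → redesign or adjust dose), and a
`manifest.json` capturing inputs, version, seed and thresholds. Reports
contain no timestamps, so a rerun with the same config and seed is
byte-identical. Exit codes: 0 success, 2 input error, 3 missing upstream
artifact.
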