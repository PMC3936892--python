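# Methods

This note documents the models and procedures the package implements,
the defaults it ships with, and what the synthetic studies do and do
not establish about behavior on real data.

## Read preprocessing

A raw library is reduced to a mappable read set by a fixed chain:
3' adapter location → length bounds → low-complexity screen →
contaminant subtraction. The chain order is normative: a read that
would match several filters is charged to the first, so the removal
ledger partitions the raw total exactly. This mirrors the accounting
layout of small-RNA sequencing reports ("sequences / unique
sequences" per category), whose published versions often contain
overlapping categories; the package deliberately enforces disjoint
accounting instead of reproducing any particular report's overlap.

* **Adapter trimming.** The adapter's prefix (≥ `min_overlap` = 6 nt)
  is aligned at every read offset; the 5'-most alignment within a 10%
  mismatch rate wins. Reads with no acceptable alignment are charged
  to the `no_3adt` category (3' adapter not found). Adapter-only reads
  yield a zero-length insert and fall to `too_short`.
* **Length bounds.** 15–30 nt inclusive, the conventional small-RNA
  window.
* **Junk.** "Junk reads" is not a standardized notion; here it is
  defined as N-fraction > 0.1 or fewer than 3 distinct bases
  (homopolymer/dinucleotide artifacts). Both thresholds are
  parameters.
* **Contaminants.** Exact substring membership in the ncRNA (Rfam-style)
  or repeat (Repbase-style) reference, either strand, with ncRNA taking
  precedence. Exact matching (rather than a heuristic local aligner)
  keeps the category assignment deterministic and is sufficient at the
  read lengths involved.

## Candidate classification

Mappable reads are classified against (i) the species' own mature
annotation (exact full-length identity → *known*), (ii) the genome
(all exact full-length hits, both strands; unmapped reads are dropped,
as are reads with more than 20 loci, treated as repetitive), and
(iii) the all-plant mature set (equal length, Hamming distance ≤ 3 →
*conserved*, family inherited from the best match with lexicographic
tie-breaking; everything else → *novel*). Equal-length matching avoids
indel ambiguity; the bound is a parameter.

## Hairpin screening

For each candidate locus a ladder of windows (default 20/50/100/150 nt
flanks, truncated at contig ends) is extracted and folded; the
smallest window whose structure passes all criteria is retained. When
none passes, the window with the fewest failed criteria (smallest
first) carries the rejection verdict, so every rejection names the
criterion that killed it.

The duplex is located by pairing the candidate's positions (excluding
its expected 2-nt 3' overhang) through the structure; the star span is
the partner region extended 2 nt at its 3' end, and a star is
"observed" when a distinct read maps within ±2 nt of that span.
Criteria, at criterion granularity:

1. **star detected** — the partner-arm sequence was itself sequenced;
2. **duplex mismatches** — fewer than 4 mismatched candidate positions
   and no run of 4 (a mismatch is a candidate-core position unpaired or
   paired outside the star span);
3. **asymmetric bulges** — at most one run of unpaired bases on one
   duplex strand with no opposing unpaired run, at most 2 nt long
   (read as ≤ 2 from an ungrammatical source constraint; configurable);
4. **arms and overhangs** — candidate and star on opposite stem arms
   (neither effective span entering the terminal loop) and both duplex
   3' ends extending exactly 2 nt beyond the partner's pairing region;
5. **MFEI** — strictly greater than 0.8, computed on the retained
   window: MFEI = AMFE/GC%, AMFE = |MFE|/L×100.

MFE/MFEI values in reports are rounded to one decimal; internal
computation keeps full precision. Published precursor tables computed
with other folders are not always internally consistent with the
MFEI formula; the package always reports the formula value.

## Folding backend

The built-in folder is a weighted maximum base-pairing dynamic program
(Watson–Crick + G:U, minimum hairpin loop 3) with an explicit proxy
energy: −2 kcal/mol per G:C pair, −1 per A:U or G:U. It is *not* a
nearest-neighbor thermodynamic model and makes no claim of MFE parity
with mfold/RNAfold; it exists so the pipeline runs deterministically
and self-contained. Externally produced structures can be supplied via
the Vienna dot-bracket reader (including `(dG = …)` energy comments)
and are used verbatim. Tracebacks are deterministic (closing pair
first, then 5' unpaired, then 3', then leftmost bifurcation), which
recovers contiguous stems whenever they are co-optimal.

## Expression

RPM normalization uses each library's mappable total as denominator
(configurable). The DE rule is strictly more than two-fold on the
larger/smaller RPM ratio. A pseudo-RPM of 0.01 is added only when one
side is zero: it keeps the ratio finite without perturbing nonzero
comparisons. No replicate-aware statistics are computed — the design
this implements has one library per condition.

## Degradome target calling

Degradome 5' ends are anchored by exact match of the read's first
20 nt, sense strand, counted on every matching transcript (flagged
multi-mapped). The miRNA scan is gapless: plant miRNA:target duplexes
are near-perfectly complementary, so the scanner slides a window of
miRNA length with Allen-style penalties (mismatch 1, G:U 0.5, doubled
at miRNA positions 2–13) and keeps windows scoring ≤ 4.5. The gap
penalty constant (2) is retained in the scorer for completeness but no
gaps are opened.

"The 9th or 10th nucleotide of the binding region" admits two counting
conventions; both are implemented behind a switch. The default counts
opposite miRNA positions 9/10 (i.e. from the region's 3' end), the
only reading consistent with the canonical slice site between target
bases paired to miRNA positions 10–11 for 21-nt miRNAs; the literal
5'-end count is available as `counting="five_prime"`. The observed
site is the most abundant evidence position inside the binding region;
a call requires the alignment retained, the position check passed and
≥ 1 read.

Categories follow t-plot conventions (the source material uses 0–4
without defining them): 0 unique transcript maximum with > 1 read,
1 shared maximum, 2 above the median of nonzero positions, 3 at/below
the median with > 1 read, 4 exactly 1 read. The 0/4 boundaries operate
on raw counts and are therefore not invariant under uniform scaling of
counts; the 1/2/3 boundaries are.

## Synthetic studies

The generator's defaults define the study conditions: two libraries of
2×10⁵ reads; 10 novel + 2 species-known + 2 plant-conserved planted
hairpins; one decoy per violable criterion (7: star withheld, 4
scattered mismatches, 4 consecutive mismatches, two 1-nt bulges, one
3-nt bulge, blunt duplex, low-MFEI stem); mature abundances log-uniform
(6,000–16,000 expected reads) with the star arm at 10% of its mature —
typical of real arm asymmetry — and Poisson count noise; planted
cross-library ratios {1, 3, 4, 5 and inverses} paired r with 1/r so
both libraries spend the same expected depth; 5% contaminant, 2% junk,
2% adapter-less, 2% short and 1% long reads; a degradome of 5 genuine
targets (binding site = exact reverse complement of a planted mature,
80% of reads at the slice site by default) plus 3 shuffled decoy
transcripts.

Planted precursors are **alphabet-insulated**: duplex arms use only
G/C with A padding (A cannot pair without U), or an A/U-only duplex
with C padding for the low-MFEI decoy (C cannot pair without G). Under
the proxy energy model this makes the planted stem the unique
maximum-weight structure, so recovery failures indicate pipeline
defects rather than folding ambiguity. The cost is realism: synthetic
matures have extreme base composition, precursor pads are homopolymeric
and all planted stems are perfect. Consequently the synthetic studies
establish the *logic* of the pipeline — exact accounting, criterion
attribution, naming, normalization, site arithmetic — but say nothing
about sensitivity on thermodynamically marginal real hairpins, isomiR
handling, or behavior under sequencing error (substitution errors are
not simulated). Every planted locus (and each decoy's star arm) is
re-screened with the production code at generation time; the generator
resamples fillers and errors out rather than publish truth the data do
not support.

Abundance planning enforces a margin around the two-fold boundary
(planted folds > 2.3 or < 1.7) so Poisson noise cannot flip a designed
DE class; at the default depths observed folds track planted folds to
within a few percent.

Problem sizes throughout (2×10⁵ reads, 30 kb genome, 1.2 kb
transcripts, 2×10³ degradome reads) are chosen so a full study
generates and analyzes in well under a minute each on one core, making
end-to-end runs cheap to repeat in tests.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based in
  human-readable reports (cleavage sites, t-plots).
* Candidates whose structure pairs them onto themselves (no
  interpretable star arm) fail the star criterion rather than erroring.
* A read equal to the adapter yields an empty insert, charged to
  `too_short`.
* Zero-count cells in DE: both-zero → unchanged at fold 1; one-sided
  zero → pseudo-RPM as above.
* The category assignment errors on a site with zero reads (it is not
  an evidence site).
* Palindromic duplexes (the blunt decoy) legitimately map on both
  strands; both orientations are screened and must fail.

## Known limitations

* The proxy folder under-penalizes long-range pairings; on real
  genomic windows its structures can differ substantially from
  thermodynamic folders, which is why externally supplied structures
  are first-class inputs.
* Conserved matching requires equal length: length-variant homologs
  (isomiR-style) are classified novel.
* The homology criterion for targets is a user-supplied map, not a
  sequence search; without a map it degrades to advisory annotation.
* Single-library-per-condition DE has no error model; calls are
  descriptive ratios, as in the study design it reproduces.
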