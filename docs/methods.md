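# Methods

This note records the models and procedures implemented in `mircms`, the
parameters that matter, the design choices made where the method left room,
and what the synthetic benchmark does and does not demonstrate.

## Study design assumptions

The pipeline targets the unreplicated two-condition design of classical
deep-sequencing bud studies: one small-RNA, one degradome and one RNA-seq
library per condition (CMS line vs maintainer).  All statistics therefore
model counting noise only — there is no dispersion estimation, and p-values
quantify sampling variability within a library pair, not biological
variability across plants.  Fold changes are always reported as
log2(CMS / control).

## Small-RNA catalog

Cleaning removes, in order: malformed records, low-quality reads (mean
phred < 20 or any N), reads without the 3′ adapter, empty inserts, 5′-adapter
contaminants, inserts shorter than 18 nt, poly-A inserts, and inserts longer
than 30 nt.  Choices the method description left open:

* **Poly-A** is defined as ≥ 80 % adenine over the insert.
* The 18–30 nt bound is applied symmetrically (> 30 nt reads are removed,
  not truncated).

Known-miRNA identification uses two rules: exact substring match to a
reference precursor, and ≥ 16 nt overlap with a reference mature in
precursor coordinates (tolerating processing offsets).  Matures sharing an
identical sequence across precursors collapse into a single record so that
multi-precursor families are not double-counted.

Family expansion aligns leftover tags to mature miRNAs of other species with
a semi-global alignment (edlib) allowing two edits; substitutions and gap
columns both count toward the budget and end offsets are free.  Per family
the highest-expressed matching tag is provisionally accepted and kept only
if one of its genomic loci (±150 nt windows, both orientations) passes the
hairpin criteria; otherwise it is discarded as a pseudo-miRNA.

Annotation assigns each tag exactly one category by priority:
known_miRNA > rRNA > scRNA > snRNA > snoRNA > tRNA > repeat > exon_sense >
exon_antisense > intron_sense > intron_antisense > unannotated.  Structural
RNAs are recognised by exact substring containment in a decoy reference;
genomic categories by interval overlap at the tag's exact-match loci.
siRNA/piRNA are not called separately (no method is defined for them); such
reads fall into unannotated — a known limitation.  Tags annotated as intron
(either strand), exon antisense or unannotated are forwarded to novel-miRNA
prediction.

## Folding and hairpin validity

Two energy backends sit behind one interface.  The default is ViennaRNA's
minimum-free-energy fold.  The bundled fallback is a simplified
nearest-neighbour model solved exactly by a Zuker-style dynamic programme:
stack energies keyed on the closing pair (GC/CG −3.0, AU/UA −2.0, GU/UG −1.0
kcal/mol), hairpin loops +4.0, internal loops/bulges +3.0 plus 0.5 per
unpaired nucleotide, multibranch loops +4.0, minimum hairpin loop 3 nt,
internal loops capped at 30 nt per side.  Ties break toward structures with
more pairs, preferring 5′-most pairings.  The DP is verified against
exhaustive enumeration of all pseudoknot-free structures on short sequences.

A hairpin candidate passes when all of the following hold, each with its own
reason code on failure:

| criterion | default |
|---|---|
| precursor length | 40–400 nt |
| single terminal loop on the mature-bearing stem | — |
| mature entirely on one arm, ≥ 55 % paired | — |
| mature:star duplex ends consistent with 2-nt 3′ overhangs | ±1 nt |
| duplex bulges | ≤ 4 nt asymmetric, ≤ 6 nt total internal loop |
| minimum free energy | ≤ −18 kcal/mol (inclusive) |

The −18 kcal/mol ceiling is applied to the folded candidate (precursor
fold), the common Mireap usage; the criteria object is fully configurable.
The star span is derived from the fold's pairing of the mature ends rather
than from sequence positions, so imperfect stems are handled.

## Novel miRNA calling

Forwarded tags with more than 5 copies (summed over both samples; the
threshold is applied per merged mature) are mapped exactly to the genome via
an 18-mer seed index; tags with more than 20 loci are dropped as repetitive.
Around each locus three windows are examined (±150, −20/+200, −200/+20 nt)
on the tag's strand; the best valid hairpin by energy wins.  Before folding,
each window is screened with a fast semi-global alignment: a valid
mature:star duplex implies a near-reverse-complement of the tag elsewhere in
the window (edit distance ≤ 6 under the duplex bulge limits), and windows
without one cannot pass validation.  This pre-screen is what keeps
genome-scale calling tractable; it is conservative with respect to the
duplex criteria.

Identical matures from multiple loci merge into one call with the precursor
count incremented.  A call's star arm is marked observed when a sequenced
tag matches the predicted star within a 2-nt shift.  Expression of a novel
miRNA sums tags whose alignment to the mature has an exactly matching core
with at most 3 edited columns (substitutions, trims, overhangs) confined to
the terminal 3 nt of each end; the "middle vs ends" boundary (3 nt) is a
configurable interpretation, as is the per-merged-mature reading of the copy
threshold.

## Expression statistics

* TPM = count / total clean reads × 10⁶; RPKM = 10⁹·C/(N·L).  The standard
  RPKM constant is used; a dimensionally inconsistent variant sometimes
  printed in methods sections is treated as a typographical slip.
* Fold change log2(CMS/control); a one-sided zero is floored at 0.01
  normalised units; features zero in both samples are excluded with a log.
* The miRNA layer uses the Audic–Claverie exact test (the IDEG6/BGI-era
  standard for unreplicated tag counts): given count x in library N1, the
  second count is negative-binomial NB(x+1, N1/(N1+N2)) under the null, and
  the two-sided p-value doubles the smaller tail.  At study-scale counts
  (~100 per feature) the empirical type-I error at α = 0.05 is ≈ 0.047;
  the test grows conservative at very low counts, as all discrete exact
  tests do.
* The mRNA layer uses the Pearson chi-squared test on
  [[c1, N1−c1], [c2, N2−c2]] with 1 df, falling back to the exact test when
  an expected cell drops below 1.
* FDR control is Benjamini–Hochberg (statsmodels), cross-checked against a
  textbook step-up implementation.
* Regulation calls: |log2FC| ≥ 1 and p < 10⁻³ (miRNA) or FDR < 10⁻²
  (mRNA; a stricter 10⁻³ preset exists for target reporting).  All
  thresholds live in `PipelineConfig`.

## Degradome target validation

Only 20–21 nt distinct reads enter the profiles; exact sense-strand matches
accumulate their abundance at the 5′-end position.  Complementarity uses the
Allen rule (mismatch 1.0, G:U wobble 0.5, gap 1.0; penalties doubled at
miRNA positions 2–13; at most one gap) with a retention ceiling of 4.  The
degradome tag 5′ end marks the 3′ cleavage product, so a hit requires signal
at the transcript base paired to miRNA position 10 (canonical) or 11.
Candidate sites are anchored at observed degradome 5′ ends and pre-screened
with a provable lower bound (per-position minimum penalty over the three
possible alignment phases) before exact scoring.

The permutation p-value re-scores seeded Fisher–Yates shuffles of the miRNA
at the same cleavage-coincident site: p = (1 + better-or-equal shuffles) /
(1 + shuffles), add-one smoothed so p is never 0; hits with p ≥ 0.05 are
dropped.  T-plot categories: 0 unique transcript maximum (> 1 read), 1 tied
maximum, 2 above the median of nonzero positions, 3 at or below it, 4 single
read; the median is computed over nonzero positions, and the category is
informational, not a filter.

## Integration

Validated pairs whose miRNA and target both have defined fold changes are
classified into clusters I (miRNA down / target up), II (both down), III
(both up), IV (miRNA up / target down); zero fold changes resolve to the
smaller cluster index and are flagged.  Tier labels require *both* members
to pass 1.5-fold or 2-fold; tier sets are nested.  Annotation is a plain
join with a user-supplied gene description table — enrichment against
external ontologies is out of scope.

## Synthetic studies: what they emulate and what they do not

The generator plants, under one root seed with named substreams (genome,
transcriptome, srna, degradome, rnaseq):

* precursors as 30-bp inverted repeats with an 8-nt unpairable A/C loop and
  two isolated star-side mismatches, GC-biased so the fold sits ≥ 10
  kcal/mol below the −18 ceiling under either energy backend — both backends
  then agree on every accept/reject decision;
* target sites as reverse complements of planted matures, mutated outside
  the cleavage-critical positions to hit any requested alignment score
  exactly;
* small-RNA libraries (default 10⁶ tags/sample) as Poisson draws around
  depth-scaled expected abundances: planted miRNAs (log-normal abundance
  spread, star strands at 2 %) honouring the planted fold changes, plus a
  background of distinct genome-derived fragments (18–30 nt, sizes peaked at
  24 and 21 nt, ≈ 1 expected read per species) and bundled synthetic
  rRNA/tRNA decoys; a negative-binomial noise option exists for robustness
  checks;
* degradome libraries with 20/21-nt tags at each planted cleavage position
  far above a uniform background of degradation hotspots;
* RNA-seq counts with the target genes carrying the anticorrelated fold
  changes.

Defaults: 100-kb genome, 10 known + 10 novel precursors, 50 transcripts,
5 planted targets with |log2FC| = 1, background fraction 0.5.  Poisson noise
matches the single-library-per-condition design.

Not emulated: base-call qualities and adapter chemistry, sequencing-error
substitutions, isomiR distributions, abundance skew within the background
(species are near-equiprobable), genome repeat structure, and multi-mapping
ambiguity beyond what a random genome produces.  Recovery results on
synthetic data therefore demonstrate the correctness of the decision rules
and their wiring, not robustness to real-library artefacts.

**DE sensitivity definition.** Planted fold changes sit exactly at the
two-fold call boundary, and an unbiased estimate lands below the strict
|log2FC| ≥ 1 filter about half the time (library renormalisation even biases
it slightly inward).  Sensitivity on synthetic data is therefore defined as
detection: the planted feature is significant at the layer's threshold with
the correct fold-change sign.  The magnitude filter remains in force for
regulation calls on real data; the benchmark measures the test, not the
filter.

## Benchmark problem sizes

The recovery benchmark runs the full pipeline on ten seeds at the default
conditions above (≈ 20 s per seed on one CPU) and averages recall of planted
novel miRNAs (criterion ≥ 90 %), planted targets (≥ 80 %), category-0 false
positives (0) and DE sensitivity (≥ 0.9).  The fold oracle suite checks
1,000 random sequences up to 22 nt against exhaustive enumeration; the
alignment oracle 600 toy 17-mers; the tag-test calibration 10⁴ null
features.  Unit tests use a reduced study (40-kb genome, 6 × 10⁴ tags) so
the whole suite stays interactive.

## Known limitations

* siRNA/piRNA classes are not separately annotated.
* The degradome stage validates cleavage only; translational repression is
  invisible to it.
* With one library per condition, significance reflects counting noise;
  biological replication would require a different testing layer.
* The family-expansion stage requires a genome; without one it is skipped
  with a warning.
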