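# Methods

## Problem and model

`cfescan` implements a knowledge-driven procedure for discovering
unannotated intronic promoters and the coding first exons (CFEs) they
drive, and for testing whether copy-number deletions over those elements
are enriched in patients relative to controls. The procedure was developed
around a locus in which partial deletions of *DLG2* (an 11q14.1 synaptic
scaffold gene with very long introns) clustered over two intronic H3K4me3
peaks, HPin7 and HPin8, each hiding a brain-expressed first exon; the
package generalises and regression-tests that analysis.

A candidate element is an H3K4me3 peak region that overlaps the deletion
footprint of at least one case patient. It is retained when all of the
following hold (the "four-criterion filter"):

1. deleted in at least one case patient;
2. at least one transcription-factor binding site overlaps the region;
3. at least one CAGE TSS peak overlaps the region;
4. the H3K4me3 / H3K4me1 peak ratio over the region exceeds 1 (strictly);

and a coding first exon is called inside the candidate when the RNA-seq
per-base depth drops abruptly (>= `min_delta`, default 20 reads) between
two adjacent bases whose 4-nt genomic context matches the donor consensus
AG|GT, no splice junction lands *inside* the region (a first exon has no
upstream acceptor), and at least one junction splits from the detected
donor into a downstream annotated exon. A screen for the recursive-splicing
element YYYAGGURAG (IUPAC alphabet, U = T) distinguishes genuine exons from
recursive-splicing intermediates.

Enrichment is a one-tailed Fisher's exact test on a per-patient 2x2 table:
cases with / without a region-overlapping deletion versus the same for
controls, with the denominator an explicitly stated analysis universe (for
a locus study: all deletions overlapping the locus). The p value is the
upper-tail hypergeometric probability computed as an exact rational
(integer binomial coefficients; the only rounding is the final conversion
to float). With several candidate regions, each setting applies Bonferroni
correction with m = the number of regions scanned; a region counts as
enriched only when the adjusted p is below alpha in *every* control
setting (the "dual-setting" rule, used because heterogeneous control
cohorts cannot be merged).

## Coordinate and boundary conventions

All internal coordinates are 1-based and fully inclusive
(`width = end - start + 1`); this is the system of the published patient
and element tables, whose coordinates are used verbatim. BED, narrowPeak
and bedGraph files are 0-based half-open on disk and converted at the I/O
boundary; a write-then-read round trip is the identity. Overlap requires at
least one shared base — bookended intervals do not overlap. Chromosome
names are compared as exact strings.

A coverage step lives between two adjacent bases; `CoverageStep.pos` is
always the lower (left) base of that pair, matching the two-base printed
notation of splice boundaries (e.g. `84431338-9`). On a plus-strand gene
`pos` is the last exonic base; on a minus-strand gene a donor-side drop is
an upward step in forward coordinates and the last exonic base is
`pos + 1`. The donor context window is forward positions `pos-1 .. pos+2`,
reverse-complemented for minus-strand genes so that the context always
reads two exonic then two intronic bases in gene orientation.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| CNV length window | 50 — 3,000,000 | bp | the common preprocessing rule applied to every cohort source |
| abs(log2ratio) | >= 0.32 | — | array-CGH calling threshold; categorical sources carry no ratio and face only the length rule |
| `min_delta` | 20 | reads | abrupt-coverage threshold of the candidate filter |
| me3/me1 ratio | > 1, strict | — | promoter- vs enhancer-leaning chromatin |
| alpha | 0.05 | — | per-setting Bonferroni-adjusted significance level |
| `min_case` | 1 | patients | SRO aggregation / candidate threshold ("deleted in at least one case") |

The me3/me1 ratio statistic is not pinned down by the source analysis; the
package uses the ratio of maximum overlapping narrowPeak signal values in
one designated tissue (configurable to the -log10 p column). A region with
H3K4me3 but no overlapping H3K4me1 peak yields an infinite ratio and
passes: absence of the enhancer-leaning mark is the strongest promoter
evidence, and a strict-ratio reading would reject exactly the cleanest
promoters. A region with no H3K4me3 yields 0 and fails. TFBS/CAGE
"presence" means >= 1 record overlapping by >= 1 base, with no score
threshold (none is stated anywhere). Brain specificity of a CAGE peak
compares the maximum TPM over a named brain-tissue set against the maximum
over all other tissues; ties resolve to "not specific".

## Smallest regions of overlap

Deletion stacks are partitioned at every deletion breakpoint (start and
end+1) into SROs: maximal segments whose overlapping-deletion set is
constant. Segments covered by no deletion are dropped; the SRO union equals
the deletion footprint, and the construction is invariant under permutation
of the input. Breakpoints from *all* cohorts define one shared partition
and per-cohort counts (distinct patients) are read off each segment — this
is forced by the constant-set invariant, since a control breakpoint strictly
inside a segment would make the control count non-constant there. Adjacent
(strictly bookended) SROs with case count >= `min_case` merge into
aggregated regions; a single uncovered base breaks adjacency.

## Tie-breaks and degenerate inputs

* Equal-delta donor candidates: the most downstream (gene-orientation)
  boundary wins, calling the longest supported exon.
* Junction-to-boundary matching is exact (0 bp tolerance): junctions and
  coverage derive from the same alignment, so slack is unjustified.
* `log2ratio == 0` is rejected as uninterpretable rather than silently
  classified.
* A patient with several qualifying CNVs counts once in every table and
  count (the counting unit is the patient).
* An empty/too-short region is vacuously free of the recursive motif.
* A 2x2 table with an empty case or control margin is a construction
  error, surfacing degenerate cohort configurations early.
* An `N` base satisfies only the fully degenerate `N` pattern class during
  motif scanning (an ambiguous base is not evidence for a motif).

## The synthetic locus generator

The generator (`cfescan.simulate`) emulates the statistical structure the
pipeline assumes on a 100 kb toy chromosome: a 4-exon plus-strand gene with
long introns; two planted intronic elements carrying promoter-like
chromatin (H3K4me3 signal ~20-30 vs H3K4me1 ~4-9), TFBS, brain-leaning CAGE
(fetal brain ~20-40 TPM vs <=1.5 TPM elsewhere), an expressed first exon
whose 3' boundary steps down by a planted delta with AG|GT context and a
junction into a downstream exon; four decoy regions each missing exactly
one filter criterion; and per-patient deletion cohorts. Defaults are the
study conditions of the reproduced locus: 14 cases and two control cohorts
of 19; per-patient element-hit probabilities 11/14 and 3/19; planted deltas
46 and 59 on an exonic depth of 60 over a baseline of 5 (nascent intronic
transcription); deletion lengths 5-40 kb, uniform breakpoints conditional
on hit status (the least-informative choice), log2 ratios uniform in
[-1.5, -0.4] so every generated record passes the preprocessing filter
unchanged. Each output stream has its own child of the master seed;
identical seeds give byte-identical files.

What the generator does *not* emulate — hence what passing tests do not
show about real data: per-base coverage noise (tracks are piecewise
constant, so the planted delta is recovered exactly rather than
approximately; real read depth would jitter the measured delta), read-level
artefacts (no BAM/FASTQ simulation), multi-gene loci, genome-build
heterogeneity, breakpoint clustering at repeats, and patients with multiple
aberrations. Within-region significance power is faithful to the small
cohort sizes: with 14 cases split across two elements, per-element
dual-setting significance is seed-dependent, while the any-element union
test (the analogue of testing "deletions affecting any candidate element")
is significant at every seed examined.

## Packaged locus fixture

`cfescan.fixtures.dlg2_fixture()` bundles the 29 published patient
deletions (hg19) with their verbatim inheritance/phenotype annotations, the
HPin7/HPin8 and CFE coding intervals, the two published candidate rows, and
the validation-cohort contingency counts (11/14 cases, 3/19 controls). The
published per-HP control breakdown (4 and 1 of 19) disagrees with the
narrative counts (2 and 1, totalling 3); the fixture stores the narrative
counts because they reproduce the printed p value exactly, and carries both
variants for inspection. The fixture fixes one genome build (hg19) per
dataset and performs no build conversion.

## Problem sizes

The default test suite and the acceptance script run the full file-based
scan on the 100 kb locus (52 patients, ~10 tracks), the exact-Fisher
equivalence over all 2x2 tables with total <= 40 (~135,000 tables against
`scipy.stats.hypergeom` as the independent oracle), 200 random SRO
instances of up to 50 deletions over 100 kb against a per-base numpy
oracle, 50-seed planted-boundary recovery, and a 200-replicate null
(equal hit probability) calibration of the dual-setting false-flag rate.
These sizes were chosen so the whole suite completes in seconds while every
oracle comparison stays exhaustive or statistically well-powered.

## Known limitations

* Peak calling is out of scope: histone peaks are consumed as narrowPeak,
  never recomputed from ChIP-seq signal.
* De novo transcript assembly and differential exon usage are replaced by
  the coverage-delta + junction logic; isoforms whose first exon lacks an
  abrupt 3' coverage step are invisible.
* The genome-wide scan's Bonferroni multiplier is the number of
  filter-passing candidates; analyses that test pre-registered region lists
  should set the multiplier explicitly.
* bedGraph ingestion materialises per-base arrays; chromosome-scale tracks
  at human genome size would need a windowed reader.
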