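# Methods

This note describes the models and procedures implemented in `tevex`,
the assumptions they make, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Problem setting

During infection of an insect host by a large double-stranded DNA
virus (a baculovirus), two things can be measured from bulk RNA-seq
time courses: (i) how the expression of host transposable-element (TE)
families responds to infection, and (ii) whether host TEs that have
integrated into viral genomes are themselves transcribed. `tevex`
implements both analyses as reusable stages — repeat-annotation
aggregation, family-level quantification and differential expression,
chimeric-read detection, and target-site-duplication (TSD) validation —
together with a simulator that generates every input with known truth.

## TE copies and the annotation filters

Repeat-masking tools report TE matches as fragments. `aggregate_hits`
merges fragments that share contig, family (consensus) and strand
whenever the gap between consecutive fragments is at most `max_gap`
(default 150 bp, configurable); overlapping or nested same-family hits
are merged by interval union so masked base pairs are never counted
twice. A copy's divergence is the length-weighted mean over its
fragments, and aggregation is idempotent.

Two retention filters follow the conventions of TE expression studies:

- **Copy filter** — a copy is kept iff it is *strictly* longer than
  80 bp and has *strictly* more than 80% identity to its consensus
  (i.e. divergence < 20%). Shorter or more degenerate copies attract
  spurious multi-mapping reads without contributing interpretable
  family-level signal.
- **Library filter** — a consensus enters the expression library iff it
  is longer than 300 bp, its best hit against a TE protein covers at
  least half of that protein (inclusive at exactly one half), and its
  category is not SINE, tRNA, rRNA or Unknown. Protein-coverage values
  are inputs; the protein alignment itself is out of scope.

Landscape summaries report copy numbers per superfamily, class
fractions, a divergence histogram in 1% bins (divergence to consensus
is the standard age proxy: older families have drifted further), the
overlap-merged masked base pairs and the masked genome fraction.
Distance to the nearest gene is 0 for any copy overlapping a gene
interval and otherwise the minimum gap to a gene boundary on the same
contig, strand-ignored; copies on contigs without genes are flagged
NaN rather than silently dropped.

## Expression quantification

Reads are counted per family with a single retained alignment per read
(longest alignment; ties broken by sorted family then copy name), so
multi-mapping reads within a family's many copies count exactly once.

TPM is computed jointly over genes and TE families: per replicate,
RPK = count / (length in kb), and TPM = RPK rescaled so the column sums
to 10^6. Carrying genes through normalization matters because TE
counts alone are a tiny, composition-biased fraction of the library.
Expression categories use condition-mean TPM (whether the original
analyses averaged replicates or classified per replicate is not
derivable; condition means are used and documented here): below 4 TPM
a family is considered not expressed, at or above 50 TPM highly
expressed (roughly 100 RPKM at these read lengths). The boundary value
4.0 itself counts as expressed; the source analyses use "< 4" and
"> 4" inconsistently around the boundary, and this package standardises
on `>= 4` meaning expressed.

## Differential expression

Size factors are median-of-ratios over genes + TEs (median, per
replicate, of the ratio to each entity's geometric mean, over entities
with no zero counts). Two contrast designs are supported:

- **matched** — infected vs mock replicates at each time point (the
  tissue time-course layout). A time point with no mock replicates is
  skipped with a warning rather than failing the whole run (in the
  cell-line data one mock time point is unavailable).
- **baseline** — each infected time point vs the mock at the earliest
  time point (the cell-line layout, motivated by the fact that
  uninfected cultures keep growing and drift in expression while
  infected cells stop dividing).

The built-in test engine is a vectorized negative-binomial Wald test:
log2 fold change from normalized condition means with a pseudocount of
0.5 (bounding fold changes for zero counts), per-entity dispersion by
pooled method of moments (solving var = mu + alpha*mu^2 within each
condition, floored at zero), and a delta-method standard error on the
log2 scale. P-values are two-sided normal, adjusted by
Benjamini–Hochberg per contrast over all tested entities; genes are
then dropped from the report. A family is differentially expressed
when padj < 0.05 and |log2FC| >= 2 (both configurable).

This engine deliberately does not reproduce DESeq2's dispersion
shrinkage: the analysis-specific content is the normalization,
thresholding and classification layer, and `apply_de_thresholds`
accepts externally computed (log2fc, padj) tables so results from any
DE engine can be classified identically. On simulated tables the
built-in engine's fold changes agree with an independent DESeq2
implementation to r > 0.99 (see the test suite), and with n = 3
replicates per side its null false-call proportion at the combined
padj/log2FC rule is far below the nominal 5% because the |log2FC| >= 2
gate dominates. The Wald p-values themselves are anti-conservative in
the extreme tail at n = 3 (method-of-moments dispersion is noisy), a
known limitation; the fold-change gate makes the final calls robust to
it.

**Induced / repressed.** A family is *induced* when its mock TPM is
below 4 at every mock time point, its infected TPM reaches 4 at one or
more time points, and it is called up at one or more time points;
*repressed* is the mirror image. Requiring the DE call prevents
borderline families that drift across the threshold from being
labelled.

**Factor correlations.** Family-level expression is correlated
(Pearson, pairwise-complete, two-sided p) with copy number, mean
divergence (age) and mean distance to genes. Zero-variance factors are
flagged NaN.

## Chimeric-read detection

A chimeric read is evidence that a TE copy integrated in the viral
genome is co-transcribed with flanking viral sequence: one portion of
the read aligns to a TE consensus only, the other to the virus only.
From per-read local alignments, a read is called chimeric iff it has a
TE alignment and a virus alignment, each at least `min_segment = 28 bp`
on the read (the shortest alignment a megablast-style search returns at
these read lengths), whose read intervals neither contain one another
nor overlap/gap by more than `overlap_tol = 10 bp` (junction
micro-homology causes small overlaps; both tolerances are
configurable). One call is made per read — the pair with the largest
combined aligned length, ties by lowest virus coordinate — so a read
can never inflate junction counts.

**Junction coordinate.** Coordinates are on the TE-free viral
reference, reported as the 0-based position immediately right of the
junction. The junction's position on the read is taken from the TE
segment boundary and mapped through the virus alignment's diagonal.
Rationale: at a tip junction the TE alignment is hard-bounded by the
consensus extremity and therefore ends exactly at the junction, whereas
the virus alignment can extend a few bases into the TE wherever the
reference continuation happens to match (and with a TSD it often does).
Using the virus segment's own end would shift coordinates by the length
of that micro-homology; with this convention, error-free reads recover
planted junctions exactly.

**Tip vs internal.** The junction-proximal end of the TE segment is
located on the consensus after orientation normalization. Within
`tip_tol = 5 bp` of position 0 it is a 5' junction, within 5 bp of the
consensus end a 3' junction, otherwise internal; the exact offset is
reported. The tolerance absorbs alignment-end fraying on real data
(the sources never quantify "at the extremity"); on error-free
synthetic reads observed offsets are exactly 0. Tip junctions are the
signature of transposition; internal junctions indicate reads entering
a fragmented or rearranged copy.

Tabulation counts tip chimeras by family x time point x replicate x
side, lumping families with fewer than 10 chimeric reads over all data
sets into an "Others" row. Hotspot histograms bin junction coordinates
into half-open windows (default 50 bp). Junction-level RPKM
(count / kb of junction feature / million mapped reads) quantifies
co-expression of a virus-borne TE with its host gene; expression over
the TE body is deliberately not attempted because internal reads cannot
be apportioned between host-borne and virus-borne copies.

## TSD pairing

Canonical transposition duplicates a short target motif on both flanks
of the insertion, so on the TE-free reference the 5'-tip and 3'-tip
junction coordinates of one insertion differ by exactly the TSD length
(4 bp with a TTAA/ATAA motif for piggyBac, 3 bp for Harbinger, 0 for a
blunt event). `pair_junctions` clusters tip chimeras by (family,
orientation, time point) and coordinate, then pairs 5' and 3' junction
groups whose coordinates agree to within `max_delta = 5 bp` (inclusive;
"within 5 bp" is read inclusively). Concordant orientation means the
TE strand implied by the 5' chimera equals that implied by the 3' one —
the criterion is stated but not operationalised in the sources, and
this is the natural reading. Pairing is greedy one-to-one by
descending read support (ties by coordinate) so each junction group —
and hence each read — supports at most one insertion; all-vs-all
pairing would combinatorially inflate distinct-insertion counts.

The TSD motif is the reference substring between the two paired
coordinates (empty for blunt events). Distinct insertions are unique
(family, coordinate pair, orientation) tuples; `merge_tol` (default 0,
exact) optionally collapses near-duplicate coordinate pairs, since no
collapsing tolerance is derivable from the sources.

## The synthetic-data generator

The generator emulates the study system so every stage has ground
truth:

- **Viral genome** — i.i.d. bases at a configurable GC content
  (default 0.41, baculovirus-like), default length 100 kb. The genome
  is treated as linear: the real genome is circular, but coordinate
  analyses are linear and reads are not simulated across the origin.
- **TE library** — random consensus sequences (default 0.6–1.6 kb);
  class II families get terminal inverted repeats. Default
  superfamilies give TSD motifs TTAA, ATAA (piggyBac-style), TTA
  (Harbinger-style) and blunt insertions for the retroelements —
  exactly the motif set the downstream stages must distinguish.
- **Insertions** — planted at actual motif occurrences on the
  reference, with the motif explicitly duplicated on both flanks and
  random orientation; k = 0 covers the blunt edge case. Sites are kept
  ≥ 500 bp apart and ≥ 300 bp from the ends so junction templates fit.
- **Reads** — single-end, uniform start positions, Poisson read counts
  giving ~`depth` per-base coverage, constant 'I' qualities, and
  substitution-only errors at `error_rate`. Defaults (101 bp, 30x,
  error-free) match the conditions under which exact junction recovery
  is asserted; 51 bp matches the tissue libraries. No indels: junction
  logic is coordinate-based and indel handling would conflate aligner
  behaviour with pipeline behaviour. Every read carries a provenance
  label (virus / te / junction_5p / junction_3p / host_gene) that
  partitions the read set.
- **Count tables** — negative-binomial counts with
  var = mu + dispersion*mu^2, planted per-entity log2 fold changes
  applied to the infected condition, and optional per-replicate size
  factors; dispersion 0 reduces to Poisson. Three replicates per
  condition is the default study layout.

What the generator does **not** emulate: splicing, paired ends, PCR
duplicates, quality-score structure, indels, sequence-composition bias,
and the time-dependent mixture of viral vs host transcripts (the
proportion of viral reads rises steeply during a real infection; the
mixture is a free parameter here, not a fitted one). Passing tests
therefore demonstrate the correctness of the coordinate logic,
counting, normalization and statistics — not robustness to alignment
noise on degraded real data, where an external aligner and its
parameters dominate.

## Built-in aligner

The exact-seed (k = 20) ungapped extender exists so the synthetic suite
runs without an external binary: reads are matched both-stranded via an
exact 20-mer index and extended while bases match. It is adequate for
error-free or near error-free reads only; real data should be aligned
externally (e.g. a megablast-style tabular output) and imported through
`parse_alignments`, which converts 1-based inclusive coordinates to the
package's 0-based half-open convention and normalizes minus-strand
subject intervals.

## Numerical and edge-case choices

- Coordinates are 0-based half-open everywhere internally; tabular
  inputs are converted at parse time and converted back on writing.
- TPM columns sum to 10^6 up to floating rounding (~1e-15 relative);
  all-zero replicates yield NaN columns with a warning instead of a
  division error.
- Degenerate inputs raise early: empty gene sets for distance
  computation, non-positive lengths or totals for RPKM, coordinates
  outside the genome for hotspot binning, contrasts with fewer than two
  replicates per side.
- Ties are always broken deterministically (sorted names, lowest
  coordinates) so repeated runs are bit-identical.

## Problem sizes

The test suite and the acceptance script run the chimera/TSD stage on a
100-kb genome with 20 insertions and ~3,500 reads, the DE null on 2,000
entities and the power analysis on 200 simulated tables, and TPM
conservation on 1,000 random tables — sizes chosen so the full analysis
of one synthetic data set completes in seconds on one core while leaving
all statistical checks well-powered.
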