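# Methods

This note documents the models and procedures implemented in clipsplice,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Coordinate conventions and data model

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted only at the parse/write boundary. A junction's
donor and acceptor are defined in transcription direction: on the +
strand the donor is the intron start and the acceptor the intron end, on
the − strand they are swapped. Uniqueness of mapping travels in the BED12
score column (1 = unique, 0 = multi-mapped); only unique reads enter gene
counting, junction counting and peak calling.

## Synthetic data generator

The generator emulates the statistical structure of a joint RNA-seq +
CLIP-seq experiment; it is the ground-truth engine for every validation
in this package.

**Gene models.** Genes are laid out without overlap on one random
chromosome, each with 3–6 exons of 120–300 bp separated by introns of
200–600 bp (defaults; all ranges configurable). Coding genes get 5'UTR
and 3'UTR blocks of 60–120 bp partitioned from the exon union in
transcription order, the remainder being CDS. One transcript per gene,
except genes hosting a planted AS event, which receive the minimal
two-isoform structure realising the event (shifted acceptor for alt3p,
shifted donor for alt5p, skipped exon for es, retained intron for ir).

**RNA-seq reads.** Reads are emitted pre-aligned (BED12), single-end,
one record per fragment; read pairing adds no information for peak
heights, junction counts or gene counts at this scale, and alignment is
out of scope. Two read classes are produced per gene and sample:

* *exon-body reads* — single-block reads uniform within exons; the
  per-gene total is negative-binomial with mean `rnaseq_depth` (default
  300) × the planted fold change (condition B) and dispersion
  `nb_dispersion` (default 0.05, a typical biological replicate value);
* *junction reads* — two-block reads spanning each annotated intron,
  Poisson with mean `junction_depth` (default 30) per intron. At a
  planted AS event, exactly `event_junction_reads` (default 200) reads
  are emitted per sample and each picks the primary variant by an
  independent Bernoulli draw at the configured ratio, so the planted
  inclusion count is exactly binomial — uniform placement over isoforms
  would only approximate this, because isoforms of different mature
  length have slightly different junction-crossing probabilities.

For ir events the "variant" read is an unspliced read crossing the
intron's donor or acceptor boundary (alternating), so a retained intron
shows coverage at both edges, as real retention does.

**CLIP reads.** Background reads (default 30 nt) are placed uniformly
over gene spans at `clip_background_rate` reads/kb (Poisson); the IP
library additionally carries each planted peak as a stack of
`stack_size` reads on a fixed interval (default 50 bp) inside the
requested region. The motif (e.g. `TTA`, read as `UUA` on the
transcript) is written into the genome across the peak interval at
gene-model generation time, strand-adjusted, so peak sequences genuinely
carry it. The control library is background-only and is reported, not
subtracted — the peak-calling null is simulation-based.

**What is not emulated:** sequencing errors, quality scores,
multi-mapping, paired-end geometry, GC or positional bias, overlapping
genes, and alignment artefacts. Passing tests therefore demonstrate the
correctness and calibration of the statistics under their stated
sampling models, not robustness to alignment noise.

**Determinism.** One root seed; each generator draws from a child stream
with a fixed spawn key (genome = 0, CLIP = 1, RNA-seq sample streams
from condition × replicate). Identical configs give byte-identical
outputs, which the end-to-end determinism check enforces at file level.

## CLIP peak calling

Reads overlapping by ≥1 bp (half-open spans) form clusters; cluster
height is the maximum per-base depth, computed by a ±1 sweep in which
interval ends sort before starts at equal coordinates. The null for a
gene re-places the same multiset of read span lengths uniformly at
random, unspliced, over the gene's genomic span — a mature-transcript
placement mode is available (`placement="mature"`) but genomic span is
the default, being simpler and more conservative for intron-rich genes.
500 iterations per gene (default); each records the maximum cluster
height. The empirical P uses an add-one pseudocount and counts ties
against the peak: `p = (1 + #{max ≥ h}) / (iterations + 1)`, so p is
never 0 and a peak no higher than every null maximum gets p = 1.
Per-gene permutation streams are derived from the root seed and a CRC of
the gene id, so results are independent of gene processing order.

Region labels use the peak midpoint with fixed priority
3'UTR > 5'UTR > CDS > noncoding exon > intron > intergenic when
overlapping transcripts disagree.

Measured behaviour (fixed seeds; also recomputed by
`scripts/acceptance.py`): on 200 background-only genes at 2 reads/kb the
fraction of genes with a significant peak is ≤ 0.10; planted 10-read
stacks over 0.5 reads/kb are recovered in ≥ 95% of 100 genes; a 20-read
stack on a 1 kb gene is never matched by a 10^5-iteration Monte-Carlo
null.

## Differential expression

Median-of-ratios size factors (genes with any zero count are excluded
from the geometric-mean reference). log2 fold change is the exact ratio
of group means; a 0.5 pseudocount is applied only when a group mean is
zero. The test is a Wald z-test on log2FC with a delta-method standard
error under NB sampling, `Var(count) = μ + α μ²`. Per-gene dispersion α
is method-of-moments from the pooled within-group variances, floored at
1e-4, then moderated by taking the maximum with the across-gene median
dispersion: with 2–4 replicates the raw moment estimate is frequently a
severe underestimate (often negative), which would make the normal-
reference Wald test anticonservative; the max-with-median rule restores
calibration at a small cost in power for genes whose moment estimate
runs high. Measured on NB simulations (2,000 null genes, dispersion
0.05, 3 vs 3): type-I error 0.04–0.06 at nominal 0.05; 50 planted 4-fold
genes among 1,000 nulls: sensitivity ≈ 1.0, false-discovery proportion
≤ 0.02. DEG flags require BH-adjusted P < 0.05 *and* fold change ≥ 2 or
≤ 0.5; the FPKM gene length is the exon-union length, the common
convention when a study does not state one.

This stage intentionally does not re-implement a full shrinkage
estimator (trended dispersion priors, LFC shrinkage); the decision
thresholds, not the estimator internals, are the reproducible content of
the workflow it supports.

## Alternative splicing

Junctions below 10 total supporting reads across samples (configurable)
are dropped, the rest are clustered by shared donor or shared acceptor
via union-find. Components in which all junctions share one site are
alt3p (shared donor) or alt5p (shared acceptor), strand-aware;
components linked through both relations — the cassette and
mutually-exclusive patterns — are kind "mixed". Intron retention events
pair a junction with unspliced reads crossing its exon–intron
boundaries; retention requires ≥5 spanning reads in total (configurable)
*and* at least one crossing read at each boundary, since genuine
retention leaves unspliced coverage at both edges whereas exonic
read-through over a single alternative splice site crosses only one.

**Classification.** The classical-type rules operate on the annotation:
for a site-sharing junction pair, a complete annotated exon between the
two varying sites means exon skipping (ES), otherwise a splice-site
shift (A3SS/A5SS by the transcription-direction side that varies). The
three-junction motif (inclusion pair + skip junction around one
annotated exon) is cassetteExon; the four-junction motif over two
disjoint annotated exons with no bridge and no skip junction is MXE; a
site-shift pair whose two source exons are both annotated terminal
(first/last) exons is 5pMXE/3pMXE; ir events are IntronR; clusters
showing both shift and skip pairs get the combination labels A3SS&ES /
A5SS&ES; anything else is reported as "complex", not dropped. These
rules are this package's operational definitions — classical-type
taxonomies differ between pipelines — and the fixture suite in
`clipsplice.examples` doubles as their executable specification.

**Differential test.** For the two junctions with the highest total
counts: Fisher's exact test (two-sided) on the 2×2 of group-summed
counts, BH across events, with RASE requiring adjusted P < 0.05,
|Δratio| ≥ 0.1, and replicate sign consistency (every group-A per-sample
ratio on one side of every group-B ratio). Pooling before testing and
demanding per-replicate consistency is a conservative substitute for a
replicate-aware GLM and is exactly testable against hypergeometric
enumeration.

**pSAR.** The dominance statistic is defined operationally: per sample,
`100 × supporting / (supporting + covering-but-non-supporting)` over the
cluster span, averaged across samples with coverage, where supporting
reads carry one of the cluster's junctions (for ir events, boundary-
spanning unspliced reads also count as event evidence — they are the
retained form). Events below 50% are excluded from the high-confidence
set. The definition lives behind a single function so an alternative
(e.g. frequency-based) definition can be swapped in.

## Motif enrichment

Exhaustive k-mer testing (k = 5 default, configurable) replaces
position-weight-matrix discovery: it is reproducible, dependency-free
and sufficient to recover short RBP motifs such as UUA repeats. The
background is per-sequence mononucleotide-preserving shuffles (default
100); dinucleotide shuffling is degenerate on 50 bp peak sequences. The
ranking statistic is z = (observed − shuffle mean)/max(shuffle sd, 1).
The P-value is *not* the normal tail of z: k-mer counts are small
non-negative integers, and with expected counts near 1 the normal tail
understates P by orders of magnitude, flooding BH with false hits on
null input. Instead P is the Poisson upper tail evaluated at a 95% upper
confidence bound of the shuffle rate (the bound absorbs the sampling
error of the estimated background mean). Measured over seeded runs: null
sequence sets produce a BH-significant k-mer in ≤ 5% of runs, and
UUA-planted peak sets put a UUA-containing 5-mer in the top 5 by z in
≥ 95% of runs.

## Integration

The bound, DEG-up, DEG-down and high-confidence AS gene sets are
intersected over the universe of all genes in the supplied annotation
(restriction to expressed genes is a config switch away; an annotation-
wide universe is the more conservative default for enrichment). Each
pairwise overlap carries an upper-tail hypergeometric P
(`P(X ≥ observed)`), explicitly labelled an addition over plain Venn
counts. Events are assigned to the gene containing their cluster span
start (the shared site for alt3p clusters), falling back to the span
end.

## Problem sizes and runtime

The validation suite and the reproduction script use: 200 genes for
peak-null calibration and 100 for recovery (500 permutation iterations),
a 10^5-iteration Monte-Carlo oracle for the 20-read stack, 2,000 null +
1,050 planted-mix genes for DE calibration, 500 junction reads per
sample for splicing recovery, a complete Fisher-vs-enumeration grid at
row margins ≤ 20 plus 2,000 random tables at margins ≤ 50, and 20 seeded
runs for the motif rates. These sizes put every stochastic check well
inside its tolerance while keeping a full run around one minute on one
CPU.

## Known limitations

* The permutation null ignores the control (input) library; input-driven
  artefact peaks would need control-aware normalisation.
* The DE stand-in has no dispersion trend over the mean and no LFC
  shrinkage; very-low-count genes rely on the median moderation.
* The splicing test pools replicates; biological replicate variability
  beyond binomial noise is handled only by the sign-consistency rule.
* Classical-type labels follow this package's rules; other pipelines
  draw the ES/cassette and MXE-variant boundaries differently.
* The generator's uniform background and exact planted ratios make
  recovery rates upper bounds on what identically parameterised real
  data would give.
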