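# clipsplice

An integrative analysis toolkit for studying how an RNA-binding protein
(RBP) shapes the transcriptome, combining four computational strands that
are usually run — and validated — separately:

1. **CLIP-seq peak calling with a permutation null.** Uniquely mapped
   CLIP reads with ≥1 bp of overlap are clustered into peaks; for each
   gene, the same multiset of read lengths is re-placed uniformly at
   random over the gene 500 times, and a peak of height *h* gets the
   add-one empirical P
   `p = (1 + #{iterations with null max ≥ h}) / 501`,
   significant at `p < 0.05`. Genes with a significant peak form the
   *bound* (target) set; peaks are annotated by the genomic region of
   their midpoint (3'UTR > 5'UTR > CDS > noncoding exon > intron).
2. **Junction-cluster alternative splicing.** Splice junctions sharing a
   donor (alt3p) or acceptor (alt5p) are clustered into events, mapped to
   classical AS types (A5SS, A3SS, ES, cassetteExon, MXE, 5pMXE, 3pMXE,
   IntronR and combinations), tested between conditions with Fisher's
   exact test on the two dominant junctions (BH-corrected,
   `|Δratio| ≥ 0.1`, replicate sign consistency), and filtered by
   **pSAR** — the event's junction-read share of all reads covering its
   span; events under 50% are considered minor and excluded from the
   high-confidence set.
3. **Threshold differential expression.** Exon-union gene counts from
   uniquely mapped reads, FPKM, and a negative-binomial Wald test with
   median-of-ratios normalisation; DEGs require BH-adjusted `P < 0.05`
   and fold change ≥2 or ≤0.5. A `2^-ΔΔCt` helper covers qPCR-style
   relative quantification.
4. **k-mer motif enrichment and set integration.** Significant-peak
   sequences are tested for enriched k-mers against per-sequence
   mononucleotide-preserving shuffles (recovering, e.g., UUA-rich RBP
   motifs), and the bound / DEG-up / DEG-down / AS gene sets are
   intersected with upper-tail hypergeometric enrichment over the
   annotated gene universe.

Because real studies of this kind hinge on dataset-specific read depths
and tool versions, the package ships a first-class **synthetic-data
generator**: random genomes with multi-exon gene models (GTF),
pre-aligned reads (BED12) with negative-binomially dispersed gene counts,
planted fold changes, planted splicing events at exact per-condition
inclusion ratios, and planted CLIP read stacks carrying a configurable
motif. Every planted signal is recorded in a ground-truth manifest, so
each stage can be validated end to end against a known answer key.

## Worked example

```python
from clipsplice import SimulationConfig
from clipsplice.pipeline import run_pipeline

config = SimulationConfig(
    seed=42,
    n_genes=12,
    as_events=[("G0001", "alt3p", 0.7, 0.3), ("G0005", "ir", 0.1, 0.6)],
    de_genes=[("G0002", 4.0), ("G0003", 0.25)],
    planted_peaks=[("G0002", "3'UTR", 25, "TTA"), ("G0006", "intron", 25, "TTA")],
    event_junction_reads=300,
)
report = run_pipeline(config, "demo_out")
print("bound genes:     ", report["sets"]["bound"])
print("up-regulated:    ", report["sets"]["deg_up"])
print("down-regulated:  ", report["sets"]["deg_down"])
print("AS genes:        ", report["sets"]["as_genes"])
ov = report["pairwise"]["bound|deg_up"]
print("bound & up:      ", ov["members"], " hypergeometric P =", round(ov["hypergeom_p"], 4))
```

prints

```
bound genes:      ['G0002', 'G0006']
up-regulated:     ['G0002']
down-regulated:   ['G0003']
AS genes:         ['G0001', 'G0005']
bound & up:       ['G0002']  hypergeometric P = 0.1667
```

Every planted signal is recovered: the two genes with planted CLIP stacks
are called bound, the 4-fold and 0.25-fold genes are flagged up/down, and
both planted splicing events reach the high-confidence set — the events
table (`demo_out/splicing.tsv`) shows the alt3p event labelled `A3SS`
with estimated ratios 0.707 vs 0.299 (planted: 0.7 vs 0.3, pSAR 92%) and
the retention event labelled `IntronR`. The gene planted with both a
3'UTR peak and a fold change appears in the bound∩DEG overlap, mirroring
the bound-gene/DEG Venn analysis this workflow is built for. With a
12-gene universe that single-gene overlap is not significant (P = 0.17) —
enrichment needs realistic set sizes.

The same stages are available from the shell:

```sh
clipsplice simulate --config cfg.yaml --outdir sim
clipsplice peaks --gtf sim/annotation.gtf --ip sim/clip_ip.bed12 --out peaks.tsv
clipsplice express --gtf sim/annotation.gtf --reads-a ... --reads-b ... 
clipsplice splice --gtf sim/annotation.gtf --group-a ... --group-b ... --out splice.tsv
clipsplice motif --peaks-fasta peaks.fa --k 5 --out motifs.tsv
clipsplice integrate --peaks peaks.tsv --de express.de.tsv --splice splice.tsv --gtf sim/annotation.gtf --out report.json
clipsplice all --config cfg.yaml --outdir run --seed 1
```

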