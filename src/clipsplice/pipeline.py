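"""End-to-end run: simulate -> peaks -> express -> splice -> motif -> integrate.

Every stage writes its table under the output directory; the integrated
overlap report is returned and written as JSON. All randomness derives
from the config seed, and no timestamps are emitted, so two runs from the
same config are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__, clip_peaks, integration, motif_enrich, splicing
from .alignio import fetch_sequence, read_fasta
from .expression import build_count_matrix, differential_expression, fpkm_table
from .synthetic_data import SimulationConfig, generate_gene_models, simulate_clip, simulate_rnaseq


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    iterations: int = 500,
    alpha: float = 0.05,
    motif_k: int = 5,
    n_shuffles: int = 100,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, models, gtf, gt = generate_gene_models(config)
    (outdir / "genome.fa").write_text(fasta)
    (outdir / "annotation.gtf").write_text(gtf)
    (outdir / "ground_truth.json").write_text(gt.to_json())
    genome = read_fasta(fasta)

    # CLIP peaks
    ip, _ctrl = simulate_clip(models, config)
    peaks = clip_peaks.call_peaks_per_gene(
        ip, models, iterations=iterations, seed=config.seed, alpha=alpha
    )
    peak_rows = [
        {
            "chrom": pk.chrom,
            "start": pk.start,
            "end": pk.end,
            "name": f"{pk.gene_id}:peak{i + 1}",
            "score": pk.height,
            "strand": pk.strand,
            "p_emp": pk.p_emp,
            "significant": pk.significant,
            "region": pk.region,
        }
        for i, pk in enumerate(peaks)
    ]
    pd.DataFrame(peak_rows).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    bound = clip_peaks.target_genes(peaks)

    # motif enrichment on significant peak sequences
    sig_seqs = [
        fetch_sequence(genome, pk.chrom, pk.start, pk.end, pk.strand)
        for pk in peaks
        if pk.significant
    ]
    if sig_seqs:
        kstats = motif_enrich.enrich_kmers(
            sig_seqs, k=motif_k, n_shuffles=n_shuffles, seed=config.seed
        )
        pd.DataFrame([vars(s) for s in kstats]).to_csv(
            outdir / "motifs.tsv", sep="\t", index=False
        )

    # expression
    samples_a = {
        f"A{r}": simulate_rnaseq(models, config, gt, "A", r)
        for r in range(1, config.n_replicates + 1)
    }
    samples_b = {
        f"B{r}": simulate_rnaseq(models, config, gt, "B", r)
        for r in range(1, config.n_replicates + 1)
    }
    counts = build_count_matrix({**samples_a, **samples_b}, models)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    fpkm_table(counts, models).to_csv(outdir / "fpkm.tsv", sep="\t")
    de = differential_expression(counts, list(samples_a), list(samples_b), alpha=alpha)
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)

    # splicing
    events, sp_table = splicing.analyze_splicing(samples_a, samples_b, models, alpha=alpha)
    sp_table.to_csv(outdir / "splicing.tsv", sep="\t", index=False)
    event_genes = {
        ev.event_id: g
        for ev in events
        if (g := splicing.host_gene(ev, models)) is not None
    }

    universe = {g.gene_id for g in models}
    report = integration.build_report(
        bound,
        de,
        sp_table,
        event_genes,
        universe,
        metadata={
            "seed": config.seed,
            "iterations": iterations,
            "alpha": alpha,
            "version": __version__,
        },
    )
    (outdir / "report.json").write_text(integration.report_to_json(report))
    return report
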