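"""From-scratch property benchmarks for every pipeline stage.

Each function regenerates its own synthetic inputs at fixed problem sizes,
runs the relevant stage, and measures a recovery/calibration quantity
against the generator's ground truth or an independent oracle. They back
both the validation suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import clip_peaks, splicing
from .examples import classical_event_fixtures
from .expression import benjamini_hochberg, ddct, differential_expression, fpkm
from .integration import hypergeometric_overlap
from .motif_enrich import enrich_kmers
from .pipeline import run_pipeline
from .synthetic_data import SimulationConfig, generate_gene_models, simulate_clip, simulate_rnaseq


# ---------------------------------------------------------------------------
# CLIP peak calling


def peak_null_calibration(
    seed: int, n_genes: int = 200, iterations: int = 500, background_rate: float = 2.0
) -> float:
    """Fraction of background-only genes yielding >=1 significant peak."""
    cfg = SimulationConfig(
        seed=seed, n_genes=n_genes, clip_background_rate=background_rate
    )
    _fa, models, _gtf, _gt = generate_gene_models(cfg)
    ip, _ctrl = simulate_clip(models, cfg)
    peaks = clip_peaks.call_peaks_per_gene(
        ip, models, iterations=iterations, seed=seed
    )
    flagged = clip_peaks.target_genes(peaks)
    return len(flagged) / n_genes


def peak_recovery(
    seed: int,
    n_genes: int = 100,
    stack: int = 10,
    background_rate: float = 0.5,
    iterations: int = 500,
) -> float:
    """Fraction of genes whose planted read stack is called significant."""
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        clip_background_rate=background_rate,
        planted_peaks=[(f"G{i + 1:04d}", "CDS", stack, "TTA") for i in range(n_genes)],
    )
    _fa, models, _gtf, _gt = generate_gene_models(cfg)
    ip, _ctrl = simulate_clip(models, cfg)
    peaks = clip_peaks.call_peaks_per_gene(
        ip, models, iterations=iterations, seed=seed
    )
    recovered = clip_peaks.target_genes(peaks)
    return len(recovered & {g.gene_id for g in models}) / n_genes


def stack20_empirical_p(seed: int, mc_iterations: int = 10**5) -> dict:
    """Empirical P for a 20-read stack on a 1 kb gene, with an independent
    Monte-Carlo oracle for the null exceedance probability."""
    from .alignio import AlignedRead, GeneModel, Transcript

    gene = GeneModel(
        "g", "chr1", "+", 0, 1000, [Transcript("t", exons=[(0, 1000)])]
    )
    reads = [AlignedRead("chr1", "+", [(500, 510)]) for _ in range(20)]
    raw = clip_peaks.cluster_reads(reads)
    null = clip_peaks.permutation_null(gene, reads, iterations=500, seed=seed)
    (pk,) = clip_peaks.call_peaks(raw, null)
    # brute-force oracle: coverage maximum under uniform placement
    rng = np.random.default_rng(seed + 1)
    starts = rng.integers(0, 991, size=(mc_iterations, 20))
    events = np.concatenate([starts, starts + 10], axis=1)
    signs = np.concatenate(
        [np.ones((mc_iterations, 20), int), -np.ones((mc_iterations, 20), int)], axis=1
    )
    order = np.lexsort((signs, events), axis=1)
    depth = np.cumsum(np.take_along_axis(signs, order, axis=1), axis=1).max(axis=1)
    return {
        "p_emp": pk.p_emp,
        "mc_exceedance": float((depth >= 20).mean()),
        "mc_iterations": mc_iterations,
    }


def empirical_p_boundaries() -> dict:
    """The four forced add-one estimator values at 500 iterations."""
    mk = lambda heights: clip_peaks.PermutationNull("g", 500, np.array(heights))
    return {
        "all_null_ties": clip_peaks.empirical_p(1, mk([1] * 500)),
        "no_exceedance": clip_peaks.empirical_p(20, mk([1] * 500)),
        "24_exceedances": clip_peaks.empirical_p(10, mk([11] * 24 + [1] * 476)),
        "25_exceedances": clip_peaks.empirical_p(10, mk([11] * 25 + [1] * 475)),
    }


# ---------------------------------------------------------------------------
# splicing


def classifier_accuracy() -> float:
    """Exact-label accuracy over the ten constructed classical AS fixtures."""
    fixtures = classical_event_fixtures()
    hits = sum(
        splicing.classify_event(ev, models) == [label]
        for label, ev, models in fixtures
    )
    return hits / len(fixtures)


def splicing_recovery(seed: int, junction_reads: int = 500) -> dict:
    """Planted 0.7-vs-0.3 event: RASE flag and ratio accuracy."""
    cfg = SimulationConfig(
        seed=seed,
        n_genes=4,
        as_events=[("G0001", "alt3p", 0.7, 0.3)],
        event_junction_reads=junction_reads,
        n_replicates=3,
    )
    _fa, models, _gtf, gt = generate_gene_models(cfg)
    samples_a = {
        f"A{r}": simulate_rnaseq(models, cfg, gt, "A", r) for r in (1, 2, 3)
    }
    samples_b = {
        f"B{r}": simulate_rnaseq(models, cfg, gt, "B", r) for r in (1, 2, 3)
    }
    events, table = splicing.analyze_splicing(samples_a, samples_b, models)
    rec = next(iter(gt.true_as.values()))
    primary = set(rec["primary_introns"])
    target = next(
        ev
        for ev in events
        if ev.kind == "alt3p" and primary <= {j.intron for j in ev.junctions}
    )
    idx = [j.intron in primary for j in target.junctions].index(True)
    n_a = junction_reads * 3
    count_a = sum(target.counts[s][idx] for s in samples_a)
    count_b = sum(target.counts[s][idx] for s in samples_b)
    lo_a, hi_a = stats.binom.interval(0.99, n_a, rec["ratio_a"])
    lo_b, hi_b = stats.binom.interval(0.99, n_a, rec["ratio_b"])
    row = table.set_index("event_id").loc[target.event_id]
    return {
        "rase_flagged": bool(row["rase_flag"]),
        "ratio_a": count_a / n_a,
        "ratio_b": count_b / n_a,
        "ratio_a_in_ci": bool(lo_a <= count_a <= hi_a),
        "ratio_b_in_ci": bool(lo_b <= count_b <= hi_b),
        "n_per_group": n_a,
    }


def fisher_oracle_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by direct hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[ks == a][0]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_agreement(
    seed: int, full_margin: int = 20, n_sampled: int = 2000, sample_margin: int = 50
) -> dict:
    """Max |scipy Fisher - enumeration| over a complete small-margin grid
    plus random larger-margin tables."""
    max_diff = 0.0
    n_tables = 0
    for r1 in range(full_margin + 1):
        for a in range(r1 + 1):
            b = r1 - a
            for r2 in range(full_margin + 1):
                for c in range(r2 + 1):
                    d = r2 - c
                    if r1 == 0 and r2 == 0:
                        continue
                    _o, p = stats.fisher_exact([[a, b], [c, d]])
                    max_diff = max(max_diff, abs(p - fisher_oracle_two_sided(a, b, c, d)))
                    n_tables += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_sampled):
        r1, r2 = rng.integers(1, sample_margin + 1, size=2)
        a = int(rng.integers(0, r1 + 1))
        c = int(rng.integers(0, r2 + 1))
        b, d = int(r1 - a), int(r2 - c)
        _o, p = stats.fisher_exact([[a, b], [c, d]])
        max_diff = max(max_diff, abs(p - fisher_oracle_two_sided(a, b, c, d)))
        n_tables += 1
    return {"max_abs_diff": max_diff, "n_tables": n_tables}


def psar_examples() -> dict:
    """The two pSAR arithmetic cases at the 50% dominance cut-off."""
    from .alignio import AlignedRead, Junction
    from .splicing import ASEvent, compute_psar

    ev = ASEvent(
        "e", "chr1", "+", "alt3p",
        [Junction("chr1", "+", 100, 200), Junction("chr1", "+", 100, 250)],
    )
    junc = lambda n: [AlignedRead("chr1", "+", [(80, 100), (200, 220)])] * n
    cover = lambda n: [AlignedRead("chr1", "+", [(190, 240)])] * n
    retained = compute_psar(ev, {"s": junc(40) + cover(10)})
    excluded = compute_psar(ev, {"s": junc(10) + cover(30)})
    return {
        "psar_retained": retained,
        "psar_excluded": excluded,
        "retained_passes_cutoff": retained >= 50.0,
        "excluded_passes_cutoff": excluded >= 50.0,
    }


# ---------------------------------------------------------------------------
# differential expression


def _nb_counts(rng, n_genes, mean, dispersion, n_samples):
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size=(n_genes, n_samples))


def de_calibration(
    seed: int,
    n_null: int = 2000,
    n_planted: int = 50,
    mean: float = 300.0,
    dispersion: float = 0.05,
    fold: float = 4.0,
) -> dict:
    """Type-I error on all-null counts; sensitivity/FDP on planted 4-fold."""
    rng = np.random.default_rng(seed)
    cols = ["A0", "A1", "A2", "B0", "B1", "B2"]
    null = pd.DataFrame(_nb_counts(rng, n_null, mean, dispersion, 6), columns=cols)
    res0 = differential_expression(null, cols[:3], cols[3:])
    type1 = float((res0["p"] < 0.05).mean())

    counts = pd.DataFrame(
        _nb_counts(rng, 1000 + n_planted, mean, dispersion, 6), columns=cols
    )
    counts.iloc[:n_planted, 3:] = _nb_counts(
        rng, n_planted, mean * fold, dispersion, 3
    )
    res = differential_expression(counts, cols[:3], cols[3:])
    flagged = res["deg_flag"] != "ns"
    sens = float(flagged.iloc[:n_planted].mean())
    fdp = float(flagged.iloc[n_planted:].sum() / max(int(flagged.sum()), 1))

    clean = pd.DataFrame(
        {c: ([100, 500, 300] if c.startswith("A") else [400, 500, 300]) for c in cols},
        index=["g1", "g2", "g3"],
    )
    res_clean = differential_expression(clean, cols[:3], cols[3:])
    return {
        "type1_error": type1,
        "sensitivity": sens,
        "fdp": fdp,
        "log2fc_clean_fourfold": float(res_clean.loc["g1", "log2fc"]),
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# closed forms


def closed_forms() -> dict:
    bh = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    max_diff = 0.0
    for n_univ in (5, 8, 12):
        for sa in range(n_univ + 1):
            for sb in range(n_univ + 1):
                lo = max(0, sa + sb - n_univ)
                for k in range(lo, min(sa, sb) + 1):
                    num = sum(
                        math.comb(sa, i) * math.comb(n_univ - sa, sb - i)
                        for i in range(k, min(sa, sb) + 1)
                    )
                    brute = num / math.comb(n_univ, sb)
                    max_diff = max(
                        max_diff, abs(hypergeometric_overlap(sa, sb, k, n_univ) - brute)
                    )
    return {
        "fpkm_example": fpkm(10, 1000, 1e6),
        "ddct_unchanged": ddct(20, 15, 20, 15),
        "ddct_fourfold": ddct(20, 15, 22, 15),
        "ddct_quarter": ddct(22, 15, 20, 15),
        "bh_uniform_example": float(bh[0]),
        "hypergeom_example": hypergeometric_overlap(4, 5, 4, 10),
        "hypergeom_bruteforce_max_diff": max_diff,
    }


# ---------------------------------------------------------------------------
# motif enrichment


def motif_rates(seed: int, n_runs: int = 20, n_peaks: int = 30) -> dict:
    """Recovery rate of planted UUA-rich signal in the top 5 k-mers, and
    false-hit rate (any padj < 0.05) on matched null sequences."""
    root = np.random.SeedSequence(seed)
    recovered = false_hit = 0
    for child in root.spawn(n_runs):
        rng = np.random.Generator(np.random.PCG64(child))
        sub = int(rng.integers(0, 2**31 - 1))
        planted = []
        null = []
        for _ in range(n_peaks):
            bg = "".join(rng.choice(list("ACGU"), size=50))
            ins = int(rng.integers(0, 30))
            planted.append(bg[:ins] + "UUAUUAUUAUUA" + bg[ins:])
            null.append("".join(rng.choice(list("ACGU"), size=60)))
        top5 = [s.kmer for s in enrich_kmers(planted, k=5, n_shuffles=100, seed=sub)[:5]]
        recovered += any("UUA" in km for km in top5)
        null_stats = enrich_kmers(null, k=5, n_shuffles=100, seed=sub + 1)
        false_hit += any(s.padj < 0.05 for s in null_stats)
    return {
        "recovery_rate": recovered / n_runs,
        "null_false_hit_rate": false_hit / n_runs,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# end-to-end determinism


def pipeline_determinism(seed: int, workdir) -> dict:
    """Run the full pipeline twice from one config; compare output bytes."""
    from pathlib import Path

    workdir = Path(workdir)
    cfg = SimulationConfig(
        seed=seed,
        n_genes=10,
        as_events=[("G0001", "alt3p", 0.7, 0.3), ("G0005", "ir", 0.1, 0.6)],
        de_genes=[("G0002", 4.0), ("G0003", 0.25)],
        planted_peaks=[("G0002", "3'UTR", 25, "TTA"), ("G0006", "intron", 25, "TTA")],
        event_junction_reads=300,
    )
    run_pipeline(cfg, workdir / "run1", iterations=200)
    run_pipeline(cfg, workdir / "run2", iterations=200)
    files = [
        "report.json",
        "peaks.tsv",
        "de.tsv",
        "splicing.tsv",
        "counts.tsv",
        "genome.fa",
        "annotation.gtf",
        "ground_truth.json",
    ]
    identical = all(
        (workdir / "run1" / f).read_bytes() == (workdir / "run2" / f).read_bytes()
        for f in files
    )
    return {"identical": identical, "n_files": len(files)}
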