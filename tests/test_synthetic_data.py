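"""Generator contracts: determinism, planted signal, structural invariants."""

import numpy as np
import pytest
from scipy import stats

from clipsplice.alignio import merge_intervals, read_gtf
from clipsplice.synthetic_data import (
    ConfigError,
    SimulationConfig,
    generate_gene_models,
    simulate_all,
    simulate_clip,
    simulate_rnaseq,
)


class TestGeneModels:
    def test_single_gene_exon_count(self):
        cfg = SimulationConfig(seed=3, n_genes=1, exons_per_gene=(3, 3))
        _fa, models, gtf, _gt = generate_gene_models(cfg)
        assert len(models) == 1
        assert sum(1 for ln in gtf.splitlines() if "\texon\t" in ln) == 3

    def test_same_seed_identical_bytes(self, small_config):
        a = generate_gene_models(small_config)
        b = generate_gene_models(small_config)
        assert a[0] == b[0] and a[2] == b[2]  # FASTA and GTF text

    def test_genes_do_not_overlap(self, small_dataset):
        _fa, models, _gtf, _gt = small_dataset
        spans = sorted((g.start, g.end) for g in models)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_utr_cds_partition_covers_exons(self, small_dataset):
        _fa, models, _gtf, _gt = small_dataset
        for g in models:
            if g.biotype != "coding":
                continue
            for t in g.transcripts:
                parts = merge_intervals(t.utr5 + t.cds + t.utr3)
                assert parts == merge_intervals(t.exons)

    def test_gtf_round_trips_through_parser(self, small_dataset):
        _fa, models, gtf, _gt = small_dataset
        parsed = {g.gene_id: g for g in read_gtf(gtf)}
        assert set(parsed) == {g.gene_id for g in models}
        for g in models:
            got = parsed[g.gene_id]
            assert [t.exons for t in got.transcripts] == [t.exons for t in g.transcripts]

    def test_as_gene_gets_two_isoforms(self, small_dataset):
        _fa, models, _gtf, _gt = small_dataset
        byid = {g.gene_id: g for g in models}
        assert len(byid["G0001"].transcripts) == 2
        assert len(byid["G0002"].transcripts) == 1

    def test_ground_truth_references_emitted_entities(self, small_dataset):
        _fa, models, _gtf, gt = small_dataset
        ids = {g.gene_id for g in models}
        assert set(gt.true_de) <= ids
        assert {rec["gene"] for rec in gt.true_as.values()} <= ids
        assert {p["gene"] for p in gt.true_peaks} <= ids
        # nothing beyond what the config planted
        assert len(gt.true_as) == 3 and len(gt.true_de) == 2 and len(gt.true_peaks) == 2

    def test_invalid_ratio_rejected(self):
        cfg = SimulationConfig(as_events=[("G0001", "alt3p", 1.2, 0.5)])
        with pytest.raises(ConfigError, match="ratios"):
            cfg.validate()


class TestRnaseq:
    def test_determinism(self, small_config, small_dataset):
        _fa, models, _gtf, gt = small_dataset
        r1 = simulate_rnaseq(models, small_config, gt, "A", 1)
        r2 = simulate_rnaseq(models, small_config, gt, "A", 1)
        assert [r.blocks for r in r1] == [r.blocks for r in r2]

    def test_degenerate_ratio_one_uses_only_inclusion_junction(self):
        cfg = SimulationConfig(
            seed=5, n_genes=2, as_events=[("G0001", "alt3p", 1.0, 1.0)],
            event_junction_reads=200,
        )
        _fa, models, _gtf, gt = generate_gene_models(cfg)
        reads = simulate_rnaseq(models, cfg, gt, "A", 1)
        rec = next(iter(gt.true_as.values()))
        alt = set(rec["alt_introns"])
        used = {j.intron for r in reads for j in r.junctions()}
        assert not (used & alt)

    def test_inclusion_fraction_within_exact_binomial_99ci(self):
        """Planted ratio 0.7 at ~1000 junction reads lands in the exact
        binomial 99% interval around 0.7."""
        cfg = SimulationConfig(
            seed=9, n_genes=2, as_events=[("G0001", "alt3p", 0.7, 0.3)],
            event_junction_reads=1000,
        )
        _fa, models, _gtf, gt = generate_gene_models(cfg)
        reads = simulate_rnaseq(models, cfg, gt, "A", 1)
        rec = next(iter(gt.true_as.values()))
        primary = set(rec["primary_introns"])
        alt = set(rec["alt_introns"])
        n_inc = n_alt = 0
        for r in reads:
            for j in r.junctions():
                if j.intron in primary:
                    n_inc += 1
                elif j.intron in alt:
                    n_alt += 1
        assert n_inc + n_alt == 1000
        lo, hi = stats.binom.interval(0.99, 1000, 0.7)
        assert lo <= n_inc <= hi

    def test_planted_fold_change_within_nb_interval(self):
        """Mean count ratio for a 4-fold gene sits inside the NB sampling
        interval computed by direct simulation at the config dispersion."""
        cfg = SimulationConfig(
            seed=13, n_genes=2, de_genes=[("G0001", 4.0)], junction_depth=0.0,
            n_replicates=3,
        )
        _fa, models, _gtf, gt = generate_gene_models(cfg)

        def gene_counts(cond):
            out = []
            for rep in (1, 2, 3):
                reads = simulate_rnaseq(models, cfg, gt, cond, rep)
                byg = {g.gene_id: 0 for g in models}
                for r in reads:
                    for g in models:
                        if g.start <= r.start and r.end <= g.end:
                            byg[g.gene_id] += 1
                out.append(byg["G0001"])
            return np.array(out, dtype=float)

        ratio = gene_counts("B").mean() / gene_counts("A").mean()
        # independent NB oracle: distribution of the ratio of two 3-sample means
        rng = np.random.default_rng(0)
        n = 1 / cfg.nb_dispersion
        m = cfg.rnaseq_depth
        sims_a = rng.negative_binomial(n, n / (n + m), size=(20000, 3)).mean(axis=1)
        sims_b = rng.negative_binomial(n, n / (n + 4 * m), size=(20000, 3)).mean(axis=1)
        lo, hi = np.quantile(sims_b / sims_a, [0.005, 0.995])
        assert lo <= ratio <= hi


class TestClip:
    def test_planted_stack_overlaps_in_utr3(self, small_config, small_dataset):
        _fa, models, _gtf, gt = small_dataset
        ip, _ctrl = simulate_clip(models, small_config)
        peak = next(p for p in gt.true_peaks if p["region"] == "3'UTR")
        inside = [
            r for r in ip if r.start >= peak["start"] and r.end <= peak["end"]
        ]
        assert len(inside) >= 25  # the configured stack size

    def test_zero_background_no_peaks_empty_ip(self):
        cfg = SimulationConfig(seed=2, n_genes=3, clip_background_rate=0.0)
        _fa, models, _gtf, _gt = generate_gene_models(cfg)
        ip, ctrl = simulate_clip(models, cfg)
        assert ip == [] and ctrl == []

    def test_planted_motif_present_in_peak_sequence(self, small_dataset):
        from clipsplice.alignio import fetch_sequence, read_fasta

        fa, models, _gtf, gt = small_dataset
        genome = read_fasta(fa)
        byid = {g.gene_id: g for g in models}
        for p in gt.true_peaks:
            g = byid[p["gene"]]
            rna = fetch_sequence(genome, g.chrom, p["start"], p["end"], g.strand)
            assert "UUA" in rna

    def test_determinism(self, small_config, small_dataset):
        _fa, models, _gtf, _gt = small_dataset
        ip1, c1 = simulate_clip(models, small_config)
        ip2, c2 = simulate_clip(models, small_config)
        assert [r.blocks for r in ip1] == [r.blocks for r in ip2]
        assert [r.blocks for r in c1] == [r.blocks for r in c2]


def test_manifest_counts_match_emitted_reads(tmp_path, small_config):
    manifest = simulate_all(small_config, tmp_path)
    from clipsplice.alignio import read_bed12

    for fname, n in manifest["files"].items():
        assert len(read_bed12((tmp_path / fname).read_text())) == n
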