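"""Junction clustering, classical-type classification, RASE testing, pSAR."""

from collections import Counter

import numpy as np
import pytest
from scipy.stats import hypergeom

from clipsplice.alignio import AlignedRead, GeneModel, Junction, Transcript
from clipsplice.splicing import (
    ASEvent,
    classify_event,
    cluster_junctions,
    compute_psar,
    detect_intron_retention,
    differential_splicing,
    flag_known,
)


def J(s, e, strand="+"):
    return Junction("chr1", strand, s, e)


def gene_with_exons(exon_lists, strand="+", gene_id="g1", biotype="coding"):
    """Gene model with one transcript per exon list."""
    txs = [
        Transcript(f"{gene_id}.t{i + 1}", exons=sorted(exons))
        for i, exons in enumerate(exon_lists)
    ]
    start = min(t.exons[0][0] for t in txs)
    end = max(t.exons[-1][1] for t in txs)
    return GeneModel(gene_id, "chr1", strand, start, end, txs, biotype=biotype)


def make_event(junctions, counts=None, kind="alt3p"):
    ev = ASEvent("ev1", "chr1", junctions[0].strand, kind, list(junctions))
    if counts:
        ev.counts = counts
    return ev


class TestClusterJunctions:
    def test_shared_donor_is_alt3p_on_plus(self):
        counts = {"s1": Counter({J(10, 50): 20, J(10, 80): 15})}
        (ev,) = cluster_junctions(counts)
        assert ev.kind == "alt3p"
        assert len(ev.junctions) == 2

    def test_shared_acceptor_is_alt5p_on_plus(self):
        counts = {"s1": Counter({J(10, 80): 20, J(40, 80): 15})}
        (ev,) = cluster_junctions(counts)
        assert ev.kind == "alt5p"

    def test_strand_swaps_kind(self):
        counts = {"s1": Counter({J(10, 50, "-"): 20, J(10, 80, "-"): 15})}
        (ev,) = cluster_junctions(counts)
        assert ev.kind == "alt5p"

    def test_disjoint_junctions_make_no_event(self):
        counts = {"s1": Counter({J(10, 50): 20, J(60, 90): 15})}
        assert cluster_junctions(counts) == []

    def test_low_count_junctions_excluded(self):
        counts = {"s1": Counter({J(10, 50): 20, J(10, 80): 3})}
        assert cluster_junctions(counts) == []

    def test_per_sample_count_vectors_align(self):
        counts = {
            "s1": Counter({J(10, 50): 20, J(10, 80): 10}),
            "s2": Counter({J(10, 50): 5}),
        }
        (ev,) = cluster_junctions(counts)
        assert ev.counts["s1"] == [20, 10]
        assert ev.counts["s2"] == [5, 0]


class TestClassifier:
    """One constructed instance per classical AS type, labels must be exact."""

    def test_a3ss(self):
        models = [gene_with_exons([[(0, 100), (200, 300)], [(0, 100), (220, 300)]])]
        ev = make_event([J(100, 200), J(100, 220)])
        assert classify_event(ev, models) == ["A3SS"]

    def test_a5ss(self):
        models = [gene_with_exons([[(0, 100), (400, 500)], [(0, 80), (400, 500)]])]
        ev = make_event([J(100, 400), J(80, 400)], kind="alt5p")
        assert classify_event(ev, models) == ["A5SS"]

    def test_es_from_shared_donor_pair(self):
        models = [
            gene_with_exons(
                [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]
            )
        ]
        ev = make_event([J(100, 200), J(100, 400)])
        assert classify_event(ev, models) == ["ES"]

    def test_cassette_exon_three_junction_motif(self):
        models = [
            gene_with_exons(
                [[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]]
            )
        ]
        ev = make_event([J(100, 200), J(300, 400), J(100, 400)], kind="mixed")
        assert classify_event(ev, models) == ["cassetteExon"]

    def test_mxe_four_junction_motif(self):
        models = [
            gene_with_exons(
                [
                    [(0, 100), (200, 250), (450, 550)],
                    [(0, 100), (300, 350), (450, 550)],
                ]
            )
        ]
        ev = make_event(
            [J(100, 200), J(250, 450), J(100, 300), J(350, 450)], kind="mixed"
        )
        assert classify_event(ev, models) == ["MXE"]

    def test_5p_mxe_alternative_first_exons(self):
        models = [
            gene_with_exons(
                [[(0, 50), (200, 300)], [(100, 150), (200, 300)]]
            )
        ]
        ev = make_event([J(50, 200), J(150, 200)], kind="alt5p")
        assert classify_event(ev, models) == ["5pMXE"]

    def test_3p_mxe_alternative_last_exons(self):
        models = [
            gene_with_exons(
                [[(0, 100), (200, 250)], [(0, 100), (300, 350)]]
            )
        ]
        ev = make_event([J(100, 200), J(100, 300)])
        assert classify_event(ev, models) == ["3pMXE"]

    def test_intron_retention(self):
        models = [gene_with_exons([[(0, 100), (200, 300)]])]
        ev = make_event([J(100, 200)], kind="ir")
        assert classify_event(ev, models) == ["IntronR"]

    def test_a3ss_and_es_combination(self):
        models = [
            gene_with_exons(
                [
                    [(0, 100), (200, 300), (400, 500)],
                    [(0, 100), (220, 300), (400, 500)],
                    [(0, 100), (400, 500)],
                ]
            )
        ]
        ev = make_event([J(100, 200), J(100, 220), J(100, 400)])
        assert classify_event(ev, models) == ["A3SS&ES"]

    def test_a5ss_and_es_combination(self):
        models = [
            gene_with_exons(
                [
                    [(0, 100), (200, 300), (400, 500)],
                    [(0, 80), (200, 300), (400, 500)],
                    [(0, 100), (400, 500)],
                ]
            )
        ]
        ev = make_event([J(100, 400), J(80, 400), J(300, 400)], kind="mixed")
        assert classify_event(ev, models) == ["A5SS&ES"]

    def test_minus_strand_a3ss(self):
        # on - strand the variable genomic-left side is the acceptor side
        models = [
            gene_with_exons(
                [[(0, 100), (200, 300)], [(0, 80), (200, 300)]], strand="-"
            )
        ]
        ev = make_event([J(100, 200, "-"), J(80, 200, "-")], kind="alt3p")
        assert classify_event(ev, models) == ["A3SS"]

    def test_unmatched_cluster_is_complex(self):
        models = [gene_with_exons([[(0, 100), (200, 300)]])]
        ev = make_event([J(1000, 2000), J(3000, 4000)], kind="mixed")
        assert classify_event(ev, models) == ["complex"]


class TestFlagKnown:
    models = [gene_with_exons([[(0, 100), (200, 300), (400, 500)]])]

    def test_all_annotated_is_known(self):
        ev = make_event([J(100, 200), J(300, 400)])
        assert flag_known(ev, self.models)

    def test_one_novel_site_is_novel(self):
        ev = make_event([J(100, 200), J(300, 420)])
        assert not flag_known(ev, self.models)

    def test_empty_annotation_all_novel(self):
        ev = make_event([J(100, 200)])
        assert not flag_known(ev, [])


class TestDifferentialSplicing:
    def two_sample_event(self, a, b):
        counts = {
            "A1": [a[0] // 2, a[1] // 2],
            "A2": [a[0] - a[0] // 2, a[1] - a[1] // 2],
            "B1": [b[0] // 2, b[1] // 2],
            "B2": [b[0] - b[0] // 2, b[1] - b[1] // 2],
        }
        return make_event([J(10, 50), J(10, 80)], counts)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher P equals the sum of hypergeometric point
        probabilities <= that of the observed table."""
        ev = self.two_sample_event((90, 10), (50, 50))
        t = differential_splicing(ev, ["A1", "A2"], ["B1", "B2"])
        assert t.dratio == pytest.approx(0.4)
        # enumeration oracle on margins (100, 100, col1=140)
        n_total, row1, col1 = 200, 100, 140
        support = np.arange(max(0, col1 - 100), min(row1, col1) + 1)
        pmf = hypergeom.pmf(support, n_total, row1, col1)
        p_obs = pmf[support == 90][0]
        expected = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
        assert t.p == pytest.approx(expected, rel=1e-9)

    def test_balanced_table_not_flagged(self):
        ev = self.two_sample_event((50, 50), (50, 50))
        t = differential_splicing(ev, ["A1", "A2"], ["B1", "B2"])
        assert t.dratio == 0.0
        assert t.p == 1.0
        assert not t.sign_consistent

    def test_group_swap_negates_dratio_preserves_p(self):
        ev = self.two_sample_event((90, 10), (50, 50))
        fwd = differential_splicing(ev, ["A1", "A2"], ["B1", "B2"])
        rev = differential_splicing(ev, ["B1", "B2"], ["A1", "A2"])
        assert fwd.dratio == pytest.approx(-rev.dratio)
        assert fwd.p == pytest.approx(rev.p)

    def test_all_zero_event_skipped(self):
        ev = make_event([J(10, 50), J(10, 80)], {s: [0, 0] for s in ("A1", "A2", "B1", "B2")})
        assert differential_splicing(ev, ["A1", "A2"], ["B1", "B2"]) is None

    def test_per_sample_ratios_sum_to_one(self):
        ev = self.two_sample_event((90, 10), (50, 50))
        for vec in ev.counts.values():
            total = sum(vec)
            assert sum(c / total for c in vec) == pytest.approx(1.0)


class TestIntronRetention:
    def spanning(self, pos, strand="+"):
        return AlignedRead("chr1", strand, [(pos - 20, pos + 20)])

    def junc_read(self):
        return AlignedRead("chr1", "+", [(80, 100), (200, 220)])

    def test_no_spanning_reads_no_event(self):
        counts = {"s1": Counter({J(100, 200): 10})}
        reads = {"s1": [self.junc_read()] * 10}
        assert detect_intron_retention(counts, reads) == []

    def test_retention_ratio_half(self):
        counts = {"s1": Counter({J(100, 200): 10})}
        spans = [self.spanning(100)] * 5 + [self.spanning(200)] * 5
        reads = {"s1": [self.junc_read()] * 10 + spans}
        (ev,) = detect_intron_retention(counts, reads)
        nj, nspan = ev.counts["s1"]
        assert (nj, nspan) == (10, 10)
        assert nspan / (nspan + nj) == 0.5

    def test_single_boundary_coverage_is_not_retention(self):
        # exonic read-through over one splice site only: no ir event
        counts = {"s1": Counter({J(100, 200): 10})}
        reads = {"s1": [self.junc_read()] * 10 + [self.spanning(200)] * 8}
        assert detect_intron_retention(counts, reads) == []

    def test_condition_restricted_retention_detected(self):
        counts = {
            "A1": Counter({J(100, 200): 10}),
            "B1": Counter({J(100, 200): 10}),
        }
        reads = {
            "A1": [self.junc_read()] * 10,
            "B1": [self.junc_read()] * 10
            + [self.spanning(100)] * 4
            + [self.spanning(200)] * 4,
        }
        (ev,) = detect_intron_retention(counts, reads)
        assert ev.counts["A1"] == [10, 0]
        assert ev.counts["B1"] == [10, 8]


class TestPsar:
    def test_psar_80_percent(self):
        ev = make_event([J(100, 200), J(100, 250)])
        junc_reads = [AlignedRead("chr1", "+", [(80, 100), (200, 220)])] * 25
        junc_reads += [AlignedRead("chr1", "+", [(80, 100), (250, 270)])] * 15
        covering = [AlignedRead("chr1", "+", [(190, 240)])] * 10
        psar = compute_psar(ev, {"s1": junc_reads + covering})
        assert psar == pytest.approx(80.0)

    def test_psar_25_percent(self):
        ev = make_event([J(100, 200), J(100, 250)])
        junc_reads = [AlignedRead("chr1", "+", [(80, 100), (200, 220)])] * 10
        covering = [AlignedRead("chr1", "+", [(190, 240)])] * 30
        psar = compute_psar(ev, {"s1": junc_reads + covering})
        assert psar == pytest.approx(25.0)

    def test_all_supporting_is_100(self):
        ev = make_event([J(100, 200), J(100, 250)])
        junc_reads = [AlignedRead("chr1", "+", [(80, 100), (200, 220)])] * 7
        assert compute_psar(ev, {"s1": junc_reads}) == pytest.approx(100.0)

    def test_no_coverage_is_nan(self):
        ev = make_event([J(100, 200), J(100, 250)])
        assert np.isnan(compute_psar(ev, {"s1": []}))
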