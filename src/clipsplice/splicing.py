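"""Junction-cluster alternative-splicing detection, classification, and testing.

Splice junctions extracted from spliced reads are clustered into events by
shared splice sites: junctions sharing a donor form an alt3p cluster
(variable acceptor), junctions sharing an acceptor an alt5p cluster
(variable donor); components linked through both relations (cassette/MXE
patterns) are kind "mixed". Intron retention (ir) events pair a junction
with unspliced reads crossing its exon-intron boundaries.

Each event is mapped to classical AS types (A5SS, A3SS, ES, cassetteExon,
MXE, 5pMXE, 3pMXE, IntronR and the A3SS&ES / A5SS&ES combinations) by rules
over the annotation, tested between conditions with Fisher's exact test on
the two dominant junctions (BH-corrected, |delta ratio| >= 0.1, replicate
sign consistency), and filtered by pSAR — the cluster's junction-read share
of all reads covering its span; events below 50% are excluded as minor.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignio import AlignedRead, GeneModel, Junction
from .expression import benjamini_hochberg

MIN_JUNCTION_TOTAL = 10
MIN_SPANNING = 5
PSAR_MIN = 50.0
ALPHA = 0.05
MIN_DRATIO = 0.1

CLASSICAL_LABELS = (
    "A5SS",
    "A3SS",
    "ES",
    "cassetteExon",
    "MXE",
    "5pMXE",
    "3pMXE",
    "IntronR",
    "A3SS&ES",
    "A5SS&ES",
)


@dataclass
class ASEvent:
    event_id: str
    chrom: str
    strand: str
    kind: str  # alt5p / alt3p / mixed / ir
    junctions: list[Junction]
    # sample -> counts aligned with `junctions`; for ir events the vector is
    # [junction reads, boundary-spanning (retention) reads]
    counts: dict[str, list[int]] = field(default_factory=dict)
    classical: list[str] = field(default_factory=list)
    known: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(j.intron_start for j in self.junctions),
            max(j.intron_end for j in self.junctions),
        )


@dataclass
class SplicingTest:
    event_id: str
    ratio_a: float
    ratio_b: float
    dratio: float
    p: float
    padj: float = 1.0
    sign_consistent: bool = False
    rase_flag: bool = False
    psar: float = float("nan")


# ---------------------------------------------------------------------------
# junction counting & clustering


def junction_counts(reads: list[AlignedRead]) -> Counter:
    """Junction -> supporting read count, unique reads only."""
    counts: Counter = Counter()
    for r in reads:
        if not r.unique:
            continue
        for j in r.junctions():
            counts[j] += 1
    return counts


def cluster_junctions(
    counts_per_sample: dict[str, Counter],
    min_total: int = MIN_JUNCTION_TOTAL,
) -> list[ASEvent]:
    """Connected components of junctions sharing a donor or an acceptor.

    Junctions below ``min_total`` summed over samples are excluded before
    clustering; components with >= 2 junctions become events.
    """
    totals: Counter = Counter()
    for c in counts_per_sample.values():
        totals.update(c)
    juncs = sorted(
        (j for j, n in totals.items() if n >= min_total),
        key=lambda j: (j.chrom, j.intron_start, j.intron_end, j.strand),
    )
    parent = list(range(len(juncs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_site: dict[tuple, list[int]] = defaultdict(list)
    for i, j in enumerate(juncs):
        by_site[(j.chrom, j.strand, "s", j.intron_start)].append(i)
        by_site[(j.chrom, j.strand, "e", j.intron_end)].append(i)
    for members in by_site.values():
        for k in members[1:]:
            union(members[0], k)

    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(juncs)):
        comps[find(i)].append(i)

    events = []
    for members in comps.values():
        if len(members) < 2:
            continue
        js = [juncs[i] for i in sorted(members)]
        starts = {j.intron_start for j in js}
        ends = {j.intron_end for j in js}
        if len(starts) == 1 or len(ends) == 1:
            shared_genomic_start = len(starts) == 1
            # shared donor -> alt3p, shared acceptor -> alt5p, strand-aware
            if js[0].strand == "+":
                kind = "alt3p" if shared_genomic_start else "alt5p"
            else:
                kind = "alt5p" if shared_genomic_start else "alt3p"
        else:
            kind = "mixed"
        ev = ASEvent(
            event_id="",
            chrom=js[0].chrom,
            strand=js[0].strand,
            kind=kind,
            junctions=js,
        )
        for sample, c in counts_per_sample.items():
            ev.counts[sample] = [int(c.get(j, 0)) for j in js]
        events.append(ev)
    events.sort(key=lambda e: (e.chrom, e.span, e.kind))
    return events


def detect_intron_retention(
    counts_per_sample: dict[str, Counter],
    reads_per_sample: dict[str, list[AlignedRead]],
    min_spanning: int = MIN_SPANNING,
    min_total: int = MIN_JUNCTION_TOTAL,
) -> list[ASEvent]:
    """Emit ir events for junctions with unspliced boundary-spanning reads.

    A spanning read is a single-block read covering >= 1 bp on both sides
    of the intron's donor or acceptor boundary. An event is emitted when
    total spanning reads across samples reach ``min_spanning`` and both
    boundaries show at least one crossing read — genuine retention leaves
    unspliced coverage at both edges, whereas exonic reads running over a
    single alternative splice site only ever cross one.
    """
    totals: Counter = Counter()
    for c in counts_per_sample.values():
        totals.update(c)
    juncs = sorted(
        (j for j, n in totals.items() if n >= min_total),
        key=lambda j: (j.chrom, j.intron_start, j.intron_end, j.strand),
    )
    events = []
    for j in juncs:
        per_sample: dict[str, list[int]] = {}
        total_span = 0
        donor_hits = acceptor_hits = 0
        for sample, reads in reads_per_sample.items():
            n_span = 0
            for r in reads:
                if not r.unique or len(r.blocks) != 1:
                    continue
                if r.chrom != j.chrom or r.strand != j.strand:
                    continue
                bs, be = r.blocks[0]
                at_start = bs < j.intron_start < be
                at_end = bs < j.intron_end < be
                if at_start or at_end:
                    n_span += 1
                    donor_hits += at_start
                    acceptor_hits += at_end
            per_sample[sample] = [
                int(counts_per_sample.get(sample, Counter()).get(j, 0)),
                n_span,
            ]
            total_span += n_span
        if total_span >= min_spanning and donor_hits >= 1 and acceptor_hits >= 1:
            ev = ASEvent(
                event_id="",
                chrom=j.chrom,
                strand=j.strand,
                kind="ir",
                junctions=[j],
                counts=per_sample,
            )
            events.append(ev)
    return events


def assign_event_ids(events: list[ASEvent]) -> None:
    events.sort(key=lambda e: (e.chrom, e.span, e.kind))
    for i, ev in enumerate(events, start=1):
        ev.event_id = f"clu{ev.kind}{i:05d}"


# ---------------------------------------------------------------------------
# classification


def _annotated_exons(models: list[GeneModel], chrom: str, strand: str) -> set[tuple[int, int]]:
    return {
        iv
        for g in models
        if g.chrom == chrom and g.strand == strand
        for t in g.transcripts
        for iv in t.exons
    }


def _first_last_exons(
    models: list[GeneModel], chrom: str, strand: str
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Transcription-direction first and last exons of every transcript."""
    first, last = set(), set()
    for g in models:
        if g.chrom != chrom or g.strand != strand:
            continue
        for t in g.transcripts:
            if not t.exons:
                continue
            if strand == "+":
                first.add(t.exons[0])
                last.add(t.exons[-1])
            else:
                first.add(t.exons[-1])
                last.add(t.exons[0])
    return first, last


def _contained_exon(
    exons: set[tuple[int, int]], lo: int, hi: int
) -> tuple[int, int] | None:
    for s, e in sorted(exons):
        if lo <= s and e <= hi:
            return (s, e)
    return None


def classify_event(event: ASEvent, models: list[GeneModel]) -> list[str]:
    """Map a junction cluster to classical AS type labels.

    Pair rules: junctions sharing a genomic start with varying ends are a
    shift on the intron's 3' genomic side; a complete annotated exon between
    the two varying sites turns the shift into exon skipping. The
    three-junction cassette motif and the four-junction mutually-exclusive
    motif are matched first. Clusters matching nothing are "complex".
    """
    if event.kind == "ir":
        return ["IntronR"]
    chrom, strand = event.chrom, event.strand
    exons = _annotated_exons(models, chrom, strand)
    first_ex, last_ex = _first_last_exons(models, chrom, strand)
    introns = {j.intron for j in event.junctions}

    # cassette: inclusion pair around a complete exon + the skip junction
    for x, y in sorted(introns):
        ex = _contained_exon(exons, x, y)
        while ex is not None:
            s, e = ex
            if (x, s) in introns and (e, y) in introns:
                return ["cassetteExon"]
            # try further candidate exons inside (x, y)
            nxt = _contained_exon({iv for iv in exons if iv > ex}, x, y)
            ex = nxt

    # mutually exclusive exons: (x,s1),(e1,y),(x,s2),(e2,y), no bridge/skip
    sorted_in = sorted(introns)
    for x, s1 in sorted_in:
        for e1, y in sorted_in:
            if e1 <= s1 or y <= e1:
                continue
            if (s1, e1) not in exons:
                continue
            for x2, s2 in sorted_in:
                if x2 != x or s2 <= e1:
                    continue
                for e2, y2 in sorted_in:
                    if y2 != y or e2 <= s2:
                        continue
                    if (s2, e2) not in exons:
                        continue
                    if (x, y) in introns or (e1, s2) in introns:
                        continue
                    return ["MXE"]

    labels: set[str] = set()
    by_start: dict[int, list[tuple[int, int]]] = defaultdict(list)
    by_end: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for iv in introns:
        by_start[iv[0]].append(iv)
        by_end[iv[1]].append(iv)

    # right-variable pairs: shared genomic start, ends a1 < a2
    for _x, group in by_start.items():
        if len(group) < 2:
            continue
        ends = sorted(iv[1] for iv in group)
        for a1, a2 in zip(ends, ends[1:]):
            contained = _contained_exon(exons, a1, a2)
            if contained is not None:
                e1 = next((iv for iv in sorted(exons) if iv[0] == a1), None)
                e2 = next((iv for iv in sorted(exons) if iv[0] == a2), None)
                terminal = last_ex if strand == "+" else first_ex
                if e1 in terminal and e2 in terminal and e1 is not None and e2 is not None:
                    labels.add("3pMXE" if strand == "+" else "5pMXE")
                else:
                    labels.add("ES")
            else:
                labels.add("A3SS" if strand == "+" else "A5SS")

    # left-variable pairs: shared genomic end, starts d1 < d2
    for _y, group in by_end.items():
        if len(group) < 2:
            continue
        starts = sorted(iv[0] for iv in group)
        for d1, d2 in zip(starts, starts[1:]):
            contained = _contained_exon(exons, d1, d2)
            if contained is not None:
                e1 = next((iv for iv in sorted(exons) if iv[1] == d1), None)
                e2 = next((iv for iv in sorted(exons) if iv[1] == d2), None)
                terminal = first_ex if strand == "+" else last_ex
                if e1 in terminal and e2 in terminal and e1 is not None and e2 is not None:
                    labels.add("5pMXE" if strand == "+" else "3pMXE")
                else:
                    labels.add("ES")
            else:
                labels.add("A5SS" if strand == "+" else "A3SS")

    if {"A3SS", "ES"} <= labels:
        labels -= {"A3SS", "ES"}
        labels.add("A3SS&ES")
    if {"A5SS", "ES"} <= labels:
        labels -= {"A5SS", "ES"}
        labels.add("A5SS&ES")
    if not labels:
        return ["complex"]
    return sorted(labels)


def host_gene(event: ASEvent, models: list[GeneModel]) -> str | None:
    """Gene whose span contains the event's shared-site region.

    Events spanning multiple genes are assigned to the gene containing
    the cluster span start (the shared site for alt3p clusters) or,
    failing that, the span end.
    """
    s, e = event.span
    for point in (s, e):
        for g in models:
            if (
                g.chrom == event.chrom
                and g.strand == event.strand
                and g.start <= point < g.end
            ):
                return g.gene_id
    return None


def flag_known(event: ASEvent, models: list[GeneModel]) -> bool:
    """Known iff every junction matches an annotated intron exactly."""
    annotated: set[tuple[int, int]] = set()
    for g in models:
        if g.chrom != event.chrom or g.strand != event.strand:
            continue
        annotated |= g.introns()
    return all(j.intron in annotated for j in event.junctions)


# ---------------------------------------------------------------------------
# differential test, pSAR


def differential_splicing(
    event: ASEvent,
    samples_a: list[str],
    samples_b: list[str],
) -> SplicingTest | None:
    """Fisher exact test on the two dominant junctions, pooled per group.

    Returns None for degenerate (all-zero) events. ``padj``/``rase_flag``
    are filled in later, across all events.
    """
    mat = np.array(
        [event.counts[s] for s in samples_a + samples_b], dtype=float
    )
    totals = mat.sum(axis=0)
    if totals.sum() == 0:
        return None
    top2 = np.argsort(-totals, kind="mergesort")[:2]
    if len(top2) < 2:
        return None
    a = mat[: len(samples_a)][:, top2]
    b = mat[len(samples_a) :][:, top2]
    sa, sb = a.sum(axis=0), b.sum(axis=0)
    if sa.sum() == 0 or sb.sum() == 0:
        return None
    table = np.array([[sa[0], sa[1]], [sb[0], sb[1]]])
    _odds, p = stats.fisher_exact(table, alternative="two-sided")
    ratio_a = sa[0] / sa.sum()
    ratio_b = sb[0] / sb.sum()
    dratio = ratio_a - ratio_b

    # replicate sign consistency: every A-sample ratio on one side of every B's
    ra = [row[0] / row.sum() for row in a if row.sum() > 0]
    rb = [row[0] / row.sum() for row in b if row.sum() > 0]
    if not ra or not rb:
        consistent = False
    elif dratio > 0:
        consistent = min(ra) > max(rb)
    elif dratio < 0:
        consistent = max(ra) < min(rb)
    else:
        consistent = False
    return SplicingTest(
        event_id=event.event_id,
        ratio_a=float(ratio_a),
        ratio_b=float(ratio_b),
        dratio=float(dratio),
        p=float(p),
        sign_consistent=consistent,
    )


def compute_psar(event: ASEvent, reads_per_sample: dict[str, list[AlignedRead]]) -> float:
    """pSAR: the event's read share of all reads covering the cluster span, in %.

    Per sample, supporting reads carry one of the cluster's junctions (for
    ir events, unspliced reads crossing the intron's boundaries also count
    as event evidence); non-supporting reads overlap the span with some
    block but support none of the junctions. The percentage is averaged
    over samples with a non-zero denominator; NaN when no sample has
    coverage.
    """
    span_s, span_e = event.span
    cluster = {j.intron for j in event.junctions}
    vals = []
    for reads in reads_per_sample.values():
        supp = non = 0
        for r in reads:
            if not r.unique or r.chrom != event.chrom or r.strand != event.strand:
                continue
            if any(j.intron in cluster for j in r.junctions()):
                supp += 1
                continue
            if event.kind == "ir" and len(r.blocks) == 1:
                bs, be = r.blocks[0]
                if bs < span_s < be or bs < span_e < be:
                    supp += 1
                    continue
            if any(bs < span_e and be > span_s for bs, be in r.blocks):
                non += 1
        if supp + non > 0:
            vals.append(100.0 * supp / (supp + non))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# pipeline


def analyze_splicing(
    samples_a: dict[str, list[AlignedRead]],
    samples_b: dict[str, list[AlignedRead]],
    models: list[GeneModel],
    min_junction_total: int = MIN_JUNCTION_TOTAL,
    min_spanning: int = MIN_SPANNING,
    psar_min: float = PSAR_MIN,
    alpha: float = ALPHA,
    min_dratio: float = MIN_DRATIO,
) -> tuple[list[ASEvent], pd.DataFrame]:
    """Full splicing analysis: cluster, classify, test, pSAR-filter.

    Returns the events plus a per-event results table; ``high_confidence``
    marks RASEs passing the pSAR >= ``psar_min`` dominance filter.
    """
    all_samples = {**samples_a, **samples_b}
    counts = {name: junction_counts(reads) for name, reads in all_samples.items()}
    events = cluster_junctions(counts, min_total=min_junction_total)
    events += detect_intron_retention(
        counts, all_samples, min_spanning=min_spanning, min_total=min_junction_total
    )
    assign_event_ids(events)
    rows = []
    tests: list[SplicingTest] = []
    for ev in events:
        ev.classical = classify_event(ev, models)
        ev.known = flag_known(ev, models)
        t = differential_splicing(ev, list(samples_a), list(samples_b))
        if t is None:
            continue
        t.psar = compute_psar(ev, all_samples)
        tests.append(t)
    if tests:
        padj = benjamini_hochberg([t.p for t in tests])
        for t, q in zip(tests, padj):
            t.padj = float(q)
            t.rase_flag = (
                t.padj < alpha and abs(t.dratio) >= min_dratio and t.sign_consistent
            )
    by_id = {ev.event_id: ev for ev in events}
    for t in tests:
        ev = by_id[t.event_id]
        rows.append(
            {
                "event_id": t.event_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "span_start": ev.span[0],
                "span_end": ev.span[1],
                "kind": ev.kind,
                "classical": "&".join(ev.classical) if len(ev.classical) > 1 else ev.classical[0],
                "known": ev.known,
                "ratio_a": t.ratio_a,
                "ratio_b": t.ratio_b,
                "dratio": t.dratio,
                "p": t.p,
                "padj": t.padj,
                "psar": t.psar,
                "rase_flag": t.rase_flag,
                "high_confidence": bool(
                    t.rase_flag and not np.isnan(t.psar) and t.psar >= psar_min
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "chrom",
            "strand",
            "span_start",
            "span_end",
            "kind",
            "classical",
            "known",
            "ratio_a",
            "ratio_b",
            "dratio",
            "p",
            "padj",
            "psar",
            "rase_flag",
            "high_confidence",
        ],
    )
    return events, table
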