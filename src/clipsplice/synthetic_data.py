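"""Synthetic genomes, gene models, and RNA-seq/CLIP read sets with planted signal.

The generator emulates the statistical structure of a joint RNA-seq +
CLIP-seq study: multi-exon gene models on a random genome, junction reads
at configurable inclusion ratios per condition (planted alternative-splicing
events), negative-binomially dispersed gene counts with planted fold
changes, and a uniform CLIP background with planted read stacks whose
genomic sequence carries a configurable (e.g. UUA-rich) motif.

Reads are emitted pre-aligned as BED12 blocks, one single-end record per
fragment. Per gene and sample two read classes are produced:

* exon-body reads — single-block reads inside exons, NB-dispersed around
  ``rnaseq_depth`` x fold change; these drive gene counting and DE;
* junction reads — two-block reads spanning each annotated intron
  (Poisson around ``junction_depth``); at a planted AS event each of the
  ``event_junction_reads`` reads picks the primary variant with exact
  probability ``ratio``, so planted inclusion fractions are exactly
  binomial.

Everything is deterministic given (config, seed): one root seed, with
per-generator child streams derived via fixed spawn keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignio import (
    AlignedRead,
    GeneModel,
    Transcript,
    write_bed12,
    write_fasta,
    write_gtf,
)

AS_KINDS = ("alt5p", "alt3p", "es", "ir")
PEAK_REGIONS = ("5'UTR", "CDS", "3'UTR", "noncoding_exon", "intron")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (200, 600)
    utr_len: tuple[int, int] = (60, 120)
    intergenic_gap: tuple[int, int] = (300, 800)
    rnaseq_depth: float = 300.0  # mean exon-body reads per gene
    junction_depth: float = 30.0  # mean junction reads per annotated intron
    event_junction_reads: int = 200  # junction reads per planted AS event/sample
    n_replicates: int = 3
    read_len: int = 100
    nb_dispersion: float = 0.05
    # (gene_id, kind in AS_KINDS, ratio_condition_A, ratio_condition_B)
    as_events: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (gene_id, fold_change B vs A)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    # CLIP
    clip_background_rate: float = 2.0  # reads per kb of gene span
    clip_read_len: int = 30
    peak_width: int = 50
    # (gene_id, region label in PEAK_REGIONS, stack size, motif string DNA/RNA)
    planted_peaks: list[tuple[str, str, int, str]] = field(default_factory=list)

    def validate(self) -> None:
        for lo, hi in (
            self.exons_per_gene,
            self.exon_len,
            self.intron_len,
            self.utr_len,
            self.intergenic_gap,
        ):
            if lo <= 0 or hi < lo:
                raise ConfigError(f"invalid range ({lo}, {hi})")
        for gid, kind, ra, rb in self.as_events:
            if kind not in AS_KINDS:
                raise ConfigError(f"unknown AS kind {kind!r} for {gid}")
            if not (0.0 <= ra <= 1.0 and 0.0 <= rb <= 1.0):
                raise ConfigError(f"AS ratios for {gid} must lie in [0,1]")
        for gid, region, stack, _motif in self.planted_peaks:
            if region not in PEAK_REGIONS:
                raise ConfigError(f"unknown peak region {region!r} for {gid}")
            if stack < 1:
                raise ConfigError("peak stack size must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted signal: the answer key for every downstream stage."""

    true_de: dict[str, float] = field(default_factory=dict)  # gene -> log2FC
    # event_id -> {gene, kind, ratio_a, ratio_b, primary_introns, alt_introns}
    true_as: dict[str, dict] = field(default_factory=dict)
    # list of {gene, start, end, region, motif}
    true_peaks: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        gt = cls(true_de=d["true_de"], true_as=d["true_as"], true_peaks=d["true_peaks"])
        for rec in gt.true_as.values():
            rec["primary_introns"] = [tuple(iv) for iv in rec["primary_introns"]]
            rec["alt_introns"] = [tuple(iv) for iv in rec["alt_introns"]]
        return gt


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(stream,)))
    )


def _rnaseq_stream(condition: str, replicate: int) -> int:
    cond = {"A": 0, "B": 1}[condition]
    return 10 + cond * 64 + replicate


_MOTIF_TR = str.maketrans("Uu", "Tt")
_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# gene models + genome


def _split_transcript_prefix(
    exons: list[tuple[int, int]], n: int, from_left: bool
) -> list[tuple[int, int]]:
    """Take the first n transcript bases from the genomic-left (or right) end."""
    out = []
    seq = exons if from_left else [(s, e) for s, e in reversed(exons)]
    for s, e in seq:
        if n <= 0:
            break
        take = min(n, e - s)
        out.append((s, s + take) if from_left else (e - take, e))
        n -= take
    return sorted(out)


def _annotate_cds_utr(tx: Transcript, strand: str, utr5: int, utr3: int) -> None:
    """Partition the exon union into 5'UTR / CDS / 3'UTR in transcription order."""
    total = sum(e - s for s, e in tx.exons)
    utr5 = min(utr5, max(total - 1, 0))
    utr3 = min(utr3, max(total - utr5 - 1, 0))
    left = utr5 if strand == "+" else utr3
    right = utr3 if strand == "+" else utr5
    left_ivs = _split_transcript_prefix(tx.exons, left, from_left=True)
    right_ivs = _split_transcript_prefix(tx.exons, right, from_left=False)
    tx.utr5 = left_ivs if strand == "+" else right_ivs
    tx.utr3 = right_ivs if strand == "+" else left_ivs
    taken = sorted(left_ivs + right_ivs)
    cds = []
    for s, e in tx.exons:
        cur = s
        for ts, te in taken:
            if te <= s or ts >= e:
                continue
            if ts > cur:
                cds.append((cur, ts))
            cur = max(cur, te)
        if cur < e:
            cds.append((cur, e))
    tx.cds = cds


def _plant_as_isoform(gene: GeneModel, kind: str, rng: np.random.Generator) -> dict:
    """Add the minimal second isoform realising a planted AS event.

    Returns the event record skeleton with primary/alternative intron lists.
    """
    t1 = gene.transcripts[0]
    if len(t1.exons) < 3:
        raise ConfigError(
            f"gene {gene.gene_id} needs >=3 exons to host a planted {kind} event"
        )
    exons = list(t1.exons)
    t2 = Transcript(transcript_id=f"{gene.gene_id}.t2")
    introns = t1.introns()
    if kind == "alt3p":
        # shared donor, shifted acceptor on intron 0 (+ strand layout)
        d, a = introns[0]
        shift = int(min(30, (exons[1][1] - exons[1][0]) // 3))
        t2.exons = [exons[0], (exons[1][0] + shift, exons[1][1])] + exons[2:]
        primary, alt = [(d, a)], [(d, a + shift)]
    elif kind == "alt5p":
        d, a = introns[0]
        shift = int(min(30, (exons[0][1] - exons[0][0]) // 3))
        t2.exons = [(exons[0][0], exons[0][1] - shift)] + exons[1:]
        primary, alt = [(d, a)], [(d - shift, a)]
    elif kind == "es":
        # isoform 2 skips the second exon
        t2.exons = [exons[0]] + exons[2:]
        primary = [introns[0], introns[1]]
        alt = [(exons[0][1], exons[2][0])]
    elif kind == "ir":
        # isoform 2 retains intron 0
        t2.exons = [(exons[0][0], exons[1][1])] + exons[2:]
        primary, alt = [introns[0]], []  # alt variant = unspliced spanning reads
    else:  # pragma: no cover
        raise ConfigError(f"unknown AS kind {kind!r}")
    if gene.biotype == "coding":
        _annotate_cds_utr(t2, gene.strand, len(t1_utr(t1, "5")), len(t1_utr(t1, "3")))
    gene.transcripts.append(t2)
    return {
        "gene": gene.gene_id,
        "kind": kind,
        "primary_introns": primary,
        "alt_introns": alt,
    }


def t1_utr(tx: Transcript, which: str) -> range:
    ivs = tx.utr5 if which == "5" else tx.utr3
    return range(sum(e - s for s, e in ivs))


def generate_gene_models(
    config: SimulationConfig,
) -> tuple[str, list[GeneModel], str, GroundTruth]:
    """Build a random genome, non-overlapping gene models, and the GTF.

    Planted CLIP-peak motifs are written into the genome here so the
    peak intervals genuinely carry the motif sequence; the intervals are
    recorded on the gene models and in the ground truth.
    """
    config.validate()
    rng = _child_rng(config.seed, 0)
    as_by_gene = {gid: kind for gid, kind, _a, _b in config.as_events}
    noncoding = {
        gid for gid, region, _s, _m in config.planted_peaks if region == "noncoding_exon"
    }
    gt = GroundTruth()

    chrom = "chr1"
    seq_parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    bases = np.array(list("ACGT"))

    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        seq_parts.append("".join(bases[rng.integers(0, 4, gap)]))
        pos += gap
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        if gid in as_by_gene:
            n_ex = max(n_ex, 3)
        strand = "+" if gid in as_by_gene else ("+" if rng.random() < 0.5 else "-")
        exons = []
        cur = pos
        for j in range(n_ex):
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append((cur, cur + elen))
            cur += elen
            if j < n_ex - 1:
                cur += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        glen = cur - pos
        seq_parts.append("".join(bases[rng.integers(0, 4, glen)]))
        tx = Transcript(transcript_id=f"{gid}.t1", exons=exons)
        gene = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            start=pos,
            end=cur,
            transcripts=[tx],
            biotype="noncoding" if gid in noncoding else "coding",
        )
        if gene.biotype == "coding":
            u5 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
            u3 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
            _annotate_cds_utr(tx, strand, u5, u3)
        if gid in as_by_gene:
            rec = _plant_as_isoform(gene, as_by_gene[gid], rng)
            gid_kind = as_by_gene[gid]
            eid = f"clu{gid_kind}{len(gt.true_as) + 1:05d}"
            ra, rb = next(
                (a, b) for g, _k, a, b in config.as_events if g == gid
            )
            rec.update(ratio_a=ra, ratio_b=rb)
            gt.true_as[eid] = rec
        models.append(gene)
        pos = cur

    genome = list("".join(seq_parts))
    by_id = {g.gene_id: g for g in models}

    # embed planted CLIP-peak motifs into the genome
    for gid, region, stack, motif in config.planted_peaks:
        if gid not in by_id:
            raise ConfigError(f"planted peak references unknown gene {gid!r}")
        gene = by_id[gid]
        iv = _pick_region_interval(gene, region, config.peak_width, rng)
        if iv is None:
            raise ConfigError(f"gene {gid} has no {region} wide enough for a peak")
        s, e = iv
        dna = motif.translate(_MOTIF_TR).upper()
        fill = (dna * ((e - s) // len(dna) + 1))[: e - s]
        if gene.strand == "-":
            fill = _revcomp(fill)
        genome[s:e] = list(fill)
        gene.planted_peaks.append((s, e, region, motif))
        gt.true_peaks.append(
            {"gene": gid, "start": s, "end": e, "region": region, "motif": motif}
        )

    for gid, fc in config.de_genes:
        if gid not in by_id:
            raise ConfigError(f"DE list references unknown gene {gid!r}")
        gt.true_de[gid] = float(np.log2(fc))

    genome_s = "".join(genome)
    fasta = write_fasta({chrom: genome_s})
    gtf = write_gtf(models)
    return fasta, models, gtf, gt


def _pick_region_interval(
    gene: GeneModel, region: str, width: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    t = gene.transcripts[0]
    if region == "3'UTR":
        cands = t.utr3
    elif region == "5'UTR":
        cands = t.utr5
    elif region == "CDS":
        cands = t.cds
    elif region == "noncoding_exon":
        cands = t.exons if gene.biotype == "noncoding" else []
    elif region == "intron":
        cands = t.introns()
    else:
        raise ConfigError(f"unknown region {region!r}")
    cands = [(s, e) for s, e in cands if e - s >= width]
    if not cands:
        return None
    s, e = cands[int(rng.integers(0, len(cands)))]
    off = int(rng.integers(0, e - s - width + 1))
    return (s + off, s + off + width)


# ---------------------------------------------------------------------------
# RNA-seq reads


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _body_reads(
    gene: GeneModel, n: int, read_len: int, rng: np.random.Generator
) -> list[AlignedRead]:
    exons = gene.transcripts[0].exons
    lens = np.array([e - s for s, e in exons], dtype=float)
    probs = lens / lens.sum()
    picks = rng.choice(len(exons), size=n, p=probs)
    reads = []
    for k in picks:
        s, e = exons[k]
        rl = min(read_len, e - s)
        start = int(rng.integers(s, e - rl + 1))
        reads.append(AlignedRead(gene.chrom, gene.strand, [(start, start + rl)]))
    return reads


def _junction_read(
    chrom: str,
    strand: str,
    intron: tuple[int, int],
    read_len: int,
    rng: np.random.Generator,
    max_left: int,
    max_right: int,
) -> AlignedRead:
    anchor_min = 8
    lo = max(anchor_min, read_len - max_right)
    hi = min(read_len - anchor_min, max_left)
    left = int(rng.integers(lo, hi + 1)) if hi > lo else max(anchor_min, min(lo, hi))
    right = read_len - left
    d, a = intron
    return AlignedRead(chrom, strand, [(d - left, d), (a, a + right)])


def _flank_lengths(
    gene: GeneModel, intron: tuple[int, int]
) -> tuple[int, int]:
    """Longest exon run ending at intron start / starting at intron end."""
    left = right = 30
    for t in gene.transcripts:
        for s, e in t.exons:
            if e == intron[0]:
                left = max(left, e - s)
            if s == intron[1]:
                right = max(right, e - s)
    return left, right


def _spanning_read(
    gene: GeneModel, boundary: int, read_len: int, rng: np.random.Generator
) -> AlignedRead:
    # unspliced read crossing an exon-intron boundary (>=1bp each side)
    off = int(rng.integers(5, read_len - 5))
    s = boundary - off
    return AlignedRead(gene.chrom, gene.strand, [(s, s + read_len)])


def simulate_rnaseq(
    models: list[GeneModel],
    config: SimulationConfig,
    gt: GroundTruth,
    condition: str,
    replicate: int,
) -> list[AlignedRead]:
    """One sample's RNA-seq reads (BED12-ready), with planted signal.

    ``condition`` is "A" or "B"; fold changes in ``config.de_genes`` apply
    to condition B.
    """
    if condition not in ("A", "B"):
        raise ConfigError(f"condition must be 'A' or 'B', got {condition!r}")
    rng = _child_rng(config.seed, _rnaseq_stream(condition, replicate))
    fc = dict(config.de_genes)
    events_by_gene: dict[str, list[tuple[str, dict]]] = {}
    for eid, rec in gt.true_as.items():
        events_by_gene.setdefault(rec["gene"], []).append((eid, rec))

    reads: list[AlignedRead] = []
    for gene in models:
        mult = fc.get(gene.gene_id, 1.0) if condition == "B" else 1.0
        n_body = _nb_count(rng, config.rnaseq_depth * mult, config.nb_dispersion)
        reads.extend(_body_reads(gene, n_body, config.read_len, rng))

        event_introns = set()
        for _eid, rec in events_by_gene.get(gene.gene_id, []):
            event_introns.update(rec["primary_introns"])
            event_introns.update(rec["alt_introns"])

        # constitutive junction reads over the primary isoform's introns
        for intron in gene.transcripts[0].introns():
            if intron in event_introns:
                continue
            nj = int(rng.poisson(config.junction_depth * mult))
            ml, mr = _flank_lengths(gene, intron)
            for _ in range(nj):
                reads.append(
                    _junction_read(
                        gene.chrom, gene.strand, intron, config.read_len, rng, ml, mr
                    )
                )

        # planted event reads: exact Bernoulli(ratio) variant choice
        for _eid, rec in events_by_gene.get(gene.gene_id, []):
            r = rec["ratio_a"] if condition == "A" else rec["ratio_b"]
            for _ in range(config.event_junction_reads):
                use_primary = rng.random() < r
                if rec["kind"] == "ir":
                    if use_primary:
                        # retention: unspliced read over the donor or the
                        # acceptor boundary, alternating so both edges of
                        # the retained intron carry coverage
                        boundary = rec["primary_introns"][0][
                            int(rng.integers(0, 2))
                        ]
                        reads.append(
                            _spanning_read(gene, boundary, config.read_len, rng)
                        )
                    else:
                        intron = rec["primary_introns"][0]
                        ml, mr = _flank_lengths(gene, intron)
                        reads.append(
                            _junction_read(
                                gene.chrom,
                                gene.strand,
                                intron,
                                config.read_len,
                                rng,
                                ml,
                                mr,
                            )
                        )
                else:
                    pool = rec["primary_introns"] if use_primary else rec["alt_introns"]
                    intron = pool[int(rng.integers(0, len(pool)))]
                    ml, mr = _flank_lengths(gene, intron)
                    reads.append(
                        _junction_read(
                            gene.chrom, gene.strand, intron, config.read_len, rng, ml, mr
                        )
                    )
    for i, r in enumerate(reads):
        r.name = f"rna_{condition}{replicate}_{i}"
    return reads


# ---------------------------------------------------------------------------
# CLIP reads


def simulate_clip(
    models: list[GeneModel], config: SimulationConfig
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """IP and control CLIP read sets.

    Background reads are placed uniformly over each gene span at
    ``clip_background_rate`` reads/kb (Poisson); the IP library
    additionally carries the planted read stacks.
    """
    rng = _child_rng(config.seed, 1)

    def background(tag: str) -> list[AlignedRead]:
        out = []
        for gene in models:
            span = gene.end - gene.start
            lam = config.clip_background_rate * span / 1000.0
            n = int(rng.poisson(lam)) if lam > 0 else 0
            rl = min(config.clip_read_len, span)
            for _ in range(n):
                s = int(rng.integers(gene.start, gene.end - rl + 1))
                out.append(AlignedRead(gene.chrom, gene.strand, [(s, s + rl)]))
        return out

    ip = background("ip")
    for gene in models:
        for s, e, region, _motif in gene.planted_peaks:
            stack = next(
                st
                for gid, reg, st, _m in config.planted_peaks
                if gid == gene.gene_id and reg == region
            )
            for _ in range(stack):
                ip.append(AlignedRead(gene.chrom, gene.strand, [(s, e)]))
    control = background("control")
    for i, r in enumerate(ip):
        r.name = f"clip_ip_{i}"
    for i, r in enumerate(control):
        r.name = f"clip_in_{i}"
    return ip, control


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run all generators and write the full synthetic dataset to disk.

    Returns the manifest (file -> emitted read/record counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, models, gtf, gt = generate_gene_models(config)
    (outdir / "genome.fa").write_text(fasta)
    (outdir / "annotation.gtf").write_text(gtf)
    (outdir / "ground_truth.json").write_text(gt.to_json())
    manifest: dict = {"seed": config.seed, "n_genes": len(models), "files": {}}
    for cond in ("A", "B"):
        for rep in range(1, config.n_replicates + 1):
            reads = simulate_rnaseq(models, config, gt, cond, rep)
            fname = f"rnaseq_{cond}_rep{rep}.bed12"
            (outdir / fname).write_text(write_bed12(reads))
            manifest["files"][fname] = len(reads)
    ip, ctrl = simulate_clip(models, config)
    (outdir / "clip_ip.bed12").write_text(write_bed12(ip))
    (outdir / "clip_control.bed12").write_text(write_bed12(ctrl))
    manifest["files"]["clip_ip.bed12"] = len(ip)
    manifest["files"]["clip_control.bed12"] = len(ctrl)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
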