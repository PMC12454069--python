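"""Genomic data model and text I/O: FASTA, GTF2.2, BED12, junctions.

All internal coordinates are 0-based half-open. GTF's 1-based closed
convention is converted at the parse/write boundary and nowhere else.
Donor/acceptor of a junction are defined in transcription direction:
on the + strand the donor is the intron start and the acceptor the
intron end; on the - strand they are swapped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq


class ParseError(ValueError):
    """Malformed input text; message names the offending line."""


# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class Junction:
    """A splice junction: the intron removed between two read blocks."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int

    @property
    def donor(self) -> int:
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor(self) -> int:
        return self.intron_end if self.strand == "+" else self.intron_start

    @property
    def intron(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)


@dataclass
class AlignedRead:
    """A (possibly spliced) aligned read: ordered genomic blocks.

    ``unique`` marks uniquely mapped reads; it travels in the BED12
    score column (1=unique, 0=multi). Only unique reads enter gene
    counting and peak calling.
    """

    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    unique: bool = True
    name: str = "."

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def junctions(self) -> list[Junction]:
        return extract_junctions(self)


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """One gene: strand, span, and its transcript structures."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)
    biotype: str = "coding"
    # planted CLIP-peak intervals, filled by the simulator: (start, end, region, motif)
    planted_peaks: list[tuple[int, int, str, str]] = field(default_factory=list)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all transcripts' exons."""
        return merge_intervals(
            [iv for t in self.transcripts for iv in t.exons]
        )

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    def introns(self) -> set[tuple[int, int]]:
        """All annotated introns across transcripts."""
        return {iv for t in self.transcripts for iv in t.introns()}

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(text: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    }


def write_fasta(seqs: dict[str, str], width: int = 60) -> str:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def fetch_sequence(
    genome: dict[str, str], chrom: str, start: int, end: int, strand: str
) -> str:
    """Extract an RNA-alphabet sequence for a half-open genomic interval.

    The - strand is reverse-complemented first; T->U is applied last.
    """
    seq = genome[chrom]
    if start < 0 or end > len(seq) or start > end:
        raise ValueError(
            f"interval [{start},{end}) out of range for {chrom} (len {len(seq)})"
        )
    sub = seq[start:end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub.replace("T", "U")


# ---------------------------------------------------------------------------
# GTF2.2

_GTF_FEATURES = ("gene", "transcript", "exon", "CDS", "five_prime_utr", "three_prime_utr")


def _parse_attrs(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, val = chunk.split(" ", 1)
        except ValueError:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(text: str) -> list[GeneModel]:
    """Parse a GTF2.2 subset into gene models (0-based half-open coords)."""
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
        if feature not in _GTF_FEATURES:
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates")
        if end1 < start1:
            raise ParseError(f"line {lineno}: end < start")
        if strand not in "+-":
            raise ParseError(f"line {lineno}: unknown strand {strand!r}")
        start, end = start1 - 1, end1  # to 0-based half-open
        attrs = _parse_attrs(attr, lineno)
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise ParseError(f"line {lineno}: missing gene_id attribute")
        if feature == "gene":
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype=attrs.get("gene_biotype", "coding"),
            )
            continue
        tx_id = attrs.get("transcript_id")
        if tx_id is None:
            raise ParseError(f"line {lineno}: missing transcript_id attribute")
        if feature == "transcript":
            transcripts[tx_id] = Transcript(transcript_id=tx_id)
            tx_gene[tx_id] = gene_id
            continue
        if tx_id not in transcripts:
            raise ParseError(
                f"line {lineno}: {feature} for unknown transcript {tx_id!r}"
            )
        tx = transcripts[tx_id]
        slot = {
            "exon": tx.exons,
            "CDS": tx.cds,
            "five_prime_utr": tx.utr5,
            "three_prime_utr": tx.utr3,
        }[feature]
        slot.append((start, end))

    for tx_id, tx in transcripts.items():
        gene_id = tx_gene[tx_id]
        if gene_id not in genes:
            raise ParseError(f"transcript {tx_id!r} references unknown gene {gene_id!r}")
        for slot in (tx.exons, tx.cds, tx.utr5, tx.utr3):
            slot.sort()
        genes[gene_id].transcripts.append(tx)
    return list(genes.values())


def write_gtf(models: list[GeneModel], source: str = "clipsplice") -> str:
    """Serialise gene models to GTF2.2 (1-based closed coordinates)."""
    lines = []

    def row(chrom, feat, s, e, strand, attrs):
        lines.append(
            "\t".join(
                [chrom, source, feat, str(s + 1), str(e), ".", strand, ".", attrs]
            )
        )

    for g in models:
        gattr = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        row(g.chrom, "gene", g.start, g.end, g.strand, gattr)
        for t in g.transcripts:
            tattr = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            row(g.chrom, "transcript", t.start, t.end, g.strand, tattr)
            for s, e in t.exons:
                row(g.chrom, "exon", s, e, g.strand, tattr)
            for s, e in t.cds:
                row(g.chrom, "CDS", s, e, g.strand, tattr)
            for s, e in t.utr5:
                row(g.chrom, "five_prime_utr", s, e, g.strand, tattr)
            for s, e in t.utr3:
                row(g.chrom, "three_prime_utr", s, e, g.strand, tattr)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BED12


def read_bed12(text: str) -> list[AlignedRead]:
    reads = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ParseError(f"line {lineno}: expected 12 columns, got {len(f)}")
        chrom, start_s, _end_s, name, score, strand = f[0], f[1], f[2], f[3], f[4], f[5]
        block_count = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
        starts = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
        if len(sizes) != block_count or len(starts) != block_count:
            raise ParseError(
                f"line {lineno}: blockCount={block_count} but "
                f"{len(sizes)} sizes / {len(starts)} starts listed"
            )
        chrom_start = int(start_s)
        blocks = [
            (chrom_start + bs, chrom_start + bs + sz)
            for bs, sz in zip(starts, sizes)
        ]
        reads.append(
            AlignedRead(
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                unique=(int(score) == 1),
                name=name,
            )
        )
    return reads


def write_bed12(reads: list[AlignedRead]) -> str:
    lines = []
    for r in reads:
        sizes = ",".join(str(e - s) for s, e in r.blocks)
        starts = ",".join(str(s - r.start) for s, _e in r.blocks)
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.start),
                    str(r.end),
                    r.name,
                    "1" if r.unique else "0",
                    r.strand,
                    str(r.start),
                    str(r.end),
                    "0",
                    str(len(r.blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def extract_junctions(read: AlignedRead) -> list[Junction]:
    """One junction per inter-block gap; intron = [prev end, next start)."""
    return [
        Junction(read.chrom, read.strand, read.blocks[i][1], read.blocks[i + 1][0])
        for i in range(len(read.blocks) - 1)
    ]
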