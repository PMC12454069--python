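"""Hand-constructed annotation/junction fixtures, one per classical AS type.

Each fixture is the minimal gene-model + junction-cluster configuration
that realises one classical event type, with the expected label as ground
truth. Used for classifier validation and as documentation of the rules.
"""

from __future__ import annotations

from .alignio import GeneModel, Junction, Transcript
from .splicing import ASEvent


def _gene(exon_lists, strand="+", gene_id="g1"):
    txs = [
        Transcript(f"{gene_id}.t{i + 1}", exons=sorted(ex))
        for i, ex in enumerate(exon_lists)
    ]
    start = min(t.exons[0][0] for t in txs)
    end = max(t.exons[-1][1] for t in txs)
    return GeneModel(gene_id, "chr1", strand, start, end, txs)


def _event(junctions, kind):
    return ASEvent("fixture", "chr1", junctions[0].strand, kind, list(junctions))


def _j(s, e, strand="+"):
    return Junction("chr1", strand, s, e)


def classical_event_fixtures() -> list[tuple[str, ASEvent, list[GeneModel]]]:
    """(expected label, event, models) for all ten classical AS types."""
    return [
        (
            "A3SS",
            _event([_j(100, 200), _j(100, 220)], "alt3p"),
            [_gene([[(0, 100), (200, 300)], [(0, 100), (220, 300)]])],
        ),
        (
            "A5SS",
            _event([_j(100, 400), _j(80, 400)], "alt5p"),
            [_gene([[(0, 100), (400, 500)], [(0, 80), (400, 500)]])],
        ),
        (
            "ES",
            _event([_j(100, 200), _j(100, 400)], "alt3p"),
            [_gene([[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]])],
        ),
        (
            "cassetteExon",
            _event([_j(100, 200), _j(300, 400), _j(100, 400)], "mixed"),
            [_gene([[(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]])],
        ),
        (
            "MXE",
            _event([_j(100, 200), _j(250, 450), _j(100, 300), _j(350, 450)], "mixed"),
            [
                _gene(
                    [
                        [(0, 100), (200, 250), (450, 550)],
                        [(0, 100), (300, 350), (450, 550)],
                    ]
                )
            ],
        ),
        (
            "5pMXE",
            _event([_j(50, 200), _j(150, 200)], "alt5p"),
            [_gene([[(0, 50), (200, 300)], [(100, 150), (200, 300)]])],
        ),
        (
            "3pMXE",
            _event([_j(100, 200), _j(100, 300)], "alt3p"),
            [_gene([[(0, 100), (200, 250)], [(0, 100), (300, 350)]])],
        ),
        (
            "IntronR",
            _event([_j(100, 200)], "ir"),
            [_gene([[(0, 100), (200, 300)]])],
        ),
        (
            "A3SS&ES",
            _event([_j(100, 200), _j(100, 220), _j(100, 400)], "alt3p"),
            [
                _gene(
                    [
                        [(0, 100), (200, 300), (400, 500)],
                        [(0, 100), (220, 300), (400, 500)],
                        [(0, 100), (400, 500)],
                    ]
                )
            ],
        ),
        (
            "A5SS&ES",
            _event([_j(100, 400), _j(80, 400), _j(300, 400)], "mixed"),
            [
                _gene(
                    [
                        [(0, 100), (200, 300), (400, 500)],
                        [(0, 80), (200, 300), (400, 500)],
                        [(0, 100), (400, 500)],
                    ]
                )
            ],
        ),
    ]
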