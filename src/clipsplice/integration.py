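"""Overlap of RBP-bound genes with DEG and AS gene sets, plus enrichment.

The Venn-style integration intersects the bound (CLIP target) gene set
with up/down DEGs and alternatively spliced genes over a declared gene
universe, and attaches an upper-tail hypergeometric enrichment P to each
pairwise overlap. The enrichment P is an addition over plain Venn counts
and is labelled as such in the report.
"""

from __future__ import annotations

import json
from itertools import combinations

from scipy import stats


def hypergeometric_overlap(size_a: int, size_b: int, overlap: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for |A ∩ B| under random draws from N genes."""
    if overlap > min(size_a, size_b) or size_a > universe or size_b > universe:
        raise ValueError(
            f"inconsistent counts: |A|={size_a}, |B|={size_b}, "
            f"overlap={overlap}, N={universe}"
        )
    if overlap < 0 or min(size_a, size_b, universe) < 0:
        raise ValueError("counts must be non-negative")
    # X ~ Hypergeom(N, K=size_a, n=size_b); sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def intersect_sets(
    sets: dict[str, set[str]], universe: set[str]
) -> dict:
    """Pairwise intersections and hypergeometric enrichment over a universe.

    Raises on any set member missing from the universe, naming the member.
    """
    for name, members in sets.items():
        stray = members - universe
        if stray:
            raise ValueError(
                f"set {name!r} member {sorted(stray)[0]!r} is outside the universe"
            )
    report = {
        "universe_size": len(universe),
        "sets": {name: sorted(members) for name, members in sets.items()},
        "set_sizes": {name: len(members) for name, members in sets.items()},
        "pairwise": {},
    }
    for a, b in combinations(sorted(sets), 2):
        inter = sets[a] & sets[b]
        report["pairwise"][f"{a}|{b}"] = {
            "size": len(inter),
            "members": sorted(inter),
            "hypergeom_p": hypergeometric_overlap(
                len(sets[a]), len(sets[b]), len(inter), len(universe)
            ),
        }
    return report


def build_report(
    bound_genes: set[str],
    de_table,
    splice_table,
    event_genes: dict[str, str],
    universe: set[str],
    metadata: dict | None = None,
) -> dict:
    """Assemble the integrated bound/DEG/AS overlap report.

    ``event_genes`` maps event ids to host gene ids (events outside any
    gene are dropped). ``metadata`` (seeds, thresholds, versions) is
    carried through verbatim; no timestamps are added so regeneration from
    identical inputs is byte-identical.
    """
    deg_up = set(de_table.loc[de_table["deg_flag"] == "up", "gene_id"])
    deg_down = set(de_table.loc[de_table["deg_flag"] == "down", "gene_id"])
    as_ids = (
        set(splice_table.loc[splice_table["high_confidence"], "event_id"])
        if len(splice_table)
        else set()
    )
    as_genes = {event_genes[e] for e in as_ids if e in event_genes}
    sets = {
        "bound": bound_genes,
        "deg_up": deg_up,
        "deg_down": deg_down,
        "as_genes": as_genes,
    }
    report = intersect_sets(sets, universe)
    report["metadata"] = metadata or {}
    report["note"] = (
        "hypergeom_p is an enrichment statistic added on top of the overlap counts"
    )
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)
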