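"""Gene counting, FPKM, threshold-based differential expression, and 2^-ddCt.

The DE test is a deliberately simple negative-binomial Wald test: counts
are normalised with median-of-ratios size factors, per-gene dispersion is
estimated by method of moments (floored at 1e-4) and moderated by taking
the maximum with the across-gene median dispersion — with 2-4 replicates
per group the raw method-of-moments estimate is frequently a severe
underestimate, and the max-with-trend rule restores type-I calibration of
the normal-reference Wald statistic at a small cost in power. The
decision thresholds are fixed: BH-adjusted P < 0.05 and fold change >= 2
or <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .alignio import AlignedRead, GeneModel

FC_UP = 2.0
FC_DOWN = 0.5
ALPHA = 0.05
DISPERSION_FLOOR = 1e-4


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    padj: float
    deg_flag: str  # up / down / ns


def count_genes(
    reads: list[AlignedRead], models: list[GeneModel]
) -> dict[str, int]:
    """Count uniquely mapped reads per gene over exon unions.

    A read is counted for a gene iff it is unique, on the same strand, and
    at least one block overlaps the gene's exon union. Reads overlapping
    exons of more than one gene are ambiguous and counted for none.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in models:
        t = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for s, e in g.exon_union():
            t.addi(s, e, g.gene_id)
    counts = {g.gene_id: 0 for g in models}
    for r in reads:
        if not r.unique:
            continue
        t = trees.get((r.chrom, r.strand))
        if t is None:
            continue
        hits = {iv.data for s, e in r.blocks for iv in t.overlap(s, e)}
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return counts


def build_count_matrix(
    samples: dict[str, list[AlignedRead]], models: list[GeneModel]
) -> pd.DataFrame:
    """Genes x samples count matrix (column order follows dict order)."""
    data = {name: count_genes(reads, models) for name, reads in samples.items()}
    genes = [g.gene_id for g in models]
    return pd.DataFrame(data, index=genes).fillna(0).astype(int)


def fpkm(count: float, gene_exonic_length_bp: float, total_counted_fragments: float) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if gene_exonic_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_counted_fragments <= 0:
        raise ValueError("total fragment count must be positive")
    return count * 1e9 / (gene_exonic_length_bp * total_counted_fragments)


def fpkm_table(counts: pd.DataFrame, models: list[GeneModel]) -> pd.DataFrame:
    lengths = pd.Series({g.gene_id: g.exonic_length() for g in models})
    totals = counts.sum(axis=0)
    return counts.div(lengths, axis=0).div(totals, axis=1) * 1e9


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios normalisation factors."""
    logc = np.log(counts.replace(0, np.nan))
    logmeans = logc.mean(axis=1)
    usable = np.isfinite(logmeans) & counts.gt(0).all(axis=1)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = logc.loc[usable].sub(logmeans[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = ALPHA,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
) -> pd.DataFrame:
    """NB Wald test per gene, B vs A; BH correction; threshold DEG flags.

    Returns a DataFrame with columns gene_id, base_mean, log2fc, p, padj,
    deg_flag (up/down/ns).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    sf = size_factors(counts[group_a + group_b])
    norm = counts[group_a + group_b].div(sf, axis=1)
    na, nb = len(group_a), len(group_b)
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # log2FC: exact ratio when both means positive; pseudocount only at zeros
    both_pos = (mean_a > 0) & (mean_b > 0)
    log2fc = np.zeros_like(mean_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc[both_pos] = np.log2(mean_b[both_pos] / mean_a[both_pos])
    zeroish = ~both_pos
    log2fc[zeroish] = np.log2((mean_b[zeroish] + 0.5) / (mean_a[zeroish] + 0.5))

    # method-of-moments dispersion, pooled over the within-group variances
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    pooled_mean = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / pooled_mean**2
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    disp = np.maximum(disp, DISPERSION_FLOOR)
    # moderation: gene-wise estimates at n=3 scatter widely around the
    # shared biological value, so take the max with the across-gene median
    informative = disp[(disp > DISPERSION_FLOOR) & (pooled_mean > 0)]
    trend = float(np.median(informative)) if informative.size else DISPERSION_FLOOR
    disp = np.maximum(disp, trend)

    # delta-method SE of log2 mean under NB sampling, Wald z-test
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_a2 = (mean_a + disp * mean_a**2) / (na * mean_a**2 * ln2sq)
        se_b2 = (mean_b + disp * mean_b**2) / (nb * mean_b**2 * ln2sq)
    se = np.sqrt(se_a2 + se_b2)
    ok = np.isfinite(se) & (se > 0)
    wald = np.where(ok, log2fc / np.where(ok, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    padj = benjamini_hochberg(p)

    fc = 2.0**log2fc
    flag = np.where(
        (padj < alpha) & (fc >= fc_up),
        "up",
        np.where((padj < alpha) & (fc <= fc_down), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "deg_flag": flag,
        }
    ).set_index("gene_id", drop=False)


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
    """
    ddct_val = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))
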