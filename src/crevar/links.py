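"""Correlation-based peak-to-gene linking, DORC scores, per-gene link
ranking, and concordance with activity-by-contact (ABC) predictions.

Single cells are aggregated into metacell groups before correlating
(sparse per-cell counts are too noisy to correlate directly). For every
(peak, gene) pair whose peak midpoint lies within a window of the gene's
TSS, the Pearson correlation across aggregates is tested via the
t-transform with df = n_aggregates - 2, p-values are BH-adjusted across
all tested pairs in the run, and links are retained when r >= r_min (the
reported minimum-correlation rule; one-sided positive retention) at
FDR < fdr_max.

DORC (domain of regulatory chromatin) scores sum per-cell
depth-normalized accessibility over a gene's linked peaks:
score(cell, gene) = sum_p count(cell, p) / fragments(cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "PeakGeneLink",
    "make_cell_aggregates",
    "compute_links",
    "dorc_scores",
    "rank_genes_by_links",
    "abc_concordance",
]


@dataclass(frozen=True)
class PeakGeneLink:
    peak: GenomicInterval
    gene: str
    r: float
    p_raw: float
    fdr: float
    distance: int  # TSS - peak midpoint, bp (signed)


def make_cell_aggregates(
    peak_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    k_groups: int = 100,
    groups: Sequence[int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sum cells into ``k_groups`` metacell aggregates.

    Rows of both matrices are cells (shared universe or a supplied pairing
    in shared row order); columns are peaks / genes. ``groups`` supplies an
    explicit cell -> group assignment (e.g. from k-means on an embedding);
    by default cells are assigned at random, which suffices for synthetic
    data where correlation is planted per cell. Column sums are conserved.
    """
    n_cells = peak_counts.shape[0]
    if gene_counts.shape[0] != n_cells:
        raise ValueError("matrices disagree on cell count")
    if k_groups > n_cells:
        raise ValueError("more groups than cells")
    if groups is None:
        rng = np.random.default_rng(rng)
        groups = rng.permutation(n_cells) % k_groups
    groups = np.asarray(groups)
    agg_peaks = peak_counts.groupby(groups).sum()
    agg_genes = gene_counts.groupby(groups).sum()
    return agg_peaks, agg_genes, groups


def _peak_midpoint(peak: GenomicInterval) -> int:
    return (peak.start + peak.end) // 2


def compute_links(
    agg_peaks: pd.DataFrame,
    agg_genes: pd.DataFrame,
    peak_coords: Mapping[str, GenomicInterval],
    tss: pd.DataFrame,  # columns gene_id, chrom, tss
    window: int = 500_000,
    r_min: float = 0.1,
    fdr_max: float = 1e-4,
    inclusive_r: bool = True,
    two_sided_retention: bool = False,
) -> list[PeakGeneLink]:
    """Test all in-window (peak, gene) pairs and retain significant links.

    Zero-variance peaks or genes are skipped. The BH family is the full set
    of tested pairs in this call.
    """
    n = agg_peaks.shape[0]
    if n < 3:
        raise ValueError("need at least 3 aggregates")
    tss_by_gene = {row.gene_id: (row.chrom, int(row.tss))
                   for row in tss.itertuples(index=False)}
    pairs: list[tuple[str, str, int]] = []
    for pid, peak in peak_coords.items():
        if pid not in agg_peaks.columns:
            continue
        mid = _peak_midpoint(peak)
        for gene in agg_genes.columns:
            info = tss_by_gene.get(gene)
            if info is None or info[0] != peak.chrom:
                continue
            dist = info[1] - mid
            if abs(dist) <= window:
                pairs.append((pid, gene, dist))
    if not pairs:
        return []
    peak_mat = agg_peaks.to_numpy(dtype=float)
    gene_mat = agg_genes.to_numpy(dtype=float)
    p_idx = {c: i for i, c in enumerate(agg_peaks.columns)}
    g_idx = {c: i for i, c in enumerate(agg_genes.columns)}
    rs, ps, keepmask = [], [], []
    tested: list[tuple[str, str, int]] = []
    df = n - 2
    for pid, gene, dist in pairs:
        x = peak_mat[:, p_idx[pid]]
        y = gene_mat[:, g_idx[gene]]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df))
        tested.append((pid, gene, dist))
        rs.append(r)
        ps.append(p)
    if not tested:
        return []
    fdr = multipletests(ps, method="fdr_bh")[1]
    links = []
    for (pid, gene, dist), r, p, q in zip(tested, rs, ps, fdr):
        stat = abs(r) if two_sided_retention else r
        r_ok = stat >= r_min if inclusive_r else stat > r_min
        if r_ok and q < fdr_max:
            links.append(PeakGeneLink(peak_coords[pid], gene, r, p, float(q), dist))
    return links


def dorc_scores(
    peak_counts: pd.DataFrame,
    fragments: pd.Series,
    links: Sequence[PeakGeneLink],
    peak_ids: Mapping[tuple, str],
    tss: pd.DataFrame,
    window: int = 500_000,
) -> pd.DataFrame:
    """Per-cell, per-gene DORC score over linked peaks within the window.

    ``peak_ids`` maps peak interval key -> column id of ``peak_counts``.
    Cells with zero fragment totals are an error. Genes without links score
    zero everywhere. Invariant under joint rescaling of counts and depths.
    """
    if (fragments <= 0).any():
        raise ValueError("cell with zero fragment count")
    tss_by_gene = {row.gene_id: (row.chrom, int(row.tss))
                   for row in tss.itertuples(index=False)}
    genes = sorted({lk.gene for lk in links} | set(tss_by_gene))
    norm = peak_counts.div(fragments, axis=0)
    out = pd.DataFrame(0.0, index=peak_counts.index, columns=genes)
    for lk in links:
        info = tss_by_gene.get(lk.gene)
        if info is None:
            continue
        if abs(info[1] - _peak_midpoint(lk.peak)) > window:
            continue
        pid = peak_ids.get(lk.peak.key)
        if pid is None:
            continue
        out[lk.gene] += norm[pid]
    return out


def rank_genes_by_links(
    links: Sequence[PeakGeneLink],
    window: int = 50_000,
) -> pd.DataFrame:
    """Per-gene counts of proximal links, each peak assigned at most once.

    Restricted to links within ``window`` of the TSS. A peak connected to
    several genes counts only for the link with the lowest FDR (ties broken
    by larger |r|, then lexicographic gene id). Returns a table sorted by
    descending link count with a top-percentile column (rank among genes
    with at least one connection).
    """
    proximal = [lk for lk in links if abs(lk.distance) <= window]
    best: dict[tuple, PeakGeneLink] = {}
    for lk in proximal:
        cur = best.get(lk.peak.key)
        if cur is None or (lk.fdr, -abs(lk.r), lk.gene) < (cur.fdr, -abs(cur.r), cur.gene):
            best[lk.peak.key] = lk
    counts: dict[str, int] = {}
    for lk in best.values():
        counts[lk.gene] = counts.get(lk.gene, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["gene", "n_links", "rank", "percentile"])
    df = pd.DataFrame(sorted(counts.items()), columns=["gene", "n_links"])
    df = df.sort_values(["n_links", "gene"], ascending=[False, True],
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["percentile"] = 100.0 * df["rank"] / len(df)
    return df


def abc_concordance(
    abc_predictions: Sequence[tuple[GenomicInterval, str]],
    links: Sequence[PeakGeneLink],
) -> tuple[float, float]:
    """Fraction of ABC enhancers matched by correlation-based links.

    matched_peak: the ABC enhancer overlaps any linked peak, regardless of
    the predicted cognate gene. matched_gene: some overlapping linked peak
    also shares the cognate gene.
    """
    if not abc_predictions:
        raise ValueError("empty ABC prediction list")
    linked = [(lk.peak, lk.gene) for lk in links]
    n_peak = n_gene = 0
    for enh, gene in abc_predictions:
        overlapping = [g for pk, g in linked
                       if pk.chrom == enh.chrom and pk.start < enh.end
                       and enh.start < pk.end]
        if overlapping:
            n_peak += 1
            if gene in overlapping:
                n_gene += 1
    n = len(abc_predictions)
    return n_peak / n, n_gene / n
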