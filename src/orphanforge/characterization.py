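"""Structural statistics and OG-vs-NOG contrasts.

Covers per-gene structure metrics (protein length, exon number and length,
GC content, isoelectric point), rank-sum contrasts between orphan and
non-orphan gene classes, and chromosomal distribution summaries including
a telomere-proximity ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import GeneModel

__all__ = [
    "GeneStats",
    "GroupContrast",
    "gene_stats",
    "gene_stats_table",
    "isoelectric_point",
    "net_charge",
    "wilcoxon_rank_sum",
    "contrast_table",
    "chromosome_density",
    "EMBOSS_PK",
]

# EMBOSS pK table: positively ionizable (N-terminus, K, R, H) and
# negatively ionizable (C-terminus, D, E, C, Y) groups.
EMBOSS_PK = {
    "Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5,
    "Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GeneStats:
    gene_id: str
    gene_class: str                 # "OG" or "NOG"
    protein_length: int
    exon_count: int
    mean_exon_length: float
    gc_content: float
    isoelectric: float


@dataclass
class GroupContrast:
    metric: str
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    direction: str                  # "a<b", "a>b" or "a=b" by median


def net_charge(protein: str, ph: float, pk: dict[str, float] = EMBOSS_PK) -> float:
    """Net charge of a peptide at the given pH (Henderson-Hasselbalch sums)."""
    counts = {aa: protein.count(aa) for aa in "KRHDECY"}
    pos = sum(
        n * 10 ** pk[g] / (10 ** ph + 10 ** pk[g])
        for g, n in [("Nterm", 1)] + [(aa, counts[aa]) for aa in "KRH"])
    neg = sum(
        n * 10 ** ph / (10 ** ph + 10 ** pk[g])
        for g, n in [("Cterm", 1)] + [(aa, counts[aa]) for aa in "DECY"])
    return pos - neg


def isoelectric_point(protein: str, pk: dict[str, float] = EMBOSS_PK,
                      tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    Non-standard residues are ignored with a warning. The free termini
    always ionize, so every peptide has a root; an empty sequence is an
    error.
    """
    seq = protein.rstrip("*")
    if not seq:
        raise ValueError("empty peptide has no ionizable groups")
    extra = set(seq) - _STANDARD_AA
    if extra:
        warnings.warn(f"ignoring non-standard residues {sorted(extra)}", stacklevel=2)
        seq = "".join(a for a in seq if a in _STANDARD_AA)
        if not seq:
            raise ValueError("no standard residues left to ionize")
    lo, hi = 0.0, 14.0
    f_lo = net_charge(seq, lo, pk)
    if f_lo < 0:                      # cannot happen with ionizable termini
        raise ValueError("net charge negative at pH 0; no isoelectric point")
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid, pk)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gene_stats(gene: GeneModel, gene_class: str = "NOG") -> GeneStats:
    """Structure statistics for one gene.

    GC is computed on the CDS; exon lengths are genomic; protein length
    excludes the stop symbol.
    """
    if not gene.cds_seq:
        raise ValueError(f"{gene.gene_id}: missing CDS")
    cds = gene.cds_seq.upper()
    gc = (cds.count("G") + cds.count("C")) / len(cds)
    protein = gene.protein_seq.rstrip("*")
    return GeneStats(
        gene_id=gene.gene_id,
        gene_class=gene_class,
        protein_length=len(protein),
        exon_count=gene.exon_count,
        mean_exon_length=float(np.mean(gene.exon_lengths)),
        gc_content=gc,
        isoelectric=isoelectric_point(protein) if protein else float("nan"),
    )


def gene_stats_table(genes: list[GeneModel], orphan_ids: set[str]) -> pd.DataFrame:
    rows = [gene_stats(g, "OG" if g.gene_id in orphan_ids else "NOG") for g in genes]
    return pd.DataFrame([r.__dict__ for r in rows])


def wilcoxon_rank_sum(x, y, metric: str = "") -> GroupContrast:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) contrast of two samples.

    Exact enumeration when the pooled size is at most 10 and the data are
    tie-free; otherwise the normal approximation with midrank ties,
    tie-corrected variance and continuity correction. Constant pooled data
    yield p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return GroupContrast(metric, float(np.median(x)), float(np.median(y)),
                             u, 1.0, "a=b")
    n_total = len(x) + len(y)
    tie_free = len(np.unique(pooled)) == n_total
    method = "exact" if (n_total <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    ma, mb = float(np.median(x)), float(np.median(y))
    direction = "a<b" if ma < mb else ("a>b" if ma > mb else "a=b")
    return GroupContrast(metric, ma, mb, float(res.statistic),
                         float(min(res.pvalue, 1.0)), direction)


_CONTRAST_METRICS = ("protein_length", "exon_count", "mean_exon_length",
                     "gc_content", "isoelectric")


def contrast_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """OG-vs-NOG rank-sum contrast for every structure metric."""
    og = stats_df[stats_df.gene_class == "OG"]
    nog = stats_df[stats_df.gene_class == "NOG"]
    rows = []
    for metric in _CONTRAST_METRICS:
        c = wilcoxon_rank_sum(og[metric].dropna(), nog[metric].dropna(), metric)
        rows.append({"metric": metric, "og_median": c.median_a,
                     "nog_median": c.median_b, "W": c.statistic,
                     "p_value": c.p_value,
                     "direction": c.direction.replace("a", "OG").replace("b", "NOG")})
    return pd.DataFrame(rows)


def chromosome_density(genes: list[GeneModel], orphan_ids: set[str],
                       chromosome_lengths: dict[str, int],
                       window_bp: int = 100_000,
                       terminal_fraction: float = 0.10):
    """Windowed OG density along chromosomes plus a telomere-proximity summary.

    Returns ``(window_table, per_chromosome_table, telomere_ratio)`` where
    the ratio is the mean OG fraction of windows inside the terminal
    ``terminal_fraction`` of each chromosome arm divided by the interior
    mean. A ratio near 1 indicates a uniform OG distribution; > 1 means OG
    enrichment near the telomeres.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    for g in genes:
        if g.end > chromosome_lengths.get(g.chromosome, 0):
            raise ValueError(f"{g.gene_id}: beyond chromosome length")
    win_rows = []
    chrom_rows = []
    term_fracs: list[float] = []
    int_fracs: list[float] = []
    for chrom, length in sorted(chromosome_lengths.items()):
        n_win = max(1, math.ceil(length / window_bp))
        counts = np.zeros(n_win, dtype=int)
        og_counts = np.zeros(n_win, dtype=int)
        chrom_genes = [g for g in genes if g.chromosome == chrom]
        for g in chrom_genes:
            mid = (g.start + g.end) // 2
            w = min(n_win - 1, (mid - 1) // window_bp)
            counts[w] += 1
            if g.gene_id in orphan_ids:
                og_counts[w] += 1
        term_bp = terminal_fraction * length
        for w in range(n_win):
            ws, we = w * window_bp + 1, min(length, (w + 1) * window_bp)
            terminal = ws <= term_bp or we > length - term_bp
            frac = og_counts[w] / counts[w] if counts[w] else np.nan
            win_rows.append({"chromosome": chrom, "start": ws, "end": we,
                             "og_count": int(og_counts[w]),
                             "gene_count": int(counts[w]),
                             "og_fraction": frac,
                             "terminal": terminal})
            if counts[w]:
                (term_fracs if terminal else int_fracs).append(frac)
        n_chrom = len(chrom_genes)
        n_og = sum(1 for g in chrom_genes if g.gene_id in orphan_ids)
        chrom_rows.append({"chromosome": chrom, "genes": n_chrom, "ogs": n_og,
                           "og_percent": 100.0 * n_og / n_chrom if n_chrom else np.nan})
    interior_mean = float(np.mean(int_fracs)) if int_fracs else np.nan
    terminal_mean = float(np.mean(term_fracs)) if term_fracs else np.nan
    if np.isnan(interior_mean) or np.isnan(terminal_mean):
        ratio = np.nan
    elif interior_mean == 0.0:
        ratio = np.inf if terminal_mean > 0 else np.nan
    else:
        ratio = terminal_mean / interior_mean
    return pd.DataFrame(win_rows), pd.DataFrame(chrom_rows), ratio
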