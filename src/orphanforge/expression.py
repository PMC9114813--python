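"""Expression-level inference: FPKM, DE screening, tissue specificity,
trend clustering, co-expression modules and pathway enrichment.

The differential-expression screen is a negative-binomial Wald test with
median-of-ratios normalization and a pooled method-of-moments dispersion —
a deliberately lightweight, fully documented procedure whose calibration
(false-discovery control, power) is validated on synthetic truth. An
adapter for externally produced DE tables is provided for users who prefer
a heavier estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "expressed_flags",
    "spm",
    "spm_table",
    "de_screen",
    "benjamini_hochberg",
    "fuzzy_cmeans",
    "FuzzyClustering",
    "select_soft_threshold",
    "coexpression_modules",
    "ModuleResult",
    "module_trait_and_hubs",
    "enrichment",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts plus design metadata.

    ``design`` maps sample -> group label (tissue, condition or time
    point); ``gene_lengths`` are summed exon lengths in bp.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray
    design: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.gene_lengths) != len(self.gene_ids):
            raise ValueError("one gene length per gene required")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        missing = [s for s in self.sample_ids if s not in self.design]
        if missing:
            raise ValueError(f"samples without design entry: {missing}")

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.sample_ids):
            out.setdefault(self.design[s], []).append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


def fpkm(counts: np.ndarray, gene_lengths: np.ndarray,
         totals: np.ndarray | None = None) -> np.ndarray:
    """Fragments per kilobase of exon per million mapped fragments.

    fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total[s]); totals
    default to per-sample column sums.
    """
    counts = np.asarray(counts, dtype=float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(gene_lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("per-sample totals must be positive")
    return counts * 1e9 / (gene_lengths[:, None] * totals[None, :])


def expressed_flags(fpkm_matrix: np.ndarray, threshold: float = 0.02,
                    rule: str = "any") -> np.ndarray:
    """Per-gene expressed call: FPKM above threshold in any sample
    (default) or on the per-gene mean (``rule='mean'``)."""
    f = np.asarray(fpkm_matrix, dtype=float)
    if rule == "any":
        return f.max(axis=1) > threshold
    if rule == "mean":
        return f.mean(axis=1) > threshold
    raise ValueError("rule must be 'any' or 'mean'")


def spm(profile: np.ndarray) -> np.ndarray:
    """Specificity measure of a cross-tissue mean-expression vector.

    SPM_i = x_i / ||x||: the cosine between the profile and the unit
    vector of tissue i. Scale-invariant; an all-zero profile is undefined.
    """
    x = np.asarray(profile, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression profile must be non-negative")
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:
        raise ValueError("all-zero profile has no specificity")
    return x / norm


def spm_table(fpkm_matrix: np.ndarray, gene_ids: list[str],
              sample_ids: list[str], design: dict[str, str],
              threshold: float = 0.9) -> pd.DataFrame:
    """Per-gene tissue SPM values and the specific-tissue call (SPM >= 0.9).

    Tissue means are taken over replicate samples first. All-zero genes
    are skipped."""
    f = np.asarray(fpkm_matrix, dtype=float)
    tissues = sorted(set(design[s] for s in sample_ids))
    cols = {t: [j for j, s in enumerate(sample_ids) if design[s] == t] for t in tissues}
    means = np.column_stack([f[:, cols[t]].mean(axis=1) for t in tissues])
    rows = []
    for i, gid in enumerate(gene_ids):
        if means[i].sum() == 0:
            continue
        s = spm(means[i])
        k = int(np.argmax(s))
        rows.append({"gene_id": gid,
                     **{f"spm_{t}": s[j] for j, t in enumerate(tissues)},
                     "max_spm": float(s[k]),
                     "specific_tissue": tissues[k] if s[k] >= threshold else None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential expression stand-in
# ---------------------------------------------------------------------------

def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Size factors by the median-of-ratios method (geometric-mean reference)."""
    c = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(c)
    ok = np.all(np.isfinite(logs), axis=1)
    if not ok.any():
        raise ValueError("no gene expressed in every sample; cannot normalize")
    ref = logs[ok].mean(axis=1)
    sf = np.exp(np.median(logs[ok] - ref[:, None], axis=0))
    return sf


def de_screen(counts: np.ndarray, gene_ids: list[str],
              sample_groups: list[str], contrast: tuple[str, str],
              alpha: float = 0.05, lfc_cutoff: float = 1.0) -> pd.DataFrame:
    """Negative-binomial Wald screen for differential expression.

    Counts are normalized with median-of-ratios size factors; the log2
    fold change uses a pseudocount of 1 on normalized group means; the
    Wald variance combines Poisson and overdispersion terms with a single
    pooled method-of-moments dispersion estimated across genes. P-values
    are Benjamini-Hochberg adjusted; a gene is called DE when
    fdr < ``alpha`` and \\|log2FC\\| > ``lfc_cutoff``.
    """
    c = np.asarray(counts, dtype=float)
    ja = [j for j, g in enumerate(sample_groups) if g == contrast[0]]
    jb = [j for j, g in enumerate(sample_groups) if g == contrast[1]]
    if len(ja) < 2 or len(jb) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    sub = c[:, ja + jb]
    if np.any(sub.sum(axis=0) == 0):
        raise ValueError("a library in the contrast is entirely zero")
    sf = median_of_ratios(sub)
    norm = sub / sf[None, :]
    na, nb = len(ja), len(jb)
    a, b = norm[:, :na], norm[:, na:]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mb + 1.0) - np.log2(ma + 1.0)

    # pooled method-of-moments dispersion: per-gene alpha from within-group
    # mean/variance, then the median over informative genes
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    num = (va - ma) * (na - 1) + (vb - mb) * (nb - 1)
    den = (ma ** 2) * (na - 1) + (mb ** 2) * (nb - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = num / den
    informative = (ma > 5) & (mb > 5) & np.isfinite(alpha_g)
    disp = float(np.median(alpha_g[informative])) if informative.any() else 0.0
    disp = max(disp, 1e-8)

    # delta-method variance of log2 fold change under NB(mu, mu + disp*mu^2)
    var_la = (1.0 / np.maximum(ma, 1e-8) + disp) / na
    var_lb = (1.0 / np.maximum(mb, 1e-8) + disp) / nb
    se = np.sqrt(var_la + var_lb) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = benjamini_hochberg(p)
    return pd.DataFrame({
        "gene_id": gene_ids,
        "base_mean_a": ma, "base_mean_b": mb,
        "log2fc": log2fc, "p_value": p, "fdr": fdr,
        "is_de": (fdr < alpha) & (np.abs(log2fc) > lfc_cutoff),
    })


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Fuzzy c-means trend clustering
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    centers: np.ndarray             # c x stages
    memberships: np.ndarray         # genes x c, rows sum to 1
    objective: list[float] = field(default_factory=list)

    def screened(self, threshold: float = 0.6) -> dict[int, np.ndarray]:
        """Cluster -> indices of genes with max membership above threshold."""
        top = self.memberships.argmax(axis=1)
        strong = self.memberships.max(axis=1) > threshold
        return {k: np.where(strong & (top == k))[0]
                for k in range(self.centers.shape[0])}


def standardize_profiles(x: np.ndarray) -> np.ndarray:
    """Per-gene z-standardization (constant rows raise)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant profiles cannot be standardized")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def fuzzy_cmeans(profiles: np.ndarray, c: int, m: float = 2.0,
                 tol: float = 1e-6, max_iter: int = 300,
                 seed: int = 0, max_restarts: int = 5) -> FuzzyClustering:
    """Bezdek fuzzy c-means with alternating center/membership updates.

    ``profiles`` should be per-gene standardized trends (genes x stages).
    Convergence is declared when the largest membership change drops below
    ``tol``; the objective is asserted non-increasing every iteration.
    Degenerate (duplicate) centers trigger a bounded re-seed.
    """
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if n < c:
        raise ValueError("need at least c profiles")
    if c == 1:
        center = x.mean(axis=0, keepdims=True)
        return FuzzyClustering(centers=center, memberships=np.ones((n, 1)))
    rng = np.random.default_rng(seed)
    for _restart in range(max_restarts):
        u = rng.dirichlet(np.ones(c), size=n)
        prev_obj = np.inf
        objective: list[float] = []
        ok = True
        for _it in range(max_iter):
            w = u ** m
            centers = (w.T @ x) / w.sum(axis=0)[:, None]
            if _duplicate_centers(centers):
                ok = False
                break
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))  # (d^2)^(-1/(m-1)) = d^(-2/(m-1))
            new_u = inv / inv.sum(axis=1, keepdims=True)
            obj = float((new_u ** m * d2).sum())
            if obj > prev_obj + 1e-9:
                raise AssertionError("fuzzy c-means objective increased")
            objective.append(obj)
            delta = np.abs(new_u - u).max()
            u = new_u
            prev_obj = obj
            if delta < tol:
                break
        if ok:
            return FuzzyClustering(centers=centers, memberships=u,
                                   objective=objective)
    raise RuntimeError("fuzzy c-means failed to avoid degenerate centers")


def _duplicate_centers(centers: np.ndarray, tol: float = 1e-9) -> bool:
    c = centers.shape[0]
    for i in range(c):
        for j in range(i + 1, c):
            if np.allclose(centers[i], centers[j], atol=tol):
                return True
    return False


# ---------------------------------------------------------------------------
# Co-expression modules (weighted-network style)
# ---------------------------------------------------------------------------

@dataclass
class ModuleResult:
    labels: np.ndarray              # per-gene module label, 0 = unassigned
    eigengenes: dict[int, np.ndarray]
    mm: np.ndarray                  # correlation with own module eigengene
    beta: int
    gene_ids: list[str]

    def module_members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]


def select_soft_threshold(expr: np.ndarray, betas=range(1, 21),
                          r2_target: float = 0.8, fallback: int = 6) -> int:
    """Smallest beta whose connectivity distribution fits a power law with
    R^2 >= ``r2_target``; falls back to ``fallback`` when none qualifies."""
    corr = np.abs(np.corrcoef(expr))
    np.fill_diagonal(corr, 0.0)
    for beta in betas:
        k = (corr ** beta).sum(axis=1)
        r2 = _scale_free_r2(k)
        if r2 >= r2_target:
            return int(beta)
    return fallback


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return 0.0
    bins = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    idx = np.digitize(k, bins) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r ** 2)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap similarity of a weighted adjacency matrix."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def coexpression_modules(expr: np.ndarray, gene_ids: list[str],
                         beta: int | None = None,
                         min_module_size: int = 30,
                         cut_height: float | None = None) -> ModuleResult:
    """Weighted co-expression modules from signed-magnitude correlations.

    adjacency = |pearson r|^beta; similarity = topological overlap;
    average-linkage hierarchical clustering on 1 - TOM. The tree is cut at
    ``cut_height`` when given; by default the cut is placed inside the
    largest gap of the merge-height sequence, which separates the
    tight within-module merges from the final between-module joins
    without a hand-picked height. Clusters below ``min_module_size`` are
    merged into the nearest module by eigengene correlation or left
    unassigned (label 0). The module eigengene is the first principal
    component of the module's standardized expression, oriented to
    correlate positively with the module mean.
    """
    x = np.asarray(expr, dtype=float)
    if x.shape[0] < 2 * min_module_size:
        raise ValueError("need at least 2 * min_module_size genes")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    keep = x.std(axis=1) > 0
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} constant gene rows", stacklevel=2)
    x_used = x[keep]
    ids_used = [g for g, k in zip(gene_ids, keep) if k]

    if beta is None:
        beta = select_soft_threshold(x_used)
    corr = np.corrcoef(x_used)
    adj = np.abs(corr) ** beta
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = average(squareform(dist, checks=False))
    if cut_height is None:
        heights = np.sort(link[:, 2])
        gaps = np.diff(heights)
        k = int(np.argmax(gaps))
        cut_height = float((heights[k] + heights[k + 1]) / 2.0)
    raw_labels = fcluster(link, t=cut_height, criterion="distance")

    z = standardize_profiles(x_used)
    labels = np.zeros(len(ids_used), dtype=int)
    eigengenes: dict[int, np.ndarray] = {}
    next_label = 1
    small_clusters = []
    for cl in np.unique(raw_labels):
        members = np.where(raw_labels == cl)[0]
        if len(members) >= min_module_size:
            labels[members] = next_label
            eigengenes[next_label] = _eigengene(z[members])
            next_label += 1
        else:
            small_clusters.append(members)
    # merge small clusters into the nearest module by eigengene correlation
    for members in small_clusters:
        if not eigengenes:
            break
        profile = z[members].mean(axis=0)
        best, best_r = 0, 0.5      # require a clearly correlated host module
        for lab, eg in eigengenes.items():
            r = abs(np.corrcoef(profile, eg)[0, 1])
            if r > best_r:
                best, best_r = lab, r
        labels[members] = best
    # recompute eigengenes after merges
    for lab in list(eigengenes):
        members = np.where(labels == lab)[0]
        eigengenes[lab] = _eigengene(z[members])

    mm = np.zeros(len(ids_used))
    for i in range(len(ids_used)):
        lab = labels[i]
        if lab:
            mm[i] = np.corrcoef(z[i], eigengenes[lab])[0, 1]

    full_labels = np.zeros(len(gene_ids), dtype=int)
    full_mm = np.zeros(len(gene_ids))
    full_labels[keep] = labels
    full_mm[keep] = mm
    return ModuleResult(labels=full_labels, eigengenes=eigengenes,
                        mm=full_mm, beta=int(beta), gene_ids=list(gene_ids))


def _eigengene(z: np.ndarray) -> np.ndarray:
    """First right singular vector of the standardized module expression,
    sign-aligned with the mean member profile."""
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eg = vt[0]
    if np.dot(eg, z.mean(axis=0)) < 0:
        eg = -eg
    return eg


def module_trait_and_hubs(result: ModuleResult, expr: np.ndarray,
                          traits: dict[str, np.ndarray],
                          mm_cutoff: float = 0.95,
                          gs_cutoff: float = 0.85) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module-trait correlations and hub genes by the MM/GS rule.

    Returns (module_trait table, per-gene table with is_hub flags). A hub
    gene has module membership MM > 0.95 and gene significance
    \\|GS\\| > 0.85 for the trait its module correlates best with.
    """
    x = np.asarray(expr, dtype=float)
    mt_rows = []
    best_trait: dict[int, str] = {}
    for lab, eg in result.eigengenes.items():
        for tname, tvec in traits.items():
            tvec = np.asarray(tvec, dtype=float)
            if tvec.std() == 0:
                mt_rows.append({"module": lab, "trait": tname,
                                "r": np.nan, "p_value": np.nan})
                continue
            r, p = stats.pearsonr(eg, tvec)
            mt_rows.append({"module": lab, "trait": tname, "r": r, "p_value": p})
    mt = pd.DataFrame(mt_rows)
    for lab in result.eigengenes:
        sub = mt[(mt.module == lab) & mt.r.notna()]
        if len(sub):
            best_trait[lab] = sub.loc[sub.r.abs().idxmax(), "trait"]

    gene_rows = []
    for i, gid in enumerate(result.gene_ids):
        lab = int(result.labels[i])
        gs = np.nan
        if lab and lab in best_trait:
            tvec = np.asarray(traits[best_trait[lab]], dtype=float)
            if x[i].std() > 0 and tvec.std() > 0:
                gs = float(stats.pearsonr(x[i], tvec)[0])
        mmv = float(result.mm[i])
        gene_rows.append({"gene_id": gid, "module": lab, "MM": mmv, "GS": gs,
                          "is_hub": bool(lab and mmv > mm_cutoff
                                         and not np.isnan(gs) and abs(gs) > gs_cutoff)})
    return mt, pd.DataFrame(gene_rows)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment(selected: set[str], universe: set[str],
               term_map: dict[str, set[str]], alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH adjustment.

    For each term, p = P[overlap >= observed] drawing |selected| genes from
    a universe containing the term's genes. Terms with no universe genes
    are skipped; significance is called at p < ``alpha``.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for term, genes in sorted(term_map.items()):
        in_universe = genes & universe
        if not in_universe:
            continue
        n = len(in_universe)
        k = len(in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"term": term, "term_size": n, "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
        df["significant"] = df["p_value"] < alpha
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df
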