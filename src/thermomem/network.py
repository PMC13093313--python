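"""Signed weighted gene co-expression networks.

Builds the classic chain: signed soft-thresholded adjacency from gene-gene
correlations, topological overlap (TOM), average-linkage clustering with a
static percentile tree cut and minimum module size, module eigengenes (first
principal component of the standardized member genes), eigengene-similarity
module merging, gene significance, intramodular weighted degree, and
module-trait Spearman correlations.

Expression matrices are genes x samples DataFrames on a normalized log scale.
Module label 0 means unassigned/background; modules 1..K are numbered by
decreasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)


class NetworkInputError(ValueError):
    pass


@dataclass
class NetworkConfig:
    power: int = 6
    target_r2: float = 0.8
    min_module_size: int = 50
    merge_height: float = 0.25
    correlation_kind: str = "pearson"
    cut_quantile: float = 0.7  # static tree-cut height = this quantile of merge heights

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not (0.0 < self.merge_height < 1.0):
            raise ValueError("merge_height must lie in (0, 1)")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be pearson or spearman")


def _gene_correlation(expr: pd.DataFrame, kind: str = "pearson") -> np.ndarray:
    vals = expr.to_numpy(dtype=float)
    if kind == "spearman":
        vals = np.apply_along_axis(stats.rankdata, 1, vals)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][:5].to_list()
        raise NetworkInputError(f"zero-variance gene(s) present (e.g. {bad}); filter first")
    return np.corrcoef(vals)


def signed_adjacency(expr: pd.DataFrame, power: int = 6, kind: str = "pearson") -> pd.DataFrame:
    """a_ij = ((1 + cor_ij) / 2) ** power with unit diagonal."""
    if expr.shape[1] < 3:
        raise NetworkInputError("adjacency needs >= 3 samples")
    cor = _gene_correlation(expr, kind)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
    target_r2: float = 0.8,
    kind: str = "pearson",
) -> tuple[int, pd.DataFrame]:
    """Scale-free topology criterion for the soft-threshold power.

    For each power the signed adjacency is built, whole-network connectivity
    k_i computed, log10 k binned into 10 bins, and log10 p(k) regressed on
    log10 mean(k) per bin. The fit index is R^2 signed negative when the
    slope is positive. Returns the smallest power reaching target_r2, else
    the argmax, together with the fit table.
    """
    cor = _gene_correlation(expr, kind)
    rows = []
    for beta in powers:
        adj = ((1.0 + cor) / 2.0) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        k = k[k > 0]
        if k.size < 10 or np.allclose(k, k[0]):
            raise NetworkInputError("degenerate connectivity distribution")
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-12, 11)
        which = np.clip(np.digitize(logk, edges) - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = which == b
            if sel.sum() == 0:
                continue
            xs.append(np.log10(np.mean(k[sel])))
            ys.append(np.log10(sel.mean()))
        if len(xs) < 3:
            raise NetworkInputError("degenerate connectivity distribution")
        slope, intercept, r, _, _ = stats.linregress(xs, ys)
        r2 = r * r * (-1.0 if slope > 0 else 1.0)
        rows.append({"power": beta, "fit_r2": r2, "slope": slope, "mean_k": float(np.mean(k))})
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= target_r2]
    power = int(ok["power"].iloc[0]) if len(ok) else int(table.loc[table["fit_r2"].idxmax(), "power"])
    return power, table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbor adjacency a_iu * a_uj over u != i, j;
    k_i is whole-network connectivity excluding the diagonal. TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise NetworkInputError("adjacency must be symmetric")
    # shared-neighbor sums; subtract the u == i and u == j terms
    # (a_ii * a_ij + a_ij * a_jj = 2 a_ij with unit diagonal)
    l = (a @ a) - 2.0 * a
    k = a.sum(axis=1) - np.diag(a)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, cfg: NetworkConfig | None = None
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static percentile cut.

    The dendrogram is cut at the cut_quantile of merge heights; clusters
    smaller than min_module_size become background (label 0); surviving
    clusters are labeled 1..K by decreasing size.
    """
    cfg = cfg or NetworkConfig()
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    heights = Z[:, 2]
    cut = np.quantile(heights, cfg.cut_quantile)
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = _relabel_by_size(raw, cfg.min_module_size)
    if labels.max() <= 1 and (labels > 0).all():
        logger.warning("all genes fall in a single module")
    return pd.Series(labels, index=tom.index, name="module")


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    keep = ids[counts >= min_size]
    order = keep[np.argsort(-counts[np.isin(ids, keep)])]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping.get(r, 0) for r in raw])


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-PC module eigengenes and kME.

    Genes are standardized across samples; the eigengene is the first
    right-singular-vector sample score scaled to unit variance, with its
    sign oriented so the mean correlation of member genes with it is >= 0.
    Returns (ME: module x sample, kME: gene x module).
    """
    labels = labels.loc[expr.index]
    modules = sorted(m for m in labels.unique() if m != 0)
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise NetworkInputError("zero-variance gene; filter before eigengene computation")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    mes = {}
    for m in modules:
        member = (labels == m).to_numpy()
        sub = z[member]
        if sub.shape[0] == 1:
            logger.warning("module %s has a single gene; eigengene = standardized gene", m)
            me = sub[0]
        else:
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            me = vt[0]
        me = me / me.std(ddof=0)
        # orientation: mean member correlation >= 0
        member_cor = (sub @ me) / (sub.shape[1] * me.std(ddof=0))
        if member_cor.mean() < 0:
            me = -me
        mes[f"ME{m}"] = me
    me_df = pd.DataFrame(mes, index=expr.columns).T
    # kME: correlation of every gene with every ME
    if modules:
        me_z = (me_df.to_numpy() - me_df.to_numpy().mean(axis=1, keepdims=True)) / me_df.to_numpy().std(
            axis=1, ddof=0, keepdims=True
        )
        kme = (z @ me_z.T) / z.shape[1]
    else:
        kme = np.zeros((len(expr), 0))
    kme_df = pd.DataFrame(kme, index=expr.index, columns=me_df.index)
    return me_df, kme_df


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_height: float = 0.25
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < merge_height."""
    labels = labels.loc[expr.index].copy()
    while True:
        modules = sorted(m for m in labels.unique() if m != 0)
        if len(modules) < 2:
            break
        me, _ = module_eigengene(expr, labels)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
        logger.info("merged module %s into %s (ME cor %.3f)", b, a, cor[i, j])
    # renumber by size
    relabeled = _relabel_by_size(labels.to_numpy(), 1)
    relabeled[labels.to_numpy() == 0] = 0
    return pd.Series(relabeled, index=labels.index, name="module")


def gene_significance(
    expr: pd.DataFrame, trait: pd.Series, kind: str = "pearson"
) -> pd.Series:
    """GS_g = |cor(expression_g, trait)| with the configured correlation kind."""
    trait = trait.loc[expr.columns].astype(float)
    if trait.nunique() < 2:
        raise NetworkInputError("trait is constant")
    t = trait.to_numpy()
    vals = expr.to_numpy(dtype=float)
    if kind == "spearman":
        vals = np.apply_along_axis(stats.rankdata, 1, vals)
        t = stats.rankdata(t)
    tz = (t - t.mean()) / t.std(ddof=0)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
        gs = np.abs((z @ tz) / vals.shape[1])
    return pd.Series(np.where(sd > 0, gs, 0.0), index=expr.index, name="GS")


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact Spearman p by enumeration (n <= 9, no ties assumed)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    count = 0
    total = 0
    for perm in _perms(range(1, n + 1)):
        d = base - np.asarray(perm, dtype=float)
        r = 1.0 - (d @ d) / denom
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def module_trait_correlation(
    mes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and two-sided p for every module x trait pair.

    Uses the t approximation for n > 9 and exact permutation enumeration
    for n <= 9 (distinct values assumed small-n case).
    """
    if mes.shape[1] < 4:
        raise NetworkInputError("module-trait correlation needs >= 4 samples")
    rows = []
    n = mes.shape[1]
    for trait in traits.columns:
        tv = traits[trait].loc[mes.columns].astype(float)
        if tv.nunique() < 2:
            raise NetworkInputError(f"trait {trait!r} has no variation")
        for m in mes.index:
            rho, p = stats.spearmanr(mes.loc[m].to_numpy(), tv.to_numpy())
            if n <= 9:
                p = _spearman_exact_p(rho, n)
            rows.append({"module": m, "trait": trait, "rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows)


def weighted_degree(
    adjacency: pd.DataFrame, labels: pd.Series | None = None, scope: str = "whole"
) -> pd.Series:
    """k_i = sum of adjacency to other genes, optionally restricted to the gene's module.

    Genes with label 0 have intramodular degree 0 by convention.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    if scope == "whole" or labels is None:
        k = a.sum(axis=1)
    elif scope == "intramodular":
        lab = labels.loc[adjacency.index].to_numpy()
        same = lab[:, None] == lab[None, :]
        k = (a * same).sum(axis=1)
        k[lab == 0] = 0.0
    else:
        raise ValueError("scope must be 'whole' or 'intramodular'")
    return pd.Series(k, index=adjacency.index, name="degree")


def code_traits(samples: pd.DataFrame) -> pd.DataFrame:
    """-1/+1 coding of priming and temperature plus raw weight, per sample."""
    out = pd.DataFrame(index=samples.index)
    out["priming"] = np.where(samples["priming"] == "primed", 1.0, -1.0)
    out["temperature"] = np.where(samples["temperature"] == "stress", 1.0, -1.0)
    if "weight" in samples:
        out["weight"] = samples["weight"].astype(float)
    return out


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Signed co-expression network + module detection as one estimator.

    fit(expr) runs adjacency -> TOM -> clustering -> size filter ->
    eigengene merge, storing ``adjacency_``, ``labels_`` (pd.Series),
    ``eigengenes_``, ``kme_`` and, when a sample table is passed,
    ``module_trait_`` (Spearman table) and ``gene_significance_``.
    """

    def __init__(
        self,
        power: int = 6,
        min_module_size: int = 50,
        merge_height: float = 0.25,
        correlation_kind: str = "pearson",
        cut_quantile: float = 0.7,
        keep_tom: bool = False,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_height = merge_height
        self.correlation_kind = correlation_kind
        self.cut_quantile = cut_quantile
        self.keep_tom = keep_tom

    def fit(self, expr: pd.DataFrame, samples: pd.DataFrame | None = None):
        cfg = NetworkConfig(
            power=self.power,
            min_module_size=self.min_module_size,
            merge_height=self.merge_height,
            correlation_kind=self.correlation_kind,
            cut_quantile=self.cut_quantile,
        )
        adj = signed_adjacency(expr, cfg.power, cfg.correlation_kind)
        tom = tom_similarity(adj)
        labels = detect_modules(tom, cfg)
        if self.keep_tom:
            self.tom_ = tom
        del tom
        if (labels > 0).any():
            labels = merge_modules(expr, labels, cfg.merge_height)
            mes, kme = module_eigengene(expr, labels)
        else:
            mes = pd.DataFrame(columns=expr.columns)
            kme = pd.DataFrame(index=expr.index)
        self.adjacency_ = adj
        self.labels_ = labels
        self.eigengenes_ = mes
        self.kme_ = kme
        self.degree_ = weighted_degree(adj, labels, scope="intramodular")
        if samples is not None and len(mes):
            traits = code_traits(samples.loc[expr.columns])
            self.module_trait_ = module_trait_correlation(mes, traits)
            self.gene_significance_ = gene_significance(
                expr, traits["priming"], kind=self.correlation_kind
            )
        return self

    def fit_predict(self, expr: pd.DataFrame, samples: pd.DataFrame | None = None):
        return self.fit(expr, samples).labels_.to_numpy()
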