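"""Rank-based and Fisher-exact functional enrichment.

Two engines: (1) a Mann-Whitney delta-rank test of per-class log2
fold-changes against the rest of the universe (KOG-style single-class maps),
also applicable to kME-or-zero vectors for module-wise enrichment; (2) a
Fisher exact test of module membership against term membership (GO-style
term sets). Both apply Benjamini-Hochberg correction across classes/terms.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

logger = logging.getLogger(__name__)


class DegenerateClassError(ValueError):
    pass


def _exact_mwu_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact MWU p-value (no ties) by dynamic programming.

    Builds the exact null distribution of U via the standard recurrence on
    the number of subsets of each rank-sum, then doubles the smaller tail.
    """
    # f[k][u] = #ways to choose k of n items with U statistic u; roll over items
    max_u = n1 * n2
    # distribution of U for sample size n1 from n1+n2 ranks
    # recurrence: N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def count(u_: int, a: int, b: int) -> int:
        if u_ < 0:
            return 0
        if a == 0:
            return 1 if u_ == 0 else 0
        if b == 0:
            return 1 if u_ == 0 else 0
        return count(u_ - b, a - 1, b) + count(u_, a, b - 1)

    total = 0
    dist = np.array([count(x, n1, n2) for x in range(max_u + 1)], dtype=float)
    count.cache_clear()
    dist = dist / dist.sum()
    u_int = int(round(u))
    lower = dist[: u_int + 1].sum()
    upper = dist[u_int:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def kog_mwu(
    scores: pd.Series, classes: Mapping[str, str], exact_max_n: int = 25
) -> pd.DataFrame:
    """Per-class delta rank and two-sided Mann-Whitney U p on a score vector.

    scores: per-gene values (log2 fold-changes, or kME-or-zero). classes:
    gene -> single class. Genes without annotation form an implicit
    background (ranked but not tested); classes covering the whole scored
    universe are an error. delta_rank = mean rank in class - mean rank
    outside, mid-ranks for ties over the full universe. The exact null
    distribution is used for small tie-free universes, the normal
    approximation with tie correction otherwise. BH across classes.
    """
    scores = scores.dropna()
    genes = scores.index
    mapped = {g: classes[g] for g in genes if g in classes}
    n_unmapped = len(genes) - len(mapped)
    if n_unmapped:
        logger.info("%d gene(s) without class annotation form the background", n_unmapped)
    by_class: dict[str, list[str]] = {}
    for g, c in mapped.items():
        by_class.setdefault(c, []).append(g)
    eligible = {c: gs for c, gs in by_class.items() if len(gs) >= 2}
    if len(eligible) < 2:
        raise DegenerateClassError("need >= 2 classes with >= 2 genes")
    ranks = pd.Series(stats.rankdata(scores.to_numpy()), index=genes)
    n = len(genes)
    has_ties = scores.duplicated().any()
    rows = []
    for c, gs in sorted(eligible.items()):
        if len(gs) == n:
            raise DegenerateClassError(f"class {c!r} covers the whole universe")
        in_c = ranks.loc[gs]
        out_c = ranks.drop(index=gs)
        delta = float(in_c.mean() - out_c.mean())
        n1, n2 = len(in_c), n - len(in_c)
        u = float(in_c.sum() - n1 * (n1 + 1) / 2.0)
        if not has_ties and n <= exact_max_n:
            p = _exact_mwu_p(u, n1, n2)
        else:
            p = float(
                stats.mannwhitneyu(
                    scores.loc[gs].to_numpy(),
                    scores.drop(index=gs).to_numpy(),
                    alternative="two-sided",
                    method="asymptotic",
                ).pvalue
            )
        rows.append({"class": c, "delta_rank": delta, "p_value": p, "n_in_class": n1})
    out = pd.DataFrame(rows).set_index("class")
    out["p_adjusted"] = adjust_bh(out["p_value"].to_numpy())
    return out


def delta_rank_correlation(tables: Sequence[pd.DataFrame], names: Sequence[str] | None = None):
    """Pairwise Pearson correlation of delta ranks across enrichment tables.

    Returns (r matrix, p matrix) over the classes shared by each pair;
    fewer than 3 shared classes is an error.
    """
    names = list(names) if names is not None else [f"t{i}" for i in range(len(tables))]
    k = len(tables)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            shared = tables[i].index.intersection(tables[j].index)
            if len(shared) < 3:
                raise ValueError(f"fewer than 3 shared classes between {names[i]} and {names[j]}")
            rij, pij = stats.pearsonr(
                tables[i].loc[shared, "delta_rank"], tables[j].loc[shared, "delta_rank"]
            )
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def fisher_enrichment(
    module_genes: Sequence[str],
    term_map: Mapping[str, set],
    universe: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher exact module-membership enrichment per term.

    term_map: term -> gene set. For each term with >= 1 universe gene, a
    2x2 table (in-module x in-term) is tested two-sided; the conditional
    odds ratio is reported (inf when a margin cell is empty in the
    denominator direction). BH across terms; significant flag at
    p_adjusted < alpha.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    module = set(module_genes) & uni
    if set(module_genes) - uni:
        raise ValueError("universe must contain all module genes")
    rows = []
    for term, genes in sorted(term_map.items()):
        in_term = set(genes) & uni
        if not in_term:
            logger.info("term %s disjoint from universe; skipped", term)
            continue
        a = len(module & in_term)
        b = len(module - in_term)
        c = len(in_term - module)
        d = len(uni) - a - b - c
        table = np.array([[a, b], [c, d]])
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        try:
            orat = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
        except Exception:
            orat = np.nan
        rows.append(
            {"term": term, "odds_ratio": orat, "p_value": p, "n_in_term": len(in_term), "n_overlap": a}
        )
    out = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["odds_ratio", "p_value", "n_in_term", "n_overlap"]
    )
    if len(out):
        out["p_adjusted"] = adjust_bh(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    return out


def module_kme_scores(kme: pd.Series, module_genes: Sequence[str]) -> pd.Series:
    """kME-or-zero score vector: module members keep their kME, others get 0."""
    out = pd.Series(0.0, index=kme.index)
    member = [g for g in module_genes if g in kme.index]
    out.loc[member] = kme.loc[member]
    return out
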