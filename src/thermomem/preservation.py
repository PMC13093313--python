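"""Cross-dataset module preservation with a permutation null.

A module discovered in one dataset (the discovery family) is scored in a
second dataset (the test family) with seven statistics that compare edge
weights, summary-profile coherence, and the concordance of correlation
structure, weighted degree and node contributions between the two datasets.
Significance comes from re-drawing gene sets of the module's size uniformly
from the test dataset: discovery-side reference quantities are computed once
and frozen, each permutation re-assigns randomly drawn test genes to the
module's positions, and one-sided (greater) p-values use the (b + 1)/(N + 1)
estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

STATISTICS = (
    "avg_weight",
    "coherence",
    "cor_cor",
    "cor_degree",
    "cor_contrib",
    "avg_cor",
    "avg_contrib",
)


class ModuleSizeError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass
class PreservationConfig:
    n_permutations: int = 10_000
    alpha: float = 1e-4
    seed: int = 0
    statistics: Sequence[str] = STATISTICS
    #: exclude module members from the null draws (default False: draw from
    #: all test genes, the simplest exchangeable null)
    exclude_members: bool = False

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.statistics) - set(STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")


@dataclass
class PreservationResult:
    module: object
    observed: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    missing_genes: list[str] = field(default_factory=list)
    verdict: str | None = None
    failing_statistics: list[str] = field(default_factory=list)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _summary_profile(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First-PC sample scores, node contributions and coherence of a
    standardized module matrix z (genes x samples)."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    h = vt[0]
    nc = (z @ h) / (z.shape[1] * h.std(ddof=0))
    if nc.mean() < 0:
        h, nc = -h, -nc
    coherence = float(s[0] ** 2 / (s**2).sum())
    return h, nc, coherence


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x @ x) * (y @ y))
    return float(x @ y / d) if d > 0 else 0.0


@dataclass
class _DiscoveryReference:
    """Frozen discovery-side quantities for one module."""

    cor: np.ndarray  # module gene x gene correlations in discovery
    nc: np.ndarray  # node contributions in discovery
    degree: np.ndarray  # intramodular weighted degree in discovery
    tril: np.ndarray  # lower-triangle of cor


def _tril(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def discovery_reference(disc_expr: np.ndarray, power: int) -> _DiscoveryReference:
    z = _standardize_rows(np.asarray(disc_expr, dtype=float))
    cor = (z @ z.T) / z.shape[1]
    np.fill_diagonal(cor, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 0.0)
    _, nc, _ = _summary_profile(z)
    return _DiscoveryReference(cor=cor, nc=nc, degree=adj.sum(axis=1), tril=_tril(cor))


def module_statistics(test_z: np.ndarray, ref: _DiscoveryReference, power: int) -> dict[str, float]:
    """The seven preservation statistics for standardized test expression
    (genes x samples, rows aligned to the discovery reference)."""
    n = test_z.shape[1]
    cor = (test_z @ test_z.T) / n
    np.fill_diagonal(cor, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 0.0)
    m = cor.shape[0]
    h, nc, coherence = _summary_profile(test_z)
    tril_test = _tril(cor)
    sign_disc = np.sign(ref.tril)
    s_i = np.sign(ref.nc)
    s_i[s_i == 0] = 1.0
    return {
        "avg_weight": float(adj.sum() / (m * (m - 1))),
        "coherence": coherence,
        "cor_cor": _pearson(ref.tril, tril_test),
        "cor_degree": _pearson(ref.degree, adj.sum(axis=1)),
        "cor_contrib": _pearson(ref.nc, nc),
        "avg_cor": float((tril_test * sign_disc).mean()),
        "avg_contrib": float((s_i * nc).mean()),
    }


def preservation_statistics(
    disc_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    module_genes: Sequence[str],
    power: int = 6,
) -> tuple[dict[str, float], list[str]]:
    """Observed statistics for one module; returns (stats, missing test genes).

    Genes absent from the test dataset are dropped from the comparison and
    reported separately ("NI" genes). More than 50% missing is an error.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 3:
        raise ModuleSizeError("module must have >= 3 genes")
    missing = [g for g in module_genes if g not in test_expr.index]
    present = [g for g in module_genes if g in test_expr.index]
    if len(missing) > 0.5 * len(module_genes):
        raise CoverageError(f"{len(missing)}/{len(module_genes)} module genes missing from test")
    if len(present) < 3:
        raise ModuleSizeError("fewer than 3 module genes present in test dataset")
    absent_disc = [g for g in present if g not in disc_expr.index]
    if absent_disc:
        raise CoverageError(f"module genes missing from discovery: {absent_disc[:5]}")
    ref = discovery_reference(disc_expr.loc[present].to_numpy(), power)
    test_z = _standardize_rows(test_expr.loc[present].to_numpy(dtype=float))
    return module_statistics(test_z, ref, power), missing


def permutation_test(
    disc_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    module_genes: Sequence[str],
    cfg: PreservationConfig | None = None,
    power: int = 6,
    rng: np.random.Generator | None = None,
) -> PreservationResult:
    """Permutation p-values for one module.

    Null gene sets of the module's (present) size are drawn without
    replacement from the test dataset's genes and injected into the module
    positions in random order; discovery references stay fixed.
    """
    cfg = cfg or PreservationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    observed, missing = preservation_statistics(disc_expr, test_expr, module_genes, power)
    present = [g for g in module_genes if g in test_expr.index]
    m = len(present)
    test_z_all = _standardize_rows(test_expr.to_numpy(dtype=float))
    pool = np.arange(test_expr.shape[0])
    if cfg.exclude_members:
        member_pos = {test_expr.index.get_loc(g) for g in present}
        pool = np.array([i for i in pool if i not in member_pos])
    if pool.size < 2 * m:
        raise CoverageError("test dataset must contain >= 2x module size genes")
    ref = discovery_reference(disc_expr.loc[present].to_numpy(), power)
    stats_req = list(cfg.statistics)
    exceed = {s: 0 for s in stats_req}
    for _ in range(cfg.n_permutations):
        draw = rng.choice(pool, size=m, replace=False)
        rng.shuffle(draw)  # random injection onto module positions
        null = module_statistics(test_z_all[draw], ref, power)
        for s in stats_req:
            if null[s] >= observed[s]:
                exceed[s] += 1
    p = {s: (exceed[s] + 1.0) / (cfg.n_permutations + 1.0) for s in stats_req}
    return PreservationResult(
        module=None,
        observed={s: observed[s] for s in stats_req},
        p_values=p,
        n_permutations=cfg.n_permutations,
        missing_genes=missing,
    )


def classify_preservation(
    result: PreservationResult, alpha: float = 1e-4, rule: str = "all"
) -> PreservationResult:
    """Attach a preserved/not_preserved verdict.

    Small p on a statistic is evidence OF preservation for that statistic.
    rule "all": preserved iff every requested statistic has p < alpha;
    rule "any": preserved iff at least one statistic has p < alpha.
    Failing statistics are listed on the result.
    """
    failing = [s for s, p in result.p_values.items() if not (p < alpha)]
    if rule == "all":
        preserved = len(failing) == 0
    elif rule == "any":
        preserved = len(failing) < len(result.p_values)
    else:
        raise ValueError("rule must be 'all' or 'any'")
    result.verdict = "preserved" if preserved else "not_preserved"
    result.failing_statistics = failing
    return result


class ModulePreservation(BaseEstimator):
    """Permutation module-preservation test between two expression datasets.

    fit(disc_expr, test_expr, labels) runs the permutation test for every
    non-background module in ``labels`` (a gene -> module Series from the
    discovery network). Fitted attributes: ``results_`` (module ->
    PreservationResult) and ``table_`` (tidy observed/p DataFrame).
    """

    def __init__(
        self,
        power: int = 6,
        n_permutations: int = 10_000,
        alpha: float = 1e-4,
        rule: str = "all",
        seed: int = 0,
        statistics: Sequence[str] = STATISTICS,
        exclude_members: bool = False,
    ):
        self.power = power
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.rule = rule
        self.seed = seed
        self.statistics = statistics
        self.exclude_members = exclude_members

    def fit(self, disc_expr: pd.DataFrame, test_expr: pd.DataFrame, labels: pd.Series):
        cfg = PreservationConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.seed,
            statistics=tuple(self.statistics),
            exclude_members=self.exclude_members,
        )
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        results: dict = {}
        rows = []
        for mod in sorted(m for m in labels.unique() if m != 0):
            genes = list(labels.index[labels == mod])
            res = permutation_test(disc_expr, test_expr, genes, cfg, self.power, rng)
            res.module = mod
            classify_preservation(res, self.alpha, self.rule)
            results[mod] = res
            for s in cfg.statistics:
                rows.append(
                    {
                        "module": mod,
                        "statistic": s,
                        "observed": res.observed[s],
                        "p_value": res.p_values[s],
                        "verdict": res.verdict,
                        "n_missing": len(res.missing_genes),
                    }
                )
        self.results_ = results
        self.table_ = pd.DataFrame(rows)
        return self
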