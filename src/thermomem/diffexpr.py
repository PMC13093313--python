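"""Per-gene negative-binomial GLM differential expression.

Dispersion is estimated per gene by method-of-moments on normalized counts
pooled within design cells (no empirical-Bayes shrinkage, so gene counts at
FDR thresholds are not expected to match shrinkage-based tools numerically).
GLMs use a log link with a log(size factor) offset, fitted by IRLS via
statsmodels with the dispersion held fixed; effects are tested either by
likelihood-ratio tests between nested models or by Wald contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)

VALID_FACTORS = ("priming", "temperature", "interaction")


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Nested full/reduced model factor lists for an LRT.

    Factors are drawn from {"priming", "temperature", "interaction"};
    "interaction" requires both main effects in the same model.
    """

    full: Sequence[str]
    reduced: Sequence[str] = ()

    def __post_init__(self):
        for term in list(self.full) + list(self.reduced):
            if term not in VALID_FACTORS:
                raise DesignError(f"unknown factor {term!r}")
        if not set(self.reduced) < set(self.full):
            raise DesignError("reduced model must be a strict subset of the full model")
        for terms in (self.full, self.reduced):
            if "interaction" in terms and not {"priming", "temperature"} <= set(terms):
                raise DesignError("interaction requires both main effects")


def design_matrix(samples: pd.DataFrame, factors: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + 0/1 dummy columns for the requested factors."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    p = (samples["priming"] == "primed").to_numpy(float)
    t = (samples["temperature"] == "stress").to_numpy(float)
    if "priming" in factors:
        cols.append(p)
        names.append("priming[primed]")
    if "temperature" in factors:
        cols.append(t)
        names.append("temperature[stress]")
    if "interaction" in factors:
        cols.append(p * t)
        names.append("priming:temperature")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return X, names


def estimate_dispersion(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series,
    factors: Sequence[str] = ("priming", "temperature"),
) -> pd.Series:
    """Method-of-moments NB dispersion per gene.

    Within each cell of the factor combination the MoM estimate is
    alpha_c = (s2_c - mean_c) / mean_c^2 on normalized counts; per-cell
    estimates are pooled weighted by their degrees of freedom, so
    between-cell mean differences (real expression effects) do not inflate
    the dispersion. Floored at eps = 1e-8; all-zero genes receive the floor.
    """
    cells = samples.groupby(
        [samples[f] for f in factors if f in ("priming", "temperature")] or [np.zeros(len(samples))]
    ).groups
    if not any(len(ix) >= 2 for ix in cells.values()):
        raise DesignError("dispersion estimation needs >= 2 replicates in some cell")
    norm = counts.div(size_factors, axis=1).to_numpy(dtype=float)
    order = {s: i for i, s in enumerate(counts.columns)}
    weighted = np.zeros(norm.shape[0])
    dof = 0
    for ix in cells.values():
        cols = [order[s] for s in ix]
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        mean_c = sub.mean(axis=1)
        var_c = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (var_c - mean_c) / mean_c**2
        alpha_c = np.where(np.isfinite(alpha_c), alpha_c, 0.0)
        weighted += alpha_c * (len(cols) - 1)
        dof += len(cols) - 1
    alpha = np.maximum(weighted / dof, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


@dataclass
class NBFit:
    """A fitted per-gene NB regression."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    cov_params: np.ndarray
    log_likelihood: float
    converged: bool
    dispersion: float
    coef_names: list[str] = field(default_factory=list)


def fit_nb_glm(
    gene_counts: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    dispersion: float,
    coef_names: Sequence[str] | None = None,
) -> NBFit:
    """Log-link NB GLM with offset log(size factor), dispersion held fixed.

    At dispersion <= the floor the model is the Poisson limit and is fitted
    as such.
    """
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    y = np.asarray(gene_counts, dtype=float)
    offset = np.log(np.asarray(size_factors, dtype=float))
    if dispersion <= DISPERSION_FLOOR:
        family = sm.families.Poisson()
    else:
        family = sm.families.NegativeBinomial(alpha=float(dispersion))
    model = sm.GLM(y, X, family=family, offset=offset)
    converged = True
    try:
        res = model.fit(maxiter=50, tol=1e-8)
        converged = bool(res.converged)
        coefs = res.params
        bse = res.bse
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
    except Exception:  # non-convergence / separation
        converged = False
        k = X.shape[1]
        coefs = np.full(k, np.nan)
        bse = np.full(k, np.nan)
        cov = np.full((k, k), np.nan)
        llf = np.nan
    return NBFit(
        coefficients=np.asarray(coefs),
        standard_errors=np.asarray(bse),
        cov_params=cov,
        log_likelihood=llf,
        converged=converged,
        dispersion=float(dispersion),
        coef_names=list(coef_names or [f"b{i}" for i in range(X.shape[1])]),
    )


def lrt(full: NBFit, reduced: NBFit) -> tuple[float, float]:
    """Likelihood-ratio test between nested fits sharing gene and dispersion."""
    df = len(full.coefficients) - len(reduced.coefficients)
    if df <= 0:
        raise DesignError("LRT needs full model with more parameters than reduced")
    if not (full.converged and reduced.converged):
        return np.nan, np.nan
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return stat, float(stats.chi2.sf(stat, df))


def wald_contrast(fit: NBFit, contrast: Sequence[float]) -> tuple[float, float, float]:
    """Wald test of c'beta = 0; returns (log2 fold-change, z, p)."""
    c = np.asarray(contrast, dtype=float)
    if c.shape[0] != fit.coefficients.shape[0]:
        raise DesignError("contrast length does not match number of coefficients")
    if not fit.converged:
        return np.nan, np.nan, np.nan
    est = float(c @ fit.coefficients)
    var = float(c @ fit.cov_params @ c)
    if np.allclose(c, 0.0):
        return 0.0, 0.0, 1.0
    se = np.sqrt(var)
    z = est / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return est / _LN2, z, p


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaN entries are excluded from m and returned NaN."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


class NegativeBinomialDE(BaseEstimator):
    """Per-gene NB differential expression over a factorial sample table.

    Parameters
    ----------
    design : DesignSpec or str
        Either an explicit full/reduced model pair or one of the shorthand
        model names "temperature", "priming", "interaction" (test the named
        term by dropping it from the priming+temperature(+interaction) model).
    test : {"lrt", "wald"}
        LRT between the nested models, or a Wald test on the single factor
        separating them.
    alpha : float
        BH-adjusted significance threshold used by ``significant_genes``.

    Fitted attributes: ``results_`` (per-gene DataFrame with lfc, stat, p,
    padj, dispersion, converged), ``size_factors_``, ``dispersions_``.
    """

    SHORTHAND = {
        "temperature": DesignSpec(("priming", "temperature"), ("priming",)),
        "priming": DesignSpec(("priming", "temperature"), ("temperature",)),
        "interaction": DesignSpec(
            ("priming", "temperature", "interaction"), ("priming", "temperature")
        ),
    }

    def __init__(self, design="temperature", test: str = "lrt", alpha: float = 0.01):
        self.design = design
        self.test = test
        self.alpha = alpha

    def _spec(self) -> DesignSpec:
        if isinstance(self.design, DesignSpec):
            return self.design
        return self.SHORTHAND[self.design]

    def fit(self, counts: pd.DataFrame, samples: pd.DataFrame):
        from .preprocessing import size_factors as _sf

        spec = self._spec()
        samples = samples.loc[counts.columns]
        sf = _sf(counts)
        disp = estimate_dispersion(counts, samples, sf, factors=spec.full)
        X_full, names_full = design_matrix(samples, spec.full)
        X_red, _ = design_matrix(samples, spec.reduced)
        tested = [t for t in spec.full if t not in spec.reduced]
        contrast_name = {
            "priming": "priming[primed]",
            "temperature": "temperature[stress]",
            "interaction": "priming:temperature",
        }[tested[0]] if len(tested) == 1 else None

        sf_arr = sf.to_numpy()
        rows = []
        n_failed = 0
        for gid, y in zip(counts.index, counts.to_numpy()):
            a = disp[gid]
            full = fit_nb_glm(y, X_full, sf_arr, a, names_full)
            lfc, wz, wp = np.nan, np.nan, np.nan
            if full.converged and contrast_name is not None:
                c = np.array([1.0 if n == contrast_name else 0.0 for n in names_full])
                lfc, wz, wp = wald_contrast(full, c)
            if self.test == "wald":
                stat, p = wz, wp
            else:
                red = fit_nb_glm(y, X_red, sf_arr, a)
                stat, p = lrt(full, red)
            if not full.converged:
                n_failed += 1
            rows.append(
                {
                    "gene_id": gid,
                    "log2_fold_change": lfc,
                    "statistic": stat,
                    "p_value": p,
                    "dispersion": a,
                    "converged": full.converged,
                }
            )
        res = pd.DataFrame(rows).set_index("gene_id")
        res["p_adjusted"] = adjust_bh(res["p_value"].to_numpy())
        res["test_kind"] = self.test
        if n_failed:
            logger.info("%d gene fit(s) failed to converge (p set to NaN)", n_failed)
        self.size_factors_ = sf
        self.dispersions_ = disp
        self.results_ = res
        return self

    def significant_genes(self) -> list[str]:
        r = self.results_
        return list(r.index[(r["p_adjusted"] < self.alpha).fillna(False)])


def deg_summary(n_deg: int, n_total: int) -> dict:
    """Report a DEG count as the rounded percentage of the analysed transcriptome."""
    if n_total <= 0 or n_deg < 0 or n_deg > n_total:
        raise ValueError("invalid DEG counts")
    return {
        "n_deg": int(n_deg),
        "n_total": int(n_total),
        "percent": int(round(100.0 * n_deg / n_total)),
    }


def venn_partition(deg_sets: dict[str, set]) -> dict[str, int]:
    """Set-algebraic partition of DEG sets (sizes of every exclusive region)."""
    names = list(deg_sets)
    universe = set().union(*deg_sets.values()) if deg_sets else set()
    out: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(deg_sets[n] for n in combo))
            outside = set().union(*(deg_sets[n] for n in names if n not in combo), set())
            out["&".join(combo)] = len(inside - outside)
    out["union"] = len(universe)
    return out
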