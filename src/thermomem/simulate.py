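"""Synthetic factorial RNA-seq counts with planted co-expression structure.

Emulates a 2-family x 2-priming x 2-temperature common-garden design:
latent module eigengenes respond to the coded factors, genes load on the
eigengenes, counts are negative binomial with per-sample library-size
offsets. One module can be "scrambled" in a single family so that its
gene-gene correlation structure is coherent in the other family only --
the ground truth needed to exercise module-preservation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("A", "B")
PRIMING_LEVELS = ("naive", "primed")
TEMPERATURE_LEVELS = ("control", "stress")

#: log2-scale standard deviation lost to NB sampling is roughly
#: sqrt(1/mu + 1/size)/ln 2; defaults below keep it small relative to the
#: planted signal amplitude so correlation structure survives counting noise.
_LN2 = np.log(2.0)


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the factorial count simulation.

    Defaults are the planted-structure study conditions used throughout the
    test-suite: 4,000 genes, four modules (300/250/150/100 genes), six
    samples per family x priming x temperature cell, and the first module
    scrambled in family A (so family B is the discovery dataset in which it
    is coherent).
    """

    n_genes: int = 4000
    module_sizes: Sequence[int] = (300, 250, 150, 100)
    samples_per_cell: int = 6
    n_families: int = 2
    #: per-module effect (in eigengene standard-deviation units before
    #: standardization) of the coded temperature / priming factors; chosen so
    #: no two module eigengenes are positively correlated (up- and
    #: down-regulated heat-response modules plus a trait-neutral one)
    eigengene_effects: Sequence[Mapping[str, float]] = (
        {"temperature": 2.0, "priming": 3.0},
        {"temperature": -2.0, "priming": 0.0},
        {"temperature": 0.0, "priming": 0.0},
        {"temperature": 1.5, "priming": -2.0},
    )
    #: gene loadings are drawn U-shaped (Beta(0.4, 0.4) scaled to this range)
    #: so every module has core (hub-like) and peripheral members -- the
    #: degree/contribution profile heterogeneity real modules show
    loading_range: tuple[float, float] = (0.65, 0.9)
    #: number of planted "hub candidate" genes in the nonpreserved module;
    #: they receive loading ``hub_loading`` and are the ground truth for
    #: candidate triangulation
    n_hub_candidates: int = 10
    hub_loading: float = 0.99
    #: log2 shift added to hub candidates under priming, on top of the
    #: module eigengene's shared response: the candidates are the genes whose
    #: priming signal exceeds their module's
    hub_priming_effect: float = 1.0
    #: log2 standard deviation of the per-gene module signal
    module_amplitude: float = 2.0
    #: NB size parameter (variance = mu + mu^2/size)
    nb_dispersion: float = 20.0
    #: interval of baseline log2 mean expression
    mean_log_expression: tuple[float, float] = (5.0, 9.0)
    #: relative library-size interval (truncated lognormal)
    library_size_range: tuple[float, float] = (0.7, 1.4)
    #: module whose loadings are re-drawn (scrambled) in family A; None
    #: disables scrambling
    nonpreserved_module_index: Optional[int] = 0
    #: fraction of background genes given a temperature log2 fold-change
    de_fraction: float = 0.1
    de_effect: float = 0.75
    #: log2 sd of intrinsic background-gene noise (keeps background genes
    #: above the low-variance filter)
    background_sd: float = 0.6
    #: background genes share one weak global expression axis (loadings drawn
    #: from this range), preserved across families -- the pervasive low-level
    #: co-expression real transcriptomes show; (0, 0) disables it
    background_factor_loading: tuple[float, float] = (0.3, 0.6)
    seed: int = 0

    def validate(self) -> None:
        if self.samples_per_cell < 1:
            raise InvalidConfigError("samples_per_cell must be positive")
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise InvalidConfigError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise InvalidConfigError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if len(self.eigengene_effects) != len(self.module_sizes):
            raise InvalidConfigError("one eigengene_effects entry required per module")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidConfigError("loading_range must lie in (0, 1]")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise InvalidConfigError("de_fraction must lie in [0, 1]")
        if self.nonpreserved_module_index is not None and not (
            0 <= self.nonpreserved_module_index < len(self.module_sizes)
        ):
            raise InvalidConfigError("nonpreserved_module_index out of range")
        for eff in self.eigengene_effects:
            if not all(np.isfinite(list(eff.values()))):
                raise InvalidConfigError("eigengene effects must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["eigengene_effects"] = [dict(e) for e in self.eigengene_effects]
        return d


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the simulated counts."""

    module_labels: pd.Series  # gene -> module id (0 = background)
    de_genes: list[str]
    nonpreserved_module: Optional[int]
    eigengenes: pd.DataFrame  # module x sample (standardized, per family)
    hub_candidates: list[str]
    loadings: pd.Series  # gene -> loading in the coherent (discovery) family


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the factorial sample table.

    Returns one row per sample: family, priming, temperature, tank (two
    duplicate tanks per cell, assigned alternately), and fresh weight drawn
    from a lognormal with log-mean ln(0.19 g) and log-sd 0.3 (the spat size
    class the assays target).
    """
    config.validate()
    if config.samples_per_cell < 2:
        raise InvalidConfigError("samples_per_cell must be >= 2 (duplicate tanks)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows = []
    idx = 0
    for fam in FAMILIES[: config.n_families]:
        for prim in PRIMING_LEVELS:
            for temp in TEMPERATURE_LEVELS:
                for r in range(config.samples_per_cell):
                    tank = f"{fam}-{prim}-{temp}-T{(r % 2) + 1}"
                    weight = float(rng.lognormal(mean=np.log(0.19), sigma=0.3))
                    rows.append(
                        {
                            "sample_id": f"s{idx:03d}",
                            "family": fam,
                            "priming": prim,
                            "temperature": temp,
                            "tank": tank,
                            "weight": round(weight, 6),
                        }
                    )
                    idx += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _coded(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """-1/+1 coding of temperature and priming."""
    t = np.where(design["temperature"].to_numpy() == "stress", 1.0, -1.0)
    p = np.where(design["priming"].to_numpy() == "primed", 1.0, -1.0)
    return t, p


def simulate_expression(
    config: SimulationConfig, design: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the count matrix for a factorial design.

    Model: for module m with effects (a, b) the latent eigengene in family f
    is E = (a*T + b*P + N(0,1)) / sqrt(a^2 + b^2 + 1), computed per sample.
    A member gene g with loading l contributes s*(l*E + sqrt(1-l^2)*z) log2
    units (s = module_amplitude, z iid normal), mean-corrected so the
    marginal expectation stays at the baseline. Counts are NB(mean, size)
    with a per-sample library-size multiplier.

    The nonpreserved module keeps this structure in family B but in family A
    each of its genes is re-assigned to a random *other* module's eigengene
    with a random sign and re-drawn loading, so the module's correlation
    structure is broken (genes split across the remaining modules, mirroring
    the split-with-opposite-sign pattern seen in real cross-family tests).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n_genes = config.n_genes
    sizes = list(config.module_sizes)
    n_modules = len(sizes)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    samples = design.index.to_list()
    n_samples = len(samples)

    labels = np.zeros(n_genes, dtype=int)
    start = 0
    for m, sz in enumerate(sizes, start=1):
        labels[start : start + sz] = m
        start += sz
    background = np.where(labels == 0)[0]

    lo, hi = config.loading_range
    # U-shaped loading distribution: core members near the top of the range,
    # peripheral members near the bottom
    loadings = lo + (hi - lo) * rng.beta(0.4, 0.4, size=n_genes)
    loadings[labels == 0] = 0.0

    # planted hub candidates inside the nonpreserved (or first) module
    hub_candidates: list[str] = []
    target_mod = (
        config.nonpreserved_module_index + 1
        if config.nonpreserved_module_index is not None
        else 1 if n_modules else None
    )
    if target_mod is not None and config.n_hub_candidates > 0:
        members = np.where(labels == target_mod)[0]
        k = min(config.n_hub_candidates, members.size)
        chosen = rng.choice(members, size=k, replace=False)
        loadings[chosen] = config.hub_loading
        hub_candidates = [gene_ids[i] for i in sorted(chosen)]

    # scrambled-family reassignment for the nonpreserved module
    scram_factor = np.full(n_genes, -1, dtype=int)  # module index gene maps to in family A
    scram_sign = np.ones(n_genes)
    scram_loading = loadings.copy()
    if config.nonpreserved_module_index is not None and n_modules > 1:
        mod_id = config.nonpreserved_module_index + 1
        members = np.where(labels == mod_id)[0]
        others = [m for m in range(1, n_modules + 1) if m != mod_id]
        # half the genes re-load onto a random other module (random sign),
        # the rest decouple entirely (gene-specific noise, factor -1): the
        # module's genes stay expressed but its coherence and correlation
        # structure disappear in the scrambled family
        scram_factor[members] = rng.choice(others, size=members.size)
        to_noise = rng.random(members.size) < 0.5
        scram_factor[members[to_noise]] = 0  # sentinel: no shared factor
        scram_sign[members] = rng.choice([-1.0, 1.0], size=members.size)
        scram_loading[members] = lo + (hi - lo) * rng.beta(0.4, 0.4, size=members.size)

    # background DE genes
    n_de = int(round(config.de_fraction * background.size))
    de_idx = (
        rng.choice(background, size=n_de, replace=False) if n_de > 0 else np.array([], int)
    )
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[de_idx] = True

    baseline = rng.uniform(*config.mean_log_expression, size=n_genes)
    t_coded, p_coded = _coded(design)
    family = design["family"].to_numpy()

    # Per-family standardized eigengenes plus one global background axis.
    # The noise components are drawn orthogonal in-sample to the design
    # codings and to each other, so the planted between-eigengene correlation
    # structure (a_m a_m' + b_m b_m') is realized exactly rather than up to
    # O(1/sqrt(n)) fluctuations that could randomly glue two planted modules
    # together at these sample sizes.
    eig = np.zeros((n_modules, n_samples))
    bg_axis = np.zeros(n_samples)
    n_factors = n_modules + 1
    for fam in np.unique(family):
        sel = family == fam
        n_f = int(sel.sum())
        basis = np.column_stack(
            [np.ones(n_f), t_coded[sel], p_coded[sel]]
        )
        raw = rng.standard_normal((n_f, n_factors))
        if n_f >= basis.shape[1] + n_factors:
            q, _ = np.linalg.qr(np.column_stack([basis, raw]))
            noise = q[:, basis.shape[1] : basis.shape[1] + n_factors]
            noise = noise / noise.std(axis=0, ddof=0)  # unit sample sd per factor
        else:  # too few samples to orthogonalize: plain draws
            noise = raw
        for m in range(n_modules):
            eff = config.eigengene_effects[m]
            a = float(eff.get("temperature", 0.0))
            b = float(eff.get("priming", 0.0))
            denom = np.sqrt(a * a + b * b + 1.0)
            eig[m, sel] = (a * t_coded[sel] + b * p_coded[sel] + noise[:, m]) / denom
        bg_axis[sel] = noise[:, n_modules]

    s = config.module_amplitude
    log2_signal = np.zeros((n_genes, n_samples))
    scrambled_family = FAMILIES[0]  # family A
    fam_is_scrambled = family == scrambled_family
    for m in range(1, n_modules + 1):
        members = np.where(labels == m)[0]
        if members.size == 0:
            continue
        lam = loadings[members][:, None]
        z = rng.standard_normal((members.size, n_samples))
        base_sig = lam * eig[m - 1][None, :] + np.sqrt(1.0 - lam**2) * z
        if config.nonpreserved_module_index is not None and m == (
            config.nonpreserved_module_index + 1
        ) and n_modules > 1:
            lam_a = (scram_sign[members] * scram_loading[members])[:, None]
            targets = scram_factor[members]
            e_a = np.empty((members.size, n_samples))
            shared = targets > 0
            e_a[shared] = eig[targets[shared] - 1, :]
            # decoupled genes ride a private latent factor: plain noise
            e_a[~shared] = rng.standard_normal(((~shared).sum(), n_samples))
            z_a = rng.standard_normal((members.size, n_samples))
            scram_sig = lam_a * e_a + np.sqrt(1.0 - scram_loading[members][:, None] ** 2) * z_a
            base_sig = np.where(fam_is_scrambled[None, :], scram_sig, base_sig)
        log2_signal[members] = s * base_sig
    if background.size:
        bg_lo, bg_hi = config.background_factor_loading
        lam_bg = rng.uniform(bg_lo, bg_hi, size=background.size)[:, None]
        z_bg = rng.standard_normal((background.size, n_samples))
        log2_signal[background] = config.background_sd * (
            lam_bg * bg_axis[None, :] + np.sqrt(1.0 - lam_bg**2) * z_bg
        )
    # temperature fold-change on the planted background DE genes
    log2_signal[de_mask] += config.de_effect * ((t_coded + 1.0) / 2.0)[None, :]
    # hub candidates: an additional gene-level priming response in the
    # coherent (discovery) family, beyond the module's shared signal
    if hub_candidates and config.hub_priming_effect:
        hub_idx = [gene_ids.index(g) for g in hub_candidates]
        boost = config.hub_priming_effect * ((p_coded + 1.0) / 2.0)
        log2_signal[hub_idx] += np.where(fam_is_scrambled, 0.0, boost)[None, :]

    # mean correction: divide by E[2^noise] so marginal mean == 2^baseline
    var_log2 = np.where(labels > 0, s * s, config.background_sd**2)
    correction = np.exp(0.5 * var_log2 * _LN2**2)  # E[2^X] = exp(var * ln(2)^2 / 2)

    lib_lo, lib_hi = config.library_size_range
    mu_log, sd_log = (np.log(lib_lo) + np.log(lib_hi)) / 2.0, (
        np.log(lib_hi) - np.log(lib_lo)
    ) / 4.0
    lib = np.exp(
        np.clip(rng.normal(mu_log, sd_log, size=n_samples), np.log(lib_lo), np.log(lib_hi))
    )

    mu = (2.0 ** (baseline[:, None] + log2_signal)) / correction[:, None] * lib[None, :]
    size = config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        de_genes=[gene_ids[i] for i in sorted(de_idx)],
        nonpreserved_module=(
            config.nonpreserved_module_index + 1
            if config.nonpreserved_module_index is not None
            else None
        ),
        eigengenes=pd.DataFrame(
            eig, index=[f"ME{m}" for m in range(1, n_modules + 1)], columns=samples
        ),
        hub_candidates=hub_candidates,
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
    )
    return counts_df, truth


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper returning (counts, design, truth)."""
    design = simulate_design(config)
    counts, truth = simulate_expression(config, design)
    return counts, design, truth


def write_dataset(
    out_dir,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, str]:
    """Write counts/design/ground-truth/config as TSV + YAML; returns paths."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "module_labels": out / "truth_module_labels.tsv",
        "de_genes": out / "truth_de_genes.tsv",
        "eigengenes": out / "truth_eigengenes.tsv",
        "hub_candidates": out / "truth_hub_candidates.tsv",
        "config": out / "config.yaml",
    }
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    design.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    truth.module_labels.to_frame().to_csv(paths["module_labels"], sep="\t", index_label="gene_id")
    pd.Series(truth.de_genes, name="gene_id").to_csv(paths["de_genes"], sep="\t", index=False)
    truth.eigengenes.to_csv(paths["eigengenes"], sep="\t", index_label="module")
    pd.Series(truth.hub_candidates, name="gene_id").to_csv(
        paths["hub_candidates"], sep="\t", index=False
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
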