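"""End-to-end orchestration of the priming-memory analysis chain.

A single run executes, per family: preprocessing, differential expression
and network construction; then module preservation in both directions
(family B modules tested in family A and vice versa), candidate
triangulation on the nonpreserved modules, and (when annotation maps are
supplied) functional enrichment. Every stochastic stage receives its own
child of one global seed, so outputs are a pure function of (inputs,
config, seed). A JSON manifest records inputs, parameters and outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import candidates as cand
from . import diffexpr, enrichment, io, network, preprocessing, preservation

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters for one run."""

    out_dir: str = "thermomem_run"
    seed: int = 0
    # stage toggles
    run_de: bool = True
    run_network: bool = True
    run_preservation: bool = True
    run_candidates: bool = True
    run_enrichment: bool = True
    # stage parameters
    filter: preprocessing.FilterConfig = field(default_factory=preprocessing.FilterConfig)
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    n_permutations: int = 1000
    #: preservation call threshold; must be attainable given n_permutations
    #: (the permutation p floor is 1/(N+1)), hence 0.01 at the default N
    preservation_alpha: float = 0.01
    triage: cand.TriageConfig = field(default_factory=cand.TriageConfig)
    de_model: str = "temperature"
    de_alpha: float = 0.01
    annotations_path: Optional[str] = None  # gene -> class TSV for MWU enrichment
    terms_path: Optional[str] = None  # GMT term sets for Fisher enrichment
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.run_preservation and not self.run_network:
            raise ConfigError("preservation requires the network stage")
        if self.run_candidates and not (self.run_network and self.run_de):
            raise ConfigError("candidate triangulation requires network and DE stages")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    parameters: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    failed_stage: Optional[str] = None

    def write(self, path) -> str:
        path = pathlib.Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        tmp.replace(path)  # atomic on POSIX
        return str(path)


def run_pipeline(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    config: PipelineConfig,
    input_paths: Mapping[str, str] | None = None,
) -> tuple[dict, RunManifest]:
    """Execute the configured stages; returns (results dict, manifest).

    Results keys (when the stage ran): ``expression`` (per family),
    ``removed_samples``, ``de`` (per family NegativeBinomialDE), ``networks``
    (per family CoexpressionNetwork), ``preservation`` (per direction
    ModulePreservation), ``candidates`` (per nonpreserved module),
    ``enrichment``.
    """
    config.validate()
    io.check_consistency(counts, samples)
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        parameters=_jsonable_params(config),
        started=_dt.datetime.now().isoformat(timespec="seconds"),
    )
    for name, p in (input_paths or {}).items():
        manifest.inputs[str(p)] = _sha256(p)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    results: dict = {"expression": {}, "removed_samples": {}, "de": {}, "networks": {}}
    families = sorted(samples["family"].unique())
    stage = "preprocess"
    try:
        for fam in families:
            fam_samples = samples.index[samples["family"] == fam]
            fam_counts = counts[[c for c in counts.columns if c in set(fam_samples)]]
            expr, removed = preprocessing.preprocess(fam_counts, config.filter)
            results["expression"][fam] = expr
            results["removed_samples"][fam] = removed
            io.write_table(expr, out / f"expression_{fam}.tsv", index_label="gene_id")

        if config.run_de:
            stage = "diffexpr"
            for fam in families:
                fam_samples = samples.loc[results["expression"][fam].columns]
                fam_counts = counts.loc[
                    results["expression"][fam].index, results["expression"][fam].columns
                ]
                de = diffexpr.NegativeBinomialDE(
                    design=config.de_model, alpha=config.de_alpha
                ).fit(fam_counts, fam_samples)
                results["de"][fam] = de
                io.write_table(de.results_, out / f"de_{fam}.tsv", index_label="gene_id")

        if config.run_network:
            stage = "network"
            for fam in families:
                expr = results["expression"][fam]
                net = network.CoexpressionNetwork(
                    power=config.network.power,
                    min_module_size=config.network.min_module_size,
                    merge_height=config.network.merge_height,
                    correlation_kind=config.network.correlation_kind,
                    cut_quantile=config.network.cut_quantile,
                ).fit(expr, samples.loc[expr.columns])
                results["networks"][fam] = net
                io.write_table(
                    net.labels_.to_frame(), out / f"modules_{fam}.tsv", index_label="gene_id"
                )
                io.write_table(net.eigengenes_, out / f"eigengenes_{fam}.tsv", index_label="module")
                io.write_table(net.kme_, out / f"kme_{fam}.tsv", index_label="gene_id")
                io.write_table(net.module_trait_, out / f"module_trait_{fam}.tsv")

        if config.run_preservation:
            stage = "preservation"
            results["preservation"] = {}
            for disc, test in [(families[1], families[0]), (families[0], families[1])]:
                shared_ok = results["networks"][disc].labels_
                mp = preservation.ModulePreservation(
                    power=config.network.power,
                    n_permutations=config.n_permutations,
                    alpha=config.preservation_alpha,
                    seed=int(seeds[0].generate_state(1)[0] % (2**31)),
                )
                # restrict to module genes present in the test matrix (NI genes
                # tracked inside the permutation test)
                mp.fit(
                    results["expression"][disc],
                    results["expression"][test],
                    shared_ok,
                )
                key = f"{disc}-in-{test}"
                results["preservation"][key] = mp
                io.write_table(mp.table_, out / f"preservation_{key}.tsv")

        if config.run_candidates:
            stage = "candidates"
            results["candidates"] = {}
            disc, test = families[1], families[0]
            mp = results["preservation"][f"{disc}-in-{test}"]
            net = results["networks"][disc]
            de = results["de"][disc]
            deg_set = set(de.significant_genes())
            expr = results["expression"][disc]
            traits = network.code_traits(samples.loc[expr.columns])
            gs = network.gene_significance(expr, traits["priming"])
            degree = net.degree_
            nonpreserved = [
                m for m, r in mp.results_.items() if r.verdict == "not_preserved"
            ]
            cor = pd.DataFrame(
                np.corrcoef(expr.to_numpy()), index=expr.index, columns=expr.index
            )
            for m in nonpreserved:
                module_genes = list(net.labels_.index[net.labels_ == m])
                found = cand.triangulate(deg_set, gs, degree, module_genes, config.triage)
                results["candidates"][m] = found
                for g in found:
                    neighbours = cand.top_correlated(
                        cor.loc[module_genes, module_genes], g, config.triage.top_corr_fraction
                    )
                    subnet = cand.build_subnetwork(
                        cor,
                        [g] + neighbours,
                        other_family_labels=results["networks"][test].labels_,
                        other_family_universe=results["expression"][test].index,
                        edge_quantile=config.triage.edge_quantile,
                    )
                    files = cand.export_graph(subnet, out / f"subnetwork_{m}_{g}.graphml")
                    manifest.outputs.extend(files)
            pd.Series(
                {m: ",".join(g) for m, g in results["candidates"].items()}, name="candidates"
            ).to_csv(out / "candidates.tsv", sep="\t", index_label="module")

        if config.run_enrichment and config.annotations_path:
            stage = "enrichment"
            classes = io.read_annotations(config.annotations_path, "tsv")
            results["enrichment"] = {}
            for fam in families:
                if fam not in results["de"]:
                    continue
                lfc = results["de"][fam].results_["log2_fold_change"].dropna()
                table = enrichment.kog_mwu(lfc, classes)
                results["enrichment"][fam] = table
                io.write_table(table, out / f"enrichment_mwu_{fam}.tsv", index_label="class")
            if len(results["enrichment"]) > 1:
                r, _ = enrichment.delta_rank_correlation(
                    list(results["enrichment"].values()), list(results["enrichment"].keys())
                )
                io.write_table(r, out / "delta_rank_correlation.tsv", index_label="contrast")
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
        manifest.write(out / "manifest.json")
        logger.error("pipeline aborted in stage %s", stage)
        raise

    manifest.outputs.extend(str(p) for p in sorted(out.glob("*.tsv")))
    manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
    manifest.write(out / "manifest.json")
    return results, manifest


def _jsonable_params(config: PipelineConfig) -> dict:
    import dataclasses

    def conv(v):
        if dataclasses.is_dataclass(v):
            return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return {f.name: conv(getattr(config, f.name)) for f in dataclasses.fields(config)}
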