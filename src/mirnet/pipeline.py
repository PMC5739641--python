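"""End-to-end orchestration of the analysis.

Per cohort: paired differential expression → per-tissue co-expression
networks over the deregulated miRNA set (normal and tumour strata) →
global/local topology → a DE-restricted network on one configured stratum
(tumour by default) → MCODE clusters with density p-values → normal vs
tumour comparison and motif census → target-gene enrichment. With two or
more cohorts a cross-cohort contrast on the paired differences is added.

All stage outputs are TSV/GraphML files with stable names under the output
directory; a JSON manifest records the config hash, seeds and package
version so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mirnet.io import (read_study, read_alias_table, read_gmt,
                       read_target_map, apply_aliases)
from mirnet.simulate import (SimulationConfig, ModuleSpec, simulate_study,
                             write_fixture)
from mirnet.diffexpr import (paired_ttest, select_deregulated,
                             cross_cohort_contrast, records_to_frame)
from mirnet.network import spearman_matrix, build_network
from mirnet.topology import (global_topology, node_topology,
                             global_report_frame, node_report_frame)
from mirnet.mcode import (McodeParams, mcode_clusters,
                          cluster_density_pvalue, clusters_to_frame)
from mirnet.compare import (compare_networks, motif_census,
                            comparison_to_frame)
from mirnet.enrich import targets_of, enrich, enrichment_to_frame
from mirnet.data import demo_gmt_path, demo_target_map_path

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one of ``matrix_path``/``samples_path`` (real inputs) or
    ``synthetic`` must be supplied.
    """

    outdir: str | Path = "mirnet_out"
    matrix_path: str | Path | None = None
    samples_path: str | Path | None = None
    aliases_path: str | Path | None = None
    target_map_path: str | Path | None = None
    gmt_path: str | Path | None = None
    synthetic: SimulationConfig | None = None
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    de_use_q: bool = False
    network_stratum: str = "tumour"  # stratum of the DE-restricted network
    mcode: McodeParams = field(default_factory=McodeParams)
    seed: int = 0

    def validate(self) -> None:
        real = self.matrix_path is not None and self.samples_path is not None
        if real == (self.synthetic is not None):
            raise PipelineError(
                "config error: supply exactly one of real inputs "
                "(matrix_path + samples_path) or a synthetic config")
        for a in (self.alpha_de, self.alpha_corr):
            if not 0.0 < a < 1.0:
                raise PipelineError(f"config error: alpha {a} outside (0,1)")
        if self.network_stratum not in ("normal", "tumour"):
            raise PipelineError(
                f"config error: unknown stratum {self.network_stratum!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "modules" in syn:
                syn["modules"] = tuple(ModuleSpec(**m)
                                       for m in syn["modules"])
            for key in ("de_log2fc_range", "baseline_mean_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SimulationConfig(**syn)
        if "mcode" in raw and raw["mcode"] is not None:
            raw["mcode"] = McodeParams(**raw["mcode"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("outdir", "matrix_path", "samples_path", "aliases_path",
                  "target_map_path", "gmt_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(df, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs.append(name)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- load / simulate -------------------------------------------------
    if config.synthetic is not None:
        study, truth = stage("simulate")(simulate_study, config.synthetic)
        paths = write_fixture(study, truth, outdir / "synthetic_input")
        outputs += [str(p.relative_to(outdir)) for p in paths.values()]
    else:
        study = stage("load")(read_study, config.matrix_path,
                              config.samples_path)
        if config.aliases_path:
            aliases = read_alias_table(config.aliases_path)
            study = apply_aliases(study, aliases)

    from mirnet import __version__
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "cohorts": {},
        "outputs": outputs,
    }

    per_cohort_studies = {}
    for cohort in study.cohorts:
        sub = study.subset_cohort(cohort)
        per_cohort_studies[cohort] = sub
        info: dict = {}

        # ---- differential expression ------------------------------------
        records = stage("diffexpr")(paired_ttest, sub)
        emit(records_to_frame(records), f"{cohort}_diffexpr.tsv")
        de_set = select_deregulated(records, config.alpha_de,
                                    use_q=config.de_use_q)
        de_feats = sorted(de_set)
        info["n_deregulated"] = len(de_feats)
        if len(de_feats) < 2:
            logger.warning("cohort %s: fewer than 2 deregulated miRNAs; "
                           "network stages skipped", cohort)
            manifest["cohorts"][cohort] = info
            continue

        # ---- per-tissue networks over the DE set ------------------------
        nets = {}
        for tissue in ("normal", "tumour"):
            corr = stage("network")(spearman_matrix, sub, de_feats,
                                    tissue)
            net = build_network(corr, alpha=config.alpha_corr)
            net.stratum = f"{cohort}/{tissue}"
            nets[tissue] = net
            net.write_edgelist(outdir / f"{cohort}_{tissue}_edges.tsv")
            net.write_graphml(outdir / f"{cohort}_{tissue}.graphml")
            outputs += [f"{cohort}_{tissue}_edges.tsv",
                        f"{cohort}_{tissue}.graphml"]
            # ---- topology -----------------------------------------------
            glob = stage("topology")(global_topology, net)
            emit(global_report_frame(glob),
                 f"{cohort}_{tissue}_global_topology.tsv")
            emit(node_report_frame(stage("topology")(node_topology, net)),
                 f"{cohort}_{tissue}_node_topology.tsv")
            info[f"{tissue}_network"] = {"nodes": net.n_nodes,
                                         "edges": net.n_edges}

        # ---- MCODE on the DE-restricted network -------------------------
        de_net = nets[config.network_stratum]
        clusters = stage("mcode")(mcode_clusters, de_net, config.mcode)
        clusters = [dataclasses.replace(
            c, p_value=cluster_density_pvalue(c, de_net))
            for c in clusters]
        emit(clusters_to_frame(clusters), f"{cohort}_mcode_clusters.tsv")
        info["n_clusters"] = len(clusters)

        # ---- normal vs tumour comparison + motif census -----------------
        report = stage("compare")(compare_networks, nets["normal"],
                                  nets["tumour"])
        emit(comparison_to_frame(report), f"{cohort}_comparison.tsv")
        for tissue, net in nets.items():
            census = stage("compare")(motif_census, net)
            import pandas as pd
            emit(pd.DataFrame(sorted(census.counts.items()),
                              columns=["class", "count"]),
                 f"{cohort}_{tissue}_motifs.tsv")

        # ---- enrichment --------------------------------------------------
        gmt = read_gmt(config.gmt_path or demo_gmt_path())
        tmap = read_target_map(config.target_map_path
                               or demo_target_map_path())
        genes = targets_of(de_set, tmap, mode="union")
        if genes:
            results = stage("enrich")(enrich, genes, gmt)
            emit(enrichment_to_frame(results), f"{cohort}_enrichment.tsv")
            info["n_enriched_sets"] = sum(r.significant for r in results)
        else:
            logger.info("cohort %s: no deregulated miRNA has mapped "
                        "targets; enrichment skipped", cohort)
        manifest["cohorts"][cohort] = info

    # ---- cross-cohort contrast ------------------------------------------
    cohorts = sorted(per_cohort_studies)
    if len(cohorts) >= 2:
        a, b = cohorts[0], cohorts[1]
        try:
            contrast = cross_cohort_contrast(per_cohort_studies[a],
                                             per_cohort_studies[b])
            emit(records_to_frame(contrast), f"contrast_{a}_vs_{b}.tsv")
        except ValueError as exc:
            logger.warning("cross-cohort contrast skipped: %s", exc)

    manifest["outputs"] = sorted(set(outputs))
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
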