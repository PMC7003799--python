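"""End-to-end orchestration: inputs (or a simulated survey) -> report.

Stage order mirrors the analysis the package implements: taxonomy
exclusions -> low-count filter -> host-clade removal -> rarefaction to the
minimum depth -> replicate pooling -> taxonomic/phylogenetic dissimilarity
and distance-decay -> alphaNTI / betaNTI null models with t-tests ->
functional decay and the module Venn partition.  A manifest records every
parameter and derived seed so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as cio
from . import dissimilarity as dis
from . import functional as fn
from . import phylo_null as pn
from . import synthetic as syn

__all__ = ["RunConfig", "RunReport", "PipelineError", "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    inputs: dict | None = None  # paths: otu_table, taxonomy, tree, coordinates, ...
    simulate: dict | None = None  # AssemblyConfig field overrides
    excluded_terms: list[str] = field(
        default_factory=lambda: sorted(cio.DEFAULT_EXCLUDED_TERMS)
    )
    min_total: int = 100
    group_term: str = "Cyanobacteria"
    n_null: int = pn.DEFAULT_N_NULL
    abundance_weighted: bool = False
    unifrac_normalized: bool = True
    earth_radius_km: float = dis.EARTH_RADIUS_KM
    pool_mode: str = "sum"  # or "mean"

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be given")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)


def derive_seeds(seed: int) -> dict[str, int]:
    """Expand the run seed into independent per-stage seeds (< 2^31)."""
    names = ("simulate", "rarefy", "alpha", "beta")
    spawned = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, spawned)}


def validate_inputs(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    tree=None,
    geo: pd.DataFrame | None = None,
    replicate_map: dict[str, str] | None = None,
) -> list[str]:
    """Cross-check identifiers between inputs; empty list iff consistent."""
    issues: list[str] = []
    if taxonomy is not None:
        for t in table.columns:
            if t not in taxonomy.index:
                issues.append(f"taxon {t!r} missing from taxonomy")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        for t in table.columns:
            if t not in tips:
                issues.append(f"taxon {t!r} missing from tree")
    if geo is not None:
        sites = (
            set(replicate_map.values()) if replicate_map else set(map(str, table.index))
        )
        for s in sorted(sites - set(map(str, geo.index))):
            issues.append(f"site {s!r} missing from coordinates")
    if replicate_map is not None:
        for s in table.index:
            if s not in replicate_map:
                issues.append(f"sample {s!r} missing from replicate map")
    return issues


@dataclass
class RunReport:
    """Headline numbers of one pipeline run (details are on disk)."""

    output_dir: str
    n_taxa_raw: int
    n_taxa_filtered: int
    rarefaction_depth: int
    mean_alpha_nti: float
    alpha_t: float
    alpha_p: float
    mean_beta_nti: float
    beta_t: float
    beta_p: float
    alpha_classifications: dict[str, int]
    bray_decay: dis.DecayFit
    unifrac_decay: dis.DecayFit
    functional_decay: dis.DecayFit | None
    venn_counts: dict[str, int] | None


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def _load_inputs(paths: dict):
    table = cio.read_otu_table(paths["otu_table"])
    taxonomy = cio.read_taxonomy(paths["taxonomy"])
    tree = cio.read_tree(paths["tree"])
    geo = cio.read_coordinates(paths["coordinates"])
    if "replicate_map" in paths:
        rep = pd.read_csv(paths["replicate_map"], sep="\t", dtype=str)
        replicate_map = dict(zip(rep.iloc[:, 0], rep.iloc[:, 1]))
    else:
        replicate_map = {s: s for s in table.index}
    host_ko = fn.read_ko_table(paths["host_ko"]) if "host_ko" in paths else None
    micro_ko = (
        fn.read_ko_table(paths["microbiome_ko"]) if "microbiome_ko" in paths else None
    )
    modules = fn.parse_module_defs(paths["modules"]) if "modules" in paths else None
    return table, taxonomy, tree, geo, replicate_map, host_ko, micro_ko, modules


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    counts_log: dict[str, int] = {}

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = syn.AssemblyConfig(**{"seed": seeds["simulate"], **config.simulate})
        truth = syn.simulate_survey(sim_cfg)
        syn.write_bundle(truth, out / "inputs")
        table, taxonomy, tree, geo = (
            truth.communities,
            truth.taxonomy,
            truth.tree,
            truth.coordinates,
        )
        replicate_map = truth.replicate_map
        host_ko, micro_ko = truth.host_ko, truth.microbiome_ko
        modules = truth.host_modules + truth.shared_modules + truth.microbiome_modules
    else:
        try:
            (table, taxonomy, tree, geo, replicate_map, host_ko, micro_ko, modules) = (
                _load_inputs(config.inputs)
            )
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc

    issues = validate_inputs(table, taxonomy, geo=geo, replicate_map=replicate_map)
    if issues:
        raise PipelineError("validate", "; ".join(issues[:5]))
    counts_log["taxa_raw"] = table.shape[1]
    counts_log["samples_raw"] = table.shape[0]

    # --- filter chain -----------------------------------------------------
    try:
        raw_taxa = set(table.columns)
        table = cio.filter_by_taxonomy(table, taxonomy, config.excluded_terms)
        counts_log["taxa_after_exclusions"] = table.shape[1]
        dropped_by_lineage = raw_taxa - set(table.columns)
        table = cio.filter_low_abundance(table, config.min_total)
        counts_log["taxa_after_low_count"] = table.shape[1]
        before_group = set(table.columns)
        table = cio.remove_group(table, taxonomy, config.group_term)
        counts_log["taxa_after_group_removal"] = table.shape[1]
        dropped_by_lineage |= before_group - set(table.columns)
        depth = int(table.sum(axis=1).min())
        table = cio.rarefy(table, "min", seed=seeds["rarefy"])
        counts_log["taxa_after_rarefaction"] = table.shape[1]
        pooled = cio.pool_replicates(table, replicate_map)
        if config.pool_mode == "mean":
            reps = pd.Series(replicate_map).value_counts()
            pooled = pooled.div(reps[pooled.index], axis=0)
        counts_log["sites"] = pooled.shape[0]
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    remaining = validate_inputs(pooled, tree=tree)
    if remaining:
        raise PipelineError("filter", "; ".join(remaining[:5]))
    # Null models run against the supplied phylogeny minus lineage-excluded
    # taxa (the regional pool); UniFrac uses the table-pruned tree, where
    # extra zero-abundance branches would contribute nothing anyway.
    keep = [t.name for t in tree.tips() if t.name not in dropped_by_lineage]
    null_tree = tree.shear(keep)
    null_tree.prune()
    union_tree = cio.prune_tree_to_table(tree, pooled)
    cio.write_otu_table(pooled, out / "pooled_table.tsv")
    cio.write_tree(union_tree, out / "pruned_tree.nwk")

    # --- dissimilarity and distance-decay ---------------------------------
    try:
        bray = dis.bray_curtis(pooled)
        unifrac = dis.weighted_unifrac(
            pooled, union_tree, normalized=config.unifrac_normalized
        )
        geodist = dis.great_circle_distances(
            geo.loc[pooled.index], radius_km=config.earth_radius_km
        )
        bray_fit = dis.distance_decay_glm(geodist, bray)
        uf_fit = dis.distance_decay_glm(geodist, unifrac)
    except Exception as exc:
        raise PipelineError("dissimilarity", str(exc)) from exc
    bray.write(str(out / "bray_curtis.tsv"))
    unifrac.write(str(out / "weighted_unifrac.tsv"))
    geodist.write(str(out / "geographic_km.tsv"))

    # --- phylogenetic null models -----------------------------------------
    try:
        alpha = pn.alpha_nti(
            pooled,
            null_tree,
            n_null=config.n_null,
            abundance_weighted=config.abundance_weighted,
            seed=seeds["alpha"],
        )
        alpha_t, alpha_p = pn.index_t_test(
            alpha.indices, alpha.standardized_null_indices()
        )
        beta = pn.beta_nti(
            pooled,
            null_tree,
            n_null=config.n_null,
            abundance_weighted=config.abundance_weighted,
            seed=seeds["beta"],
        )
        beta_t, beta_p = pn.index_t_test(
            beta.pair_indices, beta.standardized_null_indices()
        )
    except Exception as exc:
        raise PipelineError("phylo_null", str(exc)) from exc
    alpha_summary = alpha.summary()
    with open(out / "alpha_nti.tsv", "w", encoding="utf-8", newline="\n") as fh:
        alpha_summary.to_csv(fh, sep="\t", lineterminator="\n")
    with open(out / "beta_nti.tsv", "w", encoding="utf-8", newline="\n") as fh:
        beta.summary().to_csv(fh, sep="\t", index=False, lineterminator="\n")

    # --- functional profile ------------------------------------------------
    func_fit = None
    venn_counts = None
    if micro_ko is not None:
        try:
            func_fit, func_bray = fn.functional_decay(
                micro_ko, geo.loc[micro_ko.index], radius_km=config.earth_radius_km
            )
            func_bray.write(str(out / "functional_bray_curtis.tsv"))
        except Exception as exc:
            raise PipelineError("functional", str(exc)) from exc
    venn = None
    if host_ko is not None and micro_ko is not None and modules:
        host_complete = fn.complete_modules(fn.ko_presence(host_ko), modules)
        micro_complete = fn.complete_modules(fn.ko_presence(micro_ko), modules)
        venn = {k: sorted(v) for k, v in fn.venn_partition(host_complete, micro_complete).items()}
        venn_counts = {k: len(v) for k, v in venn.items()}
        _write_json(venn, out / "module_venn.json")

    # --- report and manifest ----------------------------------------------
    decays = {
        "bray_curtis": asdict(bray_fit),
        "weighted_unifrac": asdict(uf_fit),
    }
    if func_fit is not None:
        decays["functional_bray_curtis"] = asdict(func_fit)
    _write_json(decays, out / "decay_fits.json")
    classes = alpha_summary["classification"].value_counts().to_dict()
    report = RunReport(
        output_dir=str(out),
        n_taxa_raw=counts_log["taxa_raw"],
        n_taxa_filtered=counts_log["taxa_after_rarefaction"],
        rarefaction_depth=depth,
        mean_alpha_nti=float(np.nanmean(alpha.indices)),
        alpha_t=alpha_t,
        alpha_p=alpha_p,
        mean_beta_nti=float(np.nanmean(beta.pair_indices)),
        beta_t=beta_t,
        beta_p=beta_p,
        alpha_classifications=classes,
        bray_decay=bray_fit,
        unifrac_decay=uf_fit,
        functional_decay=func_fit,
        venn_counts=venn_counts,
    )
    manifest = {
        "config": {
            k: v for k, v in asdict(config).items() if k not in ("inputs", "simulate")
        },
        "inputs": config.inputs,
        "simulate": config.simulate,
        "derived_seeds": seeds,
        "stage_counts": counts_log,
        "rarefaction_depth": depth,
        "report": {
            k: (asdict(v) if isinstance(v, dis.DecayFit) else v)
            for k, v in asdict(report).items()
        },
    }
    _write_json(manifest, out / "manifest.json")
    return report
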