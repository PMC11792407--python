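"""End-to-end orchestration: simulate -> prep -> heterosis -> per-group
networks -> consensus -> preservation -> gene action -> enrichment.

A single YAML/dict config drives every stage; the global seed feeds all
stochastic stages, so a rerun with the same config and seed reproduces every
output byte for byte. Each run writes a manifest (stage, file, sha256).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons_mod
from . import enrichment as enr_mod
from . import gene_action as ga_mod
from . import heterosis as het_mod
from . import io as io_mod
from . import prep as prep_mod
from . import preservation as pres_mod
from .containers import CROSSES, GROUPS
from .network import CoexpressionModules, module_trait_correlation
from .simulate import SimulationSpec, simulate_expression, simulate_phenotypes

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "prep", "heterosis", "network", "consensus",
                  "preservation", "classify", "enrichment")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    """Pre-flight validation; raises before any output is written."""
    stages = config.get("stages", list(DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
    has_sim = "simulate" in stages
    inputs = config.get("inputs", {})
    if not has_sim:
        for key in ("fpkm", "metadata"):
            if key not in inputs:
                raise ValueError(f"without the simulate stage, inputs.{key} is required")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(inputs[key])
        if "heterosis" in stages and "phenotypes" not in inputs:
            raise ValueError("heterosis stage enabled but inputs.phenotypes missing")
        if "heterosis" in stages and not Path(inputs["phenotypes"]).exists():
            raise FileNotFoundError(inputs["phenotypes"])
    gmt = config.get("enrichment", {}).get("gmt")
    if gmt is not None and not Path(gmt).exists():
        raise FileNotFoundError(gmt)
    for cross in config.get("classify", {}).get("crosses", []):
        if cross not in CROSSES:
            raise ValueError(f"unknown cross {cross!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_traits(phenotypes: pd.DataFrame, group: str, samples: pd.DataFrame,
                  n_stages: int) -> pd.DataFrame:
    """Per-sample trait values for one group: each laying stage inherits the
    group's mean phenotype over its block of 4-week windows."""
    sub = phenotypes[phenotypes["group"] == group]
    windows = np.array(sorted(sub["window"].unique()))
    blocks = np.array_split(windows, n_stages)
    traits = {}
    for trait in ("egg_number", "oviduct_length", "body_weight"):
        if trait not in sub.columns:
            continue
        per_stage = {}
        for s, block in enumerate(blocks, start=1):
            per_stage[s] = sub.loc[sub["window"].isin(block), trait].mean()
        traits[trait] = samples["stage"].map(per_stage)
    return pd.DataFrame(traits, index=samples.index)


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Run the configured stages; returns the manifest dict."""
    validate_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = config.get("stages", list(DEFAULT_STAGES))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": list(stages), "files": []}

    def record(stage: str, path: Path):
        manifest["files"].append({"stage": stage, "file": str(path.relative_to(outdir)),
                                  "sha256": _sha256(Path(path))})

    def save(stage: str, frame: pd.DataFrame, name: str, index=False) -> Path:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
        record(stage, path)
        return path

    fpkm = None
    phenotypes = None
    truth = None

    if "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        sim_cfg["seed"] = seed
        spec = SimulationSpec(**sim_cfg)
        logger.info("simulate: %d genes, %d modules, seed %d",
                    spec.n_genes, spec.n_modules, seed)
        phenotypes, ph_truth = simulate_phenotypes(spec)
        sim = simulate_expression(spec)
        fpkm, truth = sim.fpkm, sim.truth
        truth.heterosis_by_window = ph_truth.heterosis_by_window
        for role, path in io_mod.write_expression(sim.fpkm, outdir, "expression").items():
            record("simulate", path)
        counts_path = outdir / "expression_counts.tsv"
        sim.counts.values.to_csv(counts_path, sep="\t", index_label="gene")
        record("simulate", counts_path)
        record("simulate", io_mod.write_phenotypes(phenotypes, outdir / "phenotypes.csv"))
        record("simulate", io_mod.write_truth(truth, outdir / "truth.json"))
    else:
        inputs = config["inputs"]
        fpkm = io_mod.read_expression(inputs["fpkm"], inputs["metadata"],
                                      kind="fpkm")
        if "phenotypes" in inputs:
            phenotypes = io_mod.read_phenotypes(inputs["phenotypes"])

    if "prep" in stages:
        p_cfg = config.get("prep", {})
        filtered = prep_mod.filter_expressed(
            fpkm, fpkm_min=p_cfg.get("fpkm_min", 0.1),
            frac_samples=p_cfg.get("frac_samples", 0.30))
        logger.info("prep: %d/%d genes pass the expressed filter",
                    filtered.n_genes, fpkm.n_genes)
        coords, var_frac = prep_mod.sample_pca(filtered)
        save("prep", coords.assign(var_frac=pd.Series(
            dict(zip(coords.columns, var_frac)))).reset_index()
            .rename(columns={"index": "sample"}), "sample_pca.tsv")
        save("prep", prep_mod.pairwise_sample_correlation(filtered).reset_index(),
             "sample_correlation.tsv")
        fpkm = filtered

    if "heterosis" in stages and phenotypes is not None:
        h_cfg = config.get("heterosis", {})
        frames = []
        for cross in h_cfg.get("crosses", list(CROSSES)):
            frames.append(het_mod.heterosis_by_window(
                phenotypes, cross=cross, trait=h_cfg.get("trait", "egg_number")))
        save("heterosis", pd.concat(frames, ignore_index=True), "heterosis.tsv")

    networks = {}
    group_data = {}
    n_cfg = config.get("network", {})
    net_groups = n_cfg.get("groups", list(GROUPS))
    if "network" in stages or "consensus" in stages or "preservation" in stages:
        top_mad = config.get("prep", {}).get("top_mad", 0.5)
        for group in net_groups:
            sub = fpkm.for_group(group)
            group_data[group] = prep_mod.select_top_mad(sub, top_frac=top_mad)

    if "network" in stages:
        for group in net_groups:
            model = CoexpressionModules(
                power=n_cfg.get("power"),
                min_module_size=n_cfg.get("min_module_size", 50),
                detect_cut_height=n_cfg.get("detect_cut_height", 0.995),
                merge_cut_height=n_cfg.get("merge_cut_height", 0.25),
                rsq_target=n_cfg.get("rsq_target", 0.8),
            ).fit(group_data[group])
            networks[group] = model
            logger.info("network %s: power %d, %d modules", group, model.power_,
                        model.eigengenes_.shape[1])
            save("network", model.labels_.rename("module").reset_index(),
                 f"network_{group}_modules.tsv")
            save("network", model.eigengenes_.reset_index()
                 .rename(columns={"index": "sample"}),
                 f"network_{group}_eigengenes.tsv")
            if not model.scale_free_table_.empty:
                save("network", model.scale_free_table_,
                     f"network_{group}_softthreshold.tsv")
            if phenotypes is not None and model.eigengenes_.shape[1] > 0:
                traits = _stage_traits(phenotypes, group,
                                       group_data[group].meta,
                                       int(fpkm.meta["stage"].max()))
                save("network", module_trait_correlation(model.eigengenes_, traits),
                     f"network_{group}_trait_correlation.tsv")

    cm_labels = None
    group_mes = None
    if "consensus" in stages:
        c_cfg = config.get("consensus", {})
        c_groups = c_cfg.get("groups", net_groups[:3])
        common = None
        for g in c_groups:
            idx = group_data[g].genes
            common = idx if common is None else common.intersection(idx)
        datasets = {g: group_data[g].subset_genes(common) for g in c_groups}
        cc = cons_mod.ConsensusConfig(
            power=c_cfg.get("power", 12),
            min_module_size=c_cfg.get("min_module_size", 50),
            detect_cut_height=c_cfg.get("detect_cut_height", 0.995),
            merge_cut_height=c_cfg.get("merge_cut_height", 0.25),
            deep_split=c_cfg.get("deep_split", 2))
        partition, group_mes = cons_mod.detect_consensus_modules(datasets, cc)
        cm_labels = partition.labels
        save("consensus", cm_labels.rename("cm").reset_index(),
             "consensus_modules.tsv")
        for g, mes in group_mes.items():
            save("consensus", mes.reset_index().rename(columns={"index": "sample"}),
                 f"consensus_eigengenes_{g}.tsv")
        kme, hubs = cons_mod.kme_and_hubs(
            datasets, cm_labels, kme_min=c_cfg.get("kme_min", 0.70),
            p_max=c_cfg.get("p_max", 1e-5), group_mes=group_mes)
        save("consensus", kme, "consensus_kme.tsv")
        hub_rows = [{"group": g, "n_hubs": len(s)} for g, s in hubs.per_group.items()]
        hub_rows.append({"group": "shared", "n_hubs": len(hubs.shared)})
        save("consensus", pd.DataFrame(hub_rows), "consensus_hub_counts.tsv")
        if networks:
            overlaps = []
            for g in c_groups:
                if g in networks:
                    ov = cons_mod.module_overlap_fisher(
                        cm_labels, networks[g].labels_, universe=common)
                    ov["group"] = g
                    overlaps.append(ov)
            if overlaps:
                save("consensus", pd.concat(overlaps, ignore_index=True),
                     "consensus_module_overlap.tsv")

    if "preservation" in stages:
        pv_cfg = config.get("preservation", {})
        ref = pv_cfg.get("reference", net_groups[0])
        tests = pv_cfg.get("tests", [g for g in net_groups if g != ref])
        ref_labels = (networks[ref].labels_ if ref in networks
                      else cm_labels)
        if ref_labels is None:
            raise ValueError("preservation needs the network or consensus stage")
        reports = []
        for g in tests:
            rep = pres_mod.module_preservation(
                group_data[ref], ref_labels, group_data[g],
                power=networks[ref].power_ if ref in networks
                else pv_cfg.get("power", 6),
                n_perm=pv_cfg.get("n_perm", 100), seed=seed)
            rep["test_group"] = g
            reports.append(rep)
        save("preservation", pd.concat(reports, ignore_index=True),
             "preservation.tsv")

    calls = None
    if "classify" in stages:
        g_cfg = config.get("classify", {})
        frames = []
        for cross in g_cfg.get("crosses", list(CROSSES)):
            c = ga_mod.classify_expression(fpkm, cross,
                                           fdr=g_cfg.get("fdr", 0.05))
            frames.append(c)
        calls = pd.concat(frames, ignore_index=True)
        save("classify", calls, "gene_action_calls.tsv")
        counts, transitions = ga_mod.dominance_complementarity_summary(calls)
        save("classify", counts, "gene_action_stage_counts.tsv")
        save("classify", transitions, "gene_action_transitions.tsv")

    if "enrichment" in stages:
        e_cfg = config.get("enrichment", {})
        universe = list(fpkm.genes)
        if e_cfg.get("gmt"):
            sets = io_mod.read_gmt(e_cfg["gmt"])
        elif truth is not None:
            sets = {}
            for gene, module in truth.gene_module.items():
                sets.setdefault(f"planted_{module}", []).append(gene)
        else:
            sets = {}
        if sets:
            collection = enr_mod.GeneSetCollection(sets=sets, universe=universe)
            if cm_labels is not None:
                biggest = cm_labels[cm_labels != "grey"].value_counts().idxmax()
                query = list(cm_labels.index[cm_labels == biggest])
            else:
                query = universe[: max(len(universe) // 10, 5)]
            result = enr_mod.hypergeometric_enrichment(
                query, collection, alpha=e_cfg.get("alpha", 0.05),
                min_gene_ratio=e_cfg.get("min_gene_ratio"))
            save("enrichment", result, "enrichment.tsv")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
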