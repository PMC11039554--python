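"""End-to-end pipeline driver: simulate/load -> iSCN -> topology ->
harmonize -> group stats -> NBS -> classification -> clinical association.

Every stage draws its randomness from a stream derived deterministically
from the master seed, so a fixed spec + seed reproduces every output
table bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from iscn import classify as clf
from iscn import inference
from iscn.cohort import phenotype_frame, stage_timer, write_phenotype
from iscn.config import RunConfig
from iscn.harmonize import combat
from iscn.network import build_cohort_networks, edge_names, edge_vector
from iscn.simulate import SimulationSpec, default_assignment, simulate_cohort
from iscn.topology import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    profiles_frame,
    select_threshold_range,
    topology_profile,
)

STAGE_NAMES = ("simulate", "threshold", "topology", "nbs", "classify")


def _stage_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGE_NAMES))
    return {name: int(s % (2**31 - 1)) for name, s in zip(STAGE_NAMES, states)}


def run_all(spec: SimulationSpec, config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-cohort pipeline and write result tables.

    Writes TSV tables (phenotype, edge features, topology profiles,
    harmonized features, GLM results, clinical associations), JSON for
    NBS components and classification reports, and the ground-truth
    record, all under ``outdir``.  Returns the in-memory results dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    with stage_timer("simulate cohort"):
        spec = dataclasses.replace(spec, seed=seeds["simulate"])
        cohort, phenotype, truth = simulate_cohort(spec)
        pheno = phenotype_frame(phenotype)
        write_phenotype(phenotype, outdir / "phenotype.tsv")
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    with stage_timer(f"build {len(cohort)} iSCNs"):
        networks = build_cohort_networks(cohort, kde_points=config.kde_points)
        region_ids = networks[0].region_ids
        edges = pd.DataFrame(
            np.array([edge_vector(n) for n in networks]),
            index=pheno["subject_id"],
            columns=edge_names(region_ids),
        )
        edges.to_csv(outdir / "edges.tsv", sep="\t")

    with stage_timer("select density range"):
        if config.density_range == "auto":
            k_min, k_max = select_threshold_range(
                networks,
                floor=config.small_world_floor,
                n_random=config.n_random,
                seed=seeds["threshold"],
            )
            step = 1
        else:
            k_min, k_max, step = config.density_range

    with stage_timer(f"topology profiles over K={k_min}..{k_max}"):
        profiles = [
            topology_profile(
                net,
                (k_min, k_max),
                step=step,
                n_random=config.n_random,
                seed=seeds["topology"],
                subject_index=i,
            )
            for i, net in enumerate(networks)
        ]
        topo = profiles_frame(profiles, region_ids)
        topo.to_csv(outdir / "topology_profiles.tsv", sep="\t")

    with stage_timer("harmonize"):
        preserve = ["group"] + list(config.covariates)
        # drop metrics undefined (NaN) or degenerate (infinite sigma on
        # triangle-free surrogates) for any subject
        topo_clean = topo.replace([np.inf, -np.inf], np.nan).dropna(axis=1)
        topo_h = combat(topo_clean.reset_index(drop=True), pheno, preserve=preserve)
        topo_h.index = topo.index
        edges_h = combat(edges.reset_index(drop=True), pheno, preserve=preserve)
        edges_h.index = edges.index
        topo_h.to_csv(outdir / "topology_harmonized.tsv", sep="\t")
        edges_h.to_csv(outdir / "edges_harmonized.tsv", sep="\t")

    with stage_timer("group GLM on topology"):
        glob_cols = [f"{m}_auc" for m in GLOBAL_METRICS if f"{m}_auc" in topo_h.columns]
        glm_tables = [
            inference.glm_compare(
                topo_h[glob_cols], pheno, config.covariates, family=len(glob_cols)
            )
        ]
        for m in NODAL_METRICS:
            cols = [c for c in topo_h.columns if c.startswith(f"{m}_auc_r")]
            glm_tables.append(
                inference.glm_compare(topo_h[cols], pheno, config.covariates, family=len(cols))
            )
        glm_topo = pd.concat(glm_tables)
        glm_topo.to_csv(outdir / "group_topology.tsv", sep="\t")

    with stage_timer(f"NBS ({config.nbs_permutations} permutations)"):
        nbs_res = inference.nbs(
            edges_h,
            pheno,
            covariates=config.covariates,
            region_ids=region_ids,
            edge_p=config.nbs_edge_p,
            n_perm=config.nbs_permutations,
            alpha=config.nbs_alpha,
            seed=seeds["nbs"],
        )
        assignment = default_assignment(spec.n_regions)
        nbs_json = {}
        for direction, res in nbs_res.items():
            nbs_json[direction] = [
                {
                    "nodes": c.nodes,
                    "edges": [list(e) for e in c.edges],
                    "size": c.size,
                    "p": c.p,
                    "significant": c.significant,
                    "network_weights": inference.summarize_networks(c, assignment)[
                        "weights"
                    ].to_dict()
                    if c.significant
                    else None,
                }
                for c in res.components
            ]
        (outdir / "nbs.json").write_text(json.dumps(nbs_json, indent=1))

    with stage_timer("classification"):
        reports = {}
        for feature_set, table in (("topology", topo_h), ("connectivity", edges_h)):
            rep = clf.svm_classify(
                table,
                pheno["group"].to_numpy(),
                folds=config.cv_folds,
                seed=seeds["classify"],
                feature_set=feature_set,
            )
            top10 = clf.map_region_contributions(rep.mean_abs_weight, feature_set)
            reports[feature_set] = {"report": rep, "top_regions": top10}
        (outdir / "classification.json").write_text(
            json.dumps(
                {
                    k: {
                        **v["report"].as_dict(),
                        "top_regions": v["top_regions"].to_dict("records"),
                    }
                    for k, v in reports.items()
                },
                indent=1,
            )
        )

    with stage_timer("clinical association"):
        patients = pheno["group"] == "patient"
        clin = None
        if pheno.loc[patients, "hamd17"].notna().any():
            clin_topo = inference.clinical_association(
                topo_h.loc[patients.to_numpy()].reset_index(drop=True),
                pheno.loc[patients].reset_index(drop=True),
                covariates=config.covariates,
            )
            clin_edges = inference.clinical_association(
                edges_h.loc[patients.to_numpy()].reset_index(drop=True),
                pheno.loc[patients].reset_index(drop=True),
                covariates=config.covariates,
            )
            clin = pd.concat(
                [clin_topo.assign(family="topology"), clin_edges.assign(family="connectivity")]
            )
            clin.to_csv(outdir / "clinical_association.tsv", sep="\t")

    return {
        "phenotype": pheno,
        "truth": truth,
        "networks": networks,
        "edges": edges,
        "threshold_range": (k_min, k_max),
        "topology": topo,
        "topology_harmonized": topo_h,
        "edges_harmonized": edges_h,
        "glm_topology": glm_topo,
        "nbs": nbs_res,
        "classification": reports,
        "clinical": clin,
    }
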