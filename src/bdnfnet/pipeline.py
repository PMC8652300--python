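"""Stage orchestration: simulate -> network -> score -> adversity -> irt ->
growth -> pica, with per-stage TSV/JSON outputs, a QC-style log of record
counts, and a JSON manifest recording seed, versions and parameters.

Stages communicate through files in the output directory, so any stage can
be rerun alone provided its upstream outputs exist; a missing upstream file
raises an error naming the stage to run first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, adversity as adv_mod, eprs, genio, growth as growth_mod, irt as irt_mod, network as net_mod, pica as pica_mod, simulate as sim_mod

log = logging.getLogger("bdnfnet")

STAGE_ORDER = ["simulate", "build-network", "score", "adversity", "irt",
               "growth", "pica"]


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path}; run the '{stage}' stage first")
    return path


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, out: Path) -> None:
    seed = int(cfg["seed"])
    sim_cfg = cfg["simulate"]
    spec = sim_mod.SimulationSpec(
        seed=seed,
        n_children=int(sim_cfg["n_children"]),
        visit_ages=tuple(sim_cfg["visit_ages"]),
        n_imaging=int(sim_cfg["n_imaging"]),
    )
    data_dir = out / "dataset"
    data_dir.mkdir(parents=True, exist_ok=True)

    ref = sim_mod.gen_reference_tables(spec.network, seed)
    G, geno_truth = sim_mod.gen_genotypes(
        spec.genotype, spec.n_children, seed, variants=ref["variant_plan"])
    genio.write_plink(G, data_dir / "genotypes")
    genio.write_vcf(G, data_dir / "genotypes.vcf")
    for name in ("coexpression", "homolog", "stage_expression", "annotation",
                 "weights_ref"):
        ref[name].to_csv(data_dir / f"{name}.tsv", sep="\t", index=False)

    cohort, cohort_truth = sim_mod.gen_cohort(spec, seed)
    cohort.to_csv(data_dir / "cohort.tsv", sep="\t", index=False)
    adv_tab, adv_truth = sim_mod.gen_adversity_records(
        spec.adversity, spec.n_children, seed)
    adv_tab.to_csv(data_dir / "adversity_records.tsv", sep="\t", index=False)

    # item responses: abilities are an affine map of the cohort outcome
    y = cohort["cognition"].to_numpy()
    mu, sd = float(y.mean()), float(y.std())
    theta = (y - mu) / sd * 2.0
    form = np.array([list(spec.visit_ages).index(a) for a in cohort["age"]])
    R, irt_truth = sim_mod.gen_bayley_responses(spec.irt, theta, form, seed)
    long = (
        pd.DataFrame(R.responses, index=cohort["child_id"].astype(str) + "@"
                     + cohort["age"].astype(int).astype(str).str.zfill(2),
                     columns=R.item_ids)
        .rename_axis("person_id").reset_index()
        .melt(id_vars="person_id", var_name="item_id", value_name="response")
        .dropna()
    )
    long.to_csv(data_dir / "responses.tsv", sep="\t", index=False)
    forms = pd.DataFrame(
        [{"item_id": i, "form": f} for i, fs in R.item_forms.items() for f in sorted(fs)])
    forms.to_csv(data_dir / "forms.tsv", sep="\t", index=False)

    img_children = cohort_truth["imaging_children"]
    fspec = dataclasses.replace(spec.fusion, n_subjects=spec.n_imaging)
    X1, V, fusion_truth = sim_mod.gen_fusion_data(fspec, seed)
    V.subject_ids = list(img_children)
    genio.write_gray_matter(V, data_dir / "gm")
    pd.DataFrame(X1, index=img_children,
                 columns=[f"snp{j}" for j in range(X1.shape[1])]) \
        .rename_axis("subject_id").to_csv(data_dir / "fusion_genetics.tsv", sep="\t")

    truth = {
        "seed": seed,
        "ability_transform": {"slope": sd / 2.0, "intercept": mu},
        "genotypes": {k: v for k, v in geno_truth.items()},
        "network": ref["truth"],
        "cohort": {k: v for k, v in cohort_truth.items()
                   if k not in ("random_effects",)},
        "adversity_totals": adv_truth["totals"],
        "fusion": {"rho": fusion_truth["rho"],
                   "linked_pair": list(fusion_truth["linked_pair"])},
        "irt": {"b": irt_truth["b"]},
    }
    _write_json(truth, data_dir / "truth.json")
    log.info("simulate: %d children, %d variants, %d imaging subjects",
             spec.n_children, G.n_variants, spec.n_imaging)


def stage_network(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    p = cfg["network"]
    coexpr = pd.read_csv(_need(d / "coexpression.tsv", "simulate"), sep="\t",
                         keep_default_na=False)
    homolog = pd.read_csv(d / "homolog.tsv", sep="\t", keep_default_na=False)
    stage = pd.read_csv(d / "stage_expression.tsv", sep="\t", keep_default_na=False)
    ann = pd.read_csv(d / "annotation.tsv", sep="\t", keep_default_na=False)

    sel = net_mod.select_coexpressed(coexpr, rmin=float(p["rmin"]))
    mapped, map_report = net_mod.map_to_homologs(sel, homolog)
    enriched, enr_report = net_mod.filter_stage_enrichment(
        mapped, stage, fold=float(p["fold"]))
    net = net_mod.annotate_intervals(enriched, ann, flank=int(p["flank"]))
    net.table.to_csv(out / "network.tsv", sep="\t", index=False)
    report = {
        "n_input_genes": int(len(coexpr)),
        "n_coexpressed": int(len(sel)),
        "homolog": map_report,
        "enrichment": enr_report,
        "n_network_genes": int(len(net.table)),
        "params": p,
    }
    _write_json(report, out / "network_report.json")
    log.info("network: %d -> %d coexpressed -> %d enriched",
             len(coexpr), len(sel), len(net.table))


def stage_score(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    p = cfg["score"]
    G = genio.read_genotypes(_need(d / "genotypes.bed", "simulate").with_suffix(""),
                             format="plink")
    net_tab = pd.read_csv(_need(out / "network.tsv", "build-network"), sep="\t",
                          keep_default_na=False, dtype={"chrom": str})
    network = net_mod.GeneNetwork(net_tab, flank=int(cfg["network"]["flank"]))
    weights_ref = pd.read_csv(d / "weights_ref.tsv", sep="\t", keep_default_na=False)

    Gq, report = eprs.qc_genotypes(
        G, snp_call_rate=float(p["snp_call_rate"]),
        hwe_floor=float(p["hwe_floor"]), maf_min=float(p["maf_min"]),
        sample_call_rate=float(p["sample_call_rate"]))
    table = eprs.assign_snps(Gq, network, weights_ref)
    clumped = eprs.ld_clump(Gq, table, r2_max=float(p["clump_r2"]),
                            window=int(p["clump_window"]))
    scores = eprs.compute_eprs(Gq, clumped)
    pcs = eprs.stratification_pca(
        Gq, maf_min=float(p["pca_maf_min"]), prune_r2=float(p["pca_prune_r2"]),
        window_kb=int(p["pca_window_kb"]), step=int(p["pca_step"]),
        k=int(p["pca_k"]))

    clumped.to_csv(out / "weight_table.tsv", sep="\t", index=False)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    pc_df = pd.DataFrame(pcs.scores,
                         columns=[f"pc{i+1}" for i in range(pcs.scores.shape[1])])
    pc_df.insert(0, "sample_id", Gq.sample_ids)
    pc_df.to_csv(out / "pca.tsv", sep="\t", index=False)
    qc = report.as_dict()
    qc.update({"n_assigned": int(len(table)), "n_clumped": int(len(clumped))})
    _write_json(qc, out / "qc_report.json")
    log.info("score: %d variants -> %d after QC -> %d assigned -> %d clumped",
             G.n_variants, report.n_variants_out, len(table), len(clumped))


def stage_adversity(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    tab = pd.read_csv(_need(d / "adversity_records.tsv", "simulate"), sep="\t")
    scored = adv_mod.score_cohort(tab, percentile_mode=bool(
        cfg["adversity"]["percentile_mode"]))
    labels, split = adv_mod.split_adversity_groups(scored["adversity"])
    scored["group"] = labels
    scored.to_csv(out / "adversity.tsv", sep="\t", index=False)
    _write_json(split, out / "adversity_split.json")
    log.info("adversity: n=%d, split low/high = %d/%d",
             len(scored), split["n_low"], split["n_high"])


def stage_irt(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    p = cfg["irt"]
    responses = pd.read_csv(_need(d / "responses.tsv", "simulate"), sep="\t")
    forms = pd.read_csv(d / "forms.tsv", sep="\t")
    R = irt_mod.ResponseMatrix.from_long(responses, forms)
    fit = irt_mod.fit_rasch_concurrent(
        R, tol=float(p["tol"]), max_iter=int(p["max_iter"]),
        extreme_adjust=float(p["extreme_adjust"]))
    report = irt_mod.separation_stats(fit)
    pd.DataFrame({"item_id": fit.item_ids, "difficulty": fit.b,
                  "se": fit.b_se}).to_csv(out / "difficulties.tsv", sep="\t", index=False)
    truth_path = d / "truth.json"
    slope, intercept = 1.0, 0.0
    if truth_path.exists():
        tr = json.loads(truth_path.read_text())["ability_transform"]
        slope, intercept = tr["slope"], tr["intercept"]
    scaled = irt_mod.rescale_abilities(fit, slope, intercept)
    abil = pd.DataFrame({"person_id": fit.person_ids, "theta": fit.theta,
                         "se": fit.theta_se})
    abil = abil.merge(scaled, on="person_id")
    abil.to_csv(out / "abilities.tsv", sep="\t", index=False)
    _write_json({**report.as_dict(), "converged": fit.converged,
                 "n_iter": fit.n_iter}, out / "scale_report.json")
    log.info("irt: %d persons, %d items, person reliability %.3f",
             len(fit.person_ids), len(fit.item_ids), report.person_reliability)


def stage_growth(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    p = cfg["growth"]
    if p["source"] == "cohort_table":
        data = pd.read_csv(_need(d / "cohort.tsv", "simulate"), sep="\t")
    else:
        data = _assemble_longitudinal(out)
    fit = growth_mod.fit_growth(data, random=p["random"],
                                compute_f2=bool(p["compute_f2"]))
    fit.coef_table().to_csv(out / "growth_coefficients.tsv", sep="\t", index=False)
    curves = growth_mod.predict_trajectories(fit)
    curves.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    _write_json({"marginal_r2": fit.marginal_r2,
                 "conditional_r2": fit.conditional_r2,
                 "phi": fit.phi, "sigma": fit.sigma,
                 "converged": fit.converged, "singular": fit.singular},
                out / "growth_report.json")
    log.info("growth: 3-way interaction = %.3f",
             fit["eprs_x_adversity_x_age"])


def _assemble_longitudinal(out: Path) -> pd.DataFrame:
    """Join IRT scaled abilities with scores, adversity, PCs and sex."""
    d = out / "dataset"
    abil = pd.read_csv(_need(out / "abilities.tsv", "irt"), sep="\t")
    scores = pd.read_csv(_need(out / "scores.tsv", "score"), sep="\t")
    adv = pd.read_csv(_need(out / "adversity.tsv", "adversity"), sep="\t")
    pcs = pd.read_csv(_need(out / "pca.tsv", "score"), sep="\t")
    cohort = pd.read_csv(_need(d / "cohort.tsv", "simulate"), sep="\t")
    parts = abil["person_id"].str.split("@", expand=True)
    abil = abil.assign(child_id=parts[0], age=parts[1].astype(float))
    sex = cohort[["child_id", "sex"]].drop_duplicates()
    adv = adv.rename(columns={"subject_id": "child_id"})
    adv["adversity_z"] = ((adv["adversity"] - adv["adversity"].mean())
                          / adv["adversity"].std(ddof=1))
    n = min(len(scores), len(adv))
    key = pd.DataFrame({"child_id": sorted(cohort["child_id"].unique())[:n]})
    key["eprs_z"] = scores["eprs_z"].to_numpy()[:n]
    data = (abil.rename(columns={"scaled": "cognition"})
            [["child_id", "age", "cognition"]]
            .merge(key, on="child_id")
            .merge(adv[["child_id", "adversity_z"]], on="child_id")
            .merge(sex, on="child_id"))
    pcs = pcs.rename(columns={"sample_id": "sample_idx"})
    pc_key = pd.DataFrame({"child_id": key["child_id"],
                           "pc1": pcs["pc1"][:n].to_numpy(),
                           "pc2": pcs["pc2"][:n].to_numpy(),
                           "pc3": pcs["pc3"][:n].to_numpy()})
    return data.merge(pc_key, on="child_id")


def stage_pica(cfg: dict, out: Path) -> None:
    d = out / "dataset"
    p = cfg["pica"]
    gen = pd.read_csv(_need(d / "fusion_genetics.tsv", "simulate"), sep="\t",
                      index_col="subject_id")
    gm_paths = sorted((d / "gm").glob("*.nii"))
    if not gm_paths:
        raise FileNotFoundError("missing gray-matter volumes; run 'simulate' first")
    V = genio.read_gray_matter(gm_paths, mask_threshold=float(p["mask_threshold"]))
    X1, X2 = gen.to_numpy(float), V.data
    k1 = pica_mod.estimate_order_mdl(X1)
    k2 = pica_mod.estimate_order_mdl(X2)
    result = pica_mod.fit_parallel_ica(
        X1, X2, k1, k2, lam=float(p["lam"]), seed=int(cfg["seed"]),
        max_iter=int(p["max_iter"]), tol=float(p["tol"]))

    adv = pd.read_csv(_need(out / "adversity.tsv", "adversity"), sep="\t")
    adv = adv.set_index("subject_id").reindex(gen.index)
    groups = adv["group"].to_numpy()
    tests = {}
    for mod_i, name in enumerate(("genetic", "brain")):
        A = result.loadings[mod_i]
        pd.DataFrame(A, index=gen.index,
                     columns=[f"{name}_ic{c+1}" for c in range(A.shape[1])]) \
            .to_csv(out / f"loadings_{name}.tsv", sep="\t")
        tests[name] = pica_mod.compare_groups(A, groups, welch=bool(p["welch"]))
    feats = []
    for c in range(k1):
        for j in pica_mod.threshold_component(result.sources_z[0][c],
                                              z_thresh=float(p["z_thresh"])):
            feats.append({"modality": "genetic", "component": c + 1,
                          "feature": gen.columns[j],
                          "z": float(result.sources_z[0][c][j])})
    coords = np.argwhere(V.mask)
    for c in range(k2):
        for j in pica_mod.threshold_component(result.sources_z[1][c],
                                              z_thresh=float(p["z_thresh"])):
            feats.append({"modality": "brain", "component": c + 1,
                          "feature": "voxel_" + "_".join(map(str, coords[j])),
                          "z": float(result.sources_z[1][c][j])})
    pd.DataFrame(feats).to_csv(out / "pica_features.tsv", sep="\t", index=False)
    best = np.unravel_index(np.argmax(np.abs(result.loading_corr)),
                            result.loading_corr.shape)
    _write_json({
        "k_genetic": k1, "k_brain": k2,
        "loading_corr": result.loading_corr,
        "loading_corr_p": result.loading_corr_p,
        "best_pair": [int(best[0]) + 1, int(best[1]) + 1],
        "best_pair_r": float(result.loading_corr[best]),
        "group_tests": tests,
        "converged": result.converged,
    }, out / "pica_report.json")
    log.info("pica: k=(%d,%d), best loading pair r=%.2f", k1, k2,
             result.loading_corr[best])


STAGES = {
    "simulate": stage_simulate,
    "build-network": stage_network,
    "score": stage_score,
    "adversity": stage_adversity,
    "irt": stage_irt,
    "growth": stage_growth,
    "pica": stage_pica,
}


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    from .config import dump_config, resolve_config

    cfg = resolve_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    dump_config(cfg, out / "config_resolved.yaml")
    ran = []
    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        STAGES[stage](cfg, out)
        ran.append(stage)
    manifest = {
        "seed": cfg["seed"],
        "stages_run": ran,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "parameters": {k: cfg[k] for k in
                       ("simulate", "network", "score", "adversity", "irt",
                        "growth", "pica")},
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*")
                          if p.is_file() and p.suffix in {".tsv", ".json", ".yaml"}),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
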