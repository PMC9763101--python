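"""End-to-end orchestration: simulate-or-load, preprocess, CRD calling
(cases / controls / combined), structure analysis, differential testing, QTL
passes, gene-CRD pairs, triplets and mechanism comparison, with a
deterministic run manifest.

Group-specific CRD calls feed the condition-specific structure analysis;
CRDs from the combined set feed everything downstream (differential, QTL,
pairs, triplets).  One master seed drives the run; each stage derives a
child seed from a stable hash of its name so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal, crd, differential, preprocess, qtl, structure, synthetic
from .io_formats import (
    read_genotypes,
    read_metadata,
    read_phenotype_bed,
    write_phenotype_bed,
    write_results_table,
)

log = logging.getLogger("crdscan")

DEFAULT_ANALYSIS = {
    "window": 1_000_000,
    "n_perm": 200,
    "fdr": 0.05,
    "maf_min": 0.05,
    "peak_corr_window": 250,
    "crd_factor": 2.0,
    "n_phenotype_pcs": 2,
    "n_genotype_pcs": 2,
    "bootstrap_b": 100,
    "accuracy_threshold": 0.55,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir) -> dict:
    """Run the full analysis described by ``config`` (dict or YAML path).

    Returns the manifest dict (also written to ``out_dir``/manifest.json);
    re-running with the same config and seed reproduces identical file
    checksums.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    a = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    manifest = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "analysis": a,
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage, counts, files):
        manifest["stages"][stage] = {
            "counts": counts,
            "outputs": {str(f.name): _sha256(f) for f in files},
        }
        for f in files:
            outputs[f.name] = f

    # ---- inputs --------------------------------------------------------
    if "simulate" in config:
        sim_cfg = synthetic.SimulationConfig(
            **{**config["simulate"], "seed": stage_seed(seed, "simulate")}
        )
        cohort = synthetic.simulate_cohort(sim_cfg)
        in_dir = out / "inputs"
        synthetic.write_cohort(cohort, in_dir)
        geno, peaks, genes = cohort.genotypes, cohort.peaks, cohort.genes
        peak_counts, gene_counts = cohort.peak_counts, cohort.gene_counts
        meta = cohort.metadata
        record("simulate", {"n_samples": geno.n_samples,
                            "n_variants": geno.n_variants,
                            "n_peaks": peaks.n_features,
                            "n_genes": genes.n_features},
               sorted(in_dir.glob("*")))
    elif "inputs" in config:
        paths = config["inputs"]
        geno = read_genotypes(paths["genotypes"])
        peaks = read_phenotype_bed(paths["peaks"], "quantified")
        genes = read_phenotype_bed(paths["genes"], "quantified")
        peak_counts = read_phenotype_bed(paths["peak_counts"], "raw_count")
        gene_counts = read_phenotype_bed(paths["gene_counts"], "raw_count")
        meta = read_metadata(paths["metadata"])
        record("load", {"n_samples": geno.n_samples}, [])
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    samples = geno.sample_ids
    status = meta.status_codes(samples)
    case_ids = [s for s, st in zip(samples, status) if st == 1]
    ctrl_ids = [s for s, st in zip(samples, status) if st == 0]
    if not case_ids or not ctrl_ids:
        raise ValueError("structure analysis requires both cases and controls")

    # ---- preprocess ----------------------------------------------------
    cov_names, cov_mat = meta.covariate_matrix(samples)
    gpcs = preprocess.genotype_pcs(geno, a["n_genotype_pcs"])
    def _normalize(pm):
        blocks = [gpcs]
        if cov_mat.size:
            blocks.append(cov_mat)
        if a["n_phenotype_pcs"] > 0:
            blocks.append(preprocess.compute_pcs(pm.values, a["n_phenotype_pcs"]))
        C = np.column_stack(blocks)
        cm = preprocess.CovariateModel(
            [f"c{i}" for i in range(C.shape[1])], C, a["n_phenotype_pcs"]
        )
        return preprocess.normalize_phenotypes(pm, cm)

    peaks_norm = _normalize(peaks)
    genes_norm = _normalize(genes)
    f_norm_peaks = out / "peaks.norm.bed"
    write_phenotype_bed(peaks_norm, f_norm_peaks)
    record("preprocess", {"n_phenotype_pcs": a["n_phenotype_pcs"]}, [f_norm_peaks])

    # ---- CRD calling ---------------------------------------------------
    crd_sets = {}
    for label, ids in (("cases", case_ids), ("controls", ctrl_ids),
                       ("combined", samples)):
        sub = peaks_norm.subset_samples(ids)
        crd_sets[label] = crd.call_crds_genomewide(
            sub, window=a["peak_corr_window"], factor=a["crd_factor"],
            id_prefix=label,
        )
    crd_files = []
    for label, crds in crd_sets.items():
        f = out / f"crds_{label}.bed"
        write_results_table(crd.crds_to_frame(crds), f)
        crd_files.append(f)
    activity = crd.quantify_crds(peaks_norm, crd_sets["combined"])
    f_act = out / "activity.bed"
    write_phenotype_bed(activity, f_act)
    record("crd_call", {f"n_crds_{k}": len(v) for k, v in crd_sets.items()},
           crd_files + [f_act])

    # ---- structure analysis -------------------------------------------
    specific = structure.find_specific_crds(crd_sets["cases"],
                                            crd_sets["controls"])
    spec_files = []
    counts = {"n_specific_crds": len(specific)}
    if specific:
        spec_peaks = sorted({p for c in specific for p in c.member_peaks})
        diff_peaks = structure.per_peak_differential(peaks, status, spec_peaks)
        f1 = out / "specific_peak_diff.tsv"
        write_results_table(diff_peaks, f1)
        spec_files.append(f1)
        counts["n_diff_specific_peaks"] = int((diff_peaks["q"] <= a["fdr"]).sum())
        try:
            shift, p_shift = structure.per_crd_correlation_shift(
                peaks_norm, specific, status
            )
            f2 = out / "specific_corr_shift.tsv"
            write_results_table(shift, f2)
            spec_files.append(f2)
            counts["corr_shift_p"] = p_shift
        except ValueError as e:
            log.warning("correlation-shift test skipped: %s", e)
    record("structure", counts, spec_files)

    # ---- differential --------------------------------------------------
    crd_counts = crd.sum_crd_counts(peak_counts, crd_sets["combined"])
    diff_files = []
    dcounts = {}
    for label, pm in (("crds", crd_counts), ("genes", gene_counts)):
        res = differential.nb_wald_test(
            pm.values, status, feature_ids=pm.features["feature_id"]
        )
        f = out / f"diff_{label}.tsv"
        write_results_table(res, f)
        diff_files.append(f)
        dcounts[f"n_diff_{label}"] = int((res["q"] <= a["fdr"]).sum())
    record("differential", dcounts, diff_files)

    # ---- QTL passes ----------------------------------------------------
    qtl_files = []
    qcounts = {}
    qtl_results = {}
    for label, pm in (("e", genes_norm), ("acrd", activity)):
        res = qtl.permutation_pass(
            pm, geno, window=a["window"], n_perm=a["n_perm"],
            seed=stage_seed(seed, f"qtl_{label}"), maf_min=a["maf_min"],
        )
        cond = qtl.conditional_pass(pm, geno, res, window=a["window"],
                                    fdr=a["fdr"], maf_min=a["maf_min"])
        qtl_results[label] = res
        f = out / f"qtl_{label}.tsv"
        write_results_table(res, f)
        fc = out / f"qtl_{label}_conditional.tsv"
        write_results_table(cond, fc)
        qtl_files.extend([f, fc])
        qcounts[f"n_{label}qtl"] = int((res["q"] <= a["fdr"]).sum())
        qcounts[f"n_{label}qtl_signals"] = len(cond)

    # interaction QTLs on case-discovered QTLs
    inter_frames = []
    for label, pm in (("e", genes_norm), ("acrd", activity)):
        case_pm = pm.subset_samples(case_ids)
        case_geno = geno.subset_samples(case_ids)
        case_res = qtl.permutation_pass(
            case_pm, case_geno, window=a["window"], n_perm=a["n_perm"],
            seed=stage_seed(seed, f"qtl_case_{label}"), maf_min=0.0,
        )
        hits = case_res[case_res["q"] <= a["fdr"]]
        if len(hits):
            inter = qtl.interaction_qtl(
                pm, geno, status, covariates=None,
                qtl_pairs=list(zip(hits["phenotype_id"], hits["variant_id"])),
            )
            inter["phenotype_class"] = label
            inter_frames.append(inter)
    inter = (
        pd.concat(inter_frames, ignore_index=True)
        if inter_frames
        else pd.DataFrame(columns=["phenotype_id", "variant_id",
                                   "interaction_slope", "p", "slope_case",
                                   "slope_control", "q", "phenotype_class"])
    )
    f_int = out / "interaction.tsv"
    write_results_table(inter, f_int)
    qtl_files.append(f_int)
    qcounts["n_interaction_qtls"] = int((inter["q"] <= a["fdr"]).sum()) if len(inter) else 0
    record("qtl", qcounts, qtl_files)

    # ---- gene-CRD pairs ------------------------------------------------
    pairs = causal.map_gene_crd_pairs(
        genes_norm, activity, window=a["window"], n_perm=a["n_perm"],
        seed=stage_seed(seed, "pairs"),
    )
    sig_pairs = pairs[pairs["q"] <= a["fdr"]].reset_index(drop=True) if len(pairs) else pairs
    f_pairs = out / "pairs.tsv"
    write_results_table(pairs, f_pairs)
    record("pairs", {"n_pairs_tested": len(pairs),
                     "n_pairs_significant": len(sig_pairs)}, [f_pairs])

    # ---- triplets + mechanisms ----------------------------------------
    triplets = causal.build_triplets(
        sig_pairs, genes_norm, activity, geno, window=a["window"],
        n_perm=a["n_perm"], seed=stage_seed(seed, "triplets"),
        fdr=a["fdr"], maf_min=a["maf_min"],
    )
    trip_files = []
    tcounts = {"n_triplets": len(triplets)}
    scored = {}
    for label, ids in (("cases", case_ids), ("controls", ctrl_ids)):
        sc = causal.score_triplets(
            triplets, genes_norm, activity, geno, sample_ids=ids,
            B=a["bootstrap_b"], threshold=a["accuracy_threshold"],
            seed=stage_seed(seed, f"bootstrap_{label}"),
        ) if len(triplets) else pd.DataFrame(
            columns=["variant_id", "crd_id", "gene_id", "pc1_variance",
                     "p_causal", "p_reactive", "p_independent", "top_model",
                     "accuracy", "passed"]
        )
        scored[label] = sc
        f = out / f"triplets_{label}.tsv"
        write_results_table(sc, f)
        trip_files.append(f)
        tcounts[f"n_passed_{label}"] = int(sc["passed"].sum()) if len(sc) else 0
    mech = causal.compare_mechanisms(scored["cases"], scored["controls"])
    f_mech = out / "mechanism_changes.tsv"
    write_results_table(mech, f_mech)
    trip_files.append(f_mech)
    if len(mech):
        tcounts["n_mechanism_same"] = int((mech["change"] == "same").sum())
        tcounts["n_mechanism_changed"] = int((mech["change"] != "same").sum())
    record("triplets", tcounts, trip_files)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
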