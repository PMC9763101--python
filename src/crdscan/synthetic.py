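"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants cis-regulatory domains (CRDs) as latent per-domain
activity factors shared by genomically contiguous blocks of chromatin peaks,
wires genes to domains and/or variants under known causal models, shifts
factor means between cases and controls for planted differential domains,
and links negative-binomial read counts to activity.  Every planted signal
is reported in a :class:`GroundTruth` table so recovery can be scored.

All peaks live on one synthetic chromosome at fixed 2-kb spacing with 1-kb
widths; CRD members are contiguous runs of peaks separated by at least one
background peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenotypeMatrix,
    IntervalSet,
    PhenotypeMatrix,
    SampleMetadata,
    compute_maf,
    write_genotypes,
    write_metadata,
    write_phenotype_bed,
)

PEAK_SPACING = 2_000
PEAK_WIDTH = 1_000
GENE_LENGTH = 10_000
TRIPLET_MODELS = ("causal", "reactive", "independent")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the structure of the cohort the analysis is designed
    for: a 98:174 case/control split, domains of 2-10 peaks regrouping
    ~60% of peaks, and within-domain peak correlation
    loading^2/(loading^2+noise_sd^2) = 0.5 at the default loading/noise.
    """

    n_cases: int = 98
    n_controls: int = 174
    n_peaks: int = 1000
    crd_size_range: tuple = (2, 10)
    within_crd_loading: float = 1.0
    noise_sd: float = 1.0
    fraction_peaks_in_crds: float = 0.6
    n_genes: int = 120
    maf_range: tuple = (0.05, 0.5)
    qtl_effect_sd: float = 0.5
    interaction_effect: float = 0.6
    diff_effect: float = 0.5
    fraction_diff_crds: float = 0.2
    fraction_diff_genes: float = 0.2
    nb_dispersion: float = 0.1
    triplet_models: dict = field(
        default_factory=lambda: {"causal": 5, "reactive": 5, "independent": 5}
    )
    triplet_beta_vc: float = 0.5
    triplet_beta_cg: float = 0.7
    n_crd_qtls: int = 30
    n_gene_qtls: int = 30
    n_interaction_qtls: int = 8
    n_background_variants: int = 200
    gene_crd_coupling: float = 0.7
    fraction_wired_genes: float = 0.4
    count_intercept: float = 5.0
    count_slope: float = 0.3
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_peaks", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.crd_size_range
        if lo < 2 or hi < lo:
            raise ValueError("crd_size_range must satisfy 2 <= min <= max")
        if not 0 < self.fraction_peaks_in_crds <= 1:
            raise ValueError("fraction_peaks_in_crds must be in (0, 1]")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must be ordered within (0, 0.5]")
        unknown = set(self.triplet_models) - set(TRIPLET_MODELS)
        if unknown:
            raise ValueError(f"unknown triplet models {unknown}")


@dataclass
class GroundTruth:
    """Planted signals of one simulated cohort."""

    crd_membership: dict  # crd_id -> ordered list of member peak ids
    diff_active_crds: set
    diff_genes: set
    qtl_map: pd.DataFrame  # variant_id, phenotype_id, beta
    interaction_qtls: set  # (variant_id, phenotype_id)
    triplet_labels: dict  # triplet_id -> dict(model, variant, crd, gene)


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    peaks: PhenotypeMatrix
    genes: PhenotypeMatrix
    peak_counts: PhenotypeMatrix
    gene_counts: PhenotypeMatrix
    metadata: SampleMetadata
    truth: GroundTruth


def _place_crds(cfg: SimulationConfig, rng) -> list[np.ndarray]:
    """Contiguous, mutually separated member-index blocks for planted CRDs."""
    lo, hi = cfg.crd_size_range
    if hi > cfg.n_peaks:
        raise ValueError("planted CRD sizes exceed n_peaks")
    target = int(round(cfg.fraction_peaks_in_crds * cfg.n_peaks))
    sizes = []
    total = 0
    while total < target:
        s = int(rng.integers(lo, hi + 1))
        if total + s > target:
            s = target - total
            if s < lo:
                break
        sizes.append(s)
        total += s
    n_blocks = len(sizes)
    n_members = sum(sizes)
    n_gaps = cfg.n_peaks - n_members
    # every block separated by >= 1 background peak
    if n_gaps < n_blocks - 1:
        raise ValueError("planted CRD sizes exceed n_peaks")
    extra = n_gaps - (n_blocks - 1)
    gap_extra = rng.multinomial(extra, np.ones(n_blocks + 1) / (n_blocks + 1))
    blocks = []
    pos = int(gap_extra[0])
    for k, s in enumerate(sizes):
        blocks.append(np.arange(pos, pos + s))
        pos += s + 1 + int(gap_extra[k + 1])
    return blocks


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate a full cohort; bit-for-bit reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n)]
    status = np.array([1] * cfg.n_cases + [0] * cfg.n_controls)

    blocks = _place_crds(cfg, rng)
    n_crds = len(blocks)
    crd_ids = [f"true_crd_{k:04d}" for k in range(n_crds)]
    peak_ids = [f"peak_{i:05d}" for i in range(cfg.n_peaks)]
    peak_start = 10_000 + PEAK_SPACING * np.arange(cfg.n_peaks)
    peak_end = peak_start + PEAK_WIDTH

    # ---- planted signal bookkeeping -----------------------------------
    n_triplets = sum(cfg.triplet_models.get(m, 0) for m in TRIPLET_MODELS)
    needed = cfg.n_crd_qtls + cfg.n_interaction_qtls + n_triplets
    if needed > n_crds:
        raise ValueError(
            f"config plants {needed} variant-wired CRDs but only {n_crds} exist"
        )
    crd_perm = rng.permutation(n_crds)
    qtl_crds = crd_perm[: cfg.n_crd_qtls]
    inter_crds = crd_perm[cfg.n_crd_qtls : cfg.n_crd_qtls + cfg.n_interaction_qtls]
    triplet_crds = crd_perm[
        cfg.n_crd_qtls + cfg.n_interaction_qtls : cfg.n_crd_qtls
        + cfg.n_interaction_qtls
        + n_triplets
    ]
    n_diff = int(round(cfg.fraction_diff_crds * n_crds))
    diff_crds = set(rng.choice(n_crds, size=n_diff, replace=False).tolist())

    # ---- latent CRD factors -------------------------------------------
    factors = rng.normal(size=(n, n_crds))
    for k in diff_crds:
        factors[:, k] += cfg.diff_effect * status

    # ---- variants ------------------------------------------------------
    chrom_span = int(peak_end[-1] + 1_200_000)

    def _draw_variant(anchor_pos):
        pos = int(
            np.clip(anchor_pos + rng.integers(-500_000, 500_001), 1, chrom_span)
        )
        maf = float(rng.uniform(*cfg.maf_range))
        dose = rng.binomial(2, maf, size=n).astype(float)
        return pos, dose

    var_rows = []  # (pos, dosage, role, target)
    crd_anchor = [int(peak_start[b[0]]) for b in blocks]

    def crd_effect(k, dose, beta, group=None):
        centered = dose - dose.mean()
        if group is None:
            factors[:, k] += beta * centered
        else:
            factors[:, k] += beta * centered * group

    truth_qtl = []
    for k in qtl_crds:
        pos, dose = _draw_variant(crd_anchor[k])
        beta = float(rng.normal(0.0, cfg.qtl_effect_sd))
        crd_effect(k, dose, beta)
        var_rows.append([pos, dose, "crd_qtl", crd_ids[k], beta])
    inter_pairs = []
    for k in inter_crds:
        pos, dose = _draw_variant(crd_anchor[k])
        crd_effect(k, dose, cfg.interaction_effect, group=status)
        var_rows.append([pos, dose, "interaction", crd_ids[k], cfg.interaction_effect])

    # ---- genes ---------------------------------------------------------
    gene_ids = [f"gene_{g:04d}" for g in range(cfg.n_genes)]
    gene_vals = rng.normal(size=(n, cfg.n_genes))
    gene_tss = np.zeros(cfg.n_genes, dtype=int)
    gene_strand = np.array(["+", "-"] * (cfg.n_genes // 2 + 1))[: cfg.n_genes]

    triplet_labels = {}
    gene_cursor = 0

    def next_gene():
        nonlocal gene_cursor
        g = gene_cursor
        gene_cursor += 1
        if g >= cfg.n_genes:
            raise ValueError("config wires more genes than n_genes")
        return g

    # triplet wiring: the CRD factor and one gene share a variant under a
    # known causal model (see simulate_triplet for the standalone version)
    t_idx = 0
    for model in TRIPLET_MODELS:
        for _ in range(cfg.triplet_models.get(model, 0)):
            k = triplet_crds[t_idx]
            g = next_gene()
            pos, dose = _draw_variant(crd_anchor[k])
            centered = dose - dose.mean()
            bvc, bcg = cfg.triplet_beta_vc, cfg.triplet_beta_cg
            if model == "causal":
                factors[:, k] += bvc * centered
                gene_vals[:, g] = bcg * factors[:, k] + rng.normal(size=n)
            elif model == "reactive":
                gene_vals[:, g] = bvc * centered + rng.normal(size=n)
                factors[:, k] += bcg * gene_vals[:, g]
            else:  # independent
                factors[:, k] += bvc * centered
                gene_vals[:, g] = bcg * centered + rng.normal(size=n)
            gene_tss[g] = crd_anchor[k] + int(rng.integers(-100_000, 100_001))
            tid = f"triplet_{t_idx:03d}"
            vname = f"{model[:4]}_{tid}"
            var_rows.append([pos, dose, "triplet", tid, bvc])
            triplet_labels[tid] = {
                "model": model,
                "variant_pos": pos,
                "crd": crd_ids[k],
                "gene": gene_ids[g],
            }
            t_idx += 1

    # genes wired to CRDs without their own variant
    n_wired = int(round(cfg.fraction_wired_genes * cfg.n_genes))
    wired_pairs = []
    free_crds = [k for k in range(n_crds) if k not in set(triplet_crds)]
    for _ in range(max(0, n_wired - n_triplets)):
        if gene_cursor >= cfg.n_genes or not free_crds:
            break
        g = next_gene()
        k = free_crds[int(rng.integers(len(free_crds)))]
        gene_vals[:, g] = cfg.gene_crd_coupling * factors[:, k] + rng.normal(size=n)
        gene_tss[g] = crd_anchor[k] + int(rng.integers(-100_000, 100_001))
        wired_pairs.append((gene_ids[g], crd_ids[k]))

    # gene QTLs on otherwise free genes
    for _ in range(cfg.n_gene_qtls):
        if gene_cursor >= cfg.n_genes:
            break
        g = next_gene()
        gene_tss[g] = int(rng.integers(10_000, chrom_span - 10_000))
        pos, dose = _draw_variant(gene_tss[g])
        beta = float(rng.normal(0.0, cfg.qtl_effect_sd))
        gene_vals[:, g] += beta * (dose - dose.mean())
        var_rows.append([pos, dose, "gene_qtl", gene_ids[g], beta])

    # remaining genes: pure noise, random positions
    for g in range(gene_cursor, cfg.n_genes):
        gene_tss[g] = int(rng.integers(10_000, chrom_span - 10_000))

    n_diff_genes = int(round(cfg.fraction_diff_genes * cfg.n_genes))
    diff_genes = set(rng.choice(cfg.n_genes, size=n_diff_genes, replace=False).tolist())
    for g in diff_genes:
        gene_vals[:, g] += cfg.diff_effect * status

    # background variants
    for _ in range(cfg.n_background_variants):
        pos = int(rng.integers(1, chrom_span))
        maf = float(rng.uniform(*cfg.maf_range))
        dose = rng.binomial(2, maf, size=n).astype(float)
        var_rows.append([pos, dose, "background", "", 0.0])

    # ---- peak values ---------------------------------------------------
    marginal_sd = np.sqrt(cfg.within_crd_loading**2 + cfg.noise_sd**2)
    peaks = rng.normal(0.0, marginal_sd, size=(n, cfg.n_peaks))
    crd_membership = {}
    for k, b in enumerate(blocks):
        peaks[:, b] = (
            cfg.within_crd_loading * factors[:, [k]]
            + rng.normal(0.0, cfg.noise_sd, size=(n, len(b)))
        )
        crd_membership[crd_ids[k]] = [peak_ids[i] for i in b]

    # ---- counts linked to activity ------------------------------------
    def nb_counts(values):
        z = (values - values.mean(axis=0)) / np.maximum(values.std(axis=0), 1e-12)
        mu = np.exp(cfg.count_intercept + cfg.count_slope * z)
        if cfg.nb_dispersion > 0:
            lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
        else:
            lam = mu
        return rng.poisson(lam).astype(float)

    peak_count_vals = nb_counts(peaks)
    gene_count_vals = nb_counts(gene_vals)

    # ---- assemble containers ------------------------------------------
    order = np.argsort([r[0] for r in var_rows], kind="stable")
    var_rows = [var_rows[i] for i in order]
    variant_ids = []
    role_to_vid = {}
    vrec = []
    dmat = []
    for j, (pos, dose, role, target, beta) in enumerate(var_rows):
        vid = f"var_{j:05d}"
        variant_ids.append(vid)
        vrec.append((vid, cfg.chrom, pos, "A", "G"))
        dmat.append(dose)
        role_to_vid[(role, target, pos)] = vid
    dosages = np.column_stack(dmat) if dmat else np.zeros((n, 0))
    variants = pd.DataFrame(
        vrec, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    variants["maf"] = compute_maf(dosages)
    genotypes = GenotypeMatrix(sample_ids, variants, dosages)

    qtl_map_rows = []
    interaction_set = set()
    for (role, target, pos), vid in role_to_vid.items():
        if role in ("crd_qtl", "gene_qtl"):
            beta = next(
                b for p, d, r, t, b in var_rows if r == role and t == target and p == pos
            )
            qtl_map_rows.append((vid, target, beta))
        elif role == "interaction":
            interaction_set.add((vid, target))
        elif role == "triplet":
            triplet_labels[target]["variant"] = vid
    for tid in triplet_labels:
        triplet_labels[tid].pop("variant_pos", None)
    qtl_map = pd.DataFrame(qtl_map_rows, columns=["variant_id", "phenotype_id", "beta"])

    peak_features = pd.DataFrame(
        {
            "feature_id": peak_ids,
            "chrom": cfg.chrom,
            "start": peak_start,
            "end": peak_end,
            "strand": "+",
            "group_id": peak_ids,
        }
    )[["feature_id", "chrom", "start", "end", "strand", "group_id"]]
    peaks_pm = PhenotypeMatrix(sample_ids, peak_features, peaks, "quantified")
    peak_counts_pm = PhenotypeMatrix(
        sample_ids, peak_features.copy(), peak_count_vals, "raw_count"
    )

    gene_start = np.where(gene_strand == "+", gene_tss, gene_tss - GENE_LENGTH + 1)
    gene_start = np.maximum(gene_start, 0)
    gene_features = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "chrom": cfg.chrom,
            "start": gene_start,
            "end": gene_start + GENE_LENGTH,
            "strand": gene_strand,
            "group_id": gene_ids,
        }
    )
    gorder = gene_features.sort_values(["chrom", "start"], kind="stable").index
    gene_features = gene_features.iloc[gorder].reset_index(drop=True)
    genes_pm = PhenotypeMatrix(
        sample_ids, gene_features, gene_vals[:, gorder], "quantified"
    )
    gene_counts_pm = PhenotypeMatrix(
        sample_ids, gene_features.copy(), gene_count_vals[:, gorder], "raw_count"
    )

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": np.where(status == 1, "case", "control"),
                "cov_age": rng.normal(50, 10, size=n).round(3),
                "cov_batch": rng.normal(0, 1, size=n).round(6),
            }
        )
    )
    truth = GroundTruth(
        crd_membership=crd_membership,
        diff_active_crds={crd_ids[k] for k in diff_crds},
        diff_genes={gene_ids[g] for g in diff_genes},
        qtl_map=qtl_map,
        interaction_qtls=interaction_set,
        triplet_labels=triplet_labels,
    )
    return Cohort(
        genotypes, peaks_pm, genes_pm, peak_counts_pm, gene_counts_pm, meta, truth
    )


def simulate_triplet(model: str, n: int, beta_vc: float, beta_cg: float, seed: int,
                     maf: float = 0.3):
    """Draw one (dosage, CRD activity, gene expression) triplet.

    causal:      C = b_vc*V + e1,  G = b_cg*C + e2
    reactive:    G = b_vc*V + e1,  C = b_cg*G + e2
    independent: C = b_vc*V + e1,  G = b_cg*V + e2
    with e ~ Normal(0, 1) and V a binomial(2, maf) dosage.
    """
    if model not in TRIPLET_MODELS:
        raise ValueError(f"unknown triplet model {model!r}")
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    v = rng.binomial(2, maf, size=n).astype(float)
    e1 = rng.normal(size=n)
    e2 = rng.normal(size=n)
    if model == "causal":
        c = beta_vc * v + e1
        g = beta_cg * c + e2
    elif model == "reactive":
        g = beta_vc * v + e1
        c = beta_cg * g + e2
    else:
        c = beta_vc * v + e1
        g = beta_cg * v + e2
    return v, c, g


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write a cohort to ``directory``; returns the path map.

    Everything is loadable back through :mod:`crdscan.io_formats`; the truth
    tables are plain TSVs.  An empty triplet config emits no triplet file.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": d / "genotypes.vcf",
        "peaks": d / "peaks.bed",
        "genes": d / "genes.bed",
        "peak_counts": d / "peak_counts.bed",
        "gene_counts": d / "gene_counts.bed",
        "metadata": d / "metadata.tsv",
        "truth_crds": d / "truth_crds.tsv",
        "truth_qtls": d / "truth_qtls.tsv",
        "truth_diff": d / "truth_diff.tsv",
    }
    write_genotypes(cohort.genotypes, paths["genotypes"])
    write_phenotype_bed(cohort.peaks, paths["peaks"])
    write_phenotype_bed(cohort.genes, paths["genes"])
    write_phenotype_bed(cohort.peak_counts, paths["peak_counts"])
    write_phenotype_bed(cohort.gene_counts, paths["gene_counts"])
    write_metadata(cohort.metadata, paths["metadata"])
    t = cohort.truth
    with open(paths["truth_crds"], "w") as fh:
        fh.write("crd_id\tmember_peaks\n")
        for cid, members in t.crd_membership.items():
            fh.write(f"{cid}\t{','.join(members)}\n")
    t.qtl_map.to_csv(paths["truth_qtls"], sep="\t", index=False)
    with open(paths["truth_diff"], "w") as fh:
        fh.write("phenotype_id\tkind\n")
        for cid in sorted(t.diff_active_crds):
            fh.write(f"{cid}\tcrd\n")
        for gid in sorted(t.diff_genes):
            fh.write(f"{gid}\tgene\n")
    if t.triplet_labels:
        paths["truth_triplets"] = d / "truth_triplets.tsv"
        with open(paths["truth_triplets"], "w") as fh:
            fh.write("triplet_id\tmodel\tvariant_id\tcrd_id\tgene_id\n")
            for tid in sorted(t.triplet_labels):
                lab = t.triplet_labels[tid]
                fh.write(
                    f"{tid}\t{lab['model']}\t{lab['variant']}\t{lab['crd']}"
                    f"\t{lab['gene']}\n"
                )
    return {k: str(v) for k, v in paths.items()}
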