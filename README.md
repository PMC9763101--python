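# crdscan

Calling cis-regulatory domains from population-scale chromatin data,
mapping their genetic regulation, and inferring how genetic effects flow
between coordinated regulatory activity and gene expression.

## The problem

H3K27ac ChIP-seq peaks measure the activity of regulatory elements across
individuals.  Nearby peaks do not vary independently: their interindividual
correlation is structured into well-delimited blocks — **cis-regulatory
domains (CRDs)** — that aggregate the coordinated activity of several
regulatory elements.  Treating a CRD as a single quantitative trait sharply
reduces the multiple-testing burden and exposes regulatory signal that
single-peak analyses miss.  `crdscan` implements the full analysis for a
case/control cohort with genotypes (VCF), peak and gene quantifications
(QTLtools-style phenotype BED) and raw counts:

1. **CRD calling** (`crdscan.crd`) — per chromosome, Pearson correlations
   between all peak pairs within a 250-peak window; adjacency-constrained
   hierarchical clustering into a binary tree; a node is accepted as a CRD
   iff (i) its mean pairwise correlation and (ii) its boundary-peak ("edge")
   correlation are both ≥ 2× the chromosome background, and (iii) it covers
   ≥ 2 non-overlapping elements.  Accepted nodes are maximal; activity is
   quantified as the mean member-peak quantification per individual.
2. **Condition-specific structure** (`crdscan.structure`) — domains whose
   peaks regroup into no domain of the other group; per-peak Mann-Whitney
   differential activity; per-domain correlation-shift tests; Fisher-exact
   annotation-overlap enrichment.
3. **Differential testing** (`crdscan.differential`) — negative-binomial
   Wald tests on gene counts and on member-summed CRD counts
   (median-of-ratios size factors, trend-shrunk dispersions), with Storey
   q-values/π₁ used for all FDR decisions.
4. **cis-QTL mapping** (`crdscan.qtl`) — for genes (eQTL), peaks (cQTL) and
   CRD activity (aCRD-QTL): nominal pass in a ±1 Mb window, a
   1,000-permutation pass with a Beta-approximated adjusted p, a
   forward-backward conditional scan for independent signals, genotype ×
   disease interaction tests, RTC colocalization, and π₁ replication
   sharing.
5. **Causal inference** (`crdscan.causal`) — gene–CRD association by
   permutation pass; PC1 pseudo-phenotypes of significant pairs mapped to a
   shared variant (eCRD-QTL); each (variant, CRD, gene) triplet scored under
   three Gaussian networks — causal V→C→G, reactive V→G→C, independent
   V→C, V→G — with softmax posteriors and a 100-bootstrap accuracy filter
   (default threshold 0.55); mechanism changes compared between groups.
6. **Synthetic cohorts** (`crdscan.synthetic`) — a latent-factor generator
   that plants CRDs, QTLs, case/control shifts, interaction effects and
   causally wired triplets with full ground truth, used by the test suite
   and the acceptance script.

`crdscan.pipeline.run_pipeline` chains all stages (CRDs called in cases,
controls and the combined set; combined-set CRDs feed everything
downstream) and writes a manifest with per-stage counts and output
checksums that is byte-identical across reruns of the same config + seed.

## Worked example

```python
from crdscan.synthetic import SimulationConfig, simulate_cohort
from crdscan.preprocess import normalize_phenotypes
from crdscan import crd
from crdscan.qtl import permutation_pass

cfg = SimulationConfig(n_cases=98, n_controls=174, n_peaks=400, n_genes=40,
                       n_crd_qtls=10, n_gene_qtls=10, n_interaction_qtls=0,
                       triplet_models={}, seed=42)
cohort = simulate_cohort(cfg)
peaks = normalize_phenotypes(cohort.peaks, None)   # rank-normal transform
crds = crd.call_crds_genomewide(peaks)
print(f"called {len(crds)} CRDs (planted: {len(cohort.truth.crd_membership)})")
print(f"first CRD: {crds[0].n_members} peaks, mean r = {crds[0].mean_corr:.2f}, "
      f"background = {crds[0].background:.3f}")

activity = crd.quantify_crds(peaks, crds)
qtls = permutation_pass(activity, cohort.genotypes, n_perm=1000, seed=1)
hits = qtls[qtls["q"] <= 0.05]
print(f"aCRD-QTLs at FDR 5%: {len(hits)}")
print(hits[["phenotype_id", "variant_id", "slope", "p_adjusted", "q"]]
      .head(3).to_string(index=False))
```

prints

```
called 39 CRDs (planted: 39)
first CRD: 2 peaks, mean r = 0.53, background = 0.121
aCRD-QTLs at FDR 5%: 5
 phenotype_id variant_id     slope   p_adjusted            q
crd_chr1_0004  var_00063 -0.405452 1.986145e-06 8.454679e-06
crd_chr1_0009  var_00066  0.289408 6.720528e-03 2.288651e-02
crd_chr1_0015  var_00002 -0.369307 1.113086e-08 6.317625e-08
```

All 39 planted domains are recovered (within-domain correlation 0.5 against
a background of ~0.12 after the sampling-noise floor), and half of the ten
planted regulatory variants — whose effect sizes are drawn from
Normal(0, 0.5), so several are weak — reach FDR 5% after permutation
correction at this sample size.  `slope` is the per-allele effect on the
rank-normalized activity scale; `p_adjusted` is the Beta-approximated
permutation p.

The same steps are available from the shell:

```bash
crdscan simulate --seed 3 --out sim/
crdscan preprocess --pheno sim/peaks.bed --geno sim/genotypes.vcf \
        --meta sim/metadata.tsv --pcs 2 --out peaks.norm.bed
crdscan crd-call --pheno peaks.norm.bed --out crds
crdscan qtl --pheno crds.activity.bed --geno sim/genotypes.vcf \
        --perms 1000 --seed 4 --out qtl.tsv
crdscan run --config run.yaml --out results/   # full pipeline
```

A pipeline YAML config holds a `seed`, either a `simulate:` block
(`SimulationConfig` fields) or an `inputs:` block (paths to VCF / BEDs /
metadata), and an optional `analysis:` block (`window`, `n_perm`, `fdr`,
`maf_min`, `peak_corr_window`, `crd_factor`, `n_phenotype_pcs`,
`n_genotype_pcs`, `bootstrap_b`, `accuracy_threshold`).

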