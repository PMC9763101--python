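import numpy as np
import pandas as pd
import pytest

from crdscan.io_formats import GenotypeMatrix, PhenotypeMatrix, compute_maf


def make_genotypes(dosages, positions=None, chrom="chr1", sample_ids=None):
    """GenotypeMatrix from a samples x variants dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    positions = np.asarray(positions, dtype=int)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    dosages = dosages[:, order]
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j:04d}" for j in order],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    variants["maf"] = compute_maf(dosages)
    return GenotypeMatrix(sample_ids, variants, dosages)


def make_phenotypes(values, starts=None, chrom="chr1", kind="normalized",
                    strand=None, sample_ids=None, width=1):
    """PhenotypeMatrix from a samples x features value array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if starts is None:
        starts = np.arange(m) * 2000 + 1000
    starts = np.asarray(starts, dtype=int)
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    feats = pd.DataFrame(
        {
            "feature_id": [f"p{j:04d}" for j in range(m)],
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "strand": strand if strand is not None else "+",
            "group_id": [f"p{j:04d}" for j in range(m)],
        }
    )
    return PhenotypeMatrix(sample_ids, feats, values, kind)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with every kind of planted signal, reused across
    tests that only need realistic structure (not specific effect sizes)."""
    from crdscan.synthetic import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_cases=40, n_controls=60, n_peaks=200, n_genes=40,
        n_crd_qtls=5, n_gene_qtls=5, n_interaction_qtls=2,
        n_background_variants=50,
        triplet_models={"causal": 2, "reactive": 2, "independent": 2},
        seed=1,
    )
    return simulate_cohort(cfg)
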