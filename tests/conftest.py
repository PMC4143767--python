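import numpy as np
import pytest

from goftscan import (CollapseConfig, GenotypeMatrix, PhenotypeVector,
                      SimScenario, VariantInfo, assign_variants, make_windows,
                      simulate_genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def toy_matrix(dosage, positions, chrom="chr1", sample_prefix="S"):
    """GenotypeMatrix from a plain dosage array and 1-based positions."""
    dosage = np.asarray(dosage, dtype=float)
    variants = [VariantInfo(chrom=chrom, position=int(p), id=f"v{k}")
                for k, p in enumerate(positions)]
    gm = GenotypeMatrix([f"{sample_prefix}{i}" for i in range(dosage.shape[0])],
                        dosage, variants)
    gm.compute_mafs()
    return gm


@pytest.fixture()
def small_panel():
    """50 samples x 3 windows x 10 variants, mixed MAF spectrum, with windows."""
    scn = SimScenario(n_samples=50, n_windows=3, variants_per_window=10,
                      true_window_fraction=0.0, n_replicates=1, seed=11)
    gm, windows = simulate_genotypes(scn)
    return gm, windows


@pytest.fixture()
def null_phenotype(small_panel, rng):
    gm, _ = small_panel
    return PhenotypeVector(list(gm.sample_ids), rng.standard_normal(gm.n_samples),
                           "quantitative")
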