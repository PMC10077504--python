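import numpy as np
import pandas as pd
import pytest

from isopqtl.config import SimConfig
from isopqtl.containers import GenotypePanel
from isopqtl.simulate import simulate_cohorts


@pytest.fixture(scope="session")
def small_study():
    """Two-cohort study with planted effects, shared across test modules."""
    cfg = SimConfig(
        n_samples_per_cohort=400,
        n_variants=1500,
        n_proteins=8,
        n_cis_effects=4,
        n_trans_effects=2,
        effect_betas=[1.0, -0.9, 0.8, 1.2, -1.0, 0.9],
        seed=11,
        causal_protein_effects=[("PROT000", "trait1", 0.5)],
    )
    return simulate_cohorts(cfg)


def make_panel(dosages, positions=None, chrom="1", rng=None):
    """Wrap a raw dosage matrix in a GenotypePanel with minimal metadata."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "rsid": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypePanel(dosages, variants)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
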