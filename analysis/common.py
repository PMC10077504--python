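"""Shared configuration of the worked synthetic study.

Every numbered script rebuilds the study deterministically from this
config (generation takes ~2 s), so the scripts can be run independently
and in any order.  Outputs land under results/.
"""

from pathlib import Path

from isopqtl.config import RunConfig, SimConfig
from isopqtl.simulate import simulate_cohorts

RESULTS = Path(__file__).resolve().parent.parent / "results"

SIM = SimConfig(
    n_samples_per_cohort=1000,
    n_variants=4000,
    n_proteins=10,
    n_cis_effects=5,
    n_trans_effects=2,
    effect_betas=[1.0, -0.9, 0.8, 1.1, 0.9, -1.0, 0.85],
    seed=2026,
    causal_protein_effects=[("PROT000", "trait1", 0.5)],
)

# lambda_GC band widened for desk-scale panels (see docs/methods.md)
RUN = RunConfig(lambda_gc_band=(0.8, 1.2), seed=2026)


def load_study():
    return simulate_cohorts(SIM)
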