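"""Bayesian colocalization of two association signals via Wakefield ABFs.

For each variant the approximate Bayes factor against the null is

    log ABF = 0.5 * log(1 - r) + 0.5 * z^2 * r,      r = W^2 / (W^2 + se^2)

with z = beta / se and W the prior standard deviation of the true effect.
Per-variant ABFs for the two traits combine with per-variant priors
(p1, p2 single-trait causal; p12 shared causal) into the standard five
posterior hypothesis probabilities:

    PP0 no causal variant; PP1/PP2 causal for one trait only;
    PP3 two distinct causal variants; PP4 one shared causal variant.

All sums run in log space.  Colocalization is declared at PP4 > 0.8 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


def wakefield_abf(beta: np.ndarray, se: np.ndarray, W: float = 1.0) -> np.ndarray:
    """Log approximate Bayes factor (alternative vs null) per variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("beta and se must be finite with se > 0")
    if W < 0:
        raise ValueError("prior sd W must be non-negative")
    r = W**2 / (W**2 + se**2)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int

    @property
    def colocalized(self) -> bool:
        return self.pp4 > 0.8

    def as_dict(self) -> dict:
        return {
            "pp0": self.pp0,
            "pp1": self.pp1,
            "pp2": self.pp2,
            "pp3": self.pp3,
            "pp4": self.pp4,
            "n_variants": self.n_variants,
        }


def coloc_posteriors(
    beta1: np.ndarray,
    se1: np.ndarray,
    beta2: np.ndarray,
    se2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W1: float = 1.0,
    W2: float = 1.0,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Inputs are aligned per-variant summary statistics for the two traits
    over the same region (same variants, same allele orientation).  With a
    single variant PP3 is exactly zero (two distinct causal variants are
    impossible).
    """
    for prior in (p1, p2, p12):
        if not 0 < prior < 1:
            raise ValueError("priors must lie in (0, 1)")
    l1 = wakefield_abf(beta1, se1, W1)
    l2 = wakefield_abf(beta2, se2, W2)
    if l1.shape != l2.shape or l1.size == 0:
        raise ValueError("traits must share a non-empty aligned variant set")

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs i != j of exp(l1_i + l2_j)
    both = s1 + s2
    if l1.size == 1:
        lh3 = -np.inf
    else:
        # log(exp(both) - exp(s12)), guarded against cancellation
        diff = 1.0 - np.exp(np.clip(s12 - both, None, 0.0))
        lh3 = both + np.log(diff) if diff > 0 else -np.inf

    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + lh3,
            np.log(p12) + s12,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocResult(*post.tolist(), n_variants=int(l1.size))
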