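"""In-memory containers shared across pipeline stages.

Genotypes are held as a dense sample x variant dosage matrix (float, with
``nan`` marking missing calls); variant metadata travel alongside as a
DataFrame.  Protein levels are a samples x proteins DataFrame of NPX values
(natural-log scale relative units) with a per-protein limit of detection and
a per-sample covariate sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the per-variant association output (GEMMA-style dialect).
ASSOC_COLUMNS = [
    "chr",
    "pos",
    "rsid",
    "allele1",
    "allele0",
    "af",
    "beta",
    "se",
    "p_wald",
    "n",
]


@dataclass
class GenotypePanel:
    """Per-cohort dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array of alternate-allele dosages in
        ``{0, 1, 2}`` with ``nan`` for missing genotypes.
    variants
        DataFrame with columns ``chrom, pos, rsid, ref, alt`` (``af`` is
        recomputed on demand); one row per variant, aligned with the
        columns of ``dosages``.
    samples
        Sample identifiers aligned with the rows of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant metadata does not match dosage matrix")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list does not match dosage matrix")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.alt_freq()
        return np.minimum(af, 1.0 - af)

    def mac(self) -> np.ndarray:
        """Minor allele count over non-missing calls."""
        alt = np.nansum(self.dosages, axis=0)
        n_called = 2.0 * np.sum(~np.isnan(self.dosages), axis=0)
        return np.minimum(alt, n_called - alt)

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """Hard-call genotype counts (hom ref, het, hom alt) for variant j."""
        col = self.dosages[:, j]
        col = col[~np.isnan(col)]
        g = np.rint(col).astype(int)
        return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.dosages[idx],
            self.variants.copy(),
            [self.samples[i] for i in idx],
        )

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )


@dataclass
class ProteinMatrix:
    """NPX protein levels plus per-protein LOD and per-sample covariates.

    ``values`` is samples x proteins with ``nan`` marking missing
    measurements; ``lod`` is indexed by protein; ``covariates`` is indexed by
    sample and holds ``age`` (years), ``sex`` (0/1), ``plate`` (categorical),
    ``season`` (0/1) and ``cohort``.
    """

    values: pd.DataFrame
    lod: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        missing_lod = set(self.values.columns) - set(self.lod.index)
        if missing_lod:
            raise ValueError(f"no LOD for proteins: {sorted(missing_lod)}")
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("covariate sheet does not match sample index")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def missing_fraction(self) -> pd.Series:
        """Combined missing / below-LOD proportion per protein."""
        return self.values.isna().mean(axis=0)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(), self.lod.copy(), self.covariates.copy()
        )


@dataclass
class AdjustedPhenotypes:
    """Covariate-adjusted, inverse-normal transformed protein residuals."""

    residuals: pd.DataFrame
    n_retained: pd.Series
    dropped_columns: dict[str, list[str]] = field(default_factory=dict)
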