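"""Shared domain containers for the eQTL pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tissues profiled in the study design this package models.
TISSUES: tuple[str, ...] = ("blood", "frontal_cortex", "cerebellum")


@dataclass
class DosageMatrix:
    """Samples x SNPs expected minor-allele counts (allelic dosages) in [0, 2].

    ``snps`` is a per-SNP annotation table with at least columns
    ``snp_id, chrom, pos, ref, alt, maf`` and optionally
    ``imputed, imputation_rsq, call_rate, hwe_p``.
    """

    dosages: np.ndarray  # float, shape (n_samples, n_snps)
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def hard_genotypes(self) -> np.ndarray:
        """Rounded genotypes in {0,1,2}; dosage .5 rounds up (toward het/minor hom)."""
        return np.clip(np.floor(self.dosages + 0.5), 0, 2).astype(np.int8)

    def column(self, snp_id: str) -> np.ndarray:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.dosages[:, self.snps.index.get_loc(idx[0])]


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities with per-cell detection p-values."""

    values: pd.DataFrame  # probes x samples, log2 intensity
    detection_p: pd.DataFrame  # same shape, in [0, 1]
    tissue: str

    def __post_init__(self) -> None:
        if self.values.shape != self.detection_p.shape:
            raise ValueError("intensity and detection matrices differ in shape")
        if not self.values.index.equals(self.detection_p.index) or not (
            self.values.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("intensity and detection matrices differ in labels")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EqtlResult:
    """One SNP:probe association in one tissue from the dosage regression."""

    snp_id: str
    probe_id: str
    tissue: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    p: float
    q: float = np.nan
    status: str = "tested"  # tested | excluded_min_hom | excluded_undetected | collinear


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort with planted genotype structure."""

    n_samples: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    n_duplicate_pairs: int = 0
    n_outlier_samples: int = 0
    dosage_rsq: float = 1.0
    outlier_freq_shift: float = 0.2

    def validate(self) -> None:
        lo, hi = self.maf_range
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.dosage_rsq <= 1.0:
            raise ValueError("dosage_rsq must be in [0, 1]")
        if self.n_duplicate_pairs < 0 or self.n_outlier_samples < 0:
            raise ValueError("planted counts must be non-negative")
        if 2 * self.n_duplicate_pairs + self.n_outlier_samples >= self.n_samples:
            raise ValueError("duplicates + outliers must be fewer than n_samples")


@dataclass
class PlantedEffect:
    """A known cis-eQTL planted into the synthetic expression data.

    ``beta`` is the per-minor-allele shift in expression, in units of the
    residual SD of the probe.  ``tissue_set`` is where the genetic effect
    acts; ``expressed_in`` is where the probe is detectable at all.
    """

    snp_id: str
    probe_id: str
    tissue_set: frozenset[str]
    beta: float
    expressed_in: frozenset[str] = field(default_factory=lambda: frozenset(TISSUES))

    def __post_init__(self) -> None:
        self.tissue_set = frozenset(self.tissue_set)
        self.expressed_in = frozenset(self.expressed_in)
        unknown = (self.tissue_set | self.expressed_in) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissues {sorted(unknown)}")
        if not self.tissue_set <= self.expressed_in:
            raise ValueError("tissue_set must be a subset of expressed_in")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class PowerSpec:
    """Inputs to the additive-model power calculation.

    ``z`` is the normalized effect size: SDs of expression difference per
    minor allele.  ``variance_convention`` fixes what "SD" means —
    ``total_variance_1`` standardizes the phenotype to unit total variance
    (residual variance 1 - z^2 * 2p(1-p)); ``residual_variance_1`` leaves the
    residual at unit variance.
    """

    n: int
    maf: float
    z: float
    alpha: float
    variance_convention: str = "total_variance_1"

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.variance_convention not in ("total_variance_1", "residual_variance_1"):
            raise ValueError(f"unknown variance convention {self.variance_convention!r}")
        if self.variance_convention == "total_variance_1":
            if 2 * self.maf * (1 - self.maf) * self.z**2 >= 1.0:
                raise ValueError(
                    "genetic variance z^2 * 2p(1-p) must be < 1 under total_variance_1"
                )
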