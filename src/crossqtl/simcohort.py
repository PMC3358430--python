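"""Synthetic multi-tissue eQTL cohorts with a fully known planted architecture.

Generates genotypes in Hardy-Weinberg equilibrium with imputation-style
dosage noise, planted duplicate pairs and ancestry outliers, covariate
tables, per-tissue expression matrices with planted cis effects (shared,
tissue-specific, or expression-restricted), probe and SNP annotation, and
GWAS-catalog records with known filter outcomes.  All randomness is driven
by explicit seeds; a given spec reproduces its cohort exactly.

The additive expression model per probe and sample is

    y = mu + beta * dose * [tissue in tissue_set] + covariate loadings + N(0, sigma^2)

with beta in residual-SD units (sigma = 1 by default).  Probes whose
``expressed_in`` set excludes a tissue receive detection p-values above the
0.01 threshold there, so the detection filter removes them downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import TISSUES, CohortSpec, DosageMatrix, ExpressionMatrix, PlantedEffect

__all__ = [
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_catalog",
    "simulate_probes",
    "simulate_cohort",
    "SimulatedCohort",
    "DEFAULT_TRAIT_CLASSES",
]

_SNP_SPACING = 200_000  # bp between consecutive simulated SNPs


def simulate_genotypes(spec: CohortSpec) -> tuple[DosageMatrix, pd.DataFrame]:
    """Draw HWE genotypes and imputation-noised dosages from a cohort spec.

    Per SNP, hard genotypes are Binomial(2, MAF) draws; the dosage mixes the
    genotype toward its expectation, ``dosage = r*g + (1-r)*2p + e`` with
    ``r = dosage_rsq`` and the noise SD chosen so that the squared
    correlation between dosage and genotype equals ``dosage_rsq`` (the MACH
    r-squared semantics); the final clip into [0, 2] censors noise tails and
    raises the achieved r-squared slightly (by ~0.03 at r-squared 0.6).
    ``dosage_rsq = 1`` reproduces the genotypes exactly.  Planted duplicate pairs occupy the leading samples (pairwise
    identical rows); planted ancestry outliers occupy the trailing samples
    and are drawn at allele frequencies shifted by ``outlier_freq_shift``.

    Returns the dosage matrix (with SNP annotation attached) and a
    per-sample truth table (``is_outlier``, ``duplicate_of``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_snps
    mafs = rng.uniform(*spec.maf_range, size=m)
    g = rng.binomial(2, mafs, size=(n, m)).astype(float)

    # trailing samples: ancestry outliers at shifted allele frequencies
    n_out = spec.n_outlier_samples
    if n_out:
        shifted = np.clip(mafs + spec.outlier_freq_shift, 0.0, 1.0)
        g[n - n_out :, :] = rng.binomial(2, shifted, size=(n_out, m))

    # leading samples: exact duplicate pairs (0,1), (2,3), ...
    dup_of = [None] * n
    for k in range(spec.n_duplicate_pairs):
        a, b = 2 * k, 2 * k + 1
        g[b] = g[a]
        dup_of[b] = f"s{a:04d}"

    r = spec.dosage_rsq
    v = 2.0 * mafs * (1.0 - mafs)
    noise_sd = np.sqrt(np.clip(r**2 * v * (1.0 - r) / r, 0.0, None)) if r > 0 else np.zeros(m)
    dos = r * g + (1.0 - r) * 2.0 * mafs + rng.standard_normal((n, m)) * noise_sd
    for k in range(spec.n_duplicate_pairs):  # duplicates share dosage noise too
        dos[2 * k + 1] = dos[2 * k]
    dos = np.clip(dos, 0.0, 2.0)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": [(j + 1) * _SNP_SPACING for j in range(m)],
            "ref": "A",
            "alt": "B",
            "maf": mafs,
            "imputed": r < 1.0,
            "imputation_rsq": r,
        }
    )
    sample_info = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_outlier": [i >= n - n_out for i in range(n)],
            "duplicate_of": dup_of,
        }
    )
    return DosageMatrix(dos, sample_ids, snps), sample_info


def simulate_covariates(
    n_samples: int, seed: int, n_banks: int = 2, n_batches: int = 3
) -> pd.DataFrame:
    """Per-sample covariate table: age, gender, PMI, bank, batch, C1, C2."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n_samples)],
            "age_at_death": np.clip(rng.normal(70, 10, n_samples), 20, 100).round(1),
            "gender": rng.integers(0, 2, n_samples),
            "pmi": np.clip(rng.normal(24, 8, n_samples), 1, None).round(1),
            "tissue_bank": rng.choice([f"bank{k}" for k in range(n_banks)], n_samples),
            "hybridization_batch": rng.choice(
                [f"batch{k}" for k in range(n_batches)], n_samples
            ),
            "C1": rng.normal(0, 0.01, n_samples),
            "C2": rng.normal(0, 0.01, n_samples),
        }
    ).set_index("sample_id")


def simulate_expression(
    dosages: DosageMatrix,
    effects: list[PlantedEffect],
    covariates: pd.DataFrame,
    tissue: str,
    seed: int,
    probe_ids: list[str] | None = None,
    expressed_in: dict[str, frozenset[str]] | None = None,
    sigma: float = 1.0,
    baseline: float = 8.0,
    baseline_sd: float = 1.0,
    covariate_loading: float = 0.1,
) -> ExpressionMatrix:
    """Simulate one tissue's probes x samples expression matrix.

    Probes default to those named by the planted effects; extra (null)
    probes can be supplied via ``probe_ids`` with an ``expressed_in`` map.
    Each probe has a baseline abundance offset of SD ``baseline_sd`` derived
    deterministically from its id, so tissues share the same expression
    landscape and rank profiles are comparable across them.  Numeric
    covariates contribute ``covariate_loading`` SD each after
    standardization; categorical levels get seeded offsets of the same
    scale.  Detection p-values fall below 0.01 in every sample for probes
    expressed in this tissue and above it otherwise.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    snp_ids = set(dosages.snps["snp_id"])
    for eff in effects:
        if eff.snp_id not in snp_ids:
            raise ValueError(f"planted effect references unknown SNP {eff.snp_id!r}")
    if probe_ids is None:
        probe_ids = sorted({e.probe_id for e in effects})
    eff_probes = {e.probe_id for e in effects}
    if not eff_probes <= set(probe_ids):
        raise ValueError("planted effect references a probe absent from probe_ids")
    expr_in = dict(expressed_in or {})
    for e in effects:
        expr_in.setdefault(e.probe_id, e.expressed_in)

    rng = np.random.default_rng(seed)
    n = dosages.n_samples
    n_probes = len(probe_ids)

    # covariate contribution, shared across probes
    cov_shift = np.zeros(n)
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            sd = x.std()
            if sd > 0:
                cov_shift += covariate_loading * (x - x.mean()) / sd
        else:
            levels = sorted(col.astype(str).unique())
            offsets = dict(zip(levels, rng.normal(0, covariate_loading, len(levels))))
            cov_shift += col.astype(str).map(offsets).to_numpy()

    # per-probe baseline offsets keyed on the probe id: identical across tissues
    probe_base = np.array(
        [
            np.random.default_rng(zlib.crc32(pid.encode())).normal(0.0, baseline_sd)
            for pid in probe_ids
        ]
    )
    values = baseline + probe_base[:, None] + cov_shift + rng.standard_normal(
        (n_probes, n)
    ) * sigma
    for eff in effects:
        if tissue in eff.tissue_set:
            i = probe_ids.index(eff.probe_id)
            values[i] += eff.beta * dosages.column(eff.snp_id)

    det = np.empty((n_probes, n))
    for i, pid in enumerate(probe_ids):
        here = tissue in expr_in.get(pid, frozenset(TISSUES))
        det[i] = rng.uniform(0.0, 0.009, n) if here else rng.uniform(0.02, 1.0, n)
        if not here:  # undetected probes carry background signal only
            values[i] = baseline / 2.0 + rng.standard_normal(n) * sigma

    cols = list(dosages.sample_ids)
    return ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=cols),
        pd.DataFrame(det, index=probe_ids, columns=cols),
        tissue,
    )


# ---------------------------------------------------------------------------
# GWAS catalog fixtures

_TRAITS = {
    "blood": ["Mean corpuscular volume", "Platelet count", "Protein C levels"],
    "brain": ["Schizophrenia", "Alzheimer's disease", "Major depression"],
    "other": ["Height", "Type 1 diabetes", "Crohn's disease"],
}

#: Curated trait -> class mapping matching the simulated trait names.
DEFAULT_TRAIT_CLASSES = {t: cls for cls, ts in _TRAITS.items() for t in ts}

_CRITERIA = ("p", "initial_n", "replication_n", "n_snps", "ancestry", "raf")


def simulate_catalog(
    n_records: int,
    fraction_passing: float,
    trait_class_probs: dict[str, float] | None = None,
    seed: int = 0,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """GWAS-catalog records with known inclusion-filter outcomes.

    ``round(fraction_passing * n_records)`` records satisfy all six
    inclusion criteria; each remaining record violates a random non-empty
    subset, recorded in truth columns ``true_pass`` and ``true_violations``.
    Trait classes are drawn from ``trait_class_probs`` (default
    blood/brain/other = 0.3/0.2/0.5) and recorded as ``true_class``.
    """
    probs = trait_class_probs or {"blood": 0.3, "brain": 0.2, "other": 0.5}
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("trait_class_probs must sum to 1")
    if not 0.0 <= fraction_passing <= 1.0:
        raise ValueError("fraction_passing must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = round(fraction_passing * n_records)
    classes = rng.choice(list(probs), p=list(probs.values()), size=n_records)
    rows = []
    for i in range(n_records):
        cls = classes[i]
        rec = {
            "snp_id": (snp_ids[i % len(snp_ids)] if snp_ids else f"rs{100000 + i}"),
            "chrom": "1",
            "pos": (i + 1) * _SNP_SPACING,
            "trait": rng.choice(_TRAITS[cls]),
            "discovery_p": float(10 ** rng.uniform(-30, -7.4)),  # < 5e-8
            "initial_n": int(rng.integers(1001, 50_000)),
            "replication_n": int(rng.integers(501, 20_000)),
            "n_snps_in_study": int(rng.integers(100_001, 2_500_000)),
            "ancestry": "European",
            "risk_allele_freq": float(rng.uniform(0.01, 0.5)),
            "binary_trait": False,
            "true_class": cls,
        }
        if i < n_pass:
            rec["true_pass"] = True
            rec["true_violations"] = ""
        else:
            k = int(rng.integers(1, 4))
            viol = sorted(rng.choice(_CRITERIA, size=k, replace=False))
            for v in viol:
                if v == "p":
                    rec["discovery_p"] = float(10 ** rng.uniform(-7.3, -3))
                elif v == "initial_n":
                    rec["initial_n"] = int(rng.integers(50, 1001))
                elif v == "replication_n":
                    rec["replication_n"] = int(rng.integers(10, 501))
                elif v == "n_snps":
                    rec["n_snps_in_study"] = int(rng.integers(1000, 100_001))
                elif v == "ancestry":
                    rec["ancestry"] = str(rng.choice(["East Asian", "African", "Mixed"]))
                elif v == "raf":
                    rec["risk_allele_freq"] = float(rng.uniform(0.0005, 0.0099))
            rec["true_pass"] = False
            rec["true_violations"] = ",".join(viol)
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_probes(
    snps: pd.DataFrame,
    effects: list[PlantedEffect],
    n_null_probes: int = 0,
    seed: int = 0,
    offset_bp: int = 10_000,
) -> pd.DataFrame:
    """BED-style 50-mer probe annotation placed in cis of the simulated SNPs.

    Each planted effect's probe sits ``offset_bp`` downstream of its SNP;
    null probes are scattered near randomly chosen SNPs.  All probes are
    flagged ``good`` (quality-flag violations are planted by tests).
    """
    rng = np.random.default_rng(seed)
    pos_by_snp = dict(zip(snps["snp_id"], snps["pos"]))
    chrom_by_snp = dict(zip(snps["snp_id"], snps["chrom"]))
    rows = []
    for eff in effects:
        start = pos_by_snp[eff.snp_id] + offset_bp
        rows.append(
            {
                "probe_id": eff.probe_id,
                "chrom": chrom_by_snp[eff.snp_id],
                "start": start,
                "end": start + 50,
                "quality_flag": "good",
                "maps_to_gene": f"GENE_{eff.probe_id}",
            }
        )
    used = {r["probe_id"] for r in rows}
    snp_choices = rng.choice(len(snps), size=n_null_probes) if n_null_probes else []
    for k, j in enumerate(snp_choices):
        pid = f"nullprobe{k:05d}"
        assert pid not in used
        start = int(snps["pos"].iloc[j]) + offset_bp + 100 * (k + 1)
        rows.append(
            {
                "probe_id": pid,
                "chrom": snps["chrom"].iloc[j],
                "start": start,
                "end": start + 50,
                "quality_flag": "good",
                "maps_to_gene": f"GENE_{pid}",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """Everything a pipeline run needs, plus the planted truth."""

    dosages: DosageMatrix
    covariates: pd.DataFrame
    expression: dict[str, ExpressionMatrix]
    probes: pd.DataFrame
    catalog: pd.DataFrame
    effects: list[PlantedEffect]
    sample_info: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)


def simulate_cohort(
    spec: CohortSpec,
    effects: list[PlantedEffect] | None = None,
    tissues: tuple[str, ...] = TISSUES,
    n_null_probes: int = 0,
    n_catalog_records: int = 0,
    catalog_fraction_passing: float = 1.0,
    sigma: float = 1.0,
    covariate_loading: float = 0.1,
) -> SimulatedCohort:
    """End-to-end synthetic cohort: genotypes, covariates, expression, annotation.

    Derives per-stage seeds from ``spec.seed`` so the whole bundle is a
    deterministic function of the spec and effect list.
    """
    effects = effects or []
    dosages, sample_info = simulate_genotypes(spec)
    covariates = simulate_covariates(spec.n_samples, seed=spec.seed + 1)
    probes = simulate_probes(dosages.snps, effects, n_null_probes, seed=spec.seed + 2)
    probe_ids = list(probes["probe_id"])
    expression = {
        t: simulate_expression(
            dosages,
            effects,
            covariates,
            t,
            seed=spec.seed + 10 + k,
            probe_ids=probe_ids,
            sigma=sigma,
            covariate_loading=covariate_loading,
        )
        for k, t in enumerate(tissues)
    }
    catalog = (
        simulate_catalog(
            n_catalog_records,
            catalog_fraction_passing,
            seed=spec.seed + 5,
            snp_ids=list(dosages.snps["snp_id"]),
        )
        if n_catalog_records
        else pd.DataFrame()
    )
    return SimulatedCohort(
        dosages, covariates, expression, probes, catalog, effects, sample_info, spec
    )
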