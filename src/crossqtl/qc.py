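"""Genotype- and sample-level quality control.

Reproduces the PLINK-stage filters of a GWAS-era eQTL study: per-SNP
exclusions (call rate, MAF, Hardy-Weinberg exact test, imputation quality),
LD pruning in sliding windows, identity-by-state distances with classical
MDS for ancestry outlier detection, and method-of-moments IBD (pi-hat)
relatedness exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DosageMatrix

__all__ = [
    "SnpFilterThresholds",
    "filter_snps",
    "snp_qc_stats",
    "hwe_exact_test",
    "ld_prune",
    "ibs_distance_matrix",
    "ibs_mds",
    "MdsResult",
    "relatedness_exclude",
    "RelatednessResult",
]


# ---------------------------------------------------------------------------
# SNP filters


@dataclass
class SnpFilterThresholds:
    """Per-SNP exclusion thresholds; defaults are the study's values."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-7
    min_imputation_rsq: float = 0.3


_REQUIRED_SNP_FIELDS = ("snp_id", "call_rate", "maf", "hwe_p")


def filter_snps(
    snps: pd.DataFrame, thresholds: SnpFilterThresholds | None = None
) -> pd.DataFrame:
    """Partition SNPs into kept/dropped with per-SNP reason codes.

    Drop iff call_rate < 0.95, MAF < 0.01, or HWE p < 1e-7 (strict
    comparisons).  SNPs flagged ``imputed`` are additionally dropped iff
    MAF < 0.01 or imputation r^2 < 0.3; the call-rate and HWE filters apply
    to directly genotyped SNPs.  A record with a missing required field is
    dropped with reason ``malformed``.

    Returns a copy of ``snps`` with boolean ``kept`` and comma-joined
    ``reasons`` columns.  Pure per-record predicate: idempotent and
    order-independent.
    """
    th = thresholds or SnpFilterThresholds()
    out = snps.copy()
    reasons: list[str] = []
    for _, rec in out.iterrows():
        recr: list[str] = []
        if any(pd.isna(rec.get(f)) for f in _REQUIRED_SNP_FIELDS):
            reasons.append("malformed")
            continue
        imputed = bool(rec.get("imputed", False))
        if imputed:
            if rec["maf"] < th.min_maf:
                recr.append("maf")
            rsq = rec.get("imputation_rsq")
            if pd.isna(rsq):
                recr.append("malformed")
            elif rsq < th.min_imputation_rsq:
                recr.append("rsq")
        else:
            if rec["call_rate"] < th.min_call_rate:
                recr.append("callrate")
            if rec["maf"] < th.min_maf:
                recr.append("maf")
            if rec["hwe_p"] < th.min_hwe_p:
                recr.append("hwe")
        reasons.append(",".join(recr))
    out["reasons"] = reasons
    out["kept"] = out["reasons"] == ""
    return out


def snp_qc_stats(dosages: DosageMatrix) -> pd.DataFrame:
    """Annotate SNPs with empirical call rate, MAF, and HWE exact p.

    Call rate is the fraction of non-missing dosages; MAF and the HWE test
    use hard genotypes.  The minor allele is defined per cohort from the
    observed dosage mean (frequency > 0.5 flips which allele is counted);
    an exact 0.5 tie keeps the lexicographically smaller allele string as
    minor.
    """
    out = dosages.snps.copy()
    g = dosages.hard_genotypes().astype(float)
    missing = ~np.isfinite(dosages.dosages)
    g[missing] = np.nan
    out["call_rate"] = 1.0 - missing.mean(axis=0)
    mafs, hwe_ps = [], []
    for j in range(dosages.n_snps):
        col = g[:, j]
        col = col[np.isfinite(col)]
        counts = [(col == k).sum() for k in (0, 1, 2)]
        freq = (counts[1] + 2 * counts[2]) / (2 * max(1, len(col)))
        if freq > 0.5 or (
            freq == 0.5 and str(out["alt"].iloc[j]) > str(out["ref"].iloc[j])
        ):
            counts = counts[::-1]
            freq = 1.0 - freq
        mafs.append(freq)
        hwe_ps.append(hwe_exact_test(counts[0], counts[1], counts[2]) if len(col) else np.nan)
    out["maf"] = mafs
    out["hwe_p"] = hwe_ps
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts with the same parity, the probabilities of
    configurations no more probable than the observed one:

        P(het = h | nA, n) proportional to 2^h * n! / (nAA! * h! * naa!).

    This is the standard exact HWE test used by genotype-QC tools (plain
    p, no mid-p adjustment).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # minor allele count (either allele works by symmetry)
    rare = min(n_a, 2 * n - n_a)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.array(
        [
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma((rare - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((2 * n - rare - h) // 2 + 1)
            for h in hets
        ]
    )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    # tolerance guards against float ties in the <= comparison
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    dosages: DosageMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Greedy sliding-window LD pruning on dosage correlations.

    Within each window of ``window_snps`` consecutive SNPs (per chromosome,
    positional order), any pair of retained SNPs with squared dosage
    correlation above ``r2_threshold`` loses its later member; the window
    then advances by ``step_snps``.  Zero-variance SNPs are treated as
    uncorrelated and kept.  Deterministic given input order; returns kept
    SNP ids in positional order.
    """
    snps = dosages.snps
    keep = np.ones(dosages.n_snps, dtype=bool)
    X = dosages.dosages
    sd = X.std(axis=0)
    for _, chrom_idx in snps.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(chrom_idx)
        idx = idx[np.argsort(snps["pos"].to_numpy()[idx], kind="stable")]
        m = len(idx)
        start = 0
        while True:
            win = idx[start : start + window_snps]
            active = [j for j in win if keep[j] and sd[j] > 0]
            if len(active) > 1:
                sub = X[:, active]
                r = np.corrcoef(sub, rowvar=False)
                for a in range(len(active)):
                    if not keep[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if keep[active[b]] and r[a, b] ** 2 > r2_threshold:
                            keep[active[b]] = False
            if start + window_snps >= m:
                break
            start += step_snps
    return [snps["snp_id"].iloc[j] for j in range(dosages.n_snps) if keep[j]]


# ---------------------------------------------------------------------------
# IBS distances, classical MDS, ancestry outliers


def ibs_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise IBS distance = 1 - mean shared-allele fraction.

    Per SNP the shared fraction between two hard genotypes g, g' in {0,1,2}
    is 1 - |g - g'| / 2 (i.e. 0, 1/2 or 1); the distance averages over SNPs.
    """
    g = np.asarray(genotypes, dtype=float)
    # |g_i - g_j| summed over SNPs, via cityblock identity
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(g, metric="cityblock"))
    return d / (2.0 * g.shape[1])


@dataclass
class MdsResult:
    components: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray
    outlier: np.ndarray  # boolean per sample
    sample_ids: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = {f"C{k+1}": self.components[:, k] for k in range(self.components.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols, "outlier": self.outlier})


def ibs_mds(
    dosages: DosageMatrix,
    n_components: int = 2,
    sd_threshold: float = 3.0,
    reference_samples: list[str] | None = None,
) -> MdsResult:
    """Classical (Torgerson) MDS of IBS distances with outlier flags.

    Double-centers the squared-distance matrix, eigendecomposes it, and
    returns the leading coordinates scaled by sqrt(eigenvalue), so component
    variances are ordered (C1 >= C2 >= ...).  A sample is an ancestry
    outlier iff |C_k - mean(C_k)| > sd_threshold * SD(C_k) for k = 1 or 2,
    with mean/SD taken over ``reference_samples`` (a stand-in for external
    reference-population samples; default all samples).  A degenerate
    (all-identical) cohort yields zero components and no outliers.
    """
    if dosages.n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    g = dosages.hard_genotypes()
    d = ibs_distance_matrix(g)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    comps = evecs * np.sqrt(pos)

    if reference_samples is None:
        ref_mask = np.ones(n, dtype=bool)
    else:
        ref_set = set(reference_samples)
        ref_mask = np.array([s in ref_set for s in dosages.sample_ids])
        if not ref_mask.any():
            raise ValueError("reference_samples matches no cohort sample")
    outlier = np.zeros(n, dtype=bool)
    for k in range(min(2, comps.shape[1])):
        col = comps[:, k]
        mu, sd = col[ref_mask].mean(), col[ref_mask].std()
        if sd > 0:
            outlier |= np.abs(col - mu) > sd_threshold * sd
    return MdsResult(comps, evals, outlier, list(dosages.sample_ids))


# ---------------------------------------------------------------------------
# Relatedness (pi-hat) exclusion


@dataclass
class RelatednessResult:
    sample_a: str
    sample_b: str
    ibs_distance: float
    pihat: float


def _pihat_pairs(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Method-of-moments P(IBD=z) from IBS counts and allele frequencies.

    Returns the (n, n) symmetric pi-hat matrix, pi = P(IBD=2) + P(IBD=1)/2,
    clamped to [0, 1].  Expected IBS sharing given each IBD state uses
    finite-sample (falling-factorial) corrections for allele frequencies
    estimated from the cohort itself, so unrelated pairs center near zero
    even in small cohorts.
    """
    n = g.shape[0]
    T = 2.0 * n  # alleles behind each in-sample frequency estimate
    X = T * p  # minor-allele counts
    Y = T - X

    def ff(x: np.ndarray | float, k: int) -> np.ndarray | float:
        out = np.ones_like(np.asarray(x, dtype=float))
        for i in range(k):
            out = out * (x - i)
        return out

    f4, f3 = ff(T, 4), ff(T, 3)
    e_ibs0_z0 = float(np.sum(2 * ff(X, 2) * ff(Y, 2) / f4))
    e_ibs1_z0 = float(np.sum((4 * ff(X, 3) * Y + 4 * X * ff(Y, 3)) / f4))
    e_ibs2_z0 = float(np.sum((ff(X, 4) + ff(Y, 4) + 4 * ff(X, 2) * ff(Y, 2)) / f4))
    e_ibs1_z1 = float(np.sum((2 * ff(X, 2) * Y + 2 * X * ff(Y, 2)) / f3))
    e_ibs2_z1 = float(
        np.sum((ff(X, 3) + ff(Y, 3) + ff(X, 2) * Y + X * ff(Y, 2)) / f3)
    )
    m = g.shape[1]

    from scipy.spatial.distance import squareform, pdist

    diff = squareform(pdist(g.astype(float), metric="cityblock"))  # sum |gi-gj|
    # IBS2 count: SNPs with identical genotypes; IBS0: |diff| == 2 per SNP.
    eq = squareform(pdist(g.astype(float), metric="hamming")) * m  # unequal count
    n_ibs2 = m - eq
    # diff = 1*ibs1 + 2*ibs0, eq = ibs1 + ibs0  =>  ibs0 = diff - eq
    n_ibs0 = diff - eq
    n_ibs1 = eq - n_ibs0

    z0 = n_ibs0 / e_ibs0_z0 if e_ibs0_z0 > 0 else np.zeros_like(n_ibs0)
    z1 = (n_ibs1 - z0 * e_ibs1_z0) / e_ibs1_z1 if e_ibs1_z1 > 0 else np.zeros_like(n_ibs1)
    e_ibs2_z2 = m
    z2 = (n_ibs2 - z0 * e_ibs2_z0 - z1 * e_ibs2_z1) / e_ibs2_z2
    # only the final pi-hat is clamped: clamping the per-state estimates
    # would bias pi-hat upward for unrelated pairs
    return np.clip(z2 + 0.5 * z1, 0.0, 1.0)


def relatedness_exclude(
    dosages: DosageMatrix,
    threshold: float = 0.15,
    call_rates: dict[str, float] | None = None,
    min_snps: int = 100,
) -> tuple[list[str], list[RelatednessResult]]:
    """Exclude one member of every pair sharing pi-hat strictly above threshold.

    The excluded member is the one with lower call rate; ties (including the
    no-call-rate case) drop the later sample id.  Returns excluded ids and
    the per-pair estimates for pairs above threshold.

    The moment estimator needs many independent markers to be usable; with
    fewer than ``min_snps`` polymorphic SNPs its sampling noise swamps the
    0.15 threshold, so the step is skipped with a warning.
    """
    if dosages.n_samples < 2:
        return [], []
    g = dosages.hard_genotypes()
    p = g.mean(axis=0) / 2.0  # frequency of the dosage-counted allele
    keep_snp = (p > 0) & (p < 1)
    if keep_snp.sum() < min_snps:
        import warnings

        warnings.warn(
            f"only {int(keep_snp.sum())} polymorphic SNPs (< {min_snps}); "
            "pi-hat too noisy, relatedness exclusion skipped",
            stacklevel=2,
        )
        return [], []
    pihat = _pihat_pairs(g[:, keep_snp], p[keep_snp])
    dist = ibs_distance_matrix(g[:, keep_snp])
    ids = dosages.sample_ids
    cr = call_rates or {}
    excluded: list[str] = []
    results: list[RelatednessResult] = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if pihat[i, j] > threshold:
                results.append(
                    RelatednessResult(ids[i], ids[j], float(dist[i, j]), float(pihat[i, j]))
                )
                if ids[i] in excluded or ids[j] in excluded:
                    continue
                cri, crj = cr.get(ids[i], 1.0), cr.get(ids[j], 1.0)
                if cri < crj:
                    excluded.append(ids[i])
                elif crj < cri:
                    excluded.append(ids[j])
                else:
                    excluded.append(max(ids[i], ids[j]))
    return excluded, results
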