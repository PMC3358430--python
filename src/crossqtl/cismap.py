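"""Core cis-eQTL engine.

Pairs GWAS SNPs with mRNA probes inside a ±500 kb cis window, filters SNPs
with fewer than 3 minor-allele homozygotes, regresses expression on allelic
dosage with biological and methodological covariates, adjusts p-values by
Benjamini-Hochberg within each tissue and analysis track, extracts the
consensus set of pairs testable in every tissue, and supports conditional
analysis on a proxy SNP (e.g. a haplotype-tagging variant).

The regression is ordinary least squares of expression on
``[intercept, dose, covariates]`` solved by QR; the dose coefficient's
two-sided p-value uses the t distribution with n - k degrees of freedom.
Continuous dosage enters the model as-is; only the minor-homozygote filter
uses rounded (maximum-likelihood-style) genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DosageMatrix, EqtlResult

__all__ = [
    "pair_cis",
    "min_homozygote_filter",
    "build_design",
    "fit_eqtl",
    "conditional_fit",
    "ConditionalResult",
    "bh_fdr",
    "consensus_set",
    "scan_tissue",
]

CIS_WINDOW = 500_000


def _norm_chrom(c: object) -> str:
    s = str(c).lower()
    return s[3:] if s.startswith("chr") else s


def pair_cis(
    snps: pd.DataFrame, probes: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All SNP:probe pairs on the same chromosome within ``window`` bp.

    The probe's reference point is the midpoint of its 50-mer interval
    (BED 0-based half-open ``start``/``end`` -> 1-based midpoint
    (start + end + 1) / 2); distance is |snp_pos - midpoint|, inclusive at
    the window edge.  Chromosome dialects ("chr1" vs "1") are normalized.
    """
    s = snps[["snp_id", "chrom", "pos"]].copy()
    s["chrom"] = s["chrom"].map(_norm_chrom)
    p = probes[["probe_id", "chrom", "start", "end"]].copy()
    p["chrom"] = p["chrom"].map(_norm_chrom)
    p["midpoint"] = (p["start"] + p["end"] + 1) / 2.0
    merged = s.merge(p, on="chrom")
    merged["distance"] = (merged["pos"] - merged["midpoint"]).abs()
    keep = merged["distance"] <= window
    return (
        merged.loc[keep, ["snp_id", "probe_id", "distance"]]
        .sort_values(["snp_id", "probe_id"], kind="stable")
        .reset_index(drop=True)
    )


def min_homozygote_filter(
    dosages: DosageMatrix, snp_id: str, min_count: int = 3
) -> bool:
    """True iff the SNP has at least ``min_count`` minor-allele homozygotes.

    Counted on rounded genotypes (== 2), the hard-call view of imputed
    dosages.
    """
    g = np.clip(np.floor(dosages.column(snp_id) + 0.5), 0, 2)
    return int((g == 2).sum()) >= min_count


def build_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Covariate block of the regression design (no intercept/dose columns).

    Numeric columns pass through; categorical/object columns expand to
    indicator columns against the most frequent level as reference.
    """
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0))
    cols: list[np.ndarray] = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = col.astype(str)
            ref = levels.value_counts().idxmax()
            for lev in sorted(levels.unique()):
                if lev != ref:
                    cols.append((levels == lev).to_numpy(dtype=float))
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _ols_dose(
    y: np.ndarray, dose: np.ndarray, cov_block: np.ndarray
) -> tuple[float, float, float, float, int, str]:
    """OLS of y on [1, dose, cov]; returns beta, se, t, p, n_used, status."""
    n = len(y)
    X = np.column_stack([np.ones(n), dose, cov_block])
    k = X.shape[1]
    if n < k + 1:  # need at least one residual degree of freedom
        return np.nan, np.nan, np.nan, np.nan, n, "insufficient_n"
    q, r = np.linalg.qr(X)
    if abs(np.diag(r)).min() < 1e-10 * max(1.0, abs(np.diag(r)).max()):
        return np.nan, np.nan, np.nan, np.nan, n, "collinear"
    beta_all = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta_all
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    rinv = np.linalg.inv(r)
    xtx_inv_diag = (rinv * rinv).sum(axis=1)
    se = float(np.sqrt(sigma2 * xtx_inv_diag[1]))
    beta = float(beta_all[1])
    if se == 0.0:
        return beta, se, np.inf, 0.0, n, "tested"
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return beta, se, float(t), p, n, "tested"


def fit_eqtl(
    y: np.ndarray | pd.Series,
    dose: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
    probe_id: str = "",
    tissue: str = "",
) -> EqtlResult:
    """Covariate-adjusted allelic-dosage regression for one SNP:probe pair.

    Samples with a missing expression, dosage, or covariate value are
    dropped pairwise.  A collinear design (including constant dosage after
    filtering) yields ``status='collinear'`` with NaN statistics, not an
    exception.
    """
    y = np.asarray(y, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if y.shape != dose.shape:
        raise ValueError("y and dose must have equal length")
    cov_block = build_design(covariates, len(y))
    ok = np.isfinite(y) & np.isfinite(dose)
    if cov_block.shape[1]:
        ok &= np.isfinite(cov_block).all(axis=1)
    beta, se, t, p, n_used, status = _ols_dose(y[ok], dose[ok], cov_block[ok])
    return EqtlResult(snp_id, probe_id, tissue, n_used, beta, se, t, p, status=status)


@dataclass
class ConditionalResult:
    """Marginal and proxy-conditional association for one pair."""

    marginal: EqtlResult
    conditional: EqtlResult


def conditional_fit(
    y: np.ndarray | pd.Series,
    dose: np.ndarray | pd.Series,
    proxy_dose: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    **ids: str,
) -> ConditionalResult:
    """Dosage regression with and without a proxy SNP as extra covariate.

    If an eQTL signal acts through a haplotype tagged by the proxy,
    conditioning on the proxy absorbs it and the dose p-value rises.  A
    proxy identical to the dose makes the conditional design collinear,
    reported via the status flag.
    """
    proxy = np.asarray(proxy_dose, dtype=float)
    marginal = fit_eqtl(y, dose, covariates, **ids)
    cov_with_proxy = pd.DataFrame({"__proxy__": proxy})
    if covariates is not None:
        cov_with_proxy = pd.concat(
            [covariates.reset_index(drop=True), cov_with_proxy], axis=1
        )
    conditional = fit_eqtl(y, dose, cov_with_proxy, **ids)
    return ConditionalResult(marginal, conditional)


def bh_fdr(pvals: np.ndarray | list[float], q_thresh: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjusted q-values and q < 0.05 flags."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "q": [], "significant": []})
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_thresh, method="fdr_bh")
    return pd.DataFrame({"p": p, "q": q, "significant": q < q_thresh})


def scan_tissue(
    dosages: DosageMatrix,
    expr_values: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None,
    tissue: str,
    detected_probes: set[str] | None = None,
    min_hom: int = 3,
) -> pd.DataFrame:
    """Fit every cis pair in one tissue; returns a results table with BH q.

    Pairs whose probe failed detection get ``excluded_undetected``; SNPs
    failing the minor-homozygote rule get ``excluded_min_hom``.  The BH
    family is the set of pairs actually tested in this tissue and track.
    Output is ordered by (snp_id, probe_id), independent of input order.
    """
    snp_idx = {s: i for i, s in enumerate(dosages.snps["snp_id"])}
    hard = dosages.hard_genotypes()
    min_hom_ok = (hard == 2).sum(axis=0) >= min_hom
    # covariate design is shared by every fit in this tissue
    cov_block = build_design(covariates, dosages.n_samples)
    expr_arr = expr_values.to_numpy(dtype=float)
    probe_row = {p: i for i, p in enumerate(expr_values.index)}
    rows: list[EqtlResult] = []
    for snp_id, probe_id in pairs[["snp_id", "probe_id"]].itertuples(index=False):
        if detected_probes is not None and probe_id not in detected_probes:
            rows.append(
                EqtlResult(snp_id, probe_id, tissue, 0, np.nan, np.nan, np.nan,
                           np.nan, status="excluded_undetected")
            )
            continue
        j = snp_idx[snp_id]
        if not min_hom_ok[j]:
            rows.append(
                EqtlResult(snp_id, probe_id, tissue, 0, np.nan, np.nan, np.nan,
                           np.nan, status="excluded_min_hom")
            )
            continue
        y = expr_arr[probe_row[probe_id]]
        dose = dosages.dosages[:, j]
        ok = np.isfinite(y) & np.isfinite(dose)
        if cov_block.shape[1]:
            ok &= np.isfinite(cov_block).all(axis=1)
        beta, se, t, p, n_used, status = _ols_dose(y[ok], dose[ok], cov_block[ok])
        rows.append(EqtlResult(snp_id, probe_id, tissue, n_used, beta, se, t, p,
                               status=status))
    out = pd.DataFrame([vars(r) for r in rows])
    if len(out):
        out = out.sort_values(["snp_id", "probe_id"], kind="stable").reset_index(drop=True)
        tested = out["status"] == "tested"
        if tested.any():
            out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())["q"].to_numpy()
    return out


def adjust_track(wide: pd.DataFrame, tissues: list[str]) -> pd.DataFrame:
    """Recompute BH q-values within one analysis track, per tissue.

    The FDR family is the set of pairs in this track (consensus and
    expression-restricted tracks are adjusted separately), so q columns must
    be refreshed after the track is carved out of the full per-tissue scans.
    """
    out = wide.copy()
    for t in tissues:
        pcol = f"p_{t}"
        if pcol in out.columns and len(out):
            out[f"q_{t}"] = bh_fdr(out[pcol].to_numpy())["q"].to_numpy()
    return out


def consensus_set(results_by_tissue: dict[str, pd.DataFrame]) -> tuple[
    pd.DataFrame, pd.DataFrame
]:
    """Split pairs into the consensus set (tested in every tissue) and the rest.

    Returns ``(consensus, complement)``: the consensus frame has one row per
    (snp_id, probe_id) with per-tissue ``beta_<t>, p_<t>, q_<t>`` columns; the
    complement lists pairs tested in only a subset, with the tissues where
    each was tested — the expression-restricted analysis track.
    """
    if len(results_by_tissue) < 2:
        raise ValueError("consensus needs results from at least 2 tissues")
    tested_sets = {
        t: set(map(tuple, df.loc[df["status"] == "tested", ["snp_id", "probe_id"]].values))
        for t, df in results_by_tissue.items()
    }
    common = set.intersection(*tested_sets.values())
    any_tested = set.union(*tested_sets.values())

    wide: pd.DataFrame | None = None
    for t, df in results_by_tissue.items():
        sub = df[df["status"] == "tested"][["snp_id", "probe_id", "beta", "p", "q"]]
        sub = sub.rename(columns={c: f"{c}_{t}" for c in ("beta", "p", "q")})
        wide = sub if wide is None else wide.merge(sub, on=["snp_id", "probe_id"])
    if wide is None or len(common) == 0:
        consensus = pd.DataFrame(columns=["snp_id", "probe_id"])
    else:
        key = list(map(tuple, wide[["snp_id", "probe_id"]].values))
        consensus = wide[[k in common for k in key]].reset_index(drop=True)

    comp_rows = []
    for snp_id, probe_id in sorted(any_tested - common):
        in_tissues = sorted(t for t, s in tested_sets.items() if (snp_id, probe_id) in s)
        comp_rows.append(
            {"snp_id": snp_id, "probe_id": probe_id, "tested_in": ",".join(in_tissues)}
        )
    complement = pd.DataFrame(comp_rows, columns=["snp_id", "probe_id", "tested_in"])
    return consensus, complement
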