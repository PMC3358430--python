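"""GWAS-catalog record filtering and trait-class annotation.

The study design restricts eQTL testing to SNPs from a GWAS catalog extract
that pass six inclusion criteria: discovery p < 5e-8, initial sample (or
case) count > 1000, replication sample (or case) count > 500, > 100,000 SNPs
genotyped in the study, European ancestry, and risk-allele frequency >= 0.01.
Trait classes (blood / brain / other) are a manually curated input mapping,
not computed.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["filter_catalog", "annotate_traits", "distinct_snp_view"]

_REQUIRED_FIELDS = (
    "snp_id",
    "trait",
    "discovery_p",
    "n_snps_in_study",
    "ancestry",
    "risk_allele_freq",
)


def _effective_n(rec: pd.Series, n_field: str, cases_field: str) -> float:
    """Sample size criterion value: case count for binomial traits, else total n."""
    if bool(rec.get("binary_trait", False)) and not pd.isna(rec.get(cases_field)):
        return rec[cases_field]
    return rec.get(n_field, float("nan"))


def filter_catalog(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the six inclusion criteria; annotate per-record reason codes.

    Comparisons are strict (<, >) except risk-allele frequency (>=).
    Ancestry matches case-insensitively on the substring "european" (the
    catalog's ancestry field is free text).  Missing required fields give
    reason ``malformed``.  Returns a copy with ``kept`` and ``reasons``
    columns; a pure per-record predicate (order-independent, idempotent).
    """
    out = records.copy()
    reasons: list[str] = []
    for _, rec in out.iterrows():
        if any(pd.isna(rec.get(f)) for f in _REQUIRED_FIELDS):
            reasons.append("malformed")
            continue
        recr: list[str] = []
        if not rec["discovery_p"] < 5e-8:
            recr.append("p")
        init_n = _effective_n(rec, "initial_n", "initial_cases")
        if pd.isna(init_n) or not init_n > 1000:
            recr.append("initial_n")
        repl_n = _effective_n(rec, "replication_n", "replication_cases")
        if pd.isna(repl_n) or not repl_n > 500:
            recr.append("replication_n")
        if not rec["n_snps_in_study"] > 100_000:
            recr.append("n_snps")
        if "european" not in str(rec["ancestry"]).lower():
            recr.append("ancestry")
        if not rec["risk_allele_freq"] >= 0.01:
            recr.append("raf")
        reasons.append(",".join(recr))
    out["reasons"] = reasons
    out["kept"] = out["reasons"] == ""
    return out


def annotate_traits(records: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Attach blood/brain/other trait classes via exact-string lookup.

    Traits absent from the mapping become ``unassigned`` with a warning;
    the mapping is a curated input, never inferred.
    """
    out = records.copy()
    classes = [mapping.get(t, "unassigned") for t in out["trait"]]
    missing = sorted({t for t, c in zip(out["trait"], classes) if c == "unassigned"})
    if missing:
        warnings.warn(
            f"{len(missing)} trait(s) not in mapping, set to 'unassigned': "
            + ", ".join(missing[:10]),
            stacklevel=2,
        )
    out["trait_class"] = classes
    return out


def distinct_snp_view(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate SNP ids across studies to one row per SNP.

    Keeps the first record per SNP id in input order; per-SNP counting is
    used for summary tables, while association testing keeps one record per
    catalog row.
    """
    return records.drop_duplicates(subset="snp_id", keep="first").reset_index(drop=True)
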