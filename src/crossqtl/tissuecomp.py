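"""Cross-tissue comparison of eQTL results.

Classifies each SNP:probe pair as shared across tissues, blood- or
brain-specific, or detectable only where the probe is expressed; checks
direction-of-effect consistency; tabulates tested/significant counts by
tissue and GWAS trait class; and compares proportions with chi-squared and
two-proportion z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

BLOOD = "blood"
BRAIN_TISSUES = ("frontal_cortex", "cerebellum")

__all__ = [
    "classify_sharing",
    "direction_consistency",
    "count_table",
    "proportion_tests",
    "ProportionTestResult",
]


def classify_sharing(
    consensus: pd.DataFrame,
    restricted: pd.DataFrame | None = None,
    q_thresh: float = 0.05,
    strict: bool = True,
    blood: str = BLOOD,
    brain: tuple[str, str] = BRAIN_TISSUES,
) -> pd.DataFrame:
    """Assign a sharing call to every SNP:probe pair.

    Consensus pairs (tested in all tissues):

    - ``shared_all``: q < thresh in blood and in both brain regions
      (``strict=True``), or in blood and at least one brain region
      (``strict=False``).
    - ``blood_specific``: q < thresh in blood, q >= thresh in both brain
      regions.
    - ``brain_specific``: q < thresh in at least one brain region, q >=
      thresh in blood.
    - ``null`` otherwise.

    Restricted pairs (probe detected in a subset of tissues) get
    ``blood_restricted_expression`` / ``brain_restricted_expression`` by
    which tissue group could test them, or ``null`` if not significant
    there.
    """
    for t in (blood, *brain):
        if f"q_{t}" not in consensus.columns:
            raise ValueError(f"consensus results missing tissue column q_{t}")
    calls = []
    for _, row in consensus.iterrows():
        sig_blood = row[f"q_{blood}"] < q_thresh
        sig_brain = [row[f"q_{t}"] < q_thresh for t in brain]
        if sig_blood and (all(sig_brain) if strict else any(sig_brain)):
            call = "shared_all"
        elif sig_blood and not any(sig_brain):
            call = "blood_specific"
        elif any(sig_brain) and not sig_blood:
            call = "brain_specific"
        else:
            call = "null"
        calls.append(call)
    out = consensus.copy()
    out["call"] = calls

    if restricted is not None and len(restricted):
        rest = restricted.copy()
        rest_calls = []
        for _, row in rest.iterrows():
            tissues = set(str(row["tested_in"]).split(","))
            sig = row.get("significant_any", True)
            if not sig:
                rest_calls.append("null")
            elif blood in tissues:
                rest_calls.append("blood_restricted_expression")
            else:
                rest_calls.append("brain_restricted_expression")
        rest["call"] = rest_calls
        out = pd.concat([out, rest], ignore_index=True)
    return out


def direction_consistency(betas: pd.DataFrame) -> pd.Series:
    """Per-pair flag: do all per-tissue effect estimates share one sign?

    ``betas`` holds one column per tissue.  A zero beta is counted as
    inconsistent (no direction).  NaN anywhere makes the pair inconsistent.
    """
    b = betas.to_numpy(dtype=float)
    consistent = np.all(b > 0, axis=1) | np.all(b < 0, axis=1)
    return pd.Series(consistent, index=betas.index, name="direction_consistent")


def count_table(calls: pd.DataFrame, significant_calls: set[str] | None = None) -> pd.DataFrame:
    """Tested/significant counts and row percentages by trait class.

    ``calls`` must carry ``trait_class`` (via the pair's GWAS SNP) and
    ``call``; a SNP appearing in several catalog records contributes once
    per record.  Pairs with class ``unassigned`` are counted under
    ``other`` with a warning.
    """
    if significant_calls is None:
        significant_calls = {
            "shared_all",
            "blood_specific",
            "brain_specific",
            "blood_restricted_expression",
            "brain_restricted_expression",
        }
    df = calls.copy()
    if (df["trait_class"] == "unassigned").any():
        warnings.warn("unassigned trait classes counted as 'other'", stacklevel=2)
        df.loc[df["trait_class"] == "unassigned", "trait_class"] = "other"
    rows = []
    for cls, sub in df.groupby("trait_class", sort=True):
        n_tested = len(sub)
        n_sig = int(sub["call"].isin(significant_calls).sum())
        rows.append(
            {
                "trait_class": cls,
                "n_tested": n_tested,
                "n_significant": n_sig,
                "pct_significant": 100.0 * n_sig / n_tested if n_tested else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProportionTestResult:
    chi2: float
    chi2_p: float
    z: float
    z_p: float
    degenerate: bool = False


def proportion_tests(
    successes: tuple[int, int], totals: tuple[int, int]
) -> ProportionTestResult:
    """Compare two proportions: Pearson chi-squared and pooled two-sided z.

    The chi-squared test uses no continuity correction, so on a 2x2 table
    chi2 equals z^2.  A zero-margin table (all successes or all failures)
    is degenerate: p = 1 with a flag rather than an error.
    """
    s = np.asarray(successes)
    n = np.asarray(totals)
    if np.any(s < 0) or np.any(n <= 0) or np.any(s > n):
        raise ValueError("need 0 <= successes <= totals, totals > 0")
    table = np.array([[s[0], n[0] - s[0]], [s[1], n[1] - s[1]]])
    if (table.sum(axis=0) == 0).any():
        return ProportionTestResult(0.0, 1.0, 0.0, 1.0, degenerate=True)
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    z, z_p = proportions_ztest(s, n, alternative="two-sided")
    return ProportionTestResult(float(chi2), float(chi2_p), float(z), float(z_p))
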