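"""Expression-side filtering and cross-tissue percentile-rank profiles.

Probes enter the eQTL analysis only if detected (detection p < 0.01) in
strictly more than 95% of samples, map uniquely with clean design, and
contain no analyzed SNP inside the 50-mer probe sequence (a SNP under the
probe distorts hybridization and fakes an eQTL).  Percentile-rank profiles
of per-probe mean or variance support tissue-to-tissue comparison of
expression landscapes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix

__all__ = ["detection_filter", "probe_exclusions", "percentile_rank_profile"]

PROBE_LENGTH = 50


def detection_filter(
    expr: ExpressionMatrix, p_thresh: float = 0.01, frac: float = 0.95
) -> list[str]:
    """Probe ids detected (p < p_thresh) in strictly more than ``frac`` of samples."""
    detected = (expr.detection_p.to_numpy() < p_thresh).mean(axis=1)
    return [pid for pid, f in zip(expr.probe_ids, detected) if f > frac]


def probe_exclusions(probes: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Flag probes to exclude: bad quality or an analyzed SNP under the 50-mer.

    ``probes`` carries BED-style 0-based half-open intervals (``chrom, start,
    end``, length exactly 50) plus ``probe_id`` and ``quality_flag`` in
    {good, ambiguous, bad_design}.  ``snps`` carries 1-based ``pos`` per
    ``chrom``.  A SNP at 1-based position P lies inside [start, end) iff
    start < P <= end.  Returns a copy of ``probes`` with ``excluded`` and
    ``reasons`` columns.
    """
    bad_len = (probes["end"] - probes["start"]) != PROBE_LENGTH
    if bad_len.any():
        bad = probes.loc[bad_len, "probe_id"].tolist()
        raise ValueError(f"probe interval length != {PROBE_LENGTH} for {bad}")
    out = probes.copy()
    reasons = []
    snps_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy()) for chrom, sub in snps.groupby("chrom")
    }
    for _, pr in out.iterrows():
        recr = []
        if pr["quality_flag"] != "good":
            recr.append(str(pr["quality_flag"]))
        pos = snps_by_chrom.get(pr["chrom"])
        if pos is not None:
            # 1-based SNP positions covered by [start, end): start+1 .. end
            lo = np.searchsorted(pos, pr["start"], side="right")
            hi = np.searchsorted(pos, pr["end"], side="right")
            if hi > lo:
                recr.append("snp_in_probe")
        reasons.append(",".join(recr))
    out["reasons"] = reasons
    out["excluded"] = out["reasons"] != ""
    return out


def percentile_rank_profile(
    expr_by_tissue: dict[str, ExpressionMatrix],
    statistic: str = "mean",
    p_thresh: float = 0.01,
    frac: float = 0.95,
) -> pd.DataFrame:
    """Per-probe percentile rank of expression mean (or variance) per tissue.

    Probes failing the detection filter in a tissue get rank 0 there.
    Detected probes are ranked by the statistic across all probes on the
    array (average ranks for ties), with the denominator equal to the total
    probe count, so the highest-expressed detected probe scores 1.0 and
    profiles are comparable between tissues with different detected counts.
    Ranks are invariant to any monotone rescaling of the statistic.

    Returns a probes x tissues DataFrame of ranks in [0, 1].
    """
    if statistic not in ("mean", "variance"):
        raise ValueError("statistic must be 'mean' or 'variance'")
    tissues = list(expr_by_tissue)
    probe_index = expr_by_tissue[tissues[0]].values.index
    out = pd.DataFrame(0.0, index=probe_index, columns=tissues)
    for tissue, expr in expr_by_tissue.items():
        if not expr.values.index.equals(probe_index):
            raise ValueError("tissues must share the probe set")
        detected = set(detection_filter(expr, p_thresh=p_thresh, frac=frac))
        mask = probe_index.isin(detected)
        if not mask.any():
            continue
        stat = expr.values.mean(axis=1) if statistic == "mean" else expr.values.var(axis=1)
        n_total = len(probe_index)
        n_undetected = n_total - int(mask.sum())
        ranks = rankdata(stat.to_numpy()[mask], method="average")
        out.loc[mask, tissue] = (n_undetected + ranks) / n_total
    return out
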