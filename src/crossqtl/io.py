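"""Readers and writers for the pipeline's plain-text interchange formats.

Dosages travel as VCF with a per-sample ``DS`` FORMAT field (read back with
cyvcf2) or as a TSV matrix; expression and detection p-values as TSV
matrices (probes x samples); probe annotation as BED with extra columns;
covariates, catalogs, and results as TSV; planted truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DosageMatrix, ExpressionMatrix, PlantedEffect

__all__ = [
    "write_vcf_dosages",
    "read_vcf_dosages",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_expression",
    "read_expression",
    "write_probes_bed",
    "read_probes_bed",
    "write_effects_json",
    "read_effects_json",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation r-squared">
"""


def write_vcf_dosages(dosages: DosageMatrix, path: str | Path) -> None:
    """Write a VCFv4.2 with GT (hard call) and DS (dosage) per sample."""
    hard = dosages.hard_genotypes()
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.sample_ids)
            + "\n"
        )
        for j, (_, snp) in enumerate(dosages.snps.iterrows()):
            rsq = snp.get("imputation_rsq", 1.0)
            cells = "\t".join(
                f"{gt_str[int(hard[i, j])]}:{dosages.dosages[i, j]:.4f}"
                for i in range(dosages.n_samples)
            )
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['snp_id']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\tPASS\tRSQ={rsq:.4f}\tGT:DS\t{cells}\n"
            )


def read_vcf_dosages(path: str | Path) -> DosageMatrix:
    """Read dosages from the DS field of a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, rows = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        cols.append(ds)
        rows.append(
            {
                "snp_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "maf": float(np.nan),
                "imputation_rsq": float(var.INFO.get("RSQ", 1.0)),
            }
        )
    snps = pd.DataFrame(rows)
    dos = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    p = dos.mean(axis=0) / 2.0
    snps["maf"] = np.minimum(p, 1.0 - p)
    return DosageMatrix(dos, sample_ids, snps)


def write_dosage_tsv(dosages: DosageMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        dosages.dosages.T, index=dosages.snps["snp_id"], columns=dosages.sample_ids
    )
    df.to_csv(path, sep="\t", index_label="snp_id")


def read_dosage_tsv(path: str | Path, snps: pd.DataFrame) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    df = df.loc[snps["snp_id"]]
    return DosageMatrix(df.to_numpy().T, list(df.columns), snps)


def write_expression(expr: ExpressionMatrix, values_path: str | Path,
                     detection_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="probe_id")
    expr.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_expression(values_path: str | Path, detection_path: str | Path,
                    tissue: str) -> ExpressionMatrix:
    vals = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    det = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
    return ExpressionMatrix(vals, det, tissue)


_BED_COLS = ["chrom", "start", "end", "probe_id", "quality_flag", "maps_to_gene"]


def write_probes_bed(probes: pd.DataFrame, path: str | Path) -> None:
    probes[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_probes_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS,
                     dtype={"chrom": str})
    return df[["probe_id", "chrom", "start", "end", "quality_flag", "maps_to_gene"]]


def write_effects_json(effects: list[PlantedEffect], path: str | Path) -> None:
    payload = [
        {
            "snp_id": e.snp_id,
            "probe_id": e.probe_id,
            "tissue_set": sorted(e.tissue_set),
            "beta": e.beta,
            "expressed_in": sorted(e.expressed_in),
        }
        for e in effects
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_effects_json(path: str | Path) -> list[PlantedEffect]:
    payload = json.loads(Path(path).read_text())
    return [
        PlantedEffect(
            d["snp_id"], d["probe_id"], frozenset(d["tissue_set"]), d["beta"],
            frozenset(d["expressed_in"]),
        )
        for d in payload
    ]
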