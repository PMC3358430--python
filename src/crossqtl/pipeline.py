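"""End-to-end pipeline: simulation/QC/catalog/expression/eQTL/sharing/power.

Runs the stages in order on a synthetic cohort (or on stage inputs loaded
from disk), writes per-stage TSVs and a JSON manifest of record counts and
thresholds, and is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cismap, exprqc, io, power, qc, tissuecomp
from .simcohort import SimulatedCohort, simulate_cohort
from .types import TISSUES, CohortSpec, PlantedEffect

log = logging.getLogger("crossqtl.pipeline")

__all__ = ["RunConfig", "run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


@dataclass
class Thresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-7
    min_imputation_rsq: float = 0.3
    pihat: float = 0.15
    mds_sd: float = 3.0
    detection_p: float = 0.01
    detection_frac: float = 0.95
    cis_window: int = 500_000
    min_homozygotes: int = 3
    fdr_q: float = 0.05

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "detection_frac", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")
        if self.cis_window <= 0 or self.min_homozygotes < 0:
            raise ValueError("cis_window must be positive, min_homozygotes >= 0")


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    n_samples: int = 200
    n_snps: int = 50
    n_null_probes: int = 20
    n_catalog_records: int = 20
    catalog_fraction_passing: float = 1.0
    effects: list[dict] = field(default_factory=list)
    tissues: tuple[str, ...] = TISSUES
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10 for a meaningful run")
        for t in self.tissues:
            if t not in TISSUES:
                raise ValueError(f"unknown tissue {t!r}")
        for e in self.effects:
            PlantedEffect(
                e["snp_id"], e["probe_id"], frozenset(e.get("tissue_set", self.tissues)),
                float(e["beta"]), frozenset(e.get("expressed_in", TISSUES)),
            )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    th = Thresholds(**raw.pop("thresholds", {}))
    cfg = RunConfig(thresholds=th, **raw)
    cfg.validate()
    return cfg


def _effects(cfg: RunConfig) -> list[PlantedEffect]:
    return [
        PlantedEffect(
            e["snp_id"], e["probe_id"], frozenset(e.get("tissue_set", cfg.tissues)),
            float(e["beta"]), frozenset(e.get("expressed_in", TISSUES)),
        )
        for e in cfg.effects
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": asdict(cfg.thresholds),
        "tissues": list(cfg.tissues),
        "counts": {},
    }
    th = cfg.thresholds

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        cohort: SimulatedCohort = simulate_cohort(
            CohortSpec(cfg.n_samples, cfg.n_snps, seed=cfg.seed),
            effects=_effects(cfg),
            tissues=cfg.tissues,
            n_null_probes=cfg.n_null_probes,
            n_catalog_records=cfg.n_catalog_records,
            catalog_fraction_passing=cfg.catalog_fraction_passing,
        )
        io.write_vcf_dosages(cohort.dosages, out / "dosages.vcf")
        cohort.covariates.to_csv(out / "covariates.tsv", sep="\t")
        io.write_probes_bed(cohort.probes, out / "probes.bed")
        io.write_effects_json(cohort.effects, out / "truth_effects.json")
        manifest["counts"]["samples_simulated"] = cohort.dosages.n_samples
        manifest["counts"]["snps_simulated"] = cohort.dosages.n_snps
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    try:
        stage("qc")
        annotated = qc.snp_qc_stats(cohort.dosages)
        snp_filter = qc.filter_snps(
            annotated,
            qc.SnpFilterThresholds(th.min_call_rate, th.min_maf, th.min_hwe_p,
                                   th.min_imputation_rsq),
        )
        snp_filter.to_csv(out / "snp_filter.tsv", sep="\t", index=False)
        kept_snps = set(snp_filter.loc[snp_filter["kept"], "snp_id"])
        excluded_rel, _ = qc.relatedness_exclude(cohort.dosages, threshold=th.pihat)
        mds = qc.ibs_mds(cohort.dosages, sd_threshold=th.mds_sd)
        mds.frame().to_csv(out / "mds.tsv", sep="\t", index=False)
        outliers = [s for s, o in zip(mds.sample_ids, mds.outlier) if o]
        drop_samples = set(excluded_rel) | set(outliers)
        keep_mask = [s not in drop_samples for s in cohort.dosages.sample_ids]
        manifest["counts"]["snps_kept"] = len(kept_snps)
        manifest["counts"]["samples_excluded_related"] = len(excluded_rel)
        manifest["counts"]["samples_excluded_mds"] = len(outliers)
        manifest["counts"]["samples_kept"] = int(sum(keep_mask))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    try:
        stage("catalog")
        if len(cohort.catalog):
            cat = qc_catalog = cohort.catalog
            from .catalog import filter_catalog

            qc_catalog = filter_catalog(cat)
            qc_catalog.to_csv(out / "catalog_filter.tsv", sep="\t", index=False)
            catalog_snps = set(qc_catalog.loc[qc_catalog["kept"], "snp_id"])
            manifest["counts"]["catalog_records"] = len(qc_catalog)
            manifest["counts"]["catalog_kept"] = len(catalog_snps)
        else:
            catalog_snps = None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("catalog", str(exc)) from exc

    try:
        stage("exprqc")
        # restrict cohort to QC-passing samples
        import numpy as np

        idx = np.flatnonzero(keep_mask)
        from .types import DosageMatrix

        dosages = DosageMatrix(
            cohort.dosages.dosages[idx],
            [cohort.dosages.sample_ids[i] for i in idx],
            cohort.dosages.snps,
        )
        covariates = cohort.covariates.iloc[idx]
        snp_keep = dosages.snps["snp_id"].isin(kept_snps)
        if catalog_snps is not None:
            snp_keep &= dosages.snps["snp_id"].isin(catalog_snps)
        analyzed_snps = dosages.snps[snp_keep].reset_index(drop=True)
        probe_qc = exprqc.probe_exclusions(cohort.probes, analyzed_snps)
        probe_qc.to_csv(out / "probe_exclusions.tsv", sep="\t", index=False)
        good_probes = set(probe_qc.loc[~probe_qc["excluded"], "probe_id"])
        detected: dict[str, set[str]] = {}
        for t in cfg.tissues:
            expr = cohort.expression[t]
            sub = exprqc.detection_filter(
                expr, p_thresh=th.detection_p, frac=th.detection_frac
            )
            detected[t] = set(sub) & good_probes
            manifest["counts"][f"probes_detected_{t}"] = len(detected[t])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("exprqc", str(exc)) from exc

    try:
        stage("cismap")
        probes_ok = cohort.probes[cohort.probes["probe_id"].isin(good_probes)]
        pairs = cismap.pair_cis(analyzed_snps, probes_ok, window=th.cis_window)
        manifest["counts"]["cis_pairs"] = len(pairs)
        results = {}
        for t in cfg.tissues:
            expr = cohort.expression[t]
            vals = expr.values[[s for s in dosages.sample_ids]]
            res = cismap.scan_tissue(
                dosages, vals, pairs, covariates, t,
                detected_probes=detected[t], min_hom=th.min_homozygotes,
            )
            res.to_csv(out / f"eqtl_{t}.tsv", sep="\t", index=False)
            results[t] = res
            manifest["counts"][f"tested_{t}"] = int((res["status"] == "tested").sum())
        consensus, complement = cismap.consensus_set(results)
        consensus = cismap.adjust_track(consensus, list(cfg.tissues))
        consensus.to_csv(out / "consensus.tsv", sep="\t", index=False)
        complement.to_csv(out / "restricted.tsv", sep="\t", index=False)
        manifest["counts"]["consensus_pairs"] = len(consensus)
        manifest["counts"]["restricted_pairs"] = len(complement)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cismap", str(exc)) from exc

    try:
        stage("tissuecomp")
        if len(consensus) and set(cfg.tissues) == set(TISSUES):
            calls = tissuecomp.classify_sharing(consensus, q_thresh=th.fdr_q)
            calls.to_csv(out / "sharing_calls.tsv", sep="\t", index=False)
            manifest["counts"]["sharing_calls"] = (
                calls["call"].value_counts().to_dict()
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("tissuecomp", str(exc)) from exc

    try:
        stage("power")
        n_eff = int(sum(keep_mask))
        manifest["power"] = {
            "n": n_eff,
            "alpha": power.default_alpha(),
            "power_maf0.2_z0.5": power.analytic_power(
                power.PowerSpec(n=n_eff, maf=0.2, z=0.5, alpha=power.default_alpha())
            )
            if n_eff >= 2
            else None,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("power", str(exc)) from exc

    payload = json.dumps(manifest, indent=1, sort_keys=True, default=str)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest
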