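# crossqtl

Cross-tissue cis-eQTL mapping for GWAS-nominated SNPs, in Python.

Many GWAS hits act by changing gene expression, but expression regulation
is tissue-dependent: an eQTL found in whole blood may be absent in brain,
either because the variant's effect differs or because the transcript is
simply not expressed there. `crossqtl` implements the full analysis chain
used to ask this question with array-based expression and imputed
genotypes in several tissues (here: whole blood, frontal cortex,
cerebellum):

- **cohort QC** — per-SNP filters (call rate ≥ 95%, MAF ≥ 0.01, HWE exact
  p ≥ 1e-7, imputation r² ≥ 0.3), LD pruning (50-SNP windows, step 5,
  r² > 0.2), IBS + classical MDS ancestry outlier removal (> 3 SD on
  C1/C2), and method-of-moments relatedness exclusion (π̂ > 0.15);
- **GWAS-catalog filtering** — six inclusion criteria (discovery
  p < 5e-8, initial n > 1000, replication n > 500, > 100,000 SNPs,
  European ancestry, risk-allele frequency ≥ 0.01) plus a curated
  blood/brain/other trait mapping;
- **expression QC** — detection in > 95% of samples at p < 0.01, probe
  quality flags, SNP-in-probe exclusion, and cross-tissue percentile-rank
  profiles;
- **cis-eQTL mapping** — for each SNP:probe pair within ±500 kb, OLS of
  expression on allelic dosage adjusted for age, gender, PMI, tissue bank,
  hybridization batch and two MDS components, with a ≥ 3
  minor-homozygote filter, per-tissue Benjamini–Hochberg FDR at 5%, a
  consensus set of pairs testable in every tissue, and conditional
  analysis on proxy SNPs;
- **tissue comparison** — sharing classification (`shared_all`,
  `blood_specific`, `brain_specific`, expression-restricted), direction
  consistency, count tables and proportion tests;
- **power** — closed-form power for the additive dosage model,
  `power = Φ(λ − z_{α/2}) + Φ(−λ − z_{α/2})`, λ = Z·√(n·2p(1−p))/σ_e, with
  an exact noncentral-t option, Monte-Carlo validation, and calibration of
  α from reported cohort powers;
- **simcohort** — a first-class synthetic-cohort generator with planted
  eQTL architecture (shared, tissue-specific and expression-restricted
  effects, HWE genotypes, imputation noise, duplicates, ancestry
  outliers, covariate confounding) so every stage is testable end to end.

See `docs/methods.md` for the model, defaults, and design decisions.

## Worked example

Run the whole pipeline on a simulated cohort with two planted effects —
one shared across tissues, one acting in blood only:

```python
from crossqtl.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=11, out_dir="demo", n_samples=200, n_snps=40,
    n_null_probes=20, n_catalog_records=40,
    effects=[
        {"snp_id": "snp00004", "probe_id": "probe_shared", "beta": 0.8},
        {"snp_id": "snp00012", "probe_id": "probe_blood", "beta": 0.8,
         "tissue_set": ["blood"]},
    ],
)
manifest = run_pipeline(cfg)
```

The manifest reports per-stage record counts — 200 samples and 40 SNPs
simulated and kept, 106 cis pairs, 76 in the consensus set, and the
sharing calls:

```
"sharing_calls": {"blood_specific": 1, "null": 74, "shared_all": 1}
```

`demo/sharing_calls.tsv` shows both planted effects recovered with the
correct classification, and nothing else called:

```
  snp_id     probe_id      q_blood  q_frontal_cortex  q_cerebellum           call
snp00004 probe_shared 1.576751e-08          0.000790      0.009033     shared_all
snp00012  probe_blood 8.633698e-10          0.534946      0.999073 blood_specific
```

The q-values are BH-adjusted within the consensus track per tissue: the
blood-only effect is overwhelming in blood (q ≈ 9e-10) and indistinguishable
from noise in both brain tissues — the signature of a tissue-specific eQTL.

The same stages are available from the shell:

```sh
crossqtl simcohort --spec spec.yaml --out cohort/
crossqtl qc-snps --vcf cohort/dosages.vcf --out snp_filter.tsv
crossqtl power --n 501 --maf 0.2 --z 0.5
crossqtl pipeline run --config run.yaml
```

`crossqtl power --n 501 --maf 0.2 --z 0.5` prints the calibrated
significance threshold and the resulting power:

```
alpha = 1.4002e-05
power = 0.9880
```

i.e. a cohort of 501 samples has 98.8% power to detect a cis effect of
half a phenotype SD per minor allele at MAF 0.2; at 399 samples the same
command reports 93.9%.

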