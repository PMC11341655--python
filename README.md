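# bmscreen

Analytics for **ex vivo high-throughput drug screens** of patient-derived
tumor cultures — the kind of screen in which a clinical compound library
(hundreds of FDA-approved and late-stage drugs) is dosed as dilution series
onto 1536-well plates seeded with a patient's short-term tumor culture and
two non-neoplastic control cell models (human fibroblasts, HFB, and
peripheral blood cells, PBC), and viability is read out by a luminescent
ATP assay. The package turns raw per-well luminescence into a ranked,
genetically annotated list of tumor-selective candidate drugs, and ships a
synthetic screen generator with known ground truth so the whole pipeline is
testable without any instrument data.

It is aimed at people building or auditing drug-sensitivity and resistance
testing (DSRT) pipelines: core-facility analysts, computational biologists,
and method developers who need a reference implementation with explicit,
configurable decision rules.

## The model and the decision rules

**Dose-response.** For each compound × cell model, viability is normalized
to the anchor dose (the 0-µM vehicle well when present, else the lowest
tested dose) and fitted with the four-parameter logistic (Hill) model on
log-concentration,

    v(x) = bottom + (top − bottom) / (1 + 10^(hill·(x − log10 IC50))),

x = log10(conc/µM). Drug effect is summarized as the **normalized AUC**:
the area under the fitted curve, clamped to [0, 1], over the tested
positive-dose window, divided by the window width. AUC = 1 means no effect,
AUC = 0 complete kill.

**Plate QC.** Each plate must satisfy CV < 15% over its 10–16 DMSO control
wells (CV = 100·SD/mean) and R² > 0.8 for the 4PL fits of the two broadly
cytotoxic positive-control compounds on the tumor culture. A culture's
screen is analyzed only if every one of its plates passes.

**Selectivity.** Z′ here is a *selectivity z-score on AUCs*:

    Z′ = (AUC_tumor − mean(AUC_controls)) / max(SD(AUC_controls), 0.05),

negative when the tumor culture is more sensitive than the HFB/PBC
controls; Z′ < −2 marks a selectively antitumor compound. (The classic
Zhang Z′-factor assay statistic is available separately as
`compute_zprime_factor`.)

**Hit funnel.** Compounds are triaged in stages — fit quality (R² > 0.8),
efficacy (AUC < 0.75), selectivity (Z′ < −2); the hit set is the
conjunction. Hits are then annotated with their target family and flagged
as *genetically supported* when a gene-panel variant from the same patient
maps to the hit's targets, directly or through downstream-pathway links
(e.g. STK11 → ERK, TP53 → HDAC/HSP90, ATM → MEK).

**Variant concordance.** Gene-panel calls from tumor tissue and the matched
short-term culture are paired on the exact (gene, cDNA HGVS) key and
reported with their allele-fraction shift, quantifying how faithfully the
culture preserves the tumor's mutational profile.

## Worked example

```python
import bmscreen as b

cfg = b.SimConfig(n_compounds=20, noise_cv_percent=5.0, seed=11)
wells, truths = b.simulate_screen(cfg)      # 642 wells across 3 cell models
fits = b.fit_screen(wells)
metrics = b.build_drug_metrics(
    fits, tumor_model_id=cfg.tumor_model_id,
    library=b.simulate_library(20),
    exclude=("panobinostat", "staurosporine"))
annotated, funnel = b.select_hits(metrics)
print(funnel)
for m in annotated:
    if m.is_hit:
        print(m.compound_id, m.target_family, round(m.auc_tumor, 3),
              round(m.zprime, 2))
print(sorted(b.truth_hit_set(truths)))
```

prints

```
FunnelCounts(n_screened=20, n_fit_pass=5, n_effective=4, n_selective=2)
cmpd003 FGFR 0.46 -8.79
cmpd019 CDK 0.532 -5.26
['cmpd003', 'cmpd019']
```

Of 20 simulated compounds, 5 series fit well enough to trust (flat,
inactive curves are unidentifiable and fail the R² gate), 4 are effective
on the tumor culture (AUC < 0.75), and 2 are also selective against the
HFB/PBC controls (Z′ < −2) — exactly the two compounds the generator made
tumor-selective, with tumor AUCs around 0.5 against control AUCs near 1.

The same flow is available as a CLI:

```sh
bm-screen simulate --seed 11 --n-compounds 20 --outdir sim
bm-screen qc sim/plates.csv
bm-screen fit sim/plates.csv --out fits.tsv
bm-screen hits fits.tsv sim/library.tsv --tumor-model BM-T1
bm-screen run --config pipeline.yaml      # full simulate→qc→fit→hits→concordance
```

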