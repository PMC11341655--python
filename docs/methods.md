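# Methods

This note documents the statistical model, the decision rules, the
synthetic-data model, and the numerical and design choices behind
`bmscreen`.

## Screen model and assumptions

A screen is one patient-derived tumor culture plus two non-neoplastic
control cell models (human fibroblasts, HFB; peripheral blood cells, PBC),
each dosed with a compound library on 1536-well plates (32 rows A–AF × 48
columns). Every compound is tested as a single well per dose — no
within-plate replicates — across 6–8 concentrations up to 10 µM plus a
0-µM vehicle anchor. Luminescence is assumed proportional to viable cell
number, with multiplicative noise (noise scales with signal, as is typical
for luminescent viability readouts).

## Dose-response fitting

Viability is the signal ratio to the anchor dose; the anchor is the 0-µM
vehicle well when present, otherwise the lowest tested dose (both
conventions occur in practice; the vehicle anchor is the default because
it estimates the untreated baseline directly). Replicate wells at one
concentration are averaged before fitting.

The curve family is the four-parameter logistic on log10 concentration —
the standard model for ATP-viability screens:

    v(x) = bottom + (top − bottom) / (1 + 10^(hill·(x − m))),  m = log10 IC50.

The 0-µM anchor is excluded from the fit (log 0 undefined); at least four
positive-dose points are required. Least squares uses `scipy.optimize.
least_squares` (trust-region reflective) with an analytic Jacobian and
bounds top ∈ [0.5, 1.5], bottom ∈ [−0.1, 1.1], hill ∈ [0.1, 20], m within
the tested window ± 1 decade; the start is top = max v, bottom = min v,
hill = 1, m = window midpoint. These bounds and starts make the fit
deterministic and reproducible.

*Two-stage solve.* Flat series (inactive compounds) are nearly
unidentifiable in (IC50, hill): the optimizer crawls along a ridge and can
burn thousands of iterations chasing noise without materially changing the
curve. The fit therefore first solves at moderate tolerance (1e-6, up to
5000 evaluations), then polishes at 1e-12 (up to 300 evaluations), keeping
the polish only if it converges. Informative curves reach ~1e-12 parameter
accuracy; flat curves terminate quickly with an adequate fit. A fit that
exhausts the first stage is marked non-converged; its R² and AUC are NaN
sentinels and the compound can pass no filter.

R² = 1 − SS_res/SS_tot over the fitted points. A flat series has
SS_tot = 0: R² is then the NaN sentinel, which fails the R² gate — the
correct outcome, since such a curve carries no dose-response information.

**Normalized AUC.** The drug-sensitivity score is the area under the
*fitted* curve, clamped to [0, 1], over the tested positive-dose window,
divided by the window width, so that 6-, 7- and 8-point series are
comparable and AUC ∈ [0, 1] (1 = no effect, 0 = complete kill). The
integral is a trapezoid on a uniform grid of 20 001 points — dense enough
that quadrature error is below 1e-6 even at the steepest admissible hill
slope, and far below any decision threshold (the grid is configurable;
anything ≥ 256 points is accepted).

## Quality control

Per plate: CV = 100·SD/mean over the plate's pooled DMSO wells (sample SD,
n−1, since the wells are a sample of plate behaviour) with gate CV < 15%,
and 4PL R² > 0.8 for both broadly cytotoxic positive-control compounds.
The R² gate is evaluated on the tumor culture's series; plates holding
only control cell models are exempt (their role is to supply control AUCs,
not to qualify the screen), while a tumor plate lacking positive controls
fails the gate. A culture's screen is analyzed only if *all* of its plates
pass — the conservative aggregation, chosen because per-culture
pass/fail is the reported granularity while the gates are per-plate.
DMSO wells are pooled across whatever the plate contains; the
generator seeds one cell model per plate, so pooling is per model there.

## Selectivity and hit selection

Z′ is a selectivity z-score on AUCs: (AUC_tumor − mean AUC_controls) /
max(SD_controls, 0.05), selective if < −2. With only two control models
the sample SD is unstable, hence the 0.05 floor (in AUC units, about the
scale of fitted-AUC noise at 5–10% signal CV). The classic Zhang Z′-factor
(1 − 3(σ_p+σ_n)/|µ_p−µ_n|) has opposite semantics — larger is better —
and is provided as a separately named utility, not used in hit calling.

The funnel applies R² > 0.8, then AUC < 0.75, then Z′ < −2, each within
the survivors of the previous stage. The hit set is the conjunction, so
stage order affects only the intermediate counts. "Effective" is AUC
*below* 0.75: with AUC as remaining-viability area, lower means more
killing, and the selective-hit rule uses the same direction.

Genetic support: a hit is flagged when a variant gene from the same
patient is one of the compound's annotated target genes, or maps to the
hit's target family through a configurable gene→family table that includes
downstream-pathway links (STK11 → ERK, TP53 → HDAC/HSP90, ATM → MEK)
alongside direct ones (JAK3 → JAK, ERBB2 → HER2, FGFR1–4 → FGFR).
Unmapped variant genes are ignored with a log line.

## Variant concordance

Tissue and culture calls are matched on the exact (gene, cDNA HGVS) key
after whitespace stripping; cDNA rather than protein notation because not
every call carries a protein-level annotation (e.g. splice-site
deletions). No HGVS normalization is attempted — the packaged table uses
consistent notation, and general HGVS equivalence is out of scope.
Per-patient concordance is matched / max(n_tissue, n_culture). Where a
patient has two tissue samples (primary and relapse), each is kept as a
separate record set under a suffixed ID and the default five-patient
report uses the first.

## Synthetic screens and what they do (and do not) show

The generator emulates the screen layout above: per plate, 16 DMSO wells
(configurable 2–1000; 10–16 is the realistic range, larger values exist
for estimator-convergence checks), both positive-control series, then as
many compound series as fit in 1536 wells, with extra plates as needed.
Signals are baseline (10⁶ counts, irrelevant after normalization) × 4PL
truth × unit-mean log-normal noise whose CV equals `noise_cv_percent`
exactly. Default conditions: 267 compounds, 8 half-log doses up to 10 µM,
10% noise CV, effective fraction 60/267 and selective-given-effective
29/60 — the funnel proportions of the screening setting this package
models.

Effectiveness and selectivity are assigned by deterministic quota
(round(fraction × n)) so tests can assert exact counts. Truth labels are
made semantically consistent with the decision rules: effective-class
draws (bottom ∈ [0, 0.3], IC50 log-uniform in [0.01, 1] µM, hill ∈
[0.8, 2.5]) are redrawn on the same RNG stream until the noiseless AUC
over the default window is < 0.7, leaving a deliberate margin below the
0.75 efficacy threshold so that a "true effective" label always denotes a
real, detectable effect; ineffective draws are flat (bottom ≥ 0.9, true
AUC ≳ 0.9). Selective compounds are effective on the tumor model and flat
on both controls; non-selective effective compounds share one curve across
all three models, so they cannot masquerade as selective through
independent sampling. Even so, a compound whose true AUC sits near the
0.7 ceiling can cross the 0.75 threshold under noise — exact hit-set
recovery is a high-probability, not a sure, event, which is why recovery
is asserted across seeds rather than per seed.

The generator omits spatial plate artifacts (edge effects, dispense
drift), replicate wells, batch effects between plates, and any relation
between a compound's annotated targets and its simulated potency. Passing
tests therefore demonstrate that the *analysis* is correct under the
stated noise model, not that the thresholds are optimal for real screens.

## Problem sizes used in the checks

Simulation-backed checks run at sizes chosen to exercise the full range
while staying cheap: hit recovery uses 20 screens cycling library sizes
{20, 40, 80, 160, 267} at 5% noise; IC50 recovery uses 200 independent
series at 10% noise; bias checks use 100 series per noise level; the QC
gate demonstration uses six 8-compound cultures with one corrupted by
forcing its DMSO sample CV to exactly 20% (a deterministic rescaling of
deviations, so the failure is certain rather than probabilistic).

## Known limitations

- Exact (gene, cDNA) variant matching will miss biologically identical
  calls written in different HGVS forms.
- The Z′ selectivity score with two controls leans on the SD floor; with
  more control models the floor rarely binds.
- AUC compares compounds over *their own* tested window; compounds tested
  over different windows are comparable only after the range
  normalization, which is a modelling choice, not an identity.
- The 4PL fit reports no confidence intervals; single-well-per-dose
  designs rarely support meaningful ones.
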