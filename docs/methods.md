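# Methods

## Scope and design

The package computes postprandial amino-acid and protein kinetics from a
primed-continuous D8-phenylalanine + D2-tyrosine infusion with a
D5-phenylalanine-labeled casein meal: whole-body appearance/disappearance
and its partition into meal-derived, proteolytic and hydroxylation fluxes;
protein synthesis, degradation and net balance; leg and adipose
arteriovenous balances; muscle and plasma-protein fractional synthesis
rates; and HOMA-IR/Matsuda indices. Because no machine-readable subject
data accompany the study design it implements, correctness is established
by *forward simulation and parameter recovery*: a generator with known
ground truth produces data in exactly the formats the estimators consume,
and the test suite asserts that each estimator returns the truth to a
stated tolerance.

## Whole-body estimators

All fluxes are normalised to lean mass (LM, by DXA). The single-pool
non-steady-state estimator evaluates consecutive sample pairs with midpoint
timestamps; the study grid yields midpoints −45 (fasting baseline),
−10, 15, 25, 35, 45, 55, 75, 105, 150, 210, 270 and 330 min. Pool terms use
pair means (C̄, Ē) and finite differences for the time derivative; no
smoothing is applied before differencing.

Unit conventions resolved here as design choices:

* **pV rescaling.** The pool fraction is tabulated per kg body weight
  (0.125 L/kg BW for both phenylalanine and tyrosine) while fluxes are per
  kg LM; the package uses `pV_eff = 0.125·BW/LM` so every term in the
  estimator shares μmol/kg LM/min.
* **Oral-Ra pool term.** The dimensionally consistent pool-derivative term
  is `pV·C̄·dE_D5/dt`; a `printed` mode that omits the concentration factor
  is retained for comparison with the bare typeset form. Default:
  `corrected`.
* **Endogenous Ra.** Default `simple` (`Ra_total − Ra_oral`); a
  `subtract_tracer` mode additionally removes the infusion rate F, for
  sensitivity analysis. Negative oral/endogenous estimates (possible under
  noise) are clipped to zero and counted, never silently.
* **Background correction.** The −150 min sample precedes the tracer prime
  and carries natural-abundance enrichment only; its per-isotopologue TTRs
  are subtracted from all later samples once per visit (`mode="none"` if
  inputs are pre-corrected). A per-timepoint alternative is not offered
  because a single pre-prime sample exists per visit.

Hydroxylation uses the tyrosine system: D7/D6-tyrosine arises only from
hydroxylation of the infused D8/D7-phenylalanine label, so
`hydrox = Ra_D2tyr · E_D7D6tyr / Ē_D8D7phe`. This printed estimator has no
pool-correction term of its own; under non-steady conditions it is exact at
isotopic steady state and approximate in between (see Limitations).

Splanchnic handling of the meal label is summarised as the trapezoid AUC of
oral Ra over 0–360 min (anchored at zero appearance at meal time, last
midpoint value held to 360 min), expressed as a percentage of ingested
phenylalanine; the complement is reported as a first-pass extraction
estimate. Both numbers are reported without asserting which one a given
publication calls "first-pass".

## Tissue balances

Leg balances are computed in flow mode (μmol/min/kg LM) with femoral
arterial flow linearly interpolated to blood-sample times; the supplied
flow is used as-is (no hematocrit correction). The adipose bed (epigastric
vein) has no reliable flow measure and uses difference mode: plain
arteriovenous concentration differences in μmol/L. The two-pool closure
`release = uptake − net` holds exactly by construction; with venous
enrichment ≤ arterial and venous concentration ≤ arterial the fractional
extraction lies in [0, 1].

## Fractional synthesis rates

The precursor-product model with the time-weighted trapezoid mean of the
precursor over the incorporation window ("weighted average" is not further
specified by convention; an arithmetic mean is available by flag). Muscle
FSR (%/h) uses the two biopsies (−30, 360 min) with the muscle free-pool
pooled phenylalanine TTR (D5+D7+D8) as precursor; the literal biopsy times
bound the window. Plasma-protein FSR (%/day) uses the plasma pooled TTR
series as precursor, with windows from a −30 min baseline protein sample to
60/120/240/360 min; a meal-label-only (D5) channel is computed alongside.

## Metabolic indices

HOMA-IR = G·I/(22.5·7.18) with glucose in mmol/L and insulin in pmol/L.
The Matsuda index uses the canonical composite form with the same unit
constants (×18 for glucose to mg/dL, ÷7.18 for insulin to μU/mL); the
0–120 min means are time-weighted trapezoid means because the sampling grid
is non-uniform (simple means by flag). AUCs are trapezoid after linear
interpolation of interior missing values; leading/trailing gaps are an
error rather than an extrapolation. Baselines follow the study convention:
concentrations = mean of −60/−30, kinetics = the −45 midpoint, hormones =
the −30 value.

## The forward simulator

One rapidly mixing pool per amino acid — deliberately the same physiology
the Steele estimator assumes, so that noise-free recovery isolates
discretisation error rather than model mismatch. Per subject:

* tracee phenylalanine: `V·dC/dt = Ra_endo(t) + Ra_oral(t) − k·V·C` with
  `V = 0.125·BW/LM` and the clearance rate constant `k` fixed at its
  fasting steady-state value (`k = Ra_basal/(V·C_basal)`);
* endogenous appearance: basal rate with a raised-cosine postprandial
  suppression bump (default depth 0.30 healthy / 0.25 obesity over
  0–300 min);
* meal absorption: gamma-density-shaped oral Ra (shape 3, scale 20 min →
  mode 40 min), total = ingested phenylalanine × systemic fraction (0.85);
* tracers: D8-phe (prime 3 μmol/kg LM as an instantaneous bolus at
  −150 min + 0.07 μmol/kg LM/min), D5-phe injected at `r × Ra_oral(t)`,
  D2-tyr (prime 2.3, rate 0.04), D7/D6-tyr produced at the hydroxylation
  flux × the phenylalanine precursor TTR — all cleared with the tracee's
  rate constant;
* hydroxylation: a fixed fraction (0.05) of phenylalanine Rd, feeding the
  tyrosine pool;
* protein pools: muscle- and plasma-bound enrichment accumulating at the
  true FSR × precursor enrichment (muscle free pool = 0.70 × plasma);
* venous sites: built from true uptake/release/flow profiles by exact
  algebra, so arteriovenous recovery is exact in the noise-free limit;
* measurement: sampling on the study grid, multiplicative lognormal noise
  (CVs 2% enrichment, 3% concentration, 5% flow), and an additive
  natural-abundance background TTR (0.001) on every channel, with the
  pre-prime −150 min sample carrying background only.

The ODE system (13 states, including per-channel cumulative cleared mass
for conservation checks) is integrated with LSODA at rtol 1e−10/atol 1e−12
and a 5-min step cap, evaluated on a 1-min grid; one subject-visit takes
~15 ms, keeping replicate studies (100 cohorts of 24) inside a few minutes
on one CPU.

Numbers not fixed by the study design were chosen once as field-realistic
and are exposed in `GroupPhysiology`/`ScenarioConfig`: basal phenylalanine
Ra 0.85 μmol/kg LM/min (CV 8% between subjects), basal plasma phe 55/62 and
tyr 47/60 μmol/L (healthy/obesity), ingested phenylalanine 8190 μmol (26 g
casein × 315 μmol/g), meal labeling ratio r = 0.02, muscle FSR 0.08 %/h,
plasma-protein FSR 10 %/day, femoral flow 0.35–0.50 L/min with a
postprandial rise, anthropometrics drawn from the two groups' published
means/SDs. The antibody-visit effect is a pure parameter shift (default:
+5% meal systemic fraction, +10% hydroxylation fraction).

### What the generator does and does not emulate

It reproduces the sampling design, tracer protocol, label routing, and
realistic noise; it does **not** model multi-compartment kinetics,
transmembrane transport, recycling of label from protein breakdown,
insulin-driven coupling between glucose and amino-acid kinetics, or
hematocrit. Passing recovery tests therefore demonstrates that the
estimators are correct *under the single-pool assumptions they embody* —
not that those assumptions hold in vivo.

## Verification strategy and tolerances

* Steady state: `Ra = F/E`, `Rd = Ra` to 1e−12 relative (algebraic).
* Flux split and two-pool closure: exact identities on randomised inputs.
* Whole-body recovery (noise-free): within 2% of the true inflow peak at
  1-min sampling; within 10% at the study grid between midpoints 15 and
  270 min — the residual is pair-midpoint discretisation error on a curved
  signal, largest where sampling jumps from 10- to 60-min spacing.
* Arteriovenous recovery: 1e−9 (exact algebra).
* FSR: exact (1e−10) for constant precursor; 1% under ±10% precursor
  drift. Full-loop muscle FSR is only quadrature-limited to ~5% because
  two biopsies cannot resolve the postprandial precursor excursion — a
  real-world limitation of two-point designs, reproduced faithfully;
  plasma FSR with 14 precursor points recovers to ~3%.
* Tracer conservation: cumulative infused = pool + cumulative cleared to
  1e−6 relative per channel (solver-level consistency, independently
  bookkept cumulative states).
* Effect detection: a 20% blunting of proteolysis suppression in one group
  of 12 is ordered correctly (higher postprandial endogenous Ra, lower net
  gain) in ≥95 of 100 seeded replicates. The detection statistic weights
  midpoints by a raised cosine over the postprandial window and normalises
  each subject to their own −45 min baseline, which removes between-subject
  basal variation (the dominant noise source at this sample size).
* Determinism: one seed → bit-identical CSV bundles (all numeric output at
  6 significant digits, the declared comparison precision).

## Known limitations

* The hydroxylation estimator lacks a pool correction for D7/D6-tyrosine
  and is exact only at isotopic steady state, so the recovered rate is
  biased during rapid transients around the absorption peak; this is the
  estimator's property, not an implementation artifact.
* Recycling of label from protein breakdown is ignored on the 6-h
  timescale (protein-bound enrichments stay ≪ precursor enrichments).
* The splanchnic AUC extends the last midpoint value (330 min) to 360 min;
  with near-zero late oral Ra the choice is numerically immaterial.
* The Matsuda mean definition (trapezoid vs arithmetic) changes the index
  by a few percent on non-uniform grids; both are available, trapezoid is
  the default.
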