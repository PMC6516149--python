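# Methods

## Scope

`mitoflux` models the bioenergetics of intact cultured neurons and analyses
the two kinds of measurements used to probe them: plate-based oxygraphy
(oxygen consumption rate, OCR, and extracellular acidification rate, ECAR)
and single-cell fluorescence (TMRM for membrane potential, NAD(P)H
autofluorescence and FLIM for redox state).  The centrepiece is a
flux-based ODE model of oxidative phosphorylation used for an in-silico
screen: which single-flux impairment can reproduce a phenotype in which
*only maximal (uncoupled) respiration* is reduced while basal respiration,
ATP-linked respiration and proton leak are preserved?

## The respiratory-chain model

### Structure

Three compartments — matrix (`x`), intermembrane space (`i`), cytosol (`c`)
— linked by the inner membrane (capacitance `CIM`) and a fast outer-membrane
permeation barrier.  Sixteen state variables: membrane potential `dpsi`,
matrix NADH, reduced ubiquinone, reduced cytochrome c, ATP/ADP/Pi in all
three compartments, and matrix free H+, K+ and Mg2+.  Oxygen is a fixed
boundary (assays run at saturating O2), as are cytosolic pH, K+ and free
Mg2+.

Eleven fluxes: NADH delivery (`J_DH`), complexes I/III/IV, the F1Fo ATP
synthase, the adenine nucleotide translocase (ANT), proton leak, Pi/H+
symport, K+/H+ antiport, adenylate kinase (off by default) and a cytosolic
ATP consumption closing the energy budget.  Every reversible flux is an
activity constant times a mass-action bracket whose apparent equilibrium
constant combines the reaction's standard free energy, the proton-motive
terms (`F*dpsi` and the pH gradient) and the chemically consumed matrix
protons.  A flux is therefore *exactly* zero at its thermodynamic
equilibrium and always carries the sign of its driving force — properties
the test suite checks on random states against an independently re-derived
affinity function.

Two kinetic refinements sit on top of the mass-action core:

* **Finite complex turnover.** Complexes I, III and IV carry reversible
  saturation denominators `1 + forward/k_sat`.  Without them the apparent
  equilibrium constants explode at depolarised potentials and a complex
  scaled to 20% activity (the antimycin A calibration) would still conduct
  arbitrarily large fluxes; with them, a deep activity block throttles the
  chain the way the corresponding drug does in cells, while a mild (70%)
  impairment is absorbed by displacement shifts.

* **Potential-dependent NADH delivery.** `J_DH` lumps matrix substrate
  dehydrogenation with cytosolic NADH import via the malate–aspartate
  shuttle.  The shuttle's aspartate/glutamate carrier is electrogenic and
  driven by the proton-motive force, so delivery capacity falls when the
  membrane depolarises.  We model this as a sigmoid factor
  `1/(1+exp(-(dpsi - dpsi_ref_DH)/delta_psi_DH))` (half-activation 40 mV,
  width 30 mV): essentially saturated — hence invisible — at polarised
  basal potentials, and increasingly limiting in the uncoupled state.

The second refinement is what gives the screen its discriminating power.
At the uncoupled (post-FCCP) steady state the membrane potential is slaved
to the (11x) leak line, so a small cut in delivery capacity lowers flux,
which lowers `dpsi`, which lowers delivery capacity again.  The loop is
stable (its gain stays below one because the uncoupled potential sits below
the sigmoid's steep region's critical point) but amplifies a 5% activity
impairment into a ~15–20% drop in maximal respiration, while basal
respiration — demand-limited by cytosolic ATP turnover — barely moves.
Conversely, a 30% cut in any respiratory complex is absorbed at both
operating points (near-equilibrium displacement at basal, saturation
margins under FCCP), and a 50% higher proton leak changes basal and leak
respiration as well as maximal, so no respiratory-chain impairment mimics
the supply-impairment signature.

### Proton bookkeeping and a structural conservation law

Matrix protons use the effective-buffering form `dH_x/dt =
x_buff * H_x * (net proton source)/W_x` (buffering ratio ~1/(x_buff*H_x),
i.e. about 1e5 at pH 7.4).  With the K+/H+ antiporter as the only potassium
pathway the dynamics conserve a proton/charge inventory

    Phi = (W_x/x_buff) ln H_x + CIM*dpsi - W_x (NADH_x + 2 Pi_x + ATP_x - K_x),

which makes the proton balance linearly dependent on the charge balance at
any steady state: the model has a one-parameter *family* of steady states,
and the basal matrix pH is selected by the initial condition's inventory
(in practice by the initial matrix K+, since `K_x = K_c * H_x / H_i` at
rest).  The Newton-based steady-state finder pins `Phi` to the supplied
initial state explicitly, which is why it agrees with the long-integration
limit to 1e-6 relative — the oracle-equivalence test in the suite.

### Numerics

* Stiff integration with `solve_ivp`/BDF, rtol 1e-8 for single trajectories
  (1e-6 for population work — plateau read-outs agree to 7 significant
  digits between the two), per-variable absolute tolerances scaled to
  typical magnitudes, and a hard restart at every drug event.
* Steady states by damped Newton (MINPACK hybrid on scaled residuals with
  the `Phi` row substituted) with a long-integration fallback; BDF first,
  LSODA for fully collapsed regimes (e.g. deep supply impairment under
  FCCP, where the system legitimately depolarises to ~0 mV).
* Thermodynamic exponentials are capped (`exp(min(x, 500))`) so solver
  trial states cannot overflow; pool complements are clipped at zero inside
  the right-hand side while the public API rejects invalid states.

### Parameter provenance and calibration

Thermodynamic constants (standard free energies of the complexes and the
synthase, binding constants, pool totals, the ANT partition, phosphate
activation constants) are literature values of the Beard-type oxphos model
family.  The activity constants and the two supply-coupling constants are
calibrated — as in the source study — so that the unperturbed ("WTsim")
profile reproduces intact-neuron behaviour:

* basal steady state inside literature ranges: matrix pH 7.43, `dpsi`
  136 mV, cytosolic ATP ~1 mM (configured ranges 7.2–7.8, 108–167 mV,
  0.5–5 mM);
* oligomycin (F1Fo to 13%) lowers respiration and slightly hyperpolarises;
  FCCP (leak x11) raises respiration ~1.6x and depolarises strongly;
  antimycin A (CIII to 20%) collapses respiration and depolarises; rotenone
  (CI to 20%) raises NADH and mildly depolarises;
* redox responses: NADH rises under oligomycin and rotenone, falls under
  FCCP, and recovers after rotenone-on-FCCP at a supply-limited rate.

The calibrated profile ships as `src/mitoflux/profiles/wtsim.yaml`; every
value is overridable.  Flux units are mol s^-1 (l mito)^-1; only ratios and
fold changes are compared with experiments, so the absolute scale is a free
normalisation.

Known calibration limitation: the simulated post-antimycin residual flux is
~50% of basal rather than near zero.  With a 20% antimycin block and enough
CIII saturation margin that a 70% impairment leaves maximal respiration
inside the ±10% band, the residual cannot be pushed lower — the product of
the drug scale and the impairment-neutral margin bounds it from below.  The
collapse assertions in the tests are therefore "well below basal and below
half of maximal", not "near zero".  Simulated non-mitochondrial OCR is
exactly zero, so no residual subtraction is applied to simulated metrics.

## Protocols and the screen

Drugs are timed multiplicative scalings of single activity constants
(oligomycin F1->13%, FCCP leak x11, antimycin A CIII->20%, rotenone
CI->20%), always relative to the pre-protocol baseline; chronic impairments
are pre-protocol scalings (CI/CIII/CIV/F1 70%, leak 150%, NADH delivery
95%), and a drug on an impaired cell scales the impaired baseline.
Read-outs are taken 20 min after each addition; the default inter-event
spacing (25 min) mirrors the plate-assay cadence and is configurable.

Populations draw independent unit-mean lognormal factors (CV 10% by
default) for all activity constants; the screen runs every condition on the
*same* draws (paired seeds) for variance reduction and classifies the
percent change of population-mean metrics against (a) the ±10% band and
(b) a minimal detectable difference from two-sample power analysis
(`statsmodels` noncentral-t solve; defaults alpha 0.05, power 0.8,
experimental n 67/75, dispersion 25% of the mean — the appendix-level
constants are not printed in the source, so the dispersion default is a
configuration choice).  Both flags are reported independently; labels are
`unchanged` / `altered-by-10%` / `exceeds-power-threshold`.

## Plate and imaging analysis

Metric definitions follow the standard stress-test bookkeeping (see the
module docstring of `mitoflux.metrics`); plateaus are the mean of the last
k = 3 measurement cycles per phase, and non-mitochondrial OCR (post-
antimycin) is subtracted from measured data.  The identities
`basal = ATP synthesis + leak`, `spare = maximal - basal` and
`reserve = maximal glycolysis - basal ECAR` hold exactly by construction
and are property-tested on random inputs.

ATP production rates follow proton-production-rate bookkeeping: total PPR =
ECAR / buffering power (buffering power is a required user input; a
documented default of 0.1 mpH/pmol H+ is provided); respiratory
acidification = mitochondrial OCR x max H+/O2 (1.0) x carbonic speciation
`10^(pH-pK1)/(1+10^(pH-pK1))` (pH 7.4, pK1 6.093); glycolytic PPR by
difference; ATP rates with ATP/lactate = 1, oxidative P/O 2.486 plus a TCA
substrate-level term (P/O 0.121).  All stoichiometries live in one
auditable config block (`AtpStoichiometry`).

Imaging traces are normalized to the mean of >= 3 pre-drug baseline points;
a baseline linear trend above 0.5%/min of the mean flags the trace
unstable.  Fold changes are read 20 min after each addition; the
post-rotenone recovery rate is the initial slope of the normalized signal.

Group statistics: Student's t test for means and a two-sided rank-sum
(Mann-Whitney) test for medians, with percent changes reported for the test
group against the reference group.  No wells or cells are excluded by
default.

## FLIM decay analysis

ROI-aggregated TCSPC histograms are fitted with a bi-exponential plus
constant background by Poisson maximum likelihood (weighted least squares
provides the starting point and is available as an alternative criterion).
Components are relabelled so `tau_free < tau_bound`; amplitudes are
reported at the histogram's t = 0 origin.  Collapsed lifetimes (within 5%
relative) trigger a flagged single-exponential fallback rather than a
silent bi-exponential result.  No instrument-response deconvolution is
applied (tail fitting from the peak bin, configurable offset).  Summaries:
amplitude-weighted mean lifetime, bound/free amplitude ratio (reported as
A1/A2 with A1 = bound/long — source naming is ambiguous, so the library API
uses only `A_free`/`A_bound`), and total amplitude per ROI pixel.

## Synthetic data

The generators emulate the *shape* and the reported effect sizes of the
study's measurements, not their mechanisms:

* plates: per-phase plateaus with instantaneous transitions, a per-well
  lognormal factor (CV 10%) and additive cycle noise; default TgAD effects:
  mitochondrial maximal OCR x0.76, basal ECAR x0.89, maximal glycolysis
  x0.84, basal OCR/leak preserved; default cohort sizes 37/43 wells.
* imaging traces: per-drug fold changes with an optional linear rise rate
  (the post-rotenone recovery; WT 0.08/min vs TgAD 0.05/min of baseline).
* TCSPC decays: bi-exponential expected curves (0.5/2.8 ns) integrated on a
  12.5 ns / 256-bin record (an assumption, not a measured acquisition
  setting), Poisson-sampled at ~1e5 photons, with per-compartment amplitude
  scalings encoding the reported deficits (cell body ~-35%, nucleus -47%,
  mitochondria -50%) and a slightly higher TgAD bound fraction.

Every generator writes a ground-truth ledger, and all recovery tests
compare against the ledger.  What passing recovery tests show is that the
analysis layers are unbiased at the stated noise levels — not that real
plates or microscopes behave like the noise model (no drift, no edge
effects, no instrument response, no per-well exclusions).

## Reproducibility

All randomness flows through explicit integer seeds; the CLI fans a single
run seed out to per-stage child seeds via `numpy` `SeedSequence.spawn` in a
fixed documented order.  Identical config + seed give byte-identical output
tables; every table carries a header with the package version, a hash of
the scientific configuration and the seed.

## Problem sizes

Defaults used by the shipped analyses: 100-member populations for the
screen (seven conditions, paired draws), 30 members for basal-state panels,
100 Poisson replicates for FLIM recovery, and the study-sized synthetic
cohorts above.  These sizes make population means stable to well under the
±10% classification band (standard errors scale as 1/sqrt(n)).
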