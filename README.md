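# mitoflux

Systems-biology toolkit for neuronal mitochondrial bioenergetics: a
thermodynamically balanced ODE model of the respiratory chain in intact
neurons, an in-silico impairment screen, Seahorse-style OCR/ECAR metric and
ATP-production-rate analysis, and NAD(P)H FLIM decay fitting — plus
synthetic-data generators so the whole pipeline is testable end to end
without access to primary cultures.

## The scientific problem

Cultured neurons from transgenic Alzheimer-model mice show a curious
bioenergetic phenotype: basal respiration, ATP-linked respiration and
proton leak are normal, but *maximal* (uncoupled) respiration is sharply
reduced.  Which molecular lesion can do that?  `mitoflux` asks the question
in silico: it simulates the classical mitochondrial stress test
(oligomycin → FCCP → antimycin A) on a flux-based model of oxidative
phosphorylation, applies candidate single-flux impairments — respiratory
complexes I/III/IV or the F1Fo ATP synthase at 70% activity, proton leak at
150%, or the NADH delivery flux at a mere 95% — and classifies the
predicted changes of each OCR metric against a ±10% band and a
statistical-power detection threshold.  Only the NADH-supply impairment
reproduces the "maximal-only" signature, pointing upstream of the
respiratory chain (a glycolytic/substrate-supply defect) rather than at the
chain itself.

## The model in brief

Beard-type oxidative phosphorylation in three compartments (matrix,
intermembrane space, cytosol): every flux `J = X * [mass-action bracket]`
with the apparent equilibrium constant assembled from standard free
energies and the proton-motive force, so fluxes vanish exactly at
thermodynamic equilibrium and always follow their driving force.
Complexes I/III/IV carry reversible saturation denominators (finite
turnover), and the lumped NADH delivery — substrate dehydrogenation plus
the electrogenic malate–aspartate shuttle — falls off sigmoidally as the
membrane depolarises, which is what makes uncoupled respiration acutely
sensitive to a small supply impairment while basal respiration, pinned by
cytosolic ATP demand, is not.  Full model documentation: `docs/methods.md`.

The complex IV flux `J_C4` is the model's proxy for the measured oxygen
consumption rate; the stress-test metrics are read from it 20 min after
each addition and share one formula core with the plate-data analysis:

    basal = ATP synthesis + H+ leak,   spare = maximal − basal,
    coupling efficiency = ATP synthesis / basal,
    cell RCR (basal, max) = (basal, maximal) / H+ leak.

## Worked example

```python
from mitoflux import rc_model, population, protocols

params, init = rc_model.load_profile("WTsim")

# unimpaired stress test
tc = population.run_stress_test(params, init)
m = population.extract_ocr_metrics(tc)
print(f"basal {m.basal:.3e}  maximal {m.maximal:.3e}  "
      f"leak {m.h_leak:.3e}  (mol/s/l mito)")

# the same cell with NADH delivery at 95%
imp = protocols.apply_perturbation(params, protocols.make_impairment("DH", 0.95))
mi = population.extract_ocr_metrics(population.run_stress_test(imp, init))
for name in ("basal", "maximal"):
    pct = 100 * (getattr(mi, name) - getattr(m, name)) / getattr(m, name)
    print(f"{name:8s} {pct:+6.2f}% vs WTsim")
```

prints (values are fluxes per litre of mitochondrion; ratios are what
matter):

```
basal 5.780e-05  maximal 9.465e-05  leak 3.868e-05  (mol/s/l mito)
basal     -0.20% vs WTsim
maximal  -18.27% vs WTsim
```

A 5% reduction of the NADH-delivery activity leaves basal respiration
essentially untouched but cuts maximal respiration by ~18% — beyond the
±10% detection band, reproducing the experimentally observed pattern.  No
70%/150% respiratory-chain impairment shows that signature.

The command line drives the same machinery:

```bash
mitoflux --seed 1 --outdir results screen            # the impairment screen
mitoflux --seed 1 --outdir results simulate          # stress-test trajectory
mitoflux --seed 1 --outdir results synthesize        # synthetic cohorts
mitoflux --seed 1 --outdir results metrics results/synthetic_plate.tsv
mitoflux --seed 1 --outdir results flim-fit results/synthetic_decays.tsv
mitoflux --seed 1 --outdir results reproduce-figures # simulation panels
```

Plate data are read from a tidy long table (`well, group, time_min,
channel, value` with channels `ocr`/`ecar`) or, via
`metrics.plates_from_wide`, from an analyzer-export-like wide table (a
`time_min` column plus one column per well, wells named `group/well`).
Decay histograms come from tidy text
(`roi, group, compartment, area_px, bin_ns, counts`) or a simple HDF5
layout (one group per ROI with `bin_ns`/`counts` datasets).  All outputs are
tab-separated UTF-8 with a provenance header (version, config hash, seed).

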