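# lipidflux

Organelle-resolved quantification and kinetic modelling of intracellular
lipid transport from pulse-chase fluorescence microscopy.

After a brief pulse of a labelled lipid probe delivered to the plasma
membrane, the probe redistributes over minutes to hours between the plasma
membrane (PM), endosomes, the Golgi apparatus and the endoplasmic
reticulum (ER). Given per-organelle probability masks (e.g. exported from
a pixel classifier) and the lipid-channel image of each field of view,
`lipidflux` quantifies the relative lipid signal per compartment over the
chase time course and fits a four-compartment kinetic model that separates
the two retrograde routes out of the plasma membrane:

- **vesicular**: PM → endosomes → Golgi → ER
  (rates `k_PM_Endo`, `k_Endo_Golgi`, `k_Golgi_ER`),
- **non-vesicular**: PM → ER directly via transfer proteins / membrane
  contact sites (rate `k_PM_ER`),

with a single summary anterograde return rate `k_ER_PM`. The model is the
closed linear system

```
d/dt PM    = -(k_PM_Endo + k_PM_ER)·PM + k_ER_PM·ER
d/dt Endo  =  k_PM_Endo·PM − k_Endo_Golgi·Endo
d/dt Golgi =  k_Endo_Golgi·Endo − k_Golgi_ER·Golgi
d/dt ER    =  k_PM_ER·PM + k_Golgi_ER·Golgi − k_ER_PM·ER
```

fitted by multistart bounded least squares (100 restarts in log-rate
space) to the mean ± SE compartment fractions. Derived per fit run:
the quasi-equilibrium constant `k_PM_ER / k_ER_PM` (steady-state PM↔ER
bias) and the route ratio `k_PM_ER / k_PM_Endo` (non-vesicular vs
vesicular flux). Endpoint group comparisons use an approximate permutation
test (|difference of means|, 1000 random relabelings, add-one two-sided
p-value).

Because real microscopy data are large external deposits, the package
ships a synthetic-scene generator (`lipidflux.scene`) that renders fields
of view with known organelle geometry and a lipid channel following a
known kinetic trajectory, so the entire pipeline — masks → fractions →
rates → tests — is validated end to end against ground truth.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study of
two probes whose true non-vesicular rate differs twofold — an
alkyl-ether-like probe ("ePC", `k_PM_ER` = 0.06/min) and a
plasmalogen-like probe ("pPC", `k_PM_ER` = 0.03/min):

```sh
cd analysis
python 01_simulate.py       # render 2 × 38 fields (scratch/)
python 02_quantify.py       # per-field fractions + summaries (results/)
python 03_fit_kinetics.py   # rate constants and ratios (results/)
python 04_endpoint_stats.py # permutation test + endosome control
```

which prints, among other things:

```
ePC: PM fraction 0.980 at 4 min -> 0.219 at 120 min (max SE 0.0006, n=6)
pPC: PM fraction 0.979 at 4 min -> 0.311 at 120 min (max SE 0.0006, n=6)
ePC: k_PM_ER = 0.0621/min (truth 0.06/min), ... quasi-equilibrium = 2.65
pPC: k_PM_ER = 0.0318/min (truth 0.03/min), ... quasi-equilibrium = 1.39
inter-probe quasi-equilibrium ratio ePC/pPC = 1.90 (generating truth: 2.0)
30-min PM fraction ePC vs pPC: |diff| = 0.168, p = 0.000999 (***)
```

Read: the plasmalogen-like probe is retained at the plasma membrane (PM
fraction 0.31 vs 0.22 at 120 min), the fitted `k_PM_ER` recovers the
generating truth within a few percent, the recovered quasi-equilibrium
constants differ by the built-in factor of two, and the 30-min endpoint
difference is highly significant while the endosome morphometrics control
(object count and size) is identical between probes.

The same stages are available as a CLI (`lipidflux simulate | quantify |
fit | test | all`) and as library calls (`run_pipeline`).

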