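# Methods

## Transport model

Relative lipid signal is tracked in four compartments — plasma membrane
(PM), endosomes, Golgi, ER — as a closed first-order system. All mass
starts in the PM at the first measured chase time (the probe pulse ends
there), so the initial condition is `(1, 0, 0, 0)` at t₀ and times are
re-indexed to t − t₀ internally; fitting the initial state instead is
available via the `initial_state` argument. Because only *relative* signal
is analysed, no degradation/efflux term is included: normalisation removes
any total-loss mode, and the closed system keeps fractions on the simplex
for all nonnegative rates.

Five rates (all min⁻¹, bounded to [0, 10]):

| rate | route |
|---|---|
| `k_PM_Endo` | retrograde vesicular entry, PM → endosomes |
| `k_Endo_Golgi` | vesicular leg, endosomes → Golgi |
| `k_Golgi_ER` | vesicular leg, Golgi → ER |
| `k_PM_ER` | retrograde non-vesicular, PM → ER |
| `k_ER_PM` | summary anterograde return, ER → PM (both modes lumped) |

The two intermediate vesicular legs are free parameters by default; a
`tie_vesicular_legs` switch constrains them to one value for
identifiability experiments. No Golgi → PM shortcut is modelled.

`forward_model` integrates the system with an adaptive Runge–Kutta solver
(DOP853, rtol 1e-12, atol 1e-14), integrating segment by segment so every
reported time is a true integration endpoint rather than a dense-output
interpolation; the matrix-exponential closed form (`method="expm"`) is the
independent cross-check and the fast path used inside fitting. The two
agree to ~1e-11 over the 4–120 min grid.

## Fitting

`fit_multistart` minimises the weighted residual
`(model − data) / SE` (unit weights where SE is unavailable) over
log₁₀-rates with trust-region bounded least squares. Log parametrisation
enforces positivity and lets a single fit span decades of rate magnitude;
bounds are log₁₀ k ∈ [−6, 1]. Starts are drawn log-uniformly from
[1e-4, 1] min⁻¹ with per-run seeds derived from the master seed via
`SeedSequence([seed, run])`, so an ensemble is reproducible and its runs
independent. The point estimate is the mean over converged runs and the
uncertainty their SD; the best (lowest-loss) run is also exposed. On the
synthetic data here the objective is effectively unimodal — all 100
restarts converge to the same optimum — so ensemble mean and best run
coincide; on degenerate data (e.g. nearly coincident timepoints) the
ensemble stays scattered, which `recovery_report` flags as
non-identifiable (SD/mean > 1).

Derived ratios (quasi-equilibrium `k_PM_ER/k_ER_PM`, route ratio
`k_PM_ER/k_PM_Endo`) are computed per run and then summarised — never as
ratios of ensemble means — with zero-denominator runs excluded and
counted.

## Image quantification

Per field: (1) background correction — default the 50th percentile of
intensities *outside* the cell mask, subtracted and clipped at zero (the
percentile is parameter-light and robust; a constant-background fallback
covers fields without free background); (2) Gaussian blur, σ = 4 px,
reflective boundaries (conserves mass near edges better than
zero-padding); (3) signal assignment by per-organelle probability masks.
The order correct → blur → assign is fixed and recorded in the output
provenance.

Assignment default is the proportional policy: pixel intensity I(x)
contributes `I(x)·P_o(x)/ΣP(x)` to organelle o, which conserves
`Σ assigned + unassigned = Σ I` exactly; pixels where all masks are zero
feed a reported "unassigned" pool that is excluded from the fraction
denominator. An argmax policy (winner takes the pixel, ties broken by the
canonical PM/Endo/Golgi/ER order) is available. Relative fractions are
assigned sums normalised over compartments; scaling an image leaves them
unchanged. Endosome morphometrics binarise the endosome mask at 0.5 and
label 8-connected components; touching objects merge by construction.
Coordinates are (row, col), 0-based; areas in px².

## Synthetic scenes

Each field holds `n_cells` disc-shaped cells on a jittered grid. Per cell:
a PM ring at the boundary (16 px), a reticular ER texture (smoothed-noise
threshold at density 0.55) filling the interior, a compact perinuclear
Golgi blob cluster, and mutually disjoint endosome discs (radius 8–12 px,
placement by rejection sampling; an error names the offending parameter if
the geometry cannot fit). Binary layers are softened with a σ = 1 px blur
and clipped to [0, 1] to emulate classifier-style probability maps, then
restricted to the (slightly dilated) cell mask.

The lipid channel distributes `total_signal × n_cells` photons over the
soft masks in proportion to the compartment fraction vector, adds a flat
background, and applies Poisson shot noise plus additive Gaussian read
noise. No-UV control fields contain background and noise only. Seeds
derive from one master seed by a counter scheme
(`SeedSequence([seed, time_index, field_index])`), so datasets are
bitwise reproducible and fields independent.

Two geometry choices are deliberate and matter for fidelity:

- **Scale.** Structures are chunky relative to the σ = 4 analysis blur
  (384² images, ~80 px cell radius, 16 px ring, 8–12 px endosomes):
  assignment of a blurred image through pointwise masks cannot be faithful
  when structures are thin compared with the blur. Real endosomes are
  smaller relative to a cell; the generator trades that realism for a
  quantification benchmark with a controlled error budget.
- **Compartment margins.** An 8 px signal-free margin separates the ER
  region from the PM ring and from Golgi/endosome objects. Signal blurred
  across a boundary then lands in unclaimed territory (counted as
  unassigned, ~2–5 % per field, reported) instead of in the neighbouring
  compartment; since the unassigned pool is excluded from the fraction
  denominator, near-equal per-compartment losses cancel on normalisation.
  With both choices the noise-free round trip
  (truth → render → quantify) is accurate to ≤ 0.02 absolute per
  compartment at every timepoint, which is the regime the recovery tests
  assume.

What the generator does *not* emulate: 3D structure, photobleaching,
chromatic shift, cell motion and shape diversity, classifier errors in
the masks (masks are the generator's own geometry, softened), and probe
chemistry beyond a per-probe total-signal scalar. Consequently, passing
tests show the *pipeline* recovers what the masks and model describe; they
do not certify accuracy under real segmentation error or optical
artefacts. Camera statistics of real data are unknown; the
Poisson-Gaussian defaults (scale 1, read SD 2, background 20, ~5 × 10⁶
photons/cell) are a stated modelling choice, exposed in `SceneConfig`.
Note that at much lower photon budgets the clip-at-zero in background
correction rectifies noise under the large ER mask and biases fractions
by a few percent — a known limitation of the fixed correct-then-blur
order under heavy noise.

## Statistics

The approximate permutation test uses |mean(a) − mean(b)|, n random
relabelings of the pooled values at the original group sizes, and the
add-one two-sided p-value `(1 + #{null ≥ obs})/(n + 1)`, which is valid at
finite rounds and bounded below by 1/(n+1). Sidedness is two-sided;
per-comparison p-values are reported (star map: n.s. > 0.05, * ≤ 0.05,
** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001). Summaries report mean, SD (ddof 1)
and SE = SD/√n per probe × time × compartment, with SD/SE missing for
single-field groups.

## Problem sizes

The shipped study uses 6 chase times (4, 10, 20, 30, 60, 120 min), 6
fields per time and probe, 3 cells per field, 100 fit restarts; the
stochastic-recovery experiment uses 50 simulated datasets (fraction noise
SD 0.02, 6 replicates per timepoint) with 15 restarts each, a size at
which the unimodal fit landscape makes more restarts redundant. All
simulations, fits and tests in the repository run from fixed seeds and are
deterministic end to end.
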