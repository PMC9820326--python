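# Methods

This note documents the physics models, the numerical choices, what the
synthetic data stand in for, and the known limits of the approach. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Photon physics

Photons in the 1 keV - 7 MeV window undergo three processes, built per
element and combined by mass-fraction additivity:

* **Compton scattering** on free electrons with the analytic Klein-Nishina
  cross section; the energy fraction is sampled with the standard two-branch
  rejection method, and scattered-photon/electron kinematics close exactly
  (`E0 = E' + T_e`). No incoherent-scattering-function (binding) correction
  is applied, which overestimates Compton below ~50 keV.
* **Photoelectric absorption** as a per-element power law through anchor
  values at 10 and 100 keV (approximate fits to standard tabulations), with
  a crude 8.2x jump below the Fe K edge (7.112 keV). After absorption on
  iron, a 6.4 keV K-alpha fluorescence photon is emitted with yield 0.34,
  otherwise the binding energy deposits locally (Auger); for low-Z elements
  the binding energy is neglected.
* **Pair production** as a single Z^2/A parameterization with threshold
  shape `((E - 1.022)/E)^3 * E`, anchored so water reaches the standard
  ~3.7e-3 cm^2/g at 6 MeV. The pair shares `E - 1.022 MeV` uniformly between
  the electron and positron; positrons annihilate at rest into two
  back-to-back 0.511 MeV photons.

Rayleigh scattering is omitted (no energy transfer; negligible megavoltage
dose impact). Sanity anchors asserted in tests: the Klein-Nishina total
matches independent quadrature to 0.1%, tends to the 0.6652-barn Thomson
value at low energy, and the water total attenuation at 1 MeV is within 2%
of the standard 0.0707 cm^2/g.

Photon free paths use **Woodcock (majorant) tracking** against the maximum
linear attenuation over the grid per energy (with a 1% interpolation pad),
so no per-voxel boundary crossings are needed. Photons leaving the grid are
scored as escaped and not re-entered.

## Electron/positron transport

Charged particles use a class-II-free condensed-history scheme:

* **Energy loss**: Moller collision stopping power (Bragg-additivity mean
  excitation energies, no density-effect correction; within a few percent of
  reference values over 0.1-7 MeV, asserted at 1 MeV for water at 5%), plus
  an approximate radiative fraction `Z_eff T / 800` deposited locally by
  default. All loss along a step deposits continuously; no discrete
  delta-ray production above the cut-off.
* **Multiple scattering**: Highland/Gaussian polar deflection per step using
  per-material radiation lengths.
* **Magnetic field**: the direction vector is rotated about the field axis
  by the exact helix angle `theta = -z_e * s / r` with
  `r = pc / (0.29979 B)` (mm, MeV, tesla), applied as half-rotation /
  straight move / half-rotation. The rotation never changes the kinetic
  energy. A 1 MeV electron at 1.5 T has r = 3.16 mm; the integrator
  reproduces analytic helices (radius and pitch at pitch angles 30/60/90
  degrees) to better than 1%.
* **Step control**: `step <= min(1 mm, 5% fractional energy loss, 0.1 x
  gyroradius)`. The 5% energy cap and the splitting of each step's deposit
  over two points along the segment keep single-step deposits small against
  typical voxel doses, which matters for voxel-level difference maps. An
  electron whose residual CSDA range (at local density) is below 0.3 mm
  deposits locally — a voxel-scale range rejection that cannot trigger in
  air, so cavity/interface transport is unaffected.
* **Cut-offs** are 1 keV for photons and electrons.

Every cycle asserts exact energy bookkeeping: beam energy in = deposits +
escapes, with the 1.022 MeV pair debt repaid at annihilation (a positron
escaping the grid carries its latent annihilation energy with it); violation
beyond 1e-6 relative aborts the run.

## Randomness, cycles and batch statistics

A run is `n_cycles` independent cycles; cycle c draws three independent
generator streams (source, photon stage, electron stage) from
`SeedSequence((seed, c))`. Identical configuration and seed give
bit-identical grids. Because primaries and their pre-first-interaction
transport consume only the source/photon streams and feel no Lorentz force,
the primary-fluence grids are bitwise invariant under the magnetic field at
fixed seed.

Dose is the cycle mean of energy deposit / voxel mass / primaries (GeV/g per
primary), and its uncertainty the standard error over cycles. Derived
scalars and profiles computed over voxel windows use cycle-to-cycle
variances rather than propagated per-voxel sigmas, because voxel doses
within a window are correlated through shared electron tracks.

Fluence estimators are track-length based: charged fluence at step
resolution, primary photon fluence by sub-voxel marching of
pre-first-interaction segments (switchable off; it dominates runtime when
on).

## Geometry and sources

The **synthetic head phantom** stands in for a patient CT: an ellipsoidal
soft-tissue interior (ICRU-44-like composition, 1.06 g/cm^3) in a 5 mm
cortical-bone shell, surrounded by air, with an air cavity (oral-nasal
analogue) below the target, on a 110x110x140 grid of 1 mm voxels. The PTV is
a half-open 10-voxel cube (exactly 1000 voxels ~ 1 cm^3) on the beam axis
with its centre 30 mm below the entry surface; its voxels carry the
FeNP-infused compound. It reproduces the tissue/bone/air *topology* relevant
to interface and enhancement effects, not anatomical realism — passing tests
say nothing about organ-level accuracy on real CTs. HU-volume conversion via
a whitespace-separated ascii table (fixed or linear-in-HU densities) is
provided for real integer volumes.

**FeNP compounds** are homogeneous virtual mixtures: elemental Fe by default
(matching "Fe mass concentration" on a w/w basis), magnetite Fe3O4
(5.17 g/cm^3) as the documented alternative agent; nanoparticle size
(nominally ~10 nm) is carried as a concept only — no nanoscale track
structure. Mixture density follows the inverse (volume-additive) rule by
default, `1/rho = sum(w_i/rho_i)`, with the linear rule available; the
choice is recorded with results because enhancement quantities are sensitive
to it.

The **6 MV beam** is a parallel rectangle (default 30 x 30 mm^2, a sensible
conformal field for a ~1 cm^3 intracranial target; configurable) along -z
with energies from a packaged histogram `phi(E) ~ E^0.6 exp(-E/1.2)` on
(0.025, 6.5] MeV — mean ~1.8 MeV, the characteristic low-energy rise and
broad maximum of clinical 6 MV spectra. No phase-space angular correlations
or electron contamination. Any user histogram CSV can be substituted.

## Thermal model

Survival follows the LQ model with temperature/time-dependent coefficients;
TER is parameterized as `TER0 + c1 t exp(c2 (T - T_c))`. The enhancement
convention is `TER = D_iso(unheated)/D_iso(heated) >= 1` (the reciprocal of
the heated/reference dose ratio notation). `T_c` is fixed by the user
(default 45 degC) because it is weakly identified jointly with `c2`; fitting
it is opt-in. Fits are unweighted least squares, inverse-variance weighted
when sigmas are supplied; scenario TER uncertainties come from first-order
propagation of the fit covariance.

Survival-vs-temperature series convert to TER through a joint scale factor k
on (alpha, beta) inferred from survival at the assay dose, followed by the
iso-effect dose ratio at a configurable survival level (default 10%). Note
the ratio is *below* k whenever beta > 0, because the LQ effect is quadratic
in dose — asserting otherwise is a common slip.

`IDE = TER x DER` exactly, with relative uncertainties added in quadrature
(first-order separability and independence are the model's own
assumptions). A no-hyperthermia scenario forces TER = 1, collapsing IDE to
DER. TER is concentration-independent in this model, so IDE inherits the
DER ordering across concentrations; coupling of FeNP concentration to
heating is out of scope.

## Synthetic data

The survival generator emulates hyperthermia viability series for three
glioblastoma-related cell lines (fixed 60-min application across 37-45 degC
by default) from a known TER model with multiplicative log-normal noise
(default sigma 0.02, matching the few-percent scatter typical of clonogenic
assays); the cycle-grid generator produces Normal(mean, (rel_sigma mean)^2)
batch grids truncated at zero. Every generator is a pure function of
(spec, seed) and returns its ground truth, so recovery tests are
self-contained. Neither emulates assay-specific artefacts (plating
efficiency drift, counting error structure), so fit-recovery results bound
only statistical, not systematic, errors on real data.

## Desk-scale study sizes

Default study sizes are 5 cycles x 2e5 primaries on <= 128^3 grids — enough
for sub-2% batch uncertainty on the mean PTV dose while keeping single-CPU
runtimes at minutes; all sizes are configurable upward. At these sizes,
per-voxel doses in the PTV carry ~20-30% relative uncertainty. Consequences
worth understanding when reading voxel-level difference maps:

* The *maximum* voxel percent difference over a 1000-voxel region is an
  extreme-value statistic and is dominated by batch noise whenever the
  underlying physical difference is smaller than ~3 standard deviations of a
  voxel. For the 10% w/w Fe PTV the physical mean enhancement at 6 MV is
  DER ~ 1.006 +- 0.009 (Compton dominates and scales with electron density,
  not Z; photoelectric/pair gains are percent-level), so the reported
  maximum difference at these history counts reflects the noise floor
  (order 1e2 %), not a resolved physical hotspot. Shared seeds between the
  two arms suppress but cannot eliminate this, because histories decorrelate
  once they interact inside the modified target.
* The interface measurement is different in kind: the electron return effect
  at 1.5 T changes cavity-adjacent doses by large factors (the band median
  percent difference far exceeds the bulk median), so its exceedance
  threshold is met by physics, not noise. Relative-difference maxima use the
  standard low-dose exclusion (reference dose >= 10% of the dense-voxel
  maximum) so that statistically empty denominators do not produce
  arbitrary ratios.

## Known limitations

Free-electron Compton (no Doppler/binding), fitted photoelectric amplitudes
(~10-20% accuracy per element), no Rayleigh, no discrete delta rays or
explicit bremsstrahlung photon transport (radiative loss deposits locally by
default), no density-effect correction in stopping power, parallel beam
without head scatter or electron contamination, photons not re-entered after
leaving the grid, positron transport using electron stopping powers. These
are appropriate for percent-level relative dosimetry of megavoltage
photon/electron transport at millimetre resolution, not for absolute
commissioning-grade dose calculation.
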