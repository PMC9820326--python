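# ntrtdose

Voxel Monte Carlo dosimetry for iron-nanoparticle (FeNP) infused targets in
MRI-guided radiotherapy, with hyperthermic radiosensitization folded in as a
thermal enhancement ratio.

## The problem

MRI-linac machines deliver a 6 MV photon beam inside a strong (1.5 T) static
magnetic field. Two physical effects make dosimetry in this setting
non-standard:

* the Lorentz force curls the secondary electrons that actually deposit the
  dose, most visibly at tissue/air interfaces where electrons launched into a
  low-density cavity spiral back into tissue (the *electron return effect*),
  distorting the interface dose;
* infusing the target volume (PTV) with a higher-Z agent such as iron
  nanoparticles changes the local photon interaction balance, producing a
  concentration-dependent local dose change.

If the same FeNPs are also used as magnetic-hyperthermia agents, heating
radiosensitizes the tumour cells. `ntrtdose` quantifies the combined effect
as the nano-thermo-radiotherapy **integral dose enhancement**

```
IDE_nTRT = TER x DER
```

under first-order separability, where

* `DER = <D_PTV(FeNP)> / <D_PTV(reference)>` is the dose enhancement ratio
  from a pair of Monte Carlo simulations, and
* `TER(T, t) = TER0 + c1 t exp(c2 (T - T_c))` is the thermal enhancement
  ratio, an iso-effect dose ratio of the linear-quadratic survival model
  `-ln S = alpha(T,t) D + beta(T,t) D^2`, with `c1, c2` fitted per cell line
  from survival/TER data.

Relative dose distortion maps are reported as
`dD(r) = 100 (D(r) - D_ref(r)) / D_ref(r)` [%].

The intended users are medical-physics researchers prototyping
nanoparticle/MRI-linac studies at desk scale: everything runs on one CPU in
minutes with a vectorized numpy engine, with synthetic stand-ins (head-like
voxel phantom, parameterized 6 MV spectrum, survival datasets with known
ground truth) for inputs that normally require a clinic.

## What is inside

| module | role |
| --- | --- |
| `materials` | elements, tissue/bone/air compositions, FeNP virtual compounds, photon cross sections (Klein-Nishina Compton, photoelectric power-law fits, parameterized pair production), electron stopping powers |
| `phantom` | synthetic head phantom (tissue + bone shell + air cavity + ~1 cm^3 PTV at ~3 cm depth), slab phantoms, ascii HU-to-material conversion |
| `beam` | 6 MV spectrum histogram and parallel-beam source |
| `transport` | the Monte Carlo engine: Woodcock photon tracking, condensed-history electrons/positrons, exact helical Lorentz-force rotation, batch (cycle) scoring |
| `dosimetry` | dose maps with batch uncertainties, percent-difference maps, DER, profiles, interface-band statistics |
| `thermal` | LQ survival, TER evaluation and nonlinear fitting, iso-effect conversions |
| `ide` | TER x DER synthesis with quadrature uncertainty over scenario grids |
| `synthetic` | generators with known ground truth for survival data and cycle grids |
| `workflow` / `cli` | the 13-setup study grid (5 Fe concentrations x 3 field configurations), manifests, volume/CSV outputs; `ntrtdose` console script |

## Worked example

```python
from ntrtdose import (
    FieldSpec, TransportConfig, TERModel, ScenarioSpec,
    default_6mv_spectrum, generate_head_phantom, run_simulation,
    grids_to_dosemap, compute_der, compute_ide,
)

beam = default_6mv_spectrum()
cfg = TransportConfig(n_primaries=200_000, n_cycles=5, seed=1, score_fluence=False)

ref = generate_head_phantom(fe_mass_fraction=0.0, seed=1)
fe = generate_head_phantom(fe_mass_fraction=0.10, seed=1)
map_ref = grids_to_dosemap(run_simulation(ref, beam, FieldSpec(), cfg), ref)
map_fe = grids_to_dosemap(run_simulation(fe, beam, FieldSpec(), cfg), fe)

der = compute_der(map_fe, map_ref, fe.ptv_mask, fe_mass_fraction=0.10)
print(f"DER(10% w/w Fe) = {der.der:.4f} +- {der.der_uncertainty:.4f}")

ter_model = TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
scenario = ScenarioSpec("HT 42C/90min", temperature=42.0, time=90.0)
ter = ter_model(42.0, 90.0)
ide = compute_ide(der, ter, 0.0, scenario)
print(f"TER(42C, 90min) = {ter:.4f};  IDE = {ide.ide:.4f} +- {ide.ide_sigma:.4f}")
```

prints (about one and a half minutes on one CPU):

```
DER(10% w/w Fe) = 1.0059 +- 0.0093
TER(42C, 90min) = 1.7318;  IDE = 1.7421 +- 0.0160
```

Read: at megavoltage energies a 10% w/w Fe admixture changes the mean PTV
dose by well under a percent (the Compton-dominated regime is insensitive to
Z), while a 42 degC / 90 min hyperthermia session with these illustrative
TER coefficients contributes a ~1.7x iso-effect enhancement; their product
is the integral enhancement with both uncertainties combined in quadrature.

The full 13-setup study grid (concentrations 0-10% w/w crossed with no
field, 1.5 T perpendicular and 1.5 T parallel) runs from the shell:

```bash
ntrtdose run-grid --primaries 20000 --cycles 5 --seed 1 --out results/grid
```

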