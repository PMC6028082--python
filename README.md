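# mims18o

Simulation and fitting of ¹⁸O-exchange carbonic anhydrase (CA) kinetics
measured by membrane-inlet mass spectrometry (MIMS), built to compare the
catalytic behaviour of the tumour-associated transmembrane isoforms CAIX and
CAXII in breast-cancer cell lines and membrane ghosts.

## The measurement and the model

At chemical equilibrium, CA still interconverts CO₂ and HCO₃⁻; each
hydration/dehydration cycle exchanges one substrate oxygen with the
(effectively infinite, unlabeled) water pool. Starting from ¹⁸O-enriched
dissolved carbon, the ¹⁸O atom fraction α of extracellular CO₂ therefore
decays without any net chemistry, and its decay rate reads out CA activity.
The instrument observable is α(t); the package models it with an
isotopologue-resolved linear ODE: per compartment, CO₂ with 0–2 labeled
oxygens and HCO₃⁻ with 0–3, plus an absorbing counter for ¹⁸O released to
water. Hydration (per-molecule rate `(R1 + k_h·[CO₂])/[CO₂]`) adds an
unlabeled oxygen; dehydration removes one oxygen uniformly at random;
whole cells add a second compartment coupled by first-order CO₂ exchange
(HCO₃⁻ is impermeant), with cytosolic CAII producing the fast first phase of
biphasic curves.

The quantities recovered by the fitting stages, in the field's notation:

- `k_obs` — first-order constant from OLS of ln α on time in a phase window
  (early 130–180 s, late 250–450 s);
- `R1/E` — equilibrium CO₂↔HCO₃⁻ interconversion flux per enzyme, from
  inverting the single-compartment model's slow eigenvalue;
- `kcat^exch/K_eff^CO₂` — catalytic efficiency `(R1/E)/[CO₂]`, fitted across
  pH as `A/(1 + 10^(pKa−pH))` (single ionization, hydration direction), with
  the dehydration curve derived by the equilibrium (Haldane) relation
  `eff_dehyd(pH) = eff_hyd(pH)·10^(pK1−pH)`;
- `E_total` — active-enzyme concentration from tight-binding
  (ethoxzolamide) titration via the Morrison quadratic;
- `Ki` — classical dose-response constant of the impermeant sulfonamide
  N-3500, which reaches only exofacial enzyme.

No raw instrument traces were deposited with the published study, so a
seeded synthetic-data module (`mims18o.synthetic`) generates traces,
titrations and inhibition series under the published assay conditions
(16 °C, 25 mM total CO₂ species, 2 mL, 5×10⁵ cells/mL, addition at 120 s),
parameterized by a frozen registry of every published kinetic value.

## Worked example

```python
from mims18o import fit_first_order, predict_fold_change, standard_conditions
from mims18o.synthetic import build_layout, generate_trace

trace = generate_trace("UFH001_hypoxic")        # noiseless biphasic curve
early = fit_first_order(trace, (130, 180))
late = fit_first_order(trace, (250, 450))
print(f"early k = {early.k_obs:.2e} 1/s, late k = {late.k_obs:.6e} 1/s")

cond = standard_conditions()
caix = build_layout("CAIX", cond).pools[0]      # ghost fixture: A=3.8e7, pKa 6.2
fold = predict_fold_change(caix, cond, 7.4, 6.8)
print(f"pH 7.4 -> 6.8 fold change: {fold:.2f}")
```

prints

```
early k = 1.97e-02 1/s, late k = 1.170000e-03 1/s
pH 7.4 -> 6.8 fold change: 2.85
```

The early slope (intracellular CAII, reached through membrane CO₂ exchange)
is ~17× the late slope, which matches the 1.17×10⁻³ s⁻¹ constant that
calibrated the simulator to better than 0.01%. The fold change is a pure
model prediction — CO₂ speciation rises ~3.2× from pH 7.4 to 6.8 while the
CAIX titration factor falls ~15% — and rounds to the observed 3-fold
activation.

The numbered scripts under `analysis/` run the full study in order:
simulate all fixture traces (`01`), fit and verify the rate constants with
the N-3500 blockade control (`02`), fit the pH titrations and derive the
dehydration curves (`03`), quantify active enzyme and Ki (`04`), and scan
the acidification fold-change prediction (`05`). Each writes its tables
under `results/`.

A CLI mirrors the stages:

```
mims18o simulate --fixture T47D_hypoxic --seed 1 --out trace.csv
mims18o fit trace.csv --window late
mims18o fixtures
```

## Trace CSV dialect

Traces are plain CSV with header `time_s,alpha18_co2`; times strictly
increasing in seconds, α in [0, 1]. Extra columns are preserved in trace
metadata on read. Assay conditions travel as flat YAML/JSON
(`ph`, `temperature_c`, `total_carbon_mM`, `vessel_volume_mL`,
`cell_density_per_mL`, `label_enrichment`).
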