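# thermoforage

From respirometry trials to thermal performance curves, body velocity and
predator search rates — a mechanistic pipeline for predicting how warming
reshapes predator–prey interactions in aquatic ectotherms.

## The problem

Measuring how fast a dragonfly nymph swims at 30 °C is hard; measuring how
much oxygen it consumes is routine. Metabolic theory links the two: whole-
organism respiration rate `B` follows a unimodal thermal performance curve
(TPC), locomotion is powered by metabolism, and the rate at which a predator
clears space while searching for prey is set by the relative velocity of the
pair and a body-mass-dependent detection region. `thermoforage` implements
that chain so that population-level interaction traits can be projected from
nothing more than O₂ traces, body lengths and habitat temperature loggers:

1. **respirometry** — OLS slope of each vial's O₂ trace, corrected by the
   batch control vial and vial volume; length→dry-mass allometry; screening
   against the 70%-of-start stopping rule.
2. **tpc** — the mass-dependent Sharpe–Schoolfield model

   ```
   B(T, m) = B₀ m^β exp(−E/k (1/T − 1/T_ref)) / (1 + exp(E_d/k (1/T_pk − 1/T)))
   ```

   fitted per site-population by multistart bounded NLLS (starts from an
   Arrhenius plot, best of *n* runs by residual sum of squares), with
   case-resampling bootstrap 95% bands.
3. **locomotion** — body velocity via the cost-of-transport model
   `v = Bγ / (C m g)` with `C = 1.1 m^−0.38` (m in kg), so velocity TPCs and
   their uncertainty inherit directly from the respiration fits.
4. **interaction** — predator–prey velocity mismatch over each site's
   operational temperature range (OTR), and search rates
   `a = v_rel · D` with `D = 2 d₀ (m_c m_r)^{p_d}` in 2D (sessile benthic
   prey, `p_d = 0.21`) or `D = π d₀ ((m_c m_r)^{p_d})²` in 3D (active
   pelagic prey, `p_d = 0.2`), plus Arrhenius-plot estimates of each
   search-rate curve's effective activation energy.
5. **synthdata** — a generator that emulates a three-site mesocosm campaign
   (hourly loggers, 10–45 °C acute assays at 5 °C steps, control-vial drift,
   lognormal rate noise) from known ground-truth TPCs, so every stage is
   testable by parameter recovery.

## Worked example

```
thermoforage all --config examples/demo.yaml --outdir demo_out
```

simulates the default campaign (3 sites × 3 taxa × 8 acute temperatures ×
4 individuals, rate CV 0.2, seed 42), fits all nine TPCs and writes every
table plus a manifest. `demo_out/tpc_parameters.csv` then holds rows such as

```
taxon          site    B0            E        Tpk_K    beta   r_squared
S_striolatum   Toledo  9.98e-12      0.942    304.86   0.855  0.930
S_striolatum   Porto   1.84e-11      0.592    308.56   0.499  0.861
Chironomus     Toledo  1.62e-11      0.757    302.50   0.636  0.912
```

— `B0` is the mass-normalised rate (mol O₂ s⁻¹ mg⁻ᵝ) at each site's mean
habitat temperature, `E` the activation energy in eV, `Tpk_K` the thermal
optimum. `demo_out/search_arrhenius.csv` summarises the derived search-rate
curves, e.g.

```
consumer       resource    site    strategy  E      r_squared
S_striolatum   Chironomus  Toledo  sessile   0.942  1.000
S_striolatum   C_dipterum  Toledo  active    0.885  1.000
```

showing that the sessile-prey (2D) search rate inherits the predator's
thermal sensitivity exactly, while the active-capture (3D) rate blends
predator and prey sensitivities. `demo_out/mismatch.csv` quantifies the
predator–prey velocity gap over each site's OTR (mean Δv, sign consistency,
and the fraction of the OTR where the 95% bands separate).

The same stages run individually (`simulate`, `rates`, `fit`, `velocity`,
`search`, `validate`) and exchange plain CSV, so any stage can start from
your own files instead of the generator; see `thermoforage --help`.

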