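# Methods

## Respirometry processing

Each sealed-vial trial yields an O₂ concentration trace (µmol L⁻¹ vs
seconds). The individual's oxygen consumption rate is the OLS slope of all
trace points, corrected by the slope of the animal-free control vial in the
same batch (sensor drift plus microbial respiration) and scaled by vial
volume:

    rate [mol O₂ s⁻¹] = −(slope_sample − slope_control) × V × 10⁻⁶

Consumption is reported positive. Traces are screened before use: fewer
than two points, non-increasing timestamps, or a final concentration below
70% of the start (a trial that over-ran its stopping rule) reject the
trace; a positive sample slope is physiologically implausible and is
flagged for review rather than silently dropped. The 70% boundary is
inclusive. Body length (mm) converts to dry mass (mg) by a per-taxon power
law `a·L^b`; coefficients are configuration, and the bundled defaults are
synthetic placeholders of realistic magnitude, not measured allometries.

One control per trial batch is assumed and enforced. Gaps between logging
periods within a trace are ignored: a single regression pools all points.

## The thermal performance model

Respiration follows the mass-dependent Sharpe–Schoolfield form (rates in
mol O₂ s⁻¹, temperatures in K, energies in eV, k = 8.617×10⁻⁵ eV K⁻¹):

    B(T, m) = B₀ m^β exp(−E/k (1/T − 1/T_ref)) / (1 + exp(E_d/k (1/T_pk − 1/T)))

* `B₀` — mass-normalised rate at the reference temperature, the curve's
  elevation. `T_ref` is the mean habitat temperature of the population's
  site over the larval window, so `B₀` measures baseline performance under
  the conditions the population actually experienced.
* `E` — activation energy of the rising portion; `E_d` — deactivation
  energy governing the collapse past the optimum (constraint `E_d > E`);
  `T_pk` — temperature of peak rate; `β` — mass-scaling exponent, fitted
  jointly per population.

### Fitting

Starting values come from an Arrhenius plot restricted to the rising
portion (temperatures at or below the peak of the mean mass-corrected
rate, provisional β = 3/4): ln(rate) regressed jointly on ln(mass) and
(1/kT − 1/kT_ref) gives ln B₀, β and E; the T_pk start is the peak
temperature + 2 K and the E_d start is 3E. If fewer than three rising
temperatures exist or the slope is non-positive, documented fallbacks
(E = 0.65 eV, β = 0.75) are used.

The model is then fitted by bounded trust-region NLLS in the
parametrisation (ln B₀, E, ΔE_d = E_d − E, T_pk, β), which turns the
positivity and ordering constraints into box bounds; T_pk is bounded to
the observed temperature range ± 10 K. Residuals are computed on the rate
scale and uniformly scaled by their SD for conditioning (the argmin is
unchanged). The first start is the Arrhenius estimate itself; every
further start perturbs each natural parameter with Gaussian noise of SD
25% of its starting value, drawn sequentially from one seeded generator —
so a run with more starts extends, never reshuffles, a shorter run's start
sequence, and the retained (lowest-SSR converged) fit can only improve.
The field protocol uses 10,000 starts; the package default is 200,
config-selectable. R² is reported as 1 − SSR/SST. Parameter standard
errors come from the Jacobian at the optimum, delta-method transformed to
the natural scale.

### Uncertainty

Bootstrap is nonparametric case resampling of individuals, refit by a
single NLLS run warm-started at the best-fit parameters (the resampled
objective is close to the original, so warm starts converge reliably and
cheaply). Failed refits are counted, never fabricated; more than 20%
failures records a warning. Curve bands are pointwise 2.5/97.5 percentiles
of replicate curves at a fixed representative mass (default: the
population's mean dry mass). Population comparisons report per-parameter
differences, z = Δ/√(SE_a²+SE_b²), and a 95% bootstrap-CI overlap flag;
fits at different T_ref are refused since their B₀ are not comparable.

## Velocity

Cost of transport for submerged swimmers is allometric, `C = 1.1 m^−0.38`
(J N⁻¹ m⁻¹, m in kg), and velocity follows from power balance:

    v = B γ / (C m g)

with γ = 4.5×10⁵ J per mol O₂ (the standard oxycalorific equivalent;
configurable) and g = 9.81 m s⁻². All metabolic power is assumed allocated
to locomotion — a deliberate upper-bound simplification — with a
configurable allocation fraction (default 1). Because v is a positive
linear transform of B at fixed mass, velocity TPCs, their optima and their
bootstrap bands map one-to-one from the respiration fits.

Two mass roles are kept distinct: the dry mass (mg) at which the
respiration curve is evaluated, and the body mass (kg) entering C·m·g.
By default the latter is the former converted at 1 mg = 10⁻⁶ kg; both are
overridable, and the dry-to-wet distinction is deliberately out of scope.

The velocity normalisation `v₀` (m s⁻¹ per mg^β) is defined from the
Arrhenius numerator only — deactivation excluded — so that
`v₀ m^β exp(−E/k(1/T − 1/T_ref))` reproduces the rising-portion velocity
exactly and `v₀` inherits B₀'s role one level up. This convention is a
documented package choice; with T_pk well above T_ref it agrees with the
full-model velocity at T_ref to within ~1–5%.

## Search rates

Search rate is relative velocity times a detection region. Under active
capture both parties move with random headings, giving the
root-sum-of-squares relative speed; sessile prey contribute zero velocity:

    active:  a = √(v_r² + v_c²) · D      sessile:  a = v_c · D
    2D: D = 2 d₀ (m_c m_r)^{p_d}         3D: D = π d₀ ((m_c m_r)^{p_d})²

with d₀ the minimum reaction distance (default 0.01 m, configurable per
pair) and p_d the empirical dimensionality-scaling exponent (defaults
0.21 in 2D, 0.2 in 3D). Masses in the detection region are in kg,
matching the velocity model. The 3D form is implemented exactly as
written, with d₀ to the first power; a `d0_squared` switch provides the
variant suggested by reaction-distance geometry (cross-section ∝ d₀²),
off by default — fidelity first, physics noted.

Strategy and dimensionality default to the ecologically matched pairs
(sessile ↔ 2D benthic prey, active ↔ 3D pelagic prey) but are decoupled in
configuration. Search-rate bands propagate the (v₀, β, E) bootstrap
replicates of predator and prey through the same formulas, paired by
replicate index (treating the two bootstrap streams as coupled; an
independent pairing is obtainable by permuting one stream's replicates).

The effective thermal sensitivity of a search-rate curve is recovered from
an Arrhenius plot: OLS of ln(a) on −(1/kT − 1/kT_ref), slope = E,
intercept = ln of the search rate at T_ref. The default fitting range is
the curve's rising portion intersected with the site OTR; for a sessile
pair this returns the predator's E exactly (log-linear identity), for an
active pair a blend of the two sensitivities.

## Mismatch over the OTR

The operational temperature range of a site is the min/max of its logger
records (optionally windowed). Velocity mismatch between a predator and a
prey population is summarised on a uniform 0.1 °C grid over the OTR by:
mean Δv (predator − prey), the fraction of grid points whose Δv shares the
sign of the median Δv (zeros count as consistent), and the fraction of the
grid where the two 95% bands do not overlap. These three numbers are this
package's operationalisation of qualitative "performance mismatch"; they
are deliberately simple and make no claim about encounter or consumption
rates.

## Synthetic campaign generator

The generator emulates the structure of a three-site mesocosm study:

* **Sites** — hourly logger series over an Aug–Apr larval window; window
  mean + annual sinusoid (default amplitude 6 °C) + daily sinusoid (3 °C)
  + Gaussian noise (SD 0.8 °C). The deterministic signal is centred on the
  window, so the configured mean (defaults 14.56, 16.95, 17.30 °C for the
  three sites) is the true window mean by construction.
* **Taxa** — one predator (dragonfly nymph) and two prey (benthic midge,
  pelagic mayfly). Ground-truth TPC tables per taxon × site are synthetic:
  they reproduce the study system's qualitative pattern (predator and
  mayfly B₀ rising cool→warm, midge B₀ falling; E in 0.6–1.0 eV; T_pk
  31–35 °C; β = 0.75) at realistic magnitudes (individual rates
  ~10⁻¹¹–10⁻¹⁰ mol O₂ s⁻¹, dry masses ~0.4–4 mg), and no value is an
  estimate from real data.
* **Assays** — acute temperatures 10–45 °C at 5 °C steps, 2 mL vials, one
  control per batch with a small negative drift (−0.005 µmol L⁻¹ s⁻¹),
  O₂ logged every second during three 30 s windows spread over a 3600 s
  sealed trial. The intermittent layout matters: invertebrate metabolism
  cannot measurably deplete a vial in 90 s, and the long baseline between
  windows is what gives the slope regression its precision. Reading noise
  is 0.5 µmol L⁻¹ per sample. A trial stops at the first reading below
  70% of the starting concentration, so downstream parsers must handle
  variable-length traces.
* **Rates** — each individual's true rate is the Sharpe–Schoolfield
  prediction at its mass and acute temperature times mean-one lognormal
  noise (default CV 0.2; rates are positive and their variance grows with
  the mean, which an additive model would violate). Lengths are drawn from
  a zero-truncated normal. Sample traces embed the control drift so the
  correction step is genuinely exercised.

What the generator does **not** emulate: temperature-dependent O₂
solubility, sensor autocorrelation, behavioural states (burst swimming,
burrowing), digestion effects, mortality at temperature extremes, or
between-mesocosm heterogeneity. Passing recovery tests therefore shows the
estimation chain is correct under the stated noise model, not that field
data of arbitrary quality will yield parameters this clean.

## Numerical choices and defaults

| quantity | default | notes |
|---|---|---|
| k | 8.617×10⁻⁵ eV K⁻¹ | Boltzmann constant; energies in eV |
| n_starts | 200 | field protocol 10,000; demo configs use 30–50 |
| start perturbation | 25% SD per parameter | Gaussian, clipped to bounds |
| n_boot | 200 | field protocol 10,000 |
| γ | 4.5×10⁵ J mol⁻¹ O₂ | oxycalorific equivalent |
| allocation | 1.0 | fraction of metabolic power to locomotion |
| d₀ | 0.01 m | minimum reaction distance |
| p_d | 0.21 (2D), 0.2 (3D) | dimensionality scaling exponents |
| representative mass | population mean dry mass | median available by override |
| curve band | 2.5/97.5 percentiles | pointwise |
| stopping rule | ≥70% of start, inclusive | screening and generation |

Degenerate inputs: fits require ≥5 measurements over ≥4 acute
temperatures; slopes require ≥2 distinct time points; non-positive rates
are excluded before fitting (log-scale start estimation requires
positivity); an all-failed multistart raises an error naming the
population rather than returning a fabricated fit.

Test and demo problem sizes are scaled down (2–13 individuals per
temperature, tens of starts, ≤200 bootstrap reps) as the package's own
defaults for fast, deterministic verification; the full-scale protocol
values remain one config key away.

## Known limitations

* The velocity model assumes steady swimming with all aerobic power
  applied to thrust; gait, burst-and-coast dynamics and muscular
  efficiency are out of scope.
* Search rates ignore handling time and saturation (no functional
  response) and any encounter-path geometry beyond the detection region.
* The Arrhenius summary of an active-capture curve is an effective E for
  a curve that is not exactly log-linear; its value depends mildly on the
  fitting range, which is why the range is reported alongside.
* Bootstrap percentile intervals undercover modestly at small sample
  sizes; coverage checks in the test suite run at n ≈ 100 individuals.
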