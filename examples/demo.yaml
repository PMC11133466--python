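# Small synthetic demo: three sites, three taxa, fast fit settings.
# Run:  thermoforage all --config examples/demo.yaml --outdir demo_out
seed: 42
outdir: demo_out
synthetic:
  n_per_temp: 4      # individuals per acute temperature per taxon per site
  noise_cv: 0.2      # lognormal CV of individual metabolic rates
n_starts: 50         # multistart NLLS runs (field protocol: 10000)
n_boot: 100          # bootstrap replicates (field protocol: 10000)
temp_grid:
  start: 10.0
  stop: 45.0
  step: 0.5
pairs:
  - consumer: S_striolatum
    resource: Chironomus
    strategy: sessile     # benthic midge larvae: prey velocity ~ 0
    dimensionality: 2
  - consumer: S_striolatum
    resource: C_dipterum
    strategy: active      # pelagic mayfly larvae: both velocities count
    dimensionality: 3
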