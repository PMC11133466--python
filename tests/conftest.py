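import numpy as np
import pytest
from hypothesis import settings

from thermoforage import compute_rates, fit_tpc_multistart
from thermoforage.synthdata import (
    SiteConfig,
    default_design,
    default_taxa,
    generate_respiration_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


TOLEDO = SiteConfig("Toledo", 14.56, daily_amplitude=0, seasonal_amplitude=0, noise_sd=0)


def make_dataset(taxon_id="Chironomus", noise_cv=0.0, n_per_temp=3, seed=0, **design_kw):
    """One-site, one-taxon synthetic campaign; returns (rates, truth, taxon)."""
    if noise_cv == 0.0:
        design_kw.setdefault("o2_noise_sd", 0.0)
    taxa = [t for t in default_taxa(noise_cv=noise_cv) if t.taxon_id == taxon_id]
    design = default_design(n_per_temp=n_per_temp, **design_kw)
    traces, individuals, _ = generate_respiration_dataset(
        [TOLEDO], taxa, design, seed=seed
    )
    rates, rejects = compute_rates(traces, individuals)
    assert len(rejects) == 0
    return rates, taxa[0].true_tpc["Toledo"], taxa[0]


@pytest.fixture(scope="session")
def noiseless_rates():
    return make_dataset(noise_cv=0.0, n_per_temp=3, seed=11)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_rates):
    rates, truth, _ = noiseless_rates
    fit = fit_tpc_multistart(rates, Tref=truth.Tref, n_starts=50, seed=2)
    return fit, truth, rates


@pytest.fixture(scope="session")
def stochastic_fit():
    rates, truth, _ = make_dataset(noise_cv=0.2, n_per_temp=6, seed=21)
    fit = fit_tpc_multistart(rates, Tref=truth.Tref, n_starts=30, seed=4)
    return fit, truth, rates
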