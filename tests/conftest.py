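import numpy as np
import pandas as pd
import pytest

from plumagevar import PaternityClassifier, SimulationParams, simulate_study
from plumagevar.simulate import (
    simulate_genotypes,
    simulate_matings,
    simulate_phenotypes,
    simulate_population,
)


def simulate_study_tables(params: SimulationParams):
    """Study without spectra (population, matings, genotypes, phenotypes);
    much faster than the full generator for statistical experiments."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    adults, social = simulate_population(params, rng)
    ped_truth = simulate_matings(
        adults, social, params.epp_rate, params.epp_overdispersion, rng
    )
    drop = pd.concat(
        [
            pd.DataFrame({"id": adults["id"], "dam": "", "sire": ""}),
            ped_truth.rename(columns={"individual": "id"})[["id", "dam", "sire"]],
        ],
        ignore_index=True,
    )
    genotypes = simulate_genotypes(drop, params.resolved_allele_freqs(), rng)
    phenotypes, latent = simulate_phenotypes(ped_truth, social, params, rng)
    return adults, social, ped_truth, genotypes, phenotypes, latent


@pytest.fixture(scope="session")
def study():
    """One default-scale synthetic study (~500 offspring) shared read-only."""
    return simulate_study(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def study_calls(study):
    clf = PaternityClassifier().fit(study.genotypes)
    return clf.predict(study.social)


@pytest.fixture(scope="session")
def small_study():
    """A small study (~60 offspring) for cheap end-to-end tests."""
    return simulate_study(
        SimulationParams(n_sites=4, n_mothers=14, n_fathers=12, seed=7)
    )
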