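import warnings

import pytest

from coregrn.fixtures import (
    FixtureConfig,
    generate_conversion_scenario,
    generate_fixture_bundle,
)
from coregrn.pipeline import ReconstructionParams, reconstruct_core_grn
from coregrn.specificity import ExpressionCompendium


def run_reconstruction(bundle, **param_overrides):
    """Reconstruct the core GRN of a fixture bundle's target cell type."""
    comp = ExpressionCompendium(values=bundle.compendium, phenotypes=bundle.phenotypes)
    params = ReconstructionParams(
        n_identity=bundle.config.n_identity, **param_overrides
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_core_grn(
            bundle.query_profile,
            comp,
            bundle.promoters,
            bundle.enhancer_map,
            bundle.target_peaks["H3K4me3"],
            bundle.target_peaks["H3K27ac"],
            bundle.target_peaks["DNase"],
            bundle.target_peaks["tf"],
            bundle.ppi,
            params,
        )


@pytest.fixture(scope="session")
def bundle():
    """One noiseless reconstruction fixture shared across tests."""
    return generate_fixture_bundle(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def reconstruction(bundle):
    return run_reconstruction(bundle)


@pytest.fixture(scope="session")
def scenario():
    """One noiseless conversion scenario with planted optimal set."""
    return generate_conversion_scenario(FixtureConfig(seed=3, n_tfs=8))
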