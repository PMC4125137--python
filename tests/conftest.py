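import warnings

import pytest

import fertsim


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic dataset generated from the default coefficients."""
    return fertsim.generate_dataset(
        fertsim.GeneratorConfig(n_herds=6, cows_per_herd=80, seed=2)
    )


@pytest.fixture(scope="session")
def small_records(small_synth, tmp_path_factory):
    d = tmp_path_factory.mktemp("synth")
    small_synth.lactations.to_csv(d / "lactations.csv", index=False)
    small_synth.lameness_events.to_csv(d / "lameness.csv", index=False)
    return fertsim.read_lactation_tables(
        d / "lactations.csv", d / "lameness.csv"
    )


@pytest.fixture(scope="session")
def small_table(small_records):
    return fertsim.build_risk_period_table(small_records)


@pytest.fixture(scope="session")
def fitted_small(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fertsim.fit_dtsm(small_table, seed=0)
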