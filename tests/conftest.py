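import numpy as np
import pandas as pd
import pytest

from aquameta.preprocess import MODE_MULTI, MODE_SINGLE, TableBuilder, clean_assays
from aquameta.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_phyla=2, n_classes_per_phylum=2, n_species=8,
                       n_chemicals=60, n_fp_bits=16, n_physchem=3,
                       n_assays=500, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def cleaned(small_dataset):
    assays, chemicals, taxonomy, truth = small_dataset
    return clean_assays(assays), chemicals, taxonomy, truth


@pytest.fixture(scope="session")
def linear_cfg():
    """Noiseless shared linear response surface (sanity-floor task)."""
    return SynthConfig(n_phyla=1, n_classes_per_phylum=1, n_species=3,
                       n_chemicals=120, n_fp_bits=8, n_physchem=1,
                       n_assays=600, sigma_phylum=0.0, sigma_class=0.0,
                       sigma_species=0.0, slope_sd=0.0, sigma_noise=0.0,
                       replicate_rate=0.0, bound_rate=0.0, missing_rate=0.0,
                       durations=(4.0,), seed=3)


@pytest.fixture(scope="session")
def linear_tables(linear_cfg):
    from aquameta.evaluation import split_by_chemicals

    assays, chemicals, taxonomy, _ = generate_dataset(linear_cfg)
    records = clean_assays(assays)
    plan = split_by_chemicals(records["chemical_id"].unique(), 0.2, seed=0)
    train = records[records["chemical_id"].isin(plan.train_chemicals)]
    test = records[records["chemical_id"].isin(plan.test_chemicals)]
    tables = {}
    for mode in (MODE_SINGLE, MODE_MULTI):
        builder = TableBuilder(mode=mode).fit(train, chemicals, taxonomy)
        tables[mode] = (builder.transform(train), builder.transform(test))
    return tables


def toy_records(rows):
    """Build a raw assay frame from (species, chemical, duration, value) dicts."""
    defaults = dict(subspecies_id=pd.NA, class_name="cls", phylum_name="phy",
                    duration_unit="d", endpoint_units="mg/L", bound="exact")
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def make_toy_records():
    return toy_records
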