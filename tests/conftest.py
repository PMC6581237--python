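
import pandas as pd
import pytest

from rhythmshift.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated study, shared read-only across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, low-noise study for fast pipeline tests."""
    cfg = SimulationConfig(
        n_subjects=5, n_behavioural=8, n_circadian=4, n_arrhythmic=20,
        residual_sd=0.2, amplitude_range=(0.5, 1.0),
        missing_rate=0.0, lod_quantile=0.0, seed=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_tables(tmp_path):
    """Minimal three-table TSV fixture: 2 metabolites x 3 samples (one
    subject/condition trio is deliberately tiny but valid)."""
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "subject_id": ["A", "A", "A"],
        "condition": ["baseline"] * 3,
        "clock_time_h": [23.0, 3.0, 7.0],
        "habitual_sleep_onset_h": [23.0] * 3,
        "lights_off_h": [23.0] * 3,
        "melatonin_phase_h": [21.0] * 3,
    })
    metabolites = pd.DataFrame({
        "metabolite_id": ["m1", "m2"],
        "metabolite_class": ["amino_acid", "sphingolipid"],
    })
    conc = pd.DataFrame({
        "metabolite_id": ["m1"] * 3 + ["m2"] * 3,
        "sample_id": ["s1", "s2", "s3"] * 2,
        "value": [4.0, 8.0, 16.0, 1.0, 2.0, 4.0],
        "below_lod": [False] * 6,
    })
    paths = {}
    for name, df in [("samples", samples), ("metabolites", metabolites),
                     ("concentrations", conc)]:
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths, samples, metabolites, conc
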