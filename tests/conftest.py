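import pandas as pd
import pytest

from ptsecretome.simulate import SimulationConfig, generate_truth, simulate_experiment


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: 40 proteins, 2 controls + 4 SIV-PS + 4 PT24-PS."""
    design = [("C1", "control", 1), ("C2", "control", 2)]
    design += [(f"SIV-PS{i}", "SIV-PS", i) for i in range(1, 5)]
    design += [(f"PT24-PS{i}", "PT24-PS", i) for i in range(1, 5)]
    defaults = dict(
        n_secreted_conventional=5,
        n_secreted_unconventional=5,
        n_pistil_background=20,
        n_cytosolic_contaminant=10,
        design=design,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free, dropout-free simulation plus its evidence table."""
    config = small_config(lognormal_sigma=0.0, detection_dropout_rate=0.0)
    truth = generate_truth(config)
    evidence = simulate_experiment(truth, config)
    return config, truth, evidence


@pytest.fixture(scope="session")
def noisy_run():
    config = small_config(lognormal_sigma=0.2, detection_dropout_rate=0.05, seed=23)
    truth = generate_truth(config)
    evidence = simulate_experiment(truth, config)
    return config, truth, evidence


def make_evidence(rows) -> pd.DataFrame:
    """Evidence table from (peptide, sample, area, accessions, q) tuples."""
    return pd.DataFrame(
        rows, columns=["peptide_sequence", "sample_id", "area", "accessions", "q_value"]
    )
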