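import numpy as np
import pytest

from duoproteome import (ProteinRecord, RunConfig, ScoringScheme,
                         SimulationConfig, run_pipeline, simulate)
from duoproteome.synthetic_data import AA_ALPHABET, AA_FREQS


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA_ALPHABET), size=length, p=AA_FREQS)
    return "".join(AA_ALPHABET[i] for i in idx)


def make_records(seqs, species="A", prefix="g"):
    return [ProteinRecord(f"{prefix}{i + 1:03d}", species, s)
            for i, s in enumerate(seqs)]


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


def small_sim_config() -> SimulationConfig:
    """Reduced study: same structure as the default conditions, scaled to
    keep unit tests fast."""
    return SimulationConfig(
        n_ancestral=80, mean_len=150, sd_len=50,
        n_specific_A=6, n_specific_B=6, n_hidden_A=5, n_hidden_B=5,
        seed=11)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_sim_config())


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline on the reduced study; returns (config, report)."""
    cfg = RunConfig(outdir=str(tmp_path_factory.mktemp("small_run")),
                    sim=small_sim_config())
    report = run_pipeline(cfg)
    return cfg, report
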