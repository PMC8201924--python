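import numpy as np
import pytest
from hypothesis import settings

from nuchmm.fixtures import FixtureSpec, iid_model, random_model, simulate
from nuchmm.training import TrainConfig, train

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_bundle():
    """One strongly divergent simulated chromosome shared across tests:
    generating model, 60-kb genome, truth dyad map."""
    spec = FixtureSpec(seed=11, genome_length=60_000, divergence=0.8)
    model = random_model(spec)
    genome, truth = simulate(model, spec)
    return {"spec": spec, "model": model, "genome": genome, "truth": truth,
            "seq": genome.records["chrS"],
            "ref_dyads": np.array([r.pos for r in truth.records])}


@pytest.fixture(scope="session")
def trained_model(sim_bundle):
    """Model re-estimated from the simulated chromosome (defaults:
    pseudocounts and smoothing on)."""
    return train(sim_bundle["genome"], sim_bundle["truth"], TrainConfig())


@pytest.fixture(scope="session")
def uniform_tm():
    return iid_model([0.25] * 4, [0.25] * 4)


@pytest.fixture(scope="session")
def decoded_track(sim_bundle):
    """Decoded prefix of the simulated chromosome under the generating
    model (shared to keep the suite fast)."""
    from nuchmm.dhmm import predict
    return predict(sim_bundle["seq"][:20_000], sim_bundle["model"])


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path
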