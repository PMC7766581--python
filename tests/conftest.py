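import numpy as np
import pytest

from semiflex.model import ModelParameters, straight_chain, total_energy


@pytest.fixture(scope="session")
def params10() -> ModelParameters:
    return ModelParameters(n_monomers=10, kappa=1.0)


def random_valid_chain(params: ModelParameters, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish random walk with every bond safely inside the
    FENE range; retried until the total energy is finite and moderate."""
    for _ in range(200):
        n = params.n_monomers
        pos = np.zeros((n, 3))
        for i in range(1, n):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            length = params.r0 + 0.6 * params.fene_R * (2 * rng.random() - 1)
            pos[i] = pos[i - 1] + step * length
        rep = total_energy(pos, params)
        if np.isfinite(rep.total) and rep.total < 1e4:
            return pos
    raise RuntimeError("could not generate a valid chain")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
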