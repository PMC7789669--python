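import numpy as np
import pandas as pd
import pytest

from anaerodesign import synthetic
from anaerodesign.domains import DomainHit, matrix_from_hits


@pytest.fixture(scope="session")
def toy_model():
    return synthetic.generate_toy_model()


@pytest.fixture(scope="session")
def toy_medium():
    return synthetic.toy_medium()


@pytest.fixture(scope="session")
def small_domain_dataset():
    """60+60 strains with planted structure, shared across tests."""
    cfg = synthetic.SyntheticGenomeConfig(
        n_aerobic=60, n_anaerobic=60, n_shared_core=20, n_aerobe_specific=5,
        n_anaerobe_specific=8, n_accessory=60, seed=11,
    )
    return cfg, synthetic.generate_domain_dataset(cfg)


@pytest.fixture
def six_strain_matrix():
    """Hand-built 6-strain matrix: D3 in all 4 anaerobes, no aerobes."""
    hits = []
    carriers = {
        "A1": ["D1"], "A2": ["D1", "D2"],
        "N1": ["D1", "D3"], "N2": ["D3"], "N3": ["D2", "D3"], "N4": ["D3"],
    }
    for strain, archs in carriers.items():
        for k, acc in enumerate(archs):
            hits.append(DomainHit(strain, f"{strain}_p{k}", acc, 1, 50))
    labels = pd.DataFrame(
        {
            "strain_id": ["A1", "A2", "N1", "N2", "N3", "N4"],
            "lifestyle": ["aerobic"] * 2 + ["anaerobic"] * 4,
        }
    )
    return matrix_from_hits(hits, labels), labels


def random_binary_matrix(rng: np.random.Generator, max_strains=6, max_archs=8):
    n = rng.integers(1, max_strains + 1)
    p = rng.integers(1, max_archs + 1)
    mat = rng.integers(0, 2, size=(n, p))
    return pd.DataFrame(
        mat,
        index=[f"S{i}" for i in range(n)],
        columns=[f"D{j}" for j in range(p)],
    )
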