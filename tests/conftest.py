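import numpy as np
import pytest

from phosphosat import (
    Observation,
    PhosphoSite,
    Proteome,
    SiteDataset,
    generate_phosphoproteome,
    generate_proteome,
)


@pytest.fixture(scope="session")
def toy_proteome() -> Proteome:
    return Proteome(
        {
            "p1": "MKSYAADEYST",
            "p2": "AAAAAYAAAAA",
            "p3": "DEYST",
            "p4": "KKYQQ",
        }
    )


@pytest.fixture
def toy_dataset() -> SiteDataset:
    """Multiplicities [1, 1, 2, 3] over four sites."""
    s = [
        PhosphoSite("p1", 3, "S"),
        PhosphoSite("p1", 4, "Y"),
        PhosphoSite("p1", 9, "Y"),
        PhosphoSite("p2", 6, "Y"),
    ]
    obs = [
        Observation(s[0], "r1"),
        Observation(s[1], "r1"),
        Observation(s[2], "r1"),
        Observation(s[2], "r2"),
        Observation(s[3], "r1"),
        Observation(s[3], "r2"),
        Observation(s[3], "r3"),
    ]
    return SiteDataset(obs)


@pytest.fixture(scope="session")
def synthetic_truth():
    """Medium synthetic phosphoproteome with homogeneous detection."""
    rng = np.random.default_rng(42)
    proteome = generate_proteome(60, 300, seed=rng)
    return generate_phosphoproteome(proteome, 0.18, 0.0, seed=rng)


def dataset_from_multiplicities(mults: list[int]) -> SiteDataset:
    sites = [PhosphoSite(f"g{i}", 1, "S") for i in range(len(mults))]
    return SiteDataset.from_multiplicities(zip(sites, mults))
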