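import numpy as np
import pytest

from epideconv import (
    DeconvolutionDataset,
    LandscapeSpec,
    Measurement,
    TraitLandscape,
    bm3_fixture,
    generate_dataset,
)

SITES3 = ("R47I", "T49I", "Y51I")


@pytest.fixture(scope="session")
def bm3():
    """The frozen eight-genotype, seven-trait reference dataset."""
    return bm3_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_dataset(values, sems=None, sites=SITES3, trait="f", n=2):
    """Dataset from a {label: mean} dict (SEM 0 unless given)."""
    ds = DeconvolutionDataset(sites=sites)
    sems = sems or {}
    for label, mean in values.items():
        genotype = ds.genotype_from_indices(
            {i for i, ch in enumerate(label) if ch != "-"}
        )
        ds.add(Measurement(genotype, trait, float(mean), float(sems.get(label, 0.0)), n))
    return ds


def random_dataset(rng, n_sites=3, sems=False, trait="f"):
    """Complete dataset with standard-normal-ish trait values."""
    sites = tuple(f"X{i}I" for i in range(n_sites))  # labels render as I--/III/...
    ds = DeconvolutionDataset(sites=sites)
    for genotype in ds.all_genotypes():
        mean = float(rng.normal(0.0, 10.0))
        sem = float(rng.uniform(0.1, 1.0)) if sems else 0.0
        ds.add(Measurement(genotype, trait, mean, sem, 2))
    return ds


def additive_spec(n_sites=3, interactions=None, noise_sd=0.0, n_replicates=2):
    sites = tuple(f"S{i}" for i in range(n_sites))
    return LandscapeSpec(
        sites=sites,
        traits={
            "f": TraitLandscape(
                parent_value=10.0,
                additive=tuple(float(2 + i) for i in range(n_sites)),
                interactions=interactions or {},
                noise_sd=noise_sd,
            )
        },
        n_replicates=n_replicates,
    )


@pytest.fixture()
def additive_zero_noise():
    return generate_dataset(additive_spec(), seed=0)
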