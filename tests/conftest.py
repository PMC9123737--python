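import numpy as np
import pandas as pd
import pytest

from apygblup.synthpop import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """A fast three-generation study (~140 genotyped, 300 SNPs)."""
    kwargs = dict(
        n_generations=3,
        n_sires_per_gen=4,
        n_dams_per_gen=20,
        progeny_per_litter=4,
        n_snps_per_chrom=150,
        n_chroms=2,
        chrom_length_morgans=0.5,
        genotyping_fraction_by_gen=(0.5, 0.8, 0.9),
        phenotyping_fraction=0.6,
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def medium_study():
    """~500 genotyped animals; used where the small study is too coarse."""
    return simulate_study(small_config(
        n_generations=4, n_sires_per_gen=6, n_dams_per_gen=40,
        progeny_per_litter=6, genotyping_fraction_by_gen=(0.3, 0.5, 0.7, 0.9),
        seed=7))


def random_pedigree(n: int, seed: int, p_founder: float = 0.2) -> pd.DataFrame:
    """Random valid pedigree in topological order, ids 1..n."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for i in range(1, n + 1):
        sex = "M" if rng.random() < 0.5 else "F"
        if i <= 4 or rng.random() < p_founder or not males or not females:
            sire = dam = 0
        else:
            sire = int(rng.choice(males))
            dam = int(rng.choice(females))
        rows.append((i, sire, dam, sex, 0, i, 1, True, True))
        (males if sex == "M" else females).append(i)
    return pd.DataFrame(rows, columns=[
        "animal", "sire", "dam", "sex", "cohort", "litter", "pen",
        "genotyped", "phenotyped"])


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and one offspring."""
    return pd.DataFrame({
        "animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
        "sex": ["M", "F", "M"], "cohort": [0, 0, 1], "litter": [1, 2, 3],
        "pen": [1, 1, 1], "genotyped": [True, True, True],
        "phenotyped": [True, True, True]})
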