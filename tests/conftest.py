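import numpy as np
import pytest

from ssgblup.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~530-animal bivariate CW/YW dataset with a genotyped last generation."""
    cfg = SimulationConfig(n_founders=80, n_generations=4, n_sires_per_gen=15,
                           n_offspring_per_gen=150, n_snps=400,
                           traits=["cw", "yw"], seed=3,
                           genetic_architecture="genomic")
    ped, meta, panel, table = simulate_dataset(cfg)
    return cfg, ped, meta, panel, table


@pytest.fixture(scope="session")
def small_chain(small_dataset):
    """A short stage-1 Gibbs fit on the small dataset (shared: ~15 s)."""
    from ssgblup.varcomp import GibbsSettings, gibbs_sample

    cfg, ped, meta, panel, table = small_dataset
    return gibbs_sample(table, ped,
                        settings=GibbsSettings(4000, 1000, 5, seed=11),
                        traits=["cw", "yw"])


@pytest.fixture(scope="session")
def random_pedigree():
    """A 100-animal random-mating pedigree with some inbreeding."""
    rng = np.random.default_rng(42)
    records = [(f"A{i}", None, None) for i in range(10)]
    ids = [f"A{i}" for i in range(10)]
    for i in range(10, 100):
        s, d = rng.choice(len(ids), size=2, replace=False)
        records.append((f"A{i}", ids[s], ids[d]))
        ids.append(f"A{i}")
    from ssgblup.pedigree import Pedigree

    return Pedigree.from_records(records)
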