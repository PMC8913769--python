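import numpy as np
import pytest

import imperham as ip


@pytest.fixture(scope="session")
def conformer_dataset():
    """Default conformers preset: 100 groups x 5 conformers, sigma=0.5."""
    spec = ip.SyntheticSpec(preset="conformers", n_groups=100, noise_sigma=0.5, seed=11)
    return ip.gen_conformer_dataset(spec)


@pytest.fixture(scope="session")
def delta_data(conformer_dataset):
    """Delta-corrected features/target plus the group map for splitting."""
    ds = conformer_dataset
    fm, ref_map, target = ip.delta_correct(
        ds.features, ds.groups, "vacuum|1", target=ds.target
    )
    groups = dict(zip(fm.sample_ids, fm.group_ids))
    return fm, target, groups, ref_map


@pytest.fixture(scope="session")
def small_molecules():
    return ip.gen_molecules(5, atoms_range=(3, 6), charge_set=(0, 1), seed=42)
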