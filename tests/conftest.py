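import numpy as np
import pytest

from mavenpy import (
    BrainStack,
    PhenotypeTable,
    RegionAtlas,
    RegionSignalMatrix,
)


@pytest.fixture
def small_atlas() -> RegionAtlas:
    """4x6x6 atlas with three disjoint cuboid regions and one super-region
    that fully contains region 'a'."""
    shape = (4, 6, 6)
    masks = []
    a = np.zeros(shape, dtype=bool)
    a[1:3, 0:2, 0:2] = True
    b = np.zeros(shape, dtype=bool)
    b[1:3, 0:2, 3:5] = True
    c = np.zeros(shape, dtype=bool)
    c[1:3, 3:5, 0:2] = True
    sup = np.zeros(shape, dtype=bool)
    sup[0:4, 0:3, 0:3] = True  # contains all of a
    masks.append(("a", "Region A", a))
    masks.append(("b", "Region B", b))
    masks.append(("c", "Region C", c))
    masks.append(("sup", "Super region containing A", sup))
    return RegionAtlas.from_masks(shape, masks)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix() -> RegionSignalMatrix:
    rng = np.random.default_rng(7)
    values = rng.uniform(0.1, 1.0, size=(20, 6))
    return RegionSignalMatrix.from_arrays(
        [f"s{i:02d}" for i in range(20)],
        [f"r{j}" for j in range(6)],
        values,
    )


@pytest.fixture
def toy_phenotype(toy_matrix) -> PhenotypeTable:
    rng = np.random.default_rng(8)
    phen = np.array([0, 1] * 10)
    geno = rng.choice(["wt", "het", "hom"], size=20)
    return PhenotypeTable.from_arrays(toy_matrix.subjects, phen, geno)


def make_stack(subject_id: str, shape, rng=None, constant=None) -> BrainStack:
    if constant is not None:
        vox = np.full(shape, float(constant))
    else:
        vox = rng.uniform(0, 100, size=shape)
    return BrainStack(subject_id=subject_id, voxels=vox)
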