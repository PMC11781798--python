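import numpy as np
import pytest
from hypothesis import settings

from synloc import RegionLabelMap, Volume

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def worked_volume() -> Volume:
    """The four-voxel hand example: membrane [1,2,1,0], rgfp [2,8,1,5].

    Ratios on the uncensored voxels are [2, 4, 1], mean 7/3, so
    LI = [6/7, 12/7, 3/7] and voxel 4 is censored.
    """
    membrane = np.array([[[1.0, 2.0, 1.0, 0.0]]])
    rgfp = np.array([[[2.0, 8.0, 1.0, 5.0]]])
    return Volume(channels={"rgfp": rgfp, "membrane": membrane})


@pytest.fixture
def worked_labels() -> RegionLabelMap:
    labels = np.array([[[1, 1, 2, 2]]], dtype=np.int32)
    return RegionLabelMap(labels=labels, names={1: "region1", 2: "region2"})


def random_positive_volume(rng: np.random.Generator, shape=(5, 5, 5)) -> Volume:
    """Random strictly-positive two-channel volume (nothing censored)."""
    membrane = rng.uniform(0.5, 10.0, size=shape)
    rgfp = rng.uniform(0.0, 10.0, size=shape)
    return Volume(channels={"rgfp": rgfp, "membrane": membrane})


def li_per_voxel_loop(volume: Volume, threshold: float = 0.0):
    """Independent scalar-loop oracle for the LI map.

    Deliberately naive: iterates voxels one by one with plain Python
    floats, computes ratios, their mean, and the normalized index.
    """
    mem = volume.channels["membrane"]
    rgfp = volume.channels["rgfp"]
    nz, ny, nx = mem.shape
    ratios = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if mem[z, y, x] > threshold:
                    ratios[(z, y, x)] = float(rgfp[z, y, x]) / float(mem[z, y, x])
    mean = sum(ratios.values()) / len(ratios)
    li = np.full(mem.shape, np.nan)
    for key, r in ratios.items():
        li[key] = r / mean
    return li, mean
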