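import logging

import numpy as np
import pytest
from hypothesis import settings

from somamorph import (
    SimConfig,
    derive_ganglion_mask,
    ganglion_surface,
    generate_ganglion_pair,
    measure_all,
    records_to_frame,
    sample_cell_population,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("somamorph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom_reduced():
    """One coarse-grid default phantom (seed 0): volume + ground truth."""
    return generate_ganglion_pair(SimConfig.reduced(), seed=0)


@pytest.fixture(scope="session")
def measured_reduced(phantom_reduced):
    """Full measurement pass on the seed-0 phantom.

    Returns (volume, truth, mask, surface, records, merged frame), where
    the merged frame joins measured records with planted ground truth on
    cell_id (ground-truth columns suffixed _gt).
    """
    volume, truth = phantom_reduced
    mask = derive_ganglion_mask(volume)
    surface = ganglion_surface(mask, volume.spacing_um)
    records = measure_all(volume, surface)
    df = records_to_frame(records)
    merged = df.merge(truth.to_frame(), on="cell_id", suffixes=("", "_gt"))
    return volume, truth, mask, surface, records, merged


@pytest.fixture(scope="session")
def sampled_populations():
    """100 sampled (not rasterized) default cell populations, seeds 0-99."""
    import dataclasses

    base = SimConfig()
    pops = []
    for seed in range(100):
        cells = sample_cell_population(dataclasses.replace(base, seed=seed))
        pops.append(cells)
    return pops


def sphere_volume(shape=(32, 32, 32), spacing=1.0, radius=10.0, center=None):
    """Rasterize one sphere the same way the generator does (voxel centers)."""
    from somamorph import LabelVolume

    shape = tuple(shape)
    if center is None:
        center = tuple(s * spacing / 2 for s in shape)
    idx = np.indices(shape, dtype=float)
    labels = np.zeros(shape, np.int32)
    d2 = sum((idx[a] * spacing + 0.5 * spacing - center[a]) ** 2 for a in range(3))
    labels[d2 <= radius**2] = 1
    return LabelVolume(labels=labels, spacing_um=(spacing,) * 3)
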