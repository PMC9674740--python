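"""Shared fixtures and the independent connectivity oracle."""

from __future__ import annotations

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from ctfish.synthetic import ChannelSpec, NucleusSpec


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force BFS connected components, independent of the package path.

    Returns a list of voxel-coordinate sets, sorted by size descending.
    """
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
            and (connectivity == 26 or abs(dz) + abs(dy) + abs(dx) <= 2)
        ]
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    remaining = set(map(tuple, np.argwhere(mask)))
    components = []
    while remaining:
        start = remaining.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if n in remaining:
                    remaining.discard(n)
                    comp.add(n)
                    queue.append(n)
        components.append(comp)
    return sorted(components, key=len, reverse=True)


def make_spec(chromosomes=("1", "2"), pairing=None, seed=0, **overrides) -> NucleusSpec:
    """Small, fast nucleus spec used across the suite (noise/blur off)."""
    channels = [ChannelSpec(round_id=1, fluorochrome_id=f, chromosome_id=c)
                for f, c in zip(("deac", "fitc", "texasred"), chromosomes)]
    defaults = dict(
        channels=channels,
        pairing_probability={c: 0.5 for c in chromosomes if c != "Y"},
        seed=seed,
        semiaxes_um=(1.2, 1.8, 1.8),
        voxel_spacing_um=(0.17, 0.12, 0.12),
        territory_voxels=80,
        association_probability=0.0,
        noise_sd=0.0,
        blur_sigma_um=0.0,
    )
    defaults.update(overrides)
    return NucleusSpec(**defaults)


@pytest.fixture
def clean_spec():
    return make_spec()


@pytest.fixture
def noisy_spec():
    return make_spec(noise_sd=8.0, blur_sigma_um=0.075, seed=7)


@pytest.fixture
def study_spec():
    """Two-chromosome nucleus at population-run scale with default noise/blur."""
    return make_spec(seed=7, semiaxes_um=(1.9, 2.6, 2.6), territory_voxels=240,
                     noise_sd=8.0, blur_sigma_um=0.075)
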