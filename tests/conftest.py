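"""Shared fixtures: the printed toy world, expression data on it, helpers."""

import numpy as np
import pytest

from miningabs.io_formats import ExpressionDataset, Identifier
from miningabs.synthetic import table2_world


@pytest.fixture(scope="session")
def toy_world():
    """The 3-platform, 7-probe toy world with its fixed similarity matrix."""
    platforms, M = table2_world()
    return {p.platform_id: p for p in platforms}, M


@pytest.fixture(scope="session")
def toy_platforms(toy_world):
    return toy_world[0]


@pytest.fixture(scope="session")
def toy_matrix(toy_world):
    return toy_world[1]


def make_dataset(platform, seed=0, n_samples=20, dataset_id=None):
    """Random balanced dataset on a platform (labels independent of data)."""
    rng = np.random.default_rng(seed)
    n = len(platform)
    labels = np.array([1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2))
    return ExpressionDataset(
        dataset_id=dataset_id or f"DS-{platform.platform_id}",
        platform_id=platform.platform_id,
        sample_ids=tuple(f"S{i + 1}" for i in range(n_samples)),
        labels=labels,
        intensities=rng.standard_normal((n, n_samples)),
        probe_ids=tuple(p.probe_id for p in platform.probes),
    )


@pytest.fixture()
def toy_datasets(toy_platforms):
    """One random dataset per toy platform, in PF1/PF2/PF3 order."""
    return [
        make_dataset(toy_platforms[pf], seed=i)
        for i, pf in enumerate(["PF1", "PF2", "PF3"])
    ]


@pytest.fixture(scope="session")
def worked_example_panel():
    """The printed two-identifier candidate panel."""
    return (Identifier("PF1", "P1", "G1"), Identifier("PF3", "P2", "G3"))
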