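"""Shared fixtures: small hand-built topologies and planted synthetic data."""

import numpy as np
import pytest

from mdworkbench.trajectory import Topology, Trajectory


def make_topology(
    n_protein: int = 0,
    n_water: int = 0,
    n_ions: int = 0,
    names=None,
    elements=None,
    resnames=None,
    resids=None,
    segids=None,
    moltype=None,
    bonds=None,
) -> Topology:
    """Build a topology either from per-class counts or explicit arrays."""
    if names is None:
        names, elements, resnames, resids, segids, moltype = [], [], [], [], [], []
        for i in range(n_protein):
            names.append("CA")
            elements.append("C")
            resnames.append("ALA")
            resids.append(i + 1)
            segids.append("PROT")
            moltype.append("protein")
        for i in range(n_water):
            names.append("OH2")
            elements.append("O")
            resnames.append("TIP3")
            resids.append(1000 + i)
            segids.append("WAT")
            moltype.append("solvent")
        for i in range(n_ions):
            names.append("SOD")
            elements.append("Na")
            resnames.append("SOD")
            resids.append(2000 + i)
            segids.append("ION")
            moltype.append("ion")
    return Topology(
        names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        segids=np.asarray(segids, dtype=object),
        moltype=np.asarray(moltype, dtype=object),
        bonds=None if bonds is None else np.asarray(bonds, dtype=np.intp),
    )


def make_trajectory(coords, top=None, labels=None, **top_kwargs) -> Trajectory:
    coords = np.asarray(coords, dtype=np.float64)
    if top is None:
        top = make_topology(n_protein=coords.shape[1], **top_kwargs)
    return Trajectory(topology=top, coords=coords, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def protein_trajectory(rng):
    """10 protein atoms, 20 frames of mild Gaussian jitter around a fold."""
    base = rng.normal(scale=3.0, size=(10, 3))
    coords = base[None] + 0.1 * rng.standard_normal((20, 10, 3))
    return make_trajectory(coords)
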