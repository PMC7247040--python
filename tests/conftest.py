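"""Shared fixtures: small meshes and cohorts generated at test time."""

import numpy as np
import pytest

import conparc as cp


@pytest.fixture(scope="session")
def mesh1():
    """Order-1 two-sphere mesh (42 vertices per hemisphere)."""
    return cp.icosphere(1)


@pytest.fixture(scope="session")
def mesh2():
    """Order-2 two-sphere mesh (162 vertices per hemisphere)."""
    return cp.icosphere(2)


@pytest.fixture(scope="session")
def small_spec():
    return cp.CohortSpec(mesh_order=2, n_subjects=6, seed=1234)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Six-subject cohort on the order-2 mesh with default noise levels."""
    return cp.simulate_cohort(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def set_partitions(elements):
    """Enumerate all set partitions of a sequence (Bell-number many).

    Independent brute-force oracle used to cross-check consensus operations.
    """
    elements = list(elements)
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_from_blocks(blocks, n):
    """Convert a list of blocks into a label-vector Partition."""
    labels = np.empty(n, dtype=int)
    for lab, block in enumerate(blocks):
        labels[block] = lab
    return cp.Partition(labels)
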