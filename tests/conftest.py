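"""Shared fixtures: phantoms are generated once per session at a moderate
mesh density so unit tests stay fast; acceptance tests build their own
phantoms at the densities they prescribe."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import legalign as la

UNIT_DENSITY = 2.0  # mm, unit-test phantoms


@pytest.fixture(scope="session")
def config():
    return la.RunConfig()


@pytest.fixture(scope="session")
def neutral_spec():
    return dataclasses.replace(la.PhantomSpec(), mesh_density_mm=UNIT_DENSITY)


@pytest.fixture(scope="session")
def neutral_case(neutral_spec):
    femur, tibfib, truth = la.generate_phantom(neutral_spec)
    return neutral_spec, femur, tibfib, truth


@pytest.fixture(scope="session")
def varus_spec():
    spec, _ = la.phantom_suite("VARUS5")[0]
    return dataclasses.replace(spec, mesh_density_mm=UNIT_DENSITY)


@pytest.fixture(scope="session")
def varus_case(varus_spec):
    femur, tibfib, truth = la.generate_phantom(varus_spec)
    return varus_spec, femur, tibfib, truth


@pytest.fixture(scope="session")
def neutral_assembly(neutral_case, config):
    _, femur, tibfib, _ = neutral_case
    return la.build_assembly(femur, tibfib, config)


def random_rigid(seed: int):
    """A deterministic random rotation + translation."""
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=3), rng.normal(size=3)
    z = a / np.linalg.norm(a)
    x = b - (b @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    rotation = np.column_stack([x, y, z])
    return rotation, rng.uniform(-80.0, 80.0, 3)
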