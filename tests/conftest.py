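"""Shared fixtures.

Long simulations (wild type, mutants, ablation) are session-scoped and
shared between the property and acceptance tests so each is run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import notchfence as nf
from notchfence.experiments import (
    ExperimentConfig,
    make_state,
    run_ablation_experiment,
    run_mutant,
    run_wild_type,
)
from notchfence.mesh import InitialConditionSpec


@pytest.fixture()
def hex_mesh():
    """6x6 honeycomb patch with the two-row organizer stripe."""
    return nf.build_hex_patch(InitialConditionSpec(nrows=6, ncols=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def square_cell_mesh():
    """A single unit-square cell (ccw)."""
    m = nf.TissueMesh()
    v = [m.add_vertex(p) for p in [(0, 0), (1, 0), (1, 1), (0, 1)]]
    m.add_cell(v)
    return m


def rectangle_cell_mesh(w=2.0, h=1.0):
    m = nf.TissueMesh()
    v = [m.add_vertex(p) for p in [(0, 0), (w, 0), (w, h), (0, h)]]
    m.add_cell(v)
    return m


@pytest.fixture()
def square_mesh():
    return square_cell_mesh()


def random_tissue(seed: int, nrows: int = 4, ncols: int = 4, jiggle: float = 0.04):
    """Small honeycomb with jiggled vertices: a generic valid test tissue."""
    mesh, idents = nf.build_hex_patch(InitialConditionSpec(nrows=nrows, ncols=ncols))
    r = np.random.default_rng(seed)
    mesh.positions[:] += r.normal(0.0, jiggle, mesh.positions.shape)
    nf.validate(mesh)
    return mesh, idents


# -- session-scoped simulations ---------------------------------------------

WT_CONFIG = ExperimentConfig(seed=11)  # 14x14 patch, three mean bulk cycles

MUTANT_IC = InitialConditionSpec(nrows=12, ncols=12)


@pytest.fixture(scope="session")
def wild_type_run():
    """Full wild-type growth run (~200 cells, three mean bulk cycles)."""
    return run_wild_type(WT_CONFIG)


@pytest.fixture(scope="session")
def mutant_runs():
    """All five lack-of-function mutants on a 12x12 patch, each at its
    panel evaluation window."""
    out = {}
    for variant in nf.experiments.MUTANT_VARIANTS:
        cfg = nf.experiments.mutant_panel_config(variant, MUTANT_IC, seed=23)
        out[variant] = run_mutant(cfg)
    return out


@pytest.fixture(scope="session")
def ablation_results():
    """20-replicate ablations of bulk and DV-boundary edges."""
    cfg = ExperimentConfig(
        initial_condition=InitialConditionSpec(nrows=10, ncols=10), seed=5
    )
    return run_ablation_experiment(cfg, n_replicates=20)
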