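"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.optimize import linprog

from fruitsignals.io import load_table1
from fruitsignals.spline import build_basis
from fruitsignals.synth import _birth_death_tree


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture(scope="session")
def default_basis():
    return build_basis()


@pytest.fixture(scope="session")
def yule_tree_50():
    return _birth_death_tree(50, [f"s{i:02d}" for i in range(50)], seed=42)


def ellipsoid_area_numeric(a: float, b: float, c: float, n: int = 400) -> float:
    """Numeric surface integral of an ellipsoid with semi-axes a, b, c.

    Parametrizes the surface over spherical angles and integrates the
    surface element |r_theta x r_phi| with Simpson's rule; accuracy far
    below the 1.06% of the closed-form approximation under test.
    """
    theta = np.linspace(0.0, np.pi, n)
    phi = np.linspace(0.0, 2.0 * np.pi, n)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(T), np.cos(T)
    sp, cp = np.sin(P), np.cos(P)
    element = st * np.sqrt(
        (b * c * st * cp) ** 2 + (a * c * st * sp) ** 2 + (a * b * ct) ** 2
    )
    return float(simpson(simpson(element, x=phi, axis=1), x=theta))


def lp_parsimony_steps(tree: dendropy.Tree, trait: dict[str, float]) -> float:
    """Exact linear-parsimony steps as an L1-minimization linear program.

    Independent of the interval-propagation implementation: internal node
    values are free variables, each edge contributes an absolute
    difference linearized with one auxiliary variable.
    """
    nodes = list(tree.preorder_node_iter())
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(idx[n.parent_node], idx[n]) for n in nodes if n.parent_node is not None]
    nv, ne = len(nodes), len(edges)
    cost = np.concatenate([np.zeros(nv), np.ones(ne)])
    A, b = [], []
    for k, (u, v) in enumerate(edges):
        for sign in (1.0, -1.0):
            row = np.zeros(nv + ne)
            row[u], row[v], row[nv + k] = sign, -sign, -1.0
            A.append(row)
            b.append(0.0)
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * nv + [
        (0.0, None)
    ] * ne
    for node in nodes:
        if node.is_leaf():
            x = float(trait[node.taxon.label])
            bounds[idx[node]] = (x, x)
    res = linprog(cost, A_ub=np.asarray(A), b_ub=np.asarray(b), bounds=bounds,
                  method="highs")
    assert res.status == 0, res.message
    return float(res.fun)


def random_yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    return _birth_death_tree(n_tips, [f"t{i}" for i in range(n_tips)], seed=seed)
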