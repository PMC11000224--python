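"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the code paths they check: finite
differences are applied to public maps (energies, fragment-geometry
construction), the ONIOM expansion oracle is a flat signed sum over all
nodes rather than the engine's recursion, and projections are done with
dense matrices built from scratch.
"""

from __future__ import annotations

import numpy as np
import pytest

from mconiom import (
    AtomicSystem,
    build_fragment_geometry,
    build_tree,
    composite,
    make_fixture,
)


@pytest.fixture(scope="session")
def tri_bridge():
    return make_fixture("tri_bridge_peptide", seed=11)


@pytest.fixture(scope="session")
def bridge_dimer():
    return make_fixture("bridge_dimer", seed=7)


@pytest.fixture(scope="session")
def chain5():
    return make_fixture("chain", seed=3)


@pytest.fixture(scope="session")
def diatomic():
    return make_fixture("diatomic", seed=0)


# ---------------------------------------------------------------------------
# oracles


def fd_gradient(fun, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite differences of a scalar function of flat coordinates."""
    g = np.empty_like(x0)
    for i in range(x0.size):
        xp = x0.copy(); xp[i] += step
        xm = x0.copy(); xm[i] -= step
        g[i] = (fun(xp) - fun(xm)) / (2 * step)
    return g


def fd_jacobian(fun_vec, x0: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of a vector-valued map."""
    cols = []
    for i in range(x0.size):
        xp = x0.copy(); xp[i] += step
        xm = x0.copy(); xm[i] -= step
        cols.append((fun_vec(xp) - fun_vec(xm)) / (2 * step))
    return np.array(cols).T


def fd_hessian_of_gradient(grad_fun, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    H = np.empty((x0.size, x0.size))
    for i in range(x0.size):
        xp = x0.copy(); xp[i] += step
        xm = x0.copy(); xm[i] -= step
        H[i] = (grad_fun(xp) - grad_fun(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def fd_hessian_of_energy(fun, x0: np.ndarray, step: float = 5e-3) -> np.ndarray:
    """Second-order central differences of a scalar function (no gradients)."""
    n = x0.size
    H = np.empty((n, n))
    e0 = fun(x0)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x0.copy(); xp[i] += step
                xm = x0.copy(); xm[i] -= step
                H[i, i] = (fun(xp) - 2 * e0 + fun(xm)) / step**2
            else:
                xpp = x0.copy(); xpp[[i, j]] += step
                xmm = x0.copy(); xmm[[i, j]] -= step
                xpm = x0.copy(); xpm[i] += step; xpm[j] -= step
                xmp = x0.copy(); xmp[i] -= step; xmp[j] += step
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * step**2)
    return H


def expanded_oniom(tree, calculators, wanted=("energy",)):
    """Brute-force non-recursive ONIOM expansion.

    Explicit signed sum over every node: + HIGH(model) for all nodes,
    - LOW(model) for every non-root node, each projected with a dense
    Jacobian assembled independently from the node's atom list and link
    specs.  Returns (energy, gradient-or-None, hessian-or-None).
    """
    wanted = frozenset(wanted) | {"energy"}
    n3 = 3 * tree.system.n_atoms
    e, g, H = 0.0, np.zeros(n3), np.zeros((n3, n3))
    for node in tree.nodes.values():
        model = build_fragment_geometry(node, tree.system)
        idx = sorted(node.atom_indices)
        J = np.zeros((3 * model.n_atoms, n3))
        for mi, ri in enumerate(idx):
            J[3 * mi:3 * mi + 3, 3 * ri:3 * ri + 3] = np.eye(3)
        for off, link in enumerate(node.link_atoms):
            mi = len(idx) + off
            J[3 * mi:3 * mi + 3, 3 * link.host:3 * link.host + 3] = (1 - link.k) * np.eye(3)
            J[3 * mi:3 * mi + 3, 3 * link.partner:3 * link.partner + 3] = link.k * np.eye(3)
        terms = [(calculators[node.high_level], +1.0)]
        if node.parent is not None:
            terms.append((calculators[node.low_level], -1.0))
        for calc, sign in terms:
            res = calc.evaluate(model, node.charge, node.uhf, wanted)
            e += sign * res.energy
            if "gradient" in wanted:
                g += sign * (J.T @ res.gradient)
            if "hessian" in wanted:
                H += sign * (J.T @ res.hessian @ J)
    return (e,
            g if "gradient" in wanted else None,
            0.5 * (H + H.T) if "hessian" in wanted else None)


def random_partition(system: AtomicSystem, rng: np.random.Generator) -> dict:
    """Random valid 2-3 layer, 1-3 center partition spec over a chain system.

    Layer-2 nodes are disjoint contiguous index windows; with probability
    ~1/2 one of them receives a nested layer-3 child.
    """
    n = system.n_atoms
    n_centers = int(rng.integers(1, min(4, (n - 1) // 2 + 1)))
    cuts = sorted(rng.choice(np.arange(1, n), size=2 * n_centers, replace=False).tolist())
    nodes = [{"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"}]
    windows = []
    for c in range(n_centers):
        lo, hi = cuts[2 * c] + 1, cuts[2 * c + 1]  # 1-based inclusive
        if hi < lo:
            continue
        windows.append((lo, hi))
        nodes.append({"id": f"mid{c}", "layer": 2, "atoms": f"{lo}-{hi}",
                      "calculator": "sqm"})
    if windows and rng.random() < 0.5:
        lo, hi = windows[int(rng.integers(len(windows)))]
        if hi > lo:
            nodes.append({"id": "inner", "layer": 3, "atoms": f"{lo}-{lo}",
                          "calculator": "dft"})
    return {"node": nodes}


def tree_from_random_partition(fixture, rng):
    return build_tree(fixture.system, random_partition(fixture.system, rng),
                      known_calculators=set(fixture.calculators))


def composite_vs_plain(fixture, tree, wanted):
    """Composite with ONE calculator on every level vs the plain calculation."""
    ff = fixture.calculators["ff"]
    same = {name: ff for name in fixture.calculators}
    comp = composite(tree, same, wanted)
    plain = ff.evaluate(fixture.system, wanted=frozenset(wanted) | {"energy"})
    return comp, plain
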