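"""Recursive multicenter ONIOM assembly of composite properties.

The composite property of a node i is

    F_i = HIGH_i(model_i) + sum_children_j [ F_j - LOW_j(model_j) ],

where model_i is the hydrogen-capped fragment geometry of node i,
HIGH_i is the node's own level of theory, and LOW_j is the child's low
level — by construction the parent's high level, so every child
contribution is a correction term relative to a calculation the parent
already covers.  The recursion terminates at leaf nodes, where
F_leaf = HIGH(model_leaf).  Fragment gradients and Hessians are pulled
into the real-system basis through each node's Jacobian (g -> J^T g,
H -> J^T H J) before accumulation, so the composite derivatives live on
the real system's 3n coordinates.

With the SAME calculator bound to every level the expression telescopes
exactly to the plain real-system calculation — the defining sanity
property of subtractive schemes, exercised heavily in the test suite.

Only mechanical embedding is implemented: layers couple through geometry
and the subtractive energy expression, never through electrostatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .calculators import CalcResult, Calculator, CalculatorError
from .geometry import AtomicSystem
from .partition import OniomNode, OniomTree, build_fragment_geometry, build_jacobian
from .units import HARTREE_TO_KCALMOL

__all__ = ["CompositeResult", "composite", "optimize", "OptimizeResult"]


@dataclass
class CompositeResult:
    """Composite energy (Hartree) with optional 3n gradient / 3n x 3n Hessian
    in the real-system basis, plus a per-node energy breakdown.

    ``per_node`` maps node_id -> {"high": E_high(model), "low_correction":
    -E_low(model) (0 for the root)}; the breakdown sums to ``energy``.
    """

    energy: float
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None
    per_node: dict[str, dict[str, float]] = field(default_factory=dict)
    n_evaluations: int = 0

    def breakdown_sum(self) -> float:
        return float(sum(v["high"] + v["low_correction"] for v in self.per_node.values()))

    def to_dict(self) -> dict:
        out = {
            "energy_hartree": self.energy,
            "energy_kcalmol": self.energy * HARTREE_TO_KCALMOL,
            "per_node": self.per_node,
            "n_evaluations": self.n_evaluations,
        }
        if self.gradient is not None:
            out["gradient_norm_hartree_per_A"] = float(np.linalg.norm(self.gradient))
            out["gradient_max_hartree_per_A"] = float(np.abs(self.gradient).max())
        return out


class _EvalCache:
    """Within-one-composite-call memo of (level, geometry) evaluations.

    Parent-high and child-low calculations share (calculator, geometry)
    pairs; caching avoids recomputing them.  Keyed by the raw coordinate
    bytes, so it never survives a geometry change.
    """

    def __init__(self, calculators: dict[str, Calculator]):
        self.calculators = calculators
        self.store: dict[tuple, CalcResult] = {}
        self.n_evaluations = 0

    def evaluate(self, level: str, model: AtomicSystem, node: OniomNode,
                 wanted: frozenset[str]) -> CalcResult:
        try:
            calc = self.calculators[level]
        except KeyError:
            raise CalculatorError(
                f"node {node.node_id}: no calculator bound for level {level!r} "
                f"(bound: {sorted(self.calculators)})"
            ) from None
        key = (level, node.charge, node.uhf, tuple(model.elements),
               model.coords.tobytes(), wanted)
        if key not in self.store:
            try:
                self.store[key] = calc.evaluate(model, node.charge, node.uhf, wanted)
            except CalculatorError:
                raise
            except Exception as exc:
                raise CalculatorError(
                    f"calculator {level!r} failed on node {node.node_id}: {exc}"
                ) from exc
            self.n_evaluations += 1
        return self.store[key]


def _accumulate(target: CompositeResult, res: CalcResult, jac, sign: float,
                wanted: frozenset[str]) -> None:
    target.energy += sign * res.energy
    if "gradient" in wanted:
        if res.gradient is None:
            raise CalculatorError("calculator returned no gradient although requested")
        target.gradient += sign * jac.project_gradient(res.gradient)
    if "hessian" in wanted:
        if res.hessian is None:
            raise CalculatorError("calculator returned no Hessian although requested")
        target.hessian += sign * jac.project_hessian(res.hessian)


def _node_property(tree: OniomTree, node: OniomNode, real: AtomicSystem,
                   cache: _EvalCache, wanted: frozenset[str],
                   out: CompositeResult) -> None:
    """Recursive ONIOM assembly: F_i = HIGH_i(model_i) + sum_j (F_j - LOW_j(model_j)).

    Contributions are accumulated directly into ``out`` in the real basis;
    the recursion ends at leaf nodes, which contribute HIGH(model) only.
    Children are visited in their stored (deterministic) order, so results
    are independent of any execution-order considerations.
    """
    model = build_fragment_geometry(node, real)
    jac = build_jacobian(node, real)
    high = cache.evaluate(node.high_level, model, node, wanted)
    _accumulate(out, high, jac, +1.0, wanted)
    entry = out.per_node.setdefault(node.node_id, {"low_correction": 0.0})
    entry["high"] = high.energy
    for child_id in node.children:
        child = tree.nodes[child_id]
        child_model = build_fragment_geometry(child, real)
        child_jac = build_jacobian(child, real)
        low = cache.evaluate(child.low_level, child_model, child, wanted)
        _accumulate(out, low, child_jac, -1.0, wanted)
        out.per_node[child_id] = {"low_correction": -low.energy}
        _node_property(tree, child, real, cache, wanted, out)


def composite(tree: OniomTree, calculators: dict[str, Calculator],
              wanted=("energy",), system: AtomicSystem | None = None) -> CompositeResult:
    """Full composite energy/gradient/Hessian of the tree's real system.

    ``wanted`` selects which properties to assemble; ``system`` overrides
    the tree's geometry (same atoms) without rebuilding the partition —
    link-atom factors are static, so fragment geometries and Jacobians
    follow the new coordinates automatically.
    """
    wanted = frozenset(wanted)
    if not wanted <= {"energy", "gradient", "hessian"}:
        raise ValueError(f"unknown properties requested: {sorted(wanted - {'energy', 'gradient', 'hessian'})}")
    wanted = wanted | {"energy"}
    real = system if system is not None else tree.system
    if real.n_atoms != tree.system.n_atoms:
        raise ValueError("override geometry has a different atom count than the tree")
    n3 = 3 * real.n_atoms
    out = CompositeResult(
        energy=0.0,
        gradient=np.zeros(n3) if "gradient" in wanted else None,
        hessian=np.zeros((n3, n3)) if "hessian" in wanted else None,
    )
    cache = _EvalCache(calculators)
    _node_property(tree, tree.root, real, cache, wanted, out)
    if out.hessian is not None:
        out.hessian = 0.5 * (out.hessian + out.hessian.T)
    out.n_evaluations = cache.n_evaluations
    return out


@dataclass
class OptimizeResult:
    system: AtomicSystem
    result: CompositeResult
    converged: bool
    n_iterations: int
    max_gradient: float


def optimize(tree: OniomTree, calculators: dict[str, Calculator],
             start: AtomicSystem | None = None, gtol: float = 1e-4,
             maxiter: int = 500) -> OptimizeResult:
    """Quasi-Newton (BFGS) minimization on the composite energy surface.

    Converged when max |g| < ``gtol`` (Hartree/A).  On non-convergence the
    last geometry is returned with ``converged=False``.
    """
    real = start if start is not None else tree.system
    x0 = real.coords.reshape(-1).copy()

    def fun(x):
        res = composite(tree, calculators, ("energy", "gradient"),
                        system=real.with_coords(x.reshape(-1, 3)))
        return res.energy, res.gradient

    g0 = fun(x0)[1]
    if float(np.abs(g0).max()) < gtol:
        final = composite(tree, calculators, ("energy", "gradient"), system=real)
        return OptimizeResult(real, final, True, 0, float(np.abs(g0).max()))

    opt = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})
    geom = real.with_coords(opt.x.reshape(-1, 3))
    final = composite(tree, calculators, ("energy", "gradient"), system=geom)
    gmax = float(np.abs(final.gradient).max())
    return OptimizeResult(geom, final, gmax < gtol, int(opt.nit), gmax)
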