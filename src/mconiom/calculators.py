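"""Energy/gradient/Hessian calculators behind one uniform contract.

The ONIOM engine treats every level of theory as an opaque calculator
that maps a geometry (plus charge/multiplicity labels, which mechanical
embedding passes through untouched) to an energy, optionally a gradient
and a Hessian.  Two analytic toy potentials ship with the package so the
whole multiscale machinery is testable without any external engine:

* :class:`HarmonicFF` — transferable harmonic force field (bond stretch,
  angle bend, 1-4 stretch) whose equilibrium values derive from covalent
  radii, so the same calculator evaluates the real system and any
  hydrogen-capped fragment.
* :class:`DissociativeFF` — Gaussian-well bond potential over a fixed
  reference topology plus Lennard-Jones nonbonded terms; bonds dissociate
  to zero energy without a barrier, mimicking the behaviour of
  dissociative force fields used for bond-breaking pathways.

:class:`ShiftedCalculator` makes cheap distinguishable "levels of theory"
from any base calculator, and :class:`ExternalCalculator` shells out to
an engine executable via a small JSON protocol.

Units: Hartree, Hartree/A, Hartree/A^2, geometry in Angstroem.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elements import covalent_radius
from .geometry import AtomicSystem, write_xyz
from .partition import infer_topology

__all__ = [
    "CalcResult",
    "Calculator",
    "CalculatorError",
    "HarmonicFF",
    "DissociativeFF",
    "ShiftedCalculator",
    "ExternalCalculator",
    "parse_calc_spec",
]

TETRAHEDRAL_ANGLE = float(np.arccos(-1.0 / 3.0))  # 109.471 deg

#: FD step (A) for Hessians built from analytic gradients
HESSIAN_FD_STEP = 5e-4


class CalculatorError(RuntimeError):
    pass


@dataclass
class CalcResult:
    """Result of one calculator on one geometry (Hartree / Hartree/A)."""

    energy: float
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float).reshape(-1)
        if self.hessian is not None:
            H = np.asarray(self.hessian, dtype=float)
            self.hessian = 0.5 * (H + H.T)


class Calculator:
    """Contract: ``evaluate(system, charge, uhf, wanted) -> CalcResult``.

    ``wanted`` is a subset of {"energy", "gradient", "hessian"}; asking for
    a capability the calculator lacks raises :class:`CalculatorError`.
    Built-in calculators are translation and rotation invariant and their
    gradients are consistent with the energy to finite-difference accuracy.
    """

    name: str = "calculator"
    capabilities: frozenset[str] = frozenset({"energy"})

    def evaluate(self, system: AtomicSystem, charge: int = 0, uhf: int = 0,
                 wanted: frozenset[str] = frozenset({"energy"})) -> CalcResult:
        raise NotImplementedError

    def _check_capabilities(self, wanted) -> frozenset[str]:
        wanted = frozenset(wanted)
        missing = wanted - self.capabilities
        if missing:
            raise CalculatorError(
                f"calculator {self.name!r} cannot provide {sorted(missing)} "
                f"(capabilities: {sorted(self.capabilities)})"
            )
        return wanted

    def _fd_hessian(self, system: AtomicSystem, charge: int, uhf: int,
                    step: float = HESSIAN_FD_STEP) -> np.ndarray:
        """Central finite differences of the analytic gradient."""
        x0 = system.coords.reshape(-1).copy()
        n = x0.size
        H = np.empty((n, n))
        for i in range(n):
            xp = x0.copy(); xp[i] += step
            xm = x0.copy(); xm[i] -= step
            gp = self.evaluate(system.with_coords(xp.reshape(-1, 3)), charge, uhf,
                               frozenset({"gradient"})).gradient
            gm = self.evaluate(system.with_coords(xm.reshape(-1, 3)), charge, uhf,
                               frozenset({"gradient"})).gradient
            H[i] = (gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# harmonic toy force field


def _trans_14_distance(r_ij: float, r_jk: float, r_kl: float, theta: float) -> float:
    """1-4 distance of an ideal planar-trans i-j-k-l path."""
    i = np.array([r_ij * np.cos(theta), r_ij * np.sin(theta), 0.0])
    k = np.array([r_jk, 0.0, 0.0])
    l = k + np.array([r_kl * np.cos(np.pi - theta), -r_kl * np.sin(np.pi - theta), 0.0])
    return float(np.linalg.norm(l - i))


def _angle_terms(coords: np.ndarray, i: int, j: int, k: int):
    """Angle i-j-k (vertex j), value and Cartesian derivative vectors."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    s = float(np.sqrt(max(1.0 - c * c, 1e-14)))
    theta = float(np.arccos(c))
    di = (c * uh - vh) / (nu * s)
    dk = (c * vh - uh) / (nv * s)
    return theta, di, -(di + dk), dk


class HarmonicFF(Calculator):
    """Transferable harmonic force field.

    E = sum_bonds 1/2 k_b (r - r0)^2 + sum_angles 1/2 k_a (theta - theta0)^2
        + sum_{1-4 paths} 1/2 k_14 (r - r0_14)^2

    Equilibrium bond lengths are ``r0_scale * (Rcov_a + Rcov_b)``, the
    equilibrium angle is tetrahedral, and the 1-4 equilibrium distance is
    that of an ideal planar-trans path — so the potential applies to any
    geometry, including hydrogen-capped fragments.  The weak 1-4 term
    gives chain torsions a restoring force that pure bond/angle terms
    lack.  Explicit ``bonds`` {(i,j): (k, r0)} / ``angles``
    {(i,j,k): (k, theta0)} parameter dicts switch the calculator to a
    fixed parameterized term list instead.

    Gradients are analytic; Hessians are central finite differences of
    the analytic gradient (step 5e-4 A).
    """

    capabilities = frozenset({"energy", "gradient", "hessian"})

    def __init__(self, k_bond: float = 0.35, k_angle: float = 0.15,
                 k_14: float = 0.02, theta0: float = TETRAHEDRAL_ANGLE,
                 r0_scale: float = 1.0,
                 bonds: dict[tuple[int, int], tuple[float, float]] | None = None,
                 angles: dict[tuple[int, int, int], tuple[float, float]] | None = None,
                 topology: frozenset[tuple[int, int]] | None = None,
                 name: str = "harmonic") -> None:
        self.k_bond, self.k_angle, self.k_14 = k_bond, k_angle, k_14
        self.theta0, self.r0_scale = theta0, r0_scale
        self.explicit_bonds = bonds
        self.explicit_angles = angles
        self.topology = topology
        self.name = name

    # -- term construction ---------------------------------------------------
    def _terms(self, system: AtomicSystem):
        """(bond_terms, angle_terms, pair14_terms) for one geometry.

        bond/pair14 entries: (i, j, k_force, r0); angle: (i, j, k, k_force, th0).
        """
        if self.explicit_bonds is not None or self.explicit_angles is not None:
            n = system.n_atoms
            bt = []
            for (i, j), (kf, r0) in (self.explicit_bonds or {}).items():
                if not (0 <= i < n and 0 <= j < n):
                    raise CalculatorError(f"{self.name}: bond ({i},{j}) outside geometry of {n} atoms")
                bt.append((i, j, kf, r0))
            at = []
            for (i, j, k), (kf, th0) in (self.explicit_angles or {}).items():
                if not all(0 <= q < n for q in (i, j, k)):
                    raise CalculatorError(f"{self.name}: angle ({i},{j},{k}) outside geometry")
                at.append((i, j, k, kf, th0))
            return bt, at, []

        topo = self.topology
        if topo is None or max((max(p) for p in topo), default=-1) >= system.n_atoms:
            topo = infer_topology(system)
        neighbors: dict[int, list[int]] = {i: [] for i in range(system.n_atoms)}
        for i, j in sorted(topo):
            neighbors[i].append(j)
            neighbors[j].append(i)
        r = {e: covalent_radius(e) for e in set(system.elements)}
        r0 = lambda i, j: self.r0_scale * (r[system.elements[i]] + r[system.elements[j]])

        bond_terms = [(i, j, self.k_bond, r0(i, j)) for i, j in sorted(topo)]
        angle_terms = []
        for j in range(system.n_atoms):
            nb = sorted(neighbors[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    angle_terms.append((nb[a], j, nb[b], self.k_angle, self.theta0))
        pair14 = []
        bonded = topo
        seen = set()
        for j, k in sorted(topo):
            for jj, kk in ((j, k), (k, j)):
                for i in neighbors[jj]:
                    if i == kk:
                        continue
                    for l in neighbors[kk]:
                        if l == jj or l == i:
                            continue
                        key = (min(i, l), max(i, l))
                        if key in seen or key in bonded:
                            continue
                        # skip 1-3 pairs (handled by angle terms)
                        if any(i in neighbors[m] and l in neighbors[m]
                               for m in range(system.n_atoms)):
                            continue
                        seen.add(key)
                        d14 = _trans_14_distance(r0(i, jj), r0(jj, kk), r0(kk, l),
                                                 self.theta0)
                        pair14.append((i, l, self.k_14, d14))
        return bond_terms, angle_terms, pair14

    def _energy_gradient(self, coords: np.ndarray, terms, want_grad: bool):
        bond_terms, angle_terms, pair14 = terms
        e = 0.0
        g = np.zeros_like(coords) if want_grad else None
        for i, j, kf, r0 in bond_terms + pair14:
            d = coords[i] - coords[j]
            rr = float(np.linalg.norm(d))
            e += 0.5 * kf * (rr - r0) ** 2
            if want_grad and rr > 1e-12:
                f = kf * (rr - r0) * d / rr
                g[i] += f
                g[j] -= f
        for i, j, k, kf, th0 in angle_terms:
            theta, di, dj, dk = _angle_terms(coords, i, j, k)
            e += 0.5 * kf * (theta - th0) ** 2
            if want_grad:
                pref = kf * (theta - th0)
                g[i] += pref * di
                g[j] += pref * dj
                g[k] += pref * dk
        return e, (g.reshape(-1) if want_grad else None)

    def evaluate(self, system: AtomicSystem, charge: int = 0, uhf: int = 0,
                 wanted: frozenset[str] = frozenset({"energy"})) -> CalcResult:
        wanted = self._check_capabilities(wanted)
        terms = self._terms(system)
        e, g = self._energy_gradient(system.coords, terms, "gradient" in wanted)
        H = None
        if "hessian" in wanted:
            H = self._fd_hessian_terms(system, terms)
        return CalcResult(energy=e, gradient=g, hessian=H,
                          meta={"calculator": self.name})

    def _fd_hessian_terms(self, system: AtomicSystem, terms,
                          step: float = HESSIAN_FD_STEP) -> np.ndarray:
        # fixed term list during differencing: no topology flips near cutoffs
        x0 = system.coords.reshape(-1)
        n = x0.size
        H = np.empty((n, n))
        for i in range(n):
            xp = x0.copy(); xp[i] += step
            xm = x0.copy(); xm[i] -= step
            _, gp = self._energy_gradient(xp.reshape(-1, 3), terms, True)
            _, gm = self._energy_gradient(xm.reshape(-1, 3), terms, True)
            H[i] = (gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# dissociative toy force field


class DissociativeFF(Calculator):
    """Gaussian-well bonds over a fixed reference topology + LJ nonbonded.

    E = sum_bonds -D exp(-(r - r0)^2 / (2 w^2))
        + sum_nonbonded 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]

    Each listed bond contributes -D at its minimum and decays smoothly to
    zero as the bond stretches: cleavage has no barrier.  Nonbonded pairs
    are all pairs neither bonded nor sharing a bonded neighbour (1-3).
    The bond list is frozen at construction from ``reference_topology``
    (or inferred from ``reference_system``), mirroring force fields that
    keep the native-state topology so broken bonds can reform.
    """

    capabilities = frozenset({"energy", "gradient", "hessian"})

    def __init__(self, reference_topology: frozenset[tuple[int, int]],
                 elements: list[str], D: float = 0.15, w: float = 0.5,
                 lj_epsilon: float = 2e-4, lj_sigma: float = 3.2,
                 r0_scale: float = 1.0, name: str = "dissociative") -> None:
        if D <= 0 or w <= 0:
            raise CalculatorError(f"{name}: well depth D and width w must be positive")
        self.D, self.w = D, w
        self.lj_epsilon, self.lj_sigma = lj_epsilon, lj_sigma
        self.name = name
        topo = frozenset((min(i, j), max(i, j)) for i, j in reference_topology)
        r = {e: covalent_radius(e) for e in set(elements)}
        self.bonds = [
            (i, j, r0_scale * (r[elements[i]] + r[elements[j]]))
            for i, j in sorted(topo)
        ]
        n = len(elements)
        neighbors: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in topo:
            neighbors[i].add(j)
            neighbors[j].add(i)
        excl = set(topo)
        for m in range(n):
            nb = sorted(neighbors[m])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    excl.add((nb[a], nb[b]))
        self.nonbonded = [(i, j) for i in range(n) for j in range(i + 1, n)
                          if (i, j) not in excl]
        self.n_atoms = n

    @classmethod
    def from_system(cls, system: AtomicSystem, **kw) -> "DissociativeFF":
        topo = system.topology if system.topology is not None else infer_topology(system)
        return cls(reference_topology=topo, elements=list(system.elements), **kw)

    def lower_bound(self) -> float:
        """-sum_bonds D plus the LJ minimum over nonbonded pairs."""
        return -self.D * len(self.bonds) - self.lj_epsilon * len(self.nonbonded)

    def _energy_gradient(self, coords: np.ndarray, want_grad: bool):
        e = 0.0
        g = np.zeros_like(coords) if want_grad else None
        for i, j, r0 in self.bonds:
            d = coords[i] - coords[j]
            rr = float(np.linalg.norm(d))
            gauss = np.exp(-((rr - r0) ** 2) / (2.0 * self.w**2))
            e += -self.D * gauss
            if want_grad and rr > 1e-12:
                dEdr = self.D * (rr - r0) / self.w**2 * gauss
                f = dEdr * d / rr
                g[i] += f
                g[j] -= f
        eps, sig = self.lj_epsilon, self.lj_sigma
        for i, j in self.nonbonded:
            d = coords[i] - coords[j]
            rr = float(np.linalg.norm(d))
            sr6 = (sig / rr) ** 6
            e += 4.0 * eps * (sr6 * sr6 - sr6)
            if want_grad:
                dEdr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rr
                f = dEdr * d / rr
                g[i] += f
                g[j] -= f
        return e, (g.reshape(-1) if want_grad else None)

    def evaluate(self, system: AtomicSystem, charge: int = 0, uhf: int = 0,
                 wanted: frozenset[str] = frozenset({"energy"})) -> CalcResult:
        wanted = self._check_capabilities(wanted)
        if system.n_atoms != self.n_atoms:
            raise CalculatorError(
                f"{self.name}: geometry has {system.n_atoms} atoms but the "
                f"reference topology was built for {self.n_atoms}"
            )
        e, g = self._energy_gradient(system.coords, "gradient" in wanted or "hessian" in wanted)
        H = self._fd_hessian(system, charge, uhf) if "hessian" in wanted else None
        return CalcResult(energy=e, gradient=g, hessian=H, meta={"calculator": self.name})


# ---------------------------------------------------------------------------
# wrappers


class ShiftedCalculator(Calculator):
    """Affine transform of a base calculator: E' = scale * E + shift.

    Gradients and Hessians scale accordingly.  Useful for creating cheap,
    mutually distinguishable levels of theory in layered tests.
    """

    def __init__(self, base: Calculator, scale: float = 1.0, shift: float = 0.0,
                 name: str | None = None) -> None:
        self.base, self.scale, self.shift = base, scale, shift
        self.name = name or f"shifted({base.name},{scale},{shift})"
        self.capabilities = base.capabilities

    def evaluate(self, system, charge=0, uhf=0, wanted=frozenset({"energy"})):
        wanted = self._check_capabilities(wanted)
        res = self.base.evaluate(system, charge, uhf, wanted)
        return CalcResult(
            energy=self.scale * res.energy + self.shift,
            gradient=None if res.gradient is None else self.scale * res.gradient,
            hessian=None if res.hessian is None else self.scale * res.hessian,
            meta={"calculator": self.name, "base": res.meta},
        )


class ExternalCalculator(Calculator):
    """Subprocess adapter for an external engine (optional; never required).

    Protocol: the engine is invoked as ``cmd <input.xyz> <output.json>``
    and writes a JSON object with ``energy`` (plus optional ``gradient``
    as a flat 3m list and ``hessian`` as a nested list).  ``energy_unit``
    ("hartree" | "ev" | "kcal/mol") and ``gradient_unit`` ("hartree/angstrom"
    | "hartree/bohr" | "ev/angstrom") default to Hartree and Hartree/A.
    """

    _E_UNIT = {"hartree": 1.0, "ev": 1.0 / 27.211386245988, "kcal/mol": 1.0 / 627.509474}
    _G_UNIT = {"hartree/angstrom": 1.0, "hartree/bohr": 1.0 / 0.529177210903,
               "ev/angstrom": 1.0 / 27.211386245988}

    def __init__(self, command: str, name: str = "external",
                 capabilities: frozenset[str] = frozenset({"energy", "gradient"})) -> None:
        self.command = command
        self.name = name
        self.capabilities = capabilities

    def evaluate(self, system, charge=0, uhf=0, wanted=frozenset({"energy"})):
        wanted = self._check_capabilities(wanted)
        exe = self.command.split()[0]
        if shutil.which(exe) is None:
            raise CalculatorError(
                f"external engine {exe!r} not found on PATH; this calculator is an "
                "optional dependency adapter — install the engine or use a built-in "
                "calculator instead"
            )
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.xyz"
            out = Path(tmp) / "output.json"
            write_xyz(system, inp)
            proc = subprocess.run(
                self.command.split() + [str(inp), str(out)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0 or not out.exists():
                raise CalculatorError(
                    f"engine {self.name!r} failed (exit {proc.returncode}); "
                    f"stderr: {proc.stderr.strip()[:500]}"
                )
            try:
                data = json.loads(out.read_text())
                energy = float(data["energy"]) * self._E_UNIT[
                    str(data.get("energy_unit", "hartree")).lower()]
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise CalculatorError(
                    f"engine {self.name!r} produced unparsable output: {exc}; "
                    f"stderr: {proc.stderr.strip()[:500]}"
                ) from exc
            grad = None
            if "gradient" in data:
                grad = np.asarray(data["gradient"], dtype=float).reshape(-1) * self._G_UNIT[
                    str(data.get("gradient_unit", "hartree/angstrom")).lower()]
                if grad.size != 3 * system.n_atoms:
                    raise CalculatorError(
                        f"engine {self.name!r}: gradient length {grad.size} != {3 * system.n_atoms}")
            hess = None
            if "hessian" in data:
                hess = np.asarray(data["hessian"], dtype=float)
        return CalcResult(energy=energy, gradient=grad, hessian=hess,
                          meta={"calculator": self.name, "command": self.command})


# ---------------------------------------------------------------------------
# spec-string parsing (used by the CLI and run configs)


def parse_calc_spec(spec: str | dict, existing: dict[str, Calculator] | None = None,
                    name: str | None = None) -> Calculator:
    """Build a calculator from a compact spec.

    String form: ``"harmonic"``, ``"harmonic:k_bond=0.4,r0_scale=0.99"``,
    ``"shifted:base=ff,scale=2,shift=0.01"`` (``base`` names a previously
    defined calculator), ``"external:command=mock_engine"``.  Dict form
    uses a ``type`` key plus keyword fields.
    """
    existing = existing or {}
    if isinstance(spec, str):
        kind, _, rest = spec.partition(":")
        kw: dict = {}
        if rest:
            for item in rest.split(","):
                key, _, val = item.partition("=")
                kw[key.strip()] = val.strip()
    else:
        kw = dict(spec)
        kind = kw.pop("type")
    kind = kind.strip().lower()

    def fl(d, keys):
        for k in keys:
            if k in d:
                d[k] = float(d[k])

    if kind == "harmonic":
        fl(kw, ["k_bond", "k_angle", "k_14", "theta0", "r0_scale"])
        return HarmonicFF(name=name or kw.pop("name", "harmonic"), **kw)
    if kind == "shifted":
        base_name = kw.pop("base")
        if base_name not in existing:
            raise CalculatorError(f"shifted calculator: unknown base {base_name!r}")
        fl(kw, ["scale", "shift"])
        return ShiftedCalculator(existing[base_name], name=name, **kw)
    if kind == "external":
        return ExternalCalculator(kw.pop("command"), name=name or "external")
    raise CalculatorError(
        f"unknown calculator type {kind!r} (dissociative calculators need a "
        "reference geometry; build them with DissociativeFF.from_system)"
    )
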