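"""Deterministic synthetic fixtures: toy geometries, calculators and
partition specs for every tree shape the engine supports.

Geometries are planar-trans zigzag chains built at the exact equilibrium
of the default :class:`~mconiom.calculators.HarmonicFF` (bond lengths =
covalent-radius sums, tetrahedral angles), optionally perturbed by a
seeded Gaussian jitter that breaks planarity.  The ``tri_bridge_peptide``
kind emulates, at toy scale, a protein with three disulfide bridges:
three disjoint S-S pairs embedded in a ~40-atom chain, each wrapped by a
middle-layer fragment — the natural target for a three-layer,
three-center partition (1 root + 3 middle + 3 inner nodes).

Everything is a pure function of (kind, seed): the same seed reproduces
the same fixture bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calculators import Calculator, HarmonicFF, TETRAHEDRAL_ANGLE
from .elements import covalent_radius
from .geometry import AtomicSystem, write_xyz
from .partition import OniomTree, build_tree

__all__ = ["Fixture", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("diatomic", "chain", "bridge_dimer", "tri_bridge_peptide")


@dataclass
class Fixture:
    name: str
    system: AtomicSystem
    calculators: dict[str, Calculator]
    partition_spec: dict
    provenance: dict

    def tree(self) -> OniomTree:
        return build_tree(self.system, self.partition_spec,
                          known_calculators=set(self.calculators))

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write geometry.xyz, partition.toml and calculators.toml."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {"geometry": d / "geometry.xyz",
                 "partition": d / "partition.toml",
                 "calculators": d / "calculators.toml"}
        write_xyz(self.system, paths["geometry"])
        lines = []
        for ent in self.partition_spec["node"]:
            lines.append("[[node]]")
            lines.append(f'id = "{ent["id"]}"')
            lines.append(f"layer = {ent['layer']}")
            lines.append(f'atoms = "{ent["atoms"]}"')
            lines.append(f'calculator = "{ent["calculator"]}"')
            lines.append("")
        paths["partition"].write_text("\n".join(lines))
        spec_lines = ["[calculators]"]
        for name, calc in self.calculators.items():
            if isinstance(calc, HarmonicFF):
                spec = (f"harmonic:k_bond={calc.k_bond},k_angle={calc.k_angle},"
                        f"k_14={calc.k_14},r0_scale={calc.r0_scale}")
            else:
                spec = calc.name
            spec_lines.append(f'{name} = "{spec}"')
        paths["calculators"].write_text("\n".join(spec_lines) + "\n")
        return paths


def _zigzag_chain(elements: list[str], theta: float = TETRAHEDRAL_ANGLE) -> np.ndarray:
    """Planar trans chain with bond lengths = covalent-radius sums, angles theta."""
    phi = 0.5 * (np.pi - theta)
    dirs = [np.array([np.sin(phi), np.cos(phi), 0.0]),
            np.array([-np.sin(phi), np.cos(phi), 0.0])]
    coords = [np.zeros(3)]
    for i in range(1, len(elements)):
        r0 = covalent_radius(elements[i - 1]) + covalent_radius(elements[i])
        coords.append(coords[-1] + r0 * dirs[(i - 1) % 2])
    return np.array(coords)


def _chain_topology(n: int) -> frozenset[tuple[int, int]]:
    return frozenset((i, i + 1) for i in range(n - 1))


def _level_calculators() -> dict[str, Calculator]:
    """Three mutually distinct smooth toy levels of theory."""
    return {
        "ff": HarmonicFF(name="ff"),
        "sqm": HarmonicFF(k_bond=0.45, k_angle=0.20, k_14=0.025,
                          r0_scale=0.99, name="sqm"),
        "dft": HarmonicFF(k_bond=0.55, k_angle=0.25, k_14=0.03,
                          r0_scale=0.98, name="dft"),
    }


_TRI_BRIDGE_N = 40
_TRI_BRIDGE_S = (8, 9, 20, 21, 32, 33)  # 0-based sulfur positions


def _tri_bridge_elements() -> list[str]:
    els = ["C"] * _TRI_BRIDGE_N
    for i in _TRI_BRIDGE_S:
        els[i] = "S"
    for i in (3, 15, 27, 39):
        els[i] = "N"
    for i in (5, 17, 29):
        els[i] = "O"
    return els


def make_fixture(kind: str, seed: int = 0, jitter: float = 0.03) -> Fixture:
    """Deterministic fixture of the given kind.

    kinds: ``diatomic`` (2 atoms at the toy-FF equilibrium — a
    zero-gradient start), ``chain`` (5-atom two-layer), ``bridge_dimer``
    (6 atoms, one S-S bridge, two layers), ``tri_bridge_peptide``
    (40 atoms, three S-S bridges, three layers / three centers).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    calcs = _level_calculators()

    if kind == "diatomic":
        elements = ["N", "N"]
        coords = _zigzag_chain(elements)  # exactly at the ff equilibrium
        spec = {"node": [{"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"}]}
    elif kind == "chain":
        elements = ["C"] * 5
        coords = _zigzag_chain(elements) + rng.normal(0.0, jitter, (5, 3))
        spec = {"node": [
            {"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"},
            {"id": "mid", "layer": 2, "atoms": "2-4", "calculator": "sqm"},
        ]}
    elif kind == "bridge_dimer":
        elements = ["C", "C", "S", "S", "C", "C"]
        coords = _zigzag_chain(elements) + rng.normal(0.0, jitter, (6, 3))
        spec = {"node": [
            {"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"},
            {"id": "bridge", "layer": 2, "atoms": "2-5", "calculator": "sqm"},
        ]}
    else:  # tri_bridge_peptide
        elements = _tri_bridge_elements()
        coords = (_zigzag_chain(elements)
                  + rng.normal(0.0, jitter, (_TRI_BRIDGE_N, 3)))
        spec = {"node": [
            {"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"},
            {"id": "mid1", "layer": 2, "atoms": "7-12", "calculator": "sqm"},
            {"id": "mid2", "layer": 2, "atoms": "19-24", "calculator": "sqm"},
            {"id": "mid3", "layer": 2, "atoms": "31-36", "calculator": "sqm"},
            {"id": "ss1", "layer": 3, "atoms": "9-10", "calculator": "dft"},
            {"id": "ss2", "layer": 3, "atoms": "21-22", "calculator": "dft"},
            {"id": "ss3", "layer": 3, "atoms": "33-34", "calculator": "dft"},
        ]}

    system = AtomicSystem(elements=elements, coords=coords,
                          topology=_chain_topology(len(elements)), name=kind)
    return Fixture(
        name=kind, system=system, calculators=calcs, partition_spec=spec,
        provenance={"kind": kind, "seed": int(seed), "jitter": jitter},
    )
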