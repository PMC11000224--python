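"""Molecular data model and structure file I/O (XYZ read/write, PDB read).

`AtomicSystem` is the package's "real system": element symbols, Cartesian
coordinates in Angstroem, per-atom masses in amu, and an optional bond
topology as a set of index pairs.  Capped ONIOM fragments are themselves
`AtomicSystem` instances, so every calculator sees one uniform geometry
type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elements import atomic_mass, covalent_radius, normalize_symbol

__all__ = ["AtomicSystem", "XYZParseError", "read_xyz", "write_xyz", "read_pdb"]


class XYZParseError(ValueError):
    """Malformed XYZ/PDB content; message names the offending line."""


@dataclass
class AtomicSystem:
    """A molecule: elements, coordinates (A), masses (amu), optional bonds.

    Topology pairs are stored sorted as ``(i, j)`` with ``i < j`` and use
    0-based atom indices (all user-facing files and messages are 1-based).
    """

    elements: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    topology: frozenset[tuple[int, int]] | None = None
    name: str = ""
    energy: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.elements = [normalize_symbol(e) for e in self.elements]
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3).copy()
        n = len(self.elements)
        if n < 1:
            raise ValueError("AtomicSystem needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match {n} elements"
            )
        if self.masses is None:
            self.masses = np.array([atomic_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float).copy()
            if self.masses.shape != (n,):
                raise ValueError("masses must be one per atom")
        # every element must resolve in both tables (masses resolved above)
        for e in self.elements:
            covalent_radius(e)
        if self.topology is not None:
            pairs = set()
            for pair in self.topology:
                i, j = pair
                if not (0 <= i < n and 0 <= j < n) or i == j:
                    raise ValueError(f"topology pair {pair} references invalid atom indices")
                pairs.add((min(i, j), max(i, j)))
            self.topology = frozenset(pairs)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "AtomicSystem":
        """Copy of this system with replaced coordinates (same atoms/topology)."""
        return AtomicSystem(
            elements=list(self.elements),
            coords=np.asarray(coords, dtype=float).reshape(self.n_atoms, 3),
            masses=self.masses.copy(),
            topology=self.topology,
            name=self.name,
        )

    def subsystem(self, indices: list[int] | tuple[int, ...], name: str = "") -> "AtomicSystem":
        """Sub-geometry over the given (0-based, ascending) atom indices.

        Topology is restricted to bonds internal to the selection and
        re-indexed into the subsystem.
        """
        idx = list(indices)
        remap = {p: k for k, p in enumerate(idx)}
        topo = None
        if self.topology is not None:
            topo = frozenset(
                (remap[i], remap[j]) for i, j in self.topology if i in remap and j in remap
            )
        return AtomicSystem(
            elements=[self.elements[i] for i in idx],
            coords=self.coords[idx],
            masses=self.masses[idx],
            topology=topo,
            name=name or self.name,
        )

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()


def read_xyz(path: str | Path) -> AtomicSystem:
    """Read one frame of an XYZ file (count line, comment, element x y z rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}, line 1: expected an atom count, got {lines[0]!r}") from None
    if n < 1:
        raise XYZParseError(f"{path}, line 1: atom count must be >= 1, got {n}")
    if len(lines) < n + 2:
        raise XYZParseError(f"{path}: expected {n + 2} lines for {n} atoms, file has {len(lines)}")
    comment = lines[1].strip()
    elements: list[str] = []
    coords = np.empty((n, 3))
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}, line {lineno}: expected 'element x y z', got {lines[k + 2]!r}")
        try:
            el = normalize_symbol(parts[0])
            atomic_mass(el)  # unknown symbols fail here, with the line number
            elements.append(el)
        except Exception:
            raise XYZParseError(f"{path}, line {lineno}: unknown element {parts[0]!r}") from None
        try:
            coords[k] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}, line {lineno}: non-numeric coordinate in {lines[k + 2]!r}") from None
    return AtomicSystem(elements=elements, coords=coords, name=comment)


def write_xyz(system: AtomicSystem, path: str | Path) -> None:
    """Write standard XYZ text with 6-decimal coordinates.

    The comment line carries the system name and, if set, its energy in
    Hartree.
    """
    comment = system.name
    if system.energy is not None:
        comment = f"{comment} E={system.energy:.10f} Hartree".strip()
    out = [str(system.n_atoms), comment]
    for el, (x, y, z) in zip(system.elements, system.coords):
        out.append(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_pdb(path: str | Path) -> AtomicSystem:
    """Read coordinates/elements from PDB ATOM/HETATM records (read-only subset).

    The element is taken from columns 77-78 when present, else deduced from
    the atom-name field.  Occupancy, alt-locs and multi-model files are not
    interpreted: every ATOM/HETATM line contributes one atom.
    """
    path = Path(path)
    elements: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except (ValueError, IndexError):
            raise XYZParseError(f"{path}, line {lineno}: malformed PDB coordinates") from None
        el = line[76:78].strip() if len(line) >= 78 else ""
        if not el:
            # atom-name fallback: first alphabetic run, stripped of digits
            raw = line[12:16].strip().lstrip("0123456789")
            el = raw[:2] if len(raw) >= 2 and raw[:2].capitalize() in ("Cl", "Br", "Se", "Na", "Mg", "Zn", "Fe", "Ca") else raw[:1]
        try:
            elements.append(normalize_symbol(el))
        except Exception:
            raise XYZParseError(f"{path}, line {lineno}: cannot resolve element from {line[12:16]!r}") from None
        rows.append(xyz)
    if not elements:
        raise XYZParseError(f"{path}: no ATOM/HETATM records found")
    return AtomicSystem(elements=elements, coords=np.array(rows), name=path.stem)
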