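"""Multicenter ONIOM partitioning: dependency trees, hydrogen link atoms,
capped fragment geometries, and coordinate Jacobians.

A partition is a tree of fragments.  The root (layer 1) holds every atom
of the real system; each deeper node is a strict subset of its parent,
siblings are disjoint, and a node's low level of theory is its parent's
high level.  Bonds cut by a fragment boundary are saturated by a hydrogen
link atom placed statically along the cut bond,

    r_l = r_a + k_ab (r_b - r_a),      k_ab = (R_a + R_H) / (R_a + R_b),

where a is the inside (host) atom, b the outside partner, and R are
single-bond covalent radii.  Because the cap position is an affine
combination of two real-atom positions, the map from real coordinates to
capped-fragment coordinates is linear; its Jacobian consists of 3x3
blocks that are scalar multiples of the identity: 1 for fragment atoms,
(1-k_ab) and k_ab for the two hosts of each cap.  The transpose of this
Jacobian pulls fragment gradients and Hessians back into the real basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .elements import COVALENT_RADII, covalent_radius
from .geometry import AtomicSystem

__all__ = [
    "LinkAtomSpec",
    "OniomNode",
    "OniomTree",
    "Jacobian",
    "PartitionError",
    "link_scale_factor",
    "place_link_atom",
    "infer_topology",
    "detect_cut_bonds",
    "build_fragment_geometry",
    "build_jacobian",
    "build_tree",
    "validate_tree",
]

#: bonded iff distance < BOND_TOLERANCE * (R_a + R_b) when no topology given
BOND_TOLERANCE = 1.15


class PartitionError(ValueError):
    """Invalid partition specification or tree."""


def link_scale_factor(
    el_a: str, el_b: str, radii: dict[str, float] | None = None
) -> float:
    """Dimensionless link-atom position factor from covalent-radius ratios.

    ``el_a`` is the host atom kept in the fragment, ``el_b`` the removed
    partner.  k = (R_a + R_H) / (R_a + R_b); cutting an X-H bond gives
    k = 1 exactly (the cap coincides with the hydrogen it replaces).
    """
    r_a = covalent_radius(el_a, radii)
    r_b = covalent_radius(el_b, radii)
    r_h = covalent_radius("H", radii)
    return (r_a + r_h) / (r_a + r_b)


def place_link_atom(r_a: np.ndarray, r_b: np.ndarray, k_ab: float) -> np.ndarray:
    """Cap position r_a + k_ab (r_b - r_a), collinear with the cut bond."""
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    d = r_b - r_a
    if float(np.linalg.norm(d)) < 1e-10:
        raise PartitionError("cut-bond endpoints coincide; cannot place link atom")
    return r_a + k_ab * d


@dataclass(frozen=True)
class LinkAtomSpec:
    """One hydrogen cap: host atom ``a`` inside the fragment, partner ``b`` outside."""

    host: int
    partner: int
    k: float
    cap_element: str = "H"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise PartitionError(f"link-atom scale factor must be positive, got {self.k}")


@dataclass
class OniomNode:
    node_id: str
    layer: int
    atom_indices: tuple[int, ...]
    high_level: str
    low_level: str | None = None  # parent's high level; None on the root
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    link_atoms: list[LinkAtomSpec] = field(default_factory=list)
    charge: int = 0
    uhf: int = 0

    @property
    def atom_set(self) -> frozenset[int]:
        return frozenset(self.atom_indices)


@dataclass
class OniomTree:
    nodes: dict[str, OniomNode]
    root_id: str
    system: AtomicSystem

    @property
    def root(self) -> OniomNode:
        return self.nodes[self.root_id]

    def children_of(self, node_id: str) -> list[OniomNode]:
        return [self.nodes[c] for c in self.nodes[node_id].children]

    def node_order(self) -> list[str]:
        """Deterministic depth-first node order starting at the root."""
        order: list[str] = []
        stack = [self.root_id]
        seen: set[str] = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def level_names(self) -> set[str]:
        return {n.high_level for n in self.nodes.values()}


class Jacobian:
    """Sparse linear map from real-system coordinates (3n) to capped-fragment
    coordinates (3m).

    Blocks are scalar multiples of the 3x3 identity, stored as
    ``(model_atom, real_atom) -> scalar``: exactly one unit block for each
    fragment atom, and the pair (1-k), k for each link atom's hosts.  The
    scalars of every model atom sum to 1, so rigid translations of the
    real system translate the fragment rigidly.
    """

    def __init__(self, node_id: str, n_real: int, m_model: int,
                 blocks: dict[tuple[int, int], float]) -> None:
        self.node_id = node_id
        self.n_real = n_real
        self.m_model = m_model
        self.blocks = dict(blocks)

    def to_dense(self) -> np.ndarray:
        """Dense (3m x 3n) matrix; intended for small systems and testing."""
        J = np.zeros((3 * self.m_model, 3 * self.n_real))
        eye = np.eye(3)
        for (mi, ri), s in self.blocks.items():
            J[3 * mi:3 * mi + 3, 3 * ri:3 * ri + 3] = s * eye
        return J

    def map_coords(self, real_coords: np.ndarray) -> np.ndarray:
        """Apply J to real coordinates: the capped-fragment coordinates (m x 3)."""
        real = np.asarray(real_coords, dtype=float).reshape(self.n_real, 3)
        out = np.zeros((self.m_model, 3))
        for (mi, ri), s in self.blocks.items():
            out[mi] += s * real[ri]
        return out

    def project_gradient(self, g_model: np.ndarray) -> np.ndarray:
        """J^T g: pull a fragment gradient (3m) back to the real basis (3n).

        A force on a cap with hosts (a, b) lands as (1-k) on a and k on b.
        """
        g = np.asarray(g_model, dtype=float).reshape(self.m_model, 3)
        out = np.zeros((self.n_real, 3))
        for (mi, ri), s in self.blocks.items():
            out[ri] += s * g[mi]
        return out.reshape(-1)

    def project_hessian(self, h_model: np.ndarray) -> np.ndarray:
        """J^T H J: pull a fragment Hessian (3m x 3m) back to the real basis."""
        H = np.asarray(h_model, dtype=float)
        if H.shape != (3 * self.m_model, 3 * self.m_model):
            raise ValueError(f"Hessian shape {H.shape} does not match 3m={3 * self.m_model}")
        out = np.zeros((3 * self.n_real, 3 * self.n_real))
        items = list(self.blocks.items())
        for (mi, ri), si in items:
            Hi = H[3 * mi:3 * mi + 3, :]
            for (mj, rj), sj in items:
                out[3 * ri:3 * ri + 3, 3 * rj:3 * rj + 3] += (
                    si * sj * Hi[:, 3 * mj:3 * mj + 3]
                )
        return out


def infer_topology(
    system: AtomicSystem, tolerance: float = BOND_TOLERANCE,
    radii: dict[str, float] | None = None,
) -> frozenset[tuple[int, int]]:
    """Distance-based bond perception: bonded iff d < tolerance * (R_a + R_b)."""
    n = system.n_atoms
    r = np.array([covalent_radius(e, radii) for e in system.elements])
    cut = tolerance * (r[:, None] + r[None, :])
    d = np.linalg.norm(system.coords[:, None, :] - system.coords[None, :, :], axis=-1)
    ii, jj = np.where((d < cut) & (np.triu(np.ones((n, n), dtype=bool), k=1)))
    return frozenset(zip(ii.tolist(), jj.tolist()))


def detect_cut_bonds(
    system: AtomicSystem, fragment: frozenset[int] | set[int],
    topology: frozenset[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Bonds (a, b) with host a inside the fragment and partner b outside.

    Uses the supplied topology, else the system's, else distance-based
    inference.  Sorted by (a, b) so downstream cap ordering is stable.
    """
    frag = set(fragment)
    if not frag <= set(range(system.n_atoms)):
        raise PartitionError("fragment contains atom indices outside the system")
    topo = topology if topology is not None else system.topology
    if topo is None:
        topo = infer_topology(system)
    cuts = []
    for i, j in topo:
        if (i in frag) != (j in frag):
            a, b = (i, j) if i in frag else (j, i)
            cuts.append((a, b))
    return sorted(cuts)


def _link_specs(
    system: AtomicSystem, fragment: frozenset[int],
    topology: frozenset[tuple[int, int]] | None = None,
    k_overrides: dict[tuple[int, int], float] | None = None,
    radii: dict[str, float] | None = None,
    node_id: str = "?",
) -> list[LinkAtomSpec]:
    specs = []
    hosts_seen: dict[int, int] = {}
    for a, b in detect_cut_bonds(system, fragment, topology):
        k = None
        if k_overrides:
            k = k_overrides.get((a, b))
        if k is None:
            k = link_scale_factor(system.elements[a], system.elements[b], radii)
        specs.append(LinkAtomSpec(host=a, partner=b, k=k))
        hosts_seen[a] = hosts_seen.get(a, 0) + 1
    for a, cnt in hosts_seen.items():
        if cnt > 1:
            warnings.warn(
                f"node {node_id}: atom {a + 1} hosts {cnt} link atoms; "
                "the capped geometry may be strained",
                stacklevel=2,
            )
    return specs


def build_fragment_geometry(node: OniomNode, system: AtomicSystem) -> AtomicSystem:
    """Capped model system: fragment atoms in ascending real-index order,
    then hydrogen caps in cut-bond order."""
    idx = sorted(node.atom_indices)
    elements = [system.elements[i] for i in idx]
    coords = [system.coords[i] for i in idx]
    for link in node.link_atoms:
        elements.append(link.cap_element)
        coords.append(place_link_atom(system.coords[link.host],
                                      system.coords[link.partner], link.k))
    return AtomicSystem(elements=elements, coords=np.array(coords),
                        name=f"{system.name}:{node.node_id}" if system.name else node.node_id)


def build_jacobian(node: OniomNode, system: AtomicSystem) -> Jacobian:
    """Analytic Jacobian of the real->model coordinate map for one node."""
    idx = sorted(node.atom_indices)
    blocks: dict[tuple[int, int], float] = {}
    for mi, ri in enumerate(idx):
        blocks[(mi, ri)] = 1.0
    m = len(idx)
    for off, link in enumerate(node.link_atoms):
        mi = m + off
        blocks[(mi, link.host)] = blocks.get((mi, link.host), 0.0) + (1.0 - link.k)
        blocks[(mi, link.partner)] = blocks.get((mi, link.partner), 0.0) + link.k
    return Jacobian(node.node_id, n_real=system.n_atoms,
                    m_model=m + len(node.link_atoms), blocks=blocks)


def _parse_atom_field(entry, n_atoms: int, node_id: str) -> tuple[int, ...]:
    """1-based atom lists and/or ranges ("5-14") -> sorted 0-based tuple."""
    if isinstance(entry, str):
        entry = [entry]
    out: set[int] = set()
    for item in entry:
        if isinstance(item, int):
            vals = [item]
        elif isinstance(item, str):
            item = item.strip()
            if "-" in item[1:]:
                lo, hi = item.split("-", 1)
                try:
                    vals = list(range(int(lo), int(hi) + 1))
                except ValueError:
                    raise PartitionError(f"node {node_id}: bad atom range {item!r}") from None
            else:
                try:
                    vals = [int(item)]
                except ValueError:
                    raise PartitionError(f"node {node_id}: bad atom entry {item!r}") from None
        else:
            raise PartitionError(f"node {node_id}: bad atom entry {item!r}")
        for v in vals:
            if not (1 <= v <= n_atoms):
                raise PartitionError(
                    f"node {node_id}: atom index {v} out of range 1..{n_atoms}"
                )
            out.add(v - 1)
    if not out:
        raise PartitionError(f"node {node_id}: empty atom list")
    return tuple(sorted(out))


def build_tree(
    system: AtomicSystem,
    spec: dict,
    topology: frozenset[tuple[int, int]] | None = None,
    radii: dict[str, float] | None = None,
    known_calculators: set[str] | None = None,
) -> OniomTree:
    """Build and validate an OniomTree from a partition spec mapping.

    ``spec["node"]`` is a list of entries with keys ``layer`` (int >= 1),
    ``atoms`` (1-based indices and/or "lo-hi" ranges; a layer-1 entry may
    say "all"), ``calculator``, and optional ``charge``, ``uhf``, ``id``,
    and ``links`` ({"a-b": k} overrides of the scale factor, 1-based).
    Parents are inferred by containment: a node's parent is the unique
    node one layer up whose atom set contains it.
    """
    entries = spec.get("node")
    if not entries:
        raise PartitionError("partition spec has no [[node]] entries")
    topo = topology if topology is not None else system.topology
    if topo is None:
        topo = infer_topology(system, radii=radii)

    nodes: dict[str, OniomNode] = {}
    k_overrides: dict[str, dict[tuple[int, int], float]] = {}
    for i, ent in enumerate(entries):
        node_id = str(ent.get("id", f"n{i + 1}"))
        if node_id in nodes:
            raise PartitionError(f"duplicate node id {node_id!r}")
        try:
            layer = int(ent["layer"])
        except (KeyError, ValueError):
            raise PartitionError(f"node {node_id}: missing or bad 'layer'") from None
        if layer < 1:
            raise PartitionError(f"node {node_id}: layer must be >= 1, got {layer}")
        atoms_field = ent.get("atoms", "all" if layer == 1 else None)
        if atoms_field is None:
            raise PartitionError(f"node {node_id}: missing 'atoms'")
        if atoms_field == "all":
            atoms = tuple(range(system.n_atoms))
        else:
            atoms = _parse_atom_field(atoms_field, system.n_atoms, node_id)
        calc = ent.get("calculator")
        if not calc:
            raise PartitionError(f"node {node_id}: missing 'calculator'")
        if known_calculators is not None and calc not in known_calculators:
            raise PartitionError(
                f"node {node_id}: unknown calculator {calc!r} "
                f"(known: {sorted(known_calculators)})"
            )
        ovr: dict[tuple[int, int], float] = {}
        for key, val in (ent.get("links") or {}).items():
            try:
                a1, b1 = (int(x) for x in str(key).split("-"))
            except ValueError:
                raise PartitionError(f"node {node_id}: bad link override key {key!r}") from None
            ovr[(a1 - 1, b1 - 1)] = float(val)
        k_overrides[node_id] = ovr
        nodes[node_id] = OniomNode(
            node_id=node_id, layer=layer, atom_indices=atoms, high_level=str(calc),
            charge=int(ent.get("charge", 0)), uhf=int(ent.get("uhf", 0)),
        )

    roots = [n for n in nodes.values() if n.layer == 1]
    if len(roots) != 1:
        raise PartitionError(f"expected exactly one layer-1 node, found {len(roots)}")
    root = roots[0]
    if root.atom_set != frozenset(range(system.n_atoms)):
        raise PartitionError(f"root node {root.node_id} must contain all system atoms")

    # parent inference by containment, one layer up
    by_layer: dict[int, list[OniomNode]] = {}
    for n in nodes.values():
        by_layer.setdefault(n.layer, []).append(n)
    for layer in sorted(by_layer):
        if layer == 1:
            continue
        if layer - 1 not in by_layer:
            raise PartitionError(f"layer {layer} has nodes but layer {layer - 1} has none")
        for n in by_layer[layer]:
            parents = [p for p in by_layer[layer - 1] if n.atom_set <= p.atom_set]
            if not parents:
                raise PartitionError(
                    f"node {n.node_id}: no layer-{layer - 1} node contains its atoms"
                )
            if len(parents) > 1:
                raise PartitionError(
                    f"node {n.node_id}: contained in multiple layer-{layer - 1} nodes "
                    f"{[p.node_id for p in parents]}"
                )
            parent = parents[0]
            if n.atom_set == parent.atom_set:
                raise PartitionError(
                    f"node {n.node_id}: atom set equals parent {parent.node_id}'s "
                    "(child must be a strict subset)"
                )
            n.parent = parent.node_id
            n.low_level = parent.high_level
            parent.children.append(n.node_id)

    for layer, members in by_layer.items():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                overlap = members[a].atom_set & members[b].atom_set
                if members[a].parent == members[b].parent and overlap:
                    raise PartitionError(
                        f"sibling nodes {members[a].node_id} and {members[b].node_id} "
                        f"share atoms {sorted(i + 1 for i in overlap)}"
                    )

    tree = OniomTree(nodes=nodes, root_id=root.node_id,
                     system=AtomicSystem(
                         elements=list(system.elements), coords=system.coords,
                         masses=system.masses, topology=topo, name=system.name))
    for n in nodes.values():
        n.link_atoms = _link_specs(tree.system, n.atom_set, topo,
                                   k_overrides.get(n.node_id), radii, n.node_id)
    problems = validate_tree(tree)
    if problems:
        raise PartitionError("invalid partition: " + "; ".join(problems))
    return tree


def validate_tree(tree: OniomTree) -> list[str]:
    """Diagnostics for a tree; empty list means valid.  Never mutates."""
    out: list[str] = []
    nodes = tree.nodes
    if tree.root_id not in nodes:
        return [f"root id {tree.root_id!r} not among nodes"]
    root = nodes[tree.root_id]
    all_atoms = frozenset(range(tree.system.n_atoms))
    if root.layer != 1:
        out.append(f"root {root.node_id} has layer {root.layer}, expected 1")
    if root.parent is not None:
        out.append(f"root {root.node_id} has a parent")
    if root.atom_set != all_atoms:
        out.append(f"root {root.node_id} does not cover all {len(all_atoms)} atoms")

    # reachability / acyclicity from the root
    seen: set[str] = set()
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        if nid in seen:
            out.append(f"cycle detected at node {nid} (acyclicity violated)")
            break
        seen.add(nid)
        stack.extend(nodes[nid].children if nid in nodes else [])
    unreachable = set(nodes) - seen
    if unreachable:
        out.append(f"nodes unreachable from root: {sorted(unreachable)}")

    for n in nodes.values():
        if n.parent is not None:
            if n.parent not in nodes:
                out.append(f"node {n.node_id}: parent {n.parent!r} does not exist")
                continue
            p = nodes[n.parent]
            if n.node_id not in p.children:
                out.append(f"node {n.node_id}: not listed among parent {p.node_id}'s children")
            if n.layer != p.layer + 1:
                out.append(
                    f"node {n.node_id}: layer {n.layer} != parent layer {p.layer} + 1 "
                    "(layer monotonicity violated)"
                )
            if not n.atom_set < p.atom_set:
                out.append(f"node {n.node_id}: atoms not a strict subset of parent {p.node_id}")
            if n.low_level != p.high_level:
                out.append(
                    f"node {n.node_id}: low level {n.low_level!r} != parent high level "
                    f"{p.high_level!r}"
                )
        elif n.node_id != tree.root_id:
            out.append(f"node {n.node_id}: non-root without a parent")
        for c1 in range(len(n.children)):
            for c2 in range(c1 + 1, len(n.children)):
                a, b = nodes.get(n.children[c1]), nodes.get(n.children[c2])
                if a and b and (a.atom_set & b.atom_set):
                    out.append(f"siblings {a.node_id} and {b.node_id} overlap")
        for link in n.link_atoms:
            if link.host not in n.atom_set:
                out.append(f"node {n.node_id}: link host {link.host + 1} outside fragment")
            if link.partner in n.atom_set:
                out.append(f"node {n.node_id}: link partner {link.partner + 1} inside fragment")
            if not math.isfinite(link.k) or link.k <= 0:
                out.append(f"node {n.node_id}: bad link scale factor {link.k}")
    return out
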