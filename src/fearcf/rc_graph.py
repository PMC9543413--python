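"""Reaction coordinates as directed, colored graphs over atomic coordinates.

A reaction coordinate (RC) is a scalar function of Cartesian atom positions
built from a small vocabulary of node kinds:

    atom_point      leaf; the position of one atom
    center_of_mass  mass-weighted mean of point-like parents
    vector          head - tail of two point-like parents
    cross_vector    cross product of two vector parents (a plane normal)
    distance        |head - tail| between two point-like parents   [Å]
    angle           angle between two vector parents               [deg]
    dihedral        angle between two cross_vector normals sharing
                    a common axis vector                           [deg]

Values flow bottom-up from atoms to RC nodes (forward pass); biasing-force
derivatives flow top-down from RC nodes back to atoms (reverse pass), each
edge multiplying in its local partial derivative, so that the force on an
atom is the sum over graph paths of the products of edge derivatives.

All evaluation routines are batched: positions may have any leading shape
``(..., n_atoms, 3)`` and every per-node quantity broadcasts over it.
External angle units are degrees; internally radians are used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

RAD2DEG = 180.0 / math.pi
DEG2RAD = math.pi / 180.0

POINT_KINDS = {"atom_point", "center_of_mass"}
VECTOR_KINDS = {"vector", "cross_vector"}
SCALAR_KINDS = {"distance", "angle", "dihedral"}
KINDS = POINT_KINDS | VECTOR_KINDS | SCALAR_KINDS

#: below this norm (Å) a vector entering an angle/dihedral is considered
#: degenerate: the step's derivative contribution is zeroed and a warning
#: logged, rather than aborting a running replica.
DEGENERATE_NORM = 1e-8

_ARITY = {
    "atom_point": 0,
    "vector": 2,
    "cross_vector": 2,
    "distance": 2,
    "angle": 2,
    "dihedral": 2,
}


class GraphError(ValueError):
    """Raised for invalid reaction-coordinate graph specifications."""


@dataclass
class RCNode:
    """One node of a reaction-coordinate graph."""

    id: int
    name: str
    kind: str
    parents: tuple[int, ...] = ()
    atom_index: int | None = None          # atom_point only
    weights: np.ndarray | None = None      # center_of_mass only, sums to 1
    convention: str = "arccos"             # dihedral only: arccos | signed

    @property
    def dim(self) -> int:
        return 1 if self.kind in SCALAR_KINDS else 3


@dataclass
class RCGraph:
    """Validated RC graph with adjacency matrix and cached derivative paths.

    ``rc_node_ids`` orders the scalar RC nodes ξ_1..ξ_d; ``adjacency`` is the
    symmetric 0/1 node-node matrix A; ``derivative_paths[(rc, atom)]`` lists
    every node-id path from an RC node down to an atom_point leaf.
    """

    nodes: list[RCNode]
    rc_node_ids: list[int]
    adjacency: np.ndarray
    derivative_paths: dict[tuple[int, int], list[tuple[int, ...]]]
    name_to_id: dict[str, int]
    n_atoms: int
    _topo_order: list[int] = field(default_factory=list)

    @property
    def ndim(self) -> int:
        return len(self.rc_node_ids)

    @property
    def rc_names(self) -> list[str]:
        return [self.nodes[i].name for i in self.rc_node_ids]

    @property
    def rc_kinds(self) -> list[str]:
        return [self.nodes[i].kind for i in self.rc_node_ids]

    # -- convenience wrappers -------------------------------------------
    def evaluate(self, positions):
        return evaluate(self, positions)

    def forward_values(self, positions):
        return forward_values(self, positions)

    def jacobian(self, positions):
        return jacobian(self, positions)

    def propagate_forces(self, positions, dW_dxi, vals=None):
        return propagate_forces(self, positions, dW_dxi, vals=vals)

    def adjacency_dump(self) -> str:
        """Adjacency matrix as a plain-text block for inspection."""
        lines = ["# nodes: " + " ".join(f"{n.id}:{n.name}({n.kind})" for n in self.nodes)]
        for row in self.adjacency:
            lines.append(" ".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_graph(spec: dict) -> RCGraph:
    """Build and validate an :class:`RCGraph` from a declarative spec.

    Parameters
    ----------
    spec : dict with keys
        ``nodes`` : mapping name -> {kind, parents: [names], atom: int,
        weights|masses: [float], convention: str}; ``rcs`` : ordered list of
        RC node names (must be scalar kinds).

    Raises
    ------
    GraphError
        on cycles, arity violations, unknown atom indices, non-scalar RC
        nodes, or dangling references.
    """
    node_specs = spec.get("nodes")
    rc_names = spec.get("rcs")
    if not node_specs or not rc_names:
        raise GraphError("graph spec needs 'nodes' and 'rcs'")

    names = list(node_specs)
    name_to_id = {nm: i for i, nm in enumerate(names)}
    nodes: list[RCNode] = []
    for nm in names:
        ns = dict(node_specs[nm])
        kind = ns.get("kind")
        if kind not in KINDS:
            raise GraphError(f"node {nm!r}: unknown kind {kind!r}")
        parent_names = ns.get("parents", [])
        for p in parent_names:
            if p not in name_to_id:
                raise GraphError(f"node {nm!r}: unknown parent {p!r}")
        parents = tuple(name_to_id[p] for p in parent_names)
        atom_index = ns.get("atom")
        weights = None
        if kind == "atom_point":
            if atom_index is None or atom_index < 0:
                raise GraphError(f"atom_point {nm!r} needs a non-negative 'atom' index")
        elif kind == "center_of_mass":
            if len(parents) < 1:
                raise GraphError(f"center_of_mass {nm!r} needs >=1 parents")
            w = ns.get("weights")
            if w is None and "masses" in ns:
                m = np.asarray(ns["masses"], float)
                if np.any(m <= 0):
                    raise GraphError(f"center_of_mass {nm!r}: nonpositive mass")
                w = m / m.sum()
            if w is None:
                raise GraphError(f"center_of_mass {nm!r} needs 'weights' or 'masses'")
            weights = np.asarray(w, float)
            if len(weights) != len(parents) or np.any(weights <= 0):
                raise GraphError(f"center_of_mass {nm!r}: bad weights")
            weights = weights / weights.sum()
        else:
            if len(parents) != _ARITY[kind]:
                raise GraphError(
                    f"node {nm!r}: kind {kind} takes {_ARITY[kind]} parents, "
                    f"got {len(parents)}")
        nodes.append(RCNode(
            id=name_to_id[nm], name=nm, kind=kind, parents=parents,
            atom_index=atom_index, weights=weights,
            convention=ns.get("convention", "arccos"),
        ))

    _validate_kinds(nodes)
    topo = _toposort(nodes)

    rc_ids = []
    for nm in rc_names:
        if nm not in name_to_id:
            raise GraphError(f"RC node {nm!r} not defined")
        node = nodes[name_to_id[nm]]
        if node.kind not in SCALAR_KINDS:
            raise GraphError(f"RC node {nm!r} has non-scalar kind {node.kind!r}")
        rc_ids.append(node.id)

    n = len(nodes)
    A = np.zeros((n, n), dtype=int)
    for node in nodes:
        for p in node.parents:
            A[node.id, p] = A[p, node.id] = 1

    paths: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for rc in rc_ids:
        for path in _enumerate_paths(nodes, rc):
            atom = path[-1]
            paths.setdefault((rc, atom), []).append(path)
        if not any(k[0] == rc for k in paths):
            raise GraphError(f"RC node {nodes[rc].name!r} reaches no atom_point")

    n_atoms = 1 + max(nd.atom_index for nd in nodes if nd.kind == "atom_point")
    return RCGraph(nodes=nodes, rc_node_ids=rc_ids, adjacency=A,
                   derivative_paths=paths, name_to_id=name_to_id,
                   n_atoms=n_atoms, _topo_order=topo)


def _validate_kinds(nodes: list[RCNode]) -> None:
    for node in nodes:
        kinds = [nodes[p].kind for p in node.parents]
        if node.kind in ("vector", "distance"):
            if not all(k in POINT_KINDS for k in kinds):
                raise GraphError(f"node {node.name!r}: parents must be point-like")
        elif node.kind == "center_of_mass":
            if not all(k == "atom_point" for k in kinds):
                raise GraphError(f"COM {node.name!r}: parents must be atom_points")
        elif node.kind in ("cross_vector", "angle"):
            if not all(k in VECTOR_KINDS for k in kinds):
                raise GraphError(f"node {node.name!r}: parents must be vectors")
        elif node.kind == "dihedral":
            if not all(k == "cross_vector" for k in kinds):
                raise GraphError(
                    f"dihedral {node.name!r}: parents must be two cross_vectors")
            m, n = (nodes[p] for p in node.parents)
            shared = set(m.parents) & set(n.parents)
            if len(shared) != 1:
                raise GraphError(
                    f"dihedral {node.name!r}: normals must share one axis vector")
            if node.convention not in ("arccos", "signed"):
                raise GraphError(f"dihedral {node.name!r}: bad convention")


def _toposort(nodes: list[RCNode]) -> list[int]:
    order: list[int] = []
    state = [0] * len(nodes)  # 0 unvisited, 1 in-stack, 2 done

    def visit(i: int, stack: list[int]) -> None:
        if state[i] == 2:
            return
        if state[i] == 1:
            cyc = " -> ".join(nodes[j].name for j in stack + [i])
            raise GraphError(f"cycle detected: {cyc}")
        state[i] = 1
        for p in nodes[i].parents:
            visit(p, stack + [i])
        state[i] = 2
        order.append(i)

    for i in range(len(nodes)):
        visit(i, [])
    for i in order:
        if nodes[i].kind != "atom_point" and not nodes[i].parents:
            raise GraphError(f"non-atom node {nodes[i].name!r} has no parents")
    return order


def _enumerate_paths(nodes, start: int):
    """All root→leaf paths from ``start`` down to atom_point nodes."""
    node = nodes[start]
    if node.kind == "atom_point":
        yield (start,)
        return
    for p in node.parents:
        for tail in _enumerate_paths(nodes, p):
            yield (start,) + tail


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def center_of_mass(points, masses):
    """Mass-weighted mean Σ m_i x_i / Σ m_i of ``points`` (..., n, 3)."""
    m = np.asarray(masses, float)
    if np.any(m <= 0):
        raise ValueError("nonpositive mass")
    pts = np.asarray(points, float)
    return np.einsum("...ij,i->...j", pts, m) / m.sum()


def _norm(v):
    return np.sqrt(np.einsum("...i,...i->...", v, v))


def _forward(graph: RCGraph, positions):
    """Evaluate every node bottom-up; returns {node_id: value array}."""
    x = np.asarray(positions, float)
    if x.shape[-2] < graph.n_atoms:
        raise ValueError(
            f"positions provide {x.shape[-2]} atoms, graph needs {graph.n_atoms}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinate")
    vals: dict[int, np.ndarray] = {}
    for i in graph._topo_order:
        node = graph.nodes[i]
        k = node.kind
        if k == "atom_point":
            vals[i] = x[..., node.atom_index, :]
        elif k == "center_of_mass":
            pts = np.stack([vals[p] for p in node.parents], axis=-2)
            vals[i] = np.einsum("...ij,i->...j", pts, node.weights)
        elif k == "vector":
            tail, head = node.parents
            vals[i] = vals[head] - vals[tail]
        elif k == "cross_vector":
            a, b = node.parents
            vals[i] = np.cross(vals[a], vals[b])
        elif k == "distance":
            tail, head = node.parents
            vals[i] = _norm(vals[head] - vals[tail])
        elif k == "angle":
            a, b = node.parents
            vals[i] = _angle_between(vals[a], vals[b]) * RAD2DEG
        elif k == "dihedral":
            m_id, n_id = node.parents
            phi = _angle_between(vals[m_id], vals[n_id])
            if node.convention == "signed":
                axis_id = _dihedral_axis(graph, node)
                s = np.einsum("...i,...i->...",
                              np.cross(vals[m_id], vals[n_id]), vals[axis_id])
                phi = np.where(s < 0.0, 2.0 * math.pi - phi, phi)
            vals[i] = phi * RAD2DEG
    return vals


def _angle_between(a, b):
    na, nb = _norm(a), _norm(b)
    denom = np.where((na < DEGENERATE_NORM) | (nb < DEGENERATE_NORM), 1.0, na * nb)
    c = np.einsum("...i,...i->...", a, b) / denom
    return np.arccos(np.clip(c, -1.0, 1.0))


def _dihedral_axis(graph: RCGraph, node: RCNode) -> int:
    m, n = (graph.nodes[p] for p in node.parents)
    (axis,) = set(m.parents) & set(n.parents)
    return axis


def evaluate(graph: RCGraph, positions) -> np.ndarray:
    """RC values ξ (..., d): distances in Å, angles/dihedrals in degrees."""
    vals = _forward(graph, positions)
    return np.stack([vals[i] for i in graph.rc_node_ids], axis=-1)


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def _backward(graph: RCGraph, vals, seeds: dict[int, np.ndarray], batch_shape):
    """Reverse-sweep adjoint accumulation.

    ``seeds`` maps RC node ids to scalar adjoints (∂target/∂ξ_i, external
    units).  Returns per-atom adjoints, shape ``batch_shape + (n_atoms, 3)``.
    """
    adj: dict[int, np.ndarray] = {}

    def add(i, contrib):
        if i in adj:
            adj[i] = adj[i] + contrib
        else:
            adj[i] = contrib

    for i, g in seeds.items():
        add(i, np.asarray(g, float))

    out = np.zeros(batch_shape + (graph.n_atoms, 3))
    for i in reversed(graph._topo_order):
        if i not in adj:
            continue
        node = graph.nodes[i]
        g = adj[i]
        k = node.kind
        if k == "atom_point":
            out[..., node.atom_index, :] += g
        elif k == "center_of_mass":
            for p, w in zip(node.parents, node.weights):
                add(p, w * g)
        elif k == "vector":
            tail, head = node.parents
            add(head, g)
            add(tail, -g)
        elif k == "cross_vector":
            a, b = node.parents
            add(a, np.cross(vals[b], g))
            add(b, np.cross(g, vals[a]))
        elif k == "distance":
            tail, head = node.parents
            d = vals[head] - vals[tail]
            r = _norm(d)
            bad = r < DEGENERATE_NORM
            if np.any(bad):
                log.warning("degenerate distance node %r; zeroing derivative",
                            node.name)
            u = d / np.where(bad, 1.0, r)[..., None]
            gu = np.where(bad, 0.0, g)[..., None] * u
            add(head, gu)
            add(tail, -gu)
        elif k == "angle":
            a, b = node.parents
            ga, gb = _angle_partials(vals[a], vals[b], node.name)
            gr = (g * RAD2DEG)[..., None]
            add(a, gr * ga)
            add(b, gr * gb)
        elif k == "dihedral":
            _dihedral_backward(graph, node, vals, g, add)
    return out


def _angle_partials(a, b, name):
    """(∂θ/∂a, ∂θ/∂b) for θ = arccos(â·b̂), radians; zeroed when degenerate."""
    na, nb = _norm(a), _norm(b)
    bad = (na < DEGENERATE_NORM) | (nb < DEGENERATE_NORM)
    na_s = np.where(bad, 1.0, na)
    nb_s = np.where(bad, 1.0, nb)
    ah = a / na_s[..., None]
    bh = b / nb_s[..., None]
    c = np.clip(np.einsum("...i,...i->...", ah, bh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    sing = s < 1e-9
    bad = bad | sing
    if np.any(bad):
        log.warning("degenerate geometry at angle node %r; zeroing derivative",
                    name)
    s_safe = np.where(bad, 1.0, s)[..., None]
    zero = bad[..., None]
    ga = np.where(zero, 0.0, -(bh - c[..., None] * ah) / (na_s[..., None] * s_safe))
    gb = np.where(zero, 0.0, -(ah - c[..., None] * bh) / (nb_s[..., None] * s_safe))
    return ga, gb


def _dihedral_backward(graph, node, vals, g, add):
    """Distribute a dihedral adjoint to parent nodes.

    arccos convention: treated like an angle between the two normals.
    signed convention: the smooth torsion-gradient formulas are used,
    sending derivatives directly to the three base vectors (u, axis v, w) —
    the same graph paths, composed — which stays regular at φ = 0/180° where
    the arccos form is singular.
    """
    m_id, n_id = node.parents
    gr = (g * RAD2DEG)[..., None]
    if node.convention == "arccos":
        ga, gb = _angle_partials(vals[m_id], vals[n_id], node.name)
        add(m_id, gr * ga)
        add(n_id, gr * gb)
        return

    axis_id = _dihedral_axis(graph, node)
    m_node, n_node = graph.nodes[m_id], graph.nodes[n_id]
    u_id = next(p for p in m_node.parents if p != axis_id)
    w_id = next(p for p in n_node.parents if p != axis_id)
    # orient: normals are stored as m = u x v (or v x u); recompute partials
    # in terms of the base vectors with the standard torsion formulas.
    u, v, w = vals[u_id], vals[axis_id], vals[w_id]
    if m_node.parents[0] != u_id:      # m was built as v x u: flip sign via u -> -u
        u_sign = -1.0
    else:
        u_sign = 1.0
    if n_node.parents[0] != w_id:
        w_sign = -1.0
    else:
        w_sign = 1.0
    du, dv, dw = _torsion_partials(u_sign * u, v, w_sign * w)
    add(u_id, gr * (u_sign * du))
    add(axis_id, gr * dv)
    add(w_id, gr * (w_sign * dw))


def _torsion_partials(u, v, w):
    """Gradients of the signed torsion φ = atan2(((u×v)×(w×v))·v̂, (u×v)·(w×v))
    with respect to the base vectors u, v (axis), w.  Regular wherever the
    two normals are non-degenerate."""
    m = np.cross(u, v)
    n = np.cross(w, v)
    v2 = np.einsum("...i,...i->...", v, v)
    m2 = np.einsum("...i,...i->...", m, m)
    n2 = np.einsum("...i,...i->...", n, n)
    bad = (m2 < DEGENERATE_NORM**2) | (n2 < DEGENERATE_NORM**2) | (v2 < DEGENERATE_NORM**2)
    if np.any(bad):
        log.warning("degenerate geometry at dihedral node; zeroing derivative")
    m2 = np.where(bad, 1.0, m2)
    n2 = np.where(bad, 1.0, n2)
    v2 = np.where(bad, 1.0, v2)
    vn = np.sqrt(v2)
    du = (vn / m2)[..., None] * m
    dw = -(vn / n2)[..., None] * n
    uv = np.einsum("...i,...i->...", u, v)
    wv = np.einsum("...i,...i->...", w, v)
    dv = (wv / (vn * n2))[..., None] * n - (uv / (vn * m2))[..., None] * m
    zero = bad[..., None]
    return (np.where(zero, 0.0, du), np.where(zero, 0.0, dv),
            np.where(zero, 0.0, dw))


def jacobian(graph: RCGraph, positions) -> np.ndarray:
    """∂ξ/∂x, shape (..., d, n_atoms, 3), external units (deg or Å per Å)."""
    x = np.asarray(positions, float)
    vals = _forward(graph, x)
    batch = x.shape[:-2]
    rows = []
    for rc in graph.rc_node_ids:
        seed = {rc: np.ones(batch)}
        rows.append(_backward(graph, vals, seed, batch))
    return np.stack(rows, axis=-3)


def forward_values(graph: RCGraph, positions):
    """Evaluate all graph nodes once; reusable by :func:`propagate_forces`.

    Returns ``(xi, vals)`` where ``xi`` is the RC value array (..., d) and
    ``vals`` the per-node value cache.
    """
    vals = _forward(graph, positions)
    xi = np.stack([vals[i] for i in graph.rc_node_ids], axis=-1)
    return xi, vals


def propagate_forces(graph: RCGraph, positions, dW_dxi, vals=None) -> np.ndarray:
    """Atomic biasing forces F = −Σ_i (∂W/∂ξ_i)(∂ξ_i/∂x), (..., n_atoms, 3).

    ``dW_dxi`` (..., d) is in kcal/mol per external RC unit.  Forces on
    composite nodes (COMs) are distributed to their atoms by mass fraction;
    the net force over all atoms vanishes for internal coordinates.
    """
    x = np.asarray(positions, float)
    g = np.asarray(dW_dxi, float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite RC gradient")
    if vals is None:
        vals = _forward(graph, x)
    batch = x.shape[:-2]
    seeds = {rc: -g[..., i] for i, rc in enumerate(graph.rc_node_ids)}
    return _backward(graph, vals, seeds, batch)


# ---------------------------------------------------------------------------
# derivative matrix
# ---------------------------------------------------------------------------

def derivative_matrix(graph: RCGraph, positions) -> np.ndarray:
    """Edge-partial matrix D with the sparsity pattern of the adjacency A.

    ``D[i, j]`` is an ndarray of shape ``(dim_i, dim_j)`` holding ∂(node i)/
    ∂(node j) for j a parent of i (and its transpose on the mirrored entry,
    the edge being bidirectional).  The product of entries along a
    derivative path from an RC node to an atom, summed over all paths,
    equals the corresponding Jacobian row block.
    """
    x = np.asarray(positions, float)
    if x.ndim != 2:
        raise ValueError("derivative_matrix expects a single (n_atoms, 3) geometry")
    vals = _forward(graph, x)
    nn = len(graph.nodes)
    D = np.empty((nn, nn), dtype=object)
    D.fill(None)
    for node in graph.nodes:
        for slot, p in enumerate(node.parents):
            block = _local_partial(graph, node, slot, vals)
            if D[node.id, p] is None:
                D[node.id, p] = block
            else:                      # repeated parent (e.g. both slots)
                D[node.id, p] = D[node.id, p] + block
            D[p, node.id] = D[node.id, p].T
    return D


def _local_partial(graph, node, slot, vals):
    """∂(node)/∂(parents[slot]) at the evaluated geometry."""
    p = node.parents[slot]
    k = node.kind
    if k == "center_of_mass":
        return node.weights[slot] * np.eye(3)
    if k == "vector":
        return -np.eye(3) if slot == 0 else np.eye(3)
    if k == "cross_vector":
        a, b = (vals[q] for q in node.parents)
        if slot == 0:  # d(a×b)/da = -[b]x
            return -_skew(b)
        return _skew(a)
    if k == "distance":
        tail, head = node.parents
        d = vals[head] - vals[tail]
        r = max(_norm(d), DEGENERATE_NORM)
        u = (d / r)[None, :]
        return u if slot == 1 else -u
    if k in ("angle", "dihedral"):
        a, b = (vals[q] for q in node.parents)
        ga, gb = _angle_partials(a, b, node.name)
        grad = ga if slot == 0 else gb
        if k == "dihedral" and node.convention == "signed":
            axis_id = _dihedral_axis(graph, node)
            s = np.einsum("i,i->", np.cross(vals[node.parents[0]],
                                            vals[node.parents[1]]), vals[axis_id])
            if s < 0:
                grad = -grad
        return RAD2DEG * grad[None, :]
    raise GraphError(f"node kind {k!r} has no parents")


def _skew(v):
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def path_product_jacobian(graph: RCGraph, positions) -> np.ndarray:
    """Jacobian ∂ξ/∂x assembled purely from derivative-matrix path products.

    Independent route to the same quantity as :func:`jacobian`; used to show
    the sum-over-paths-of-edge-products identity.
    """
    x = np.asarray(positions, float)
    D = derivative_matrix(graph, x)
    J = np.zeros((graph.ndim, graph.n_atoms, 3))
    for i, rc in enumerate(graph.rc_node_ids):
        for (r, atom), paths in graph.derivative_paths.items():
            if r != rc:
                continue
            ai = graph.nodes[atom].atom_index
            for path in paths:
                block = np.eye(1)
                for a, b in zip(path[:-1], path[1:]):
                    block = block @ D[a, b]
                J[i, ai, :] += block[0]
    return J


# ---------------------------------------------------------------------------
# water-dimer presets
# ---------------------------------------------------------------------------

def water_dimer_graph(ndim: int, masses=None) -> RCGraph:
    """The 1D, 2D or 4D water-dimer RC graph.

    Atom order: O1 H11 H12 O2 H21 H22 (indices 0..5).

    * 1D: ξ = O–O distance r.
    * 2D: ξ = (COM–COM distance r, angle φ between the two oxygen→COM
      dipole-proxy vectors b1, b2).
    * 4D: ξ = (r, θ1, θ2, φ) with θ_i the angle between b_i and the
      intermolecular vector r⃗, and φ the torsion between the plane normals
      m = b1×r⃗ and n = b2×r⃗ (signed convention, [0°, 360°)).
    """
    from .constants import MASS_H, MASS_O
    if masses is None:
        masses = [MASS_O, MASS_H, MASS_H]
    if ndim == 1:
        return build_graph({
            "nodes": {
                "O1": {"kind": "atom_point", "atom": 0},
                "O2": {"kind": "atom_point", "atom": 3},
                "r": {"kind": "distance", "parents": ["O1", "O2"]},
            },
            "rcs": ["r"],
        })
    atoms = {
        "O1": {"kind": "atom_point", "atom": 0},
        "H11": {"kind": "atom_point", "atom": 1},
        "H12": {"kind": "atom_point", "atom": 2},
        "O2": {"kind": "atom_point", "atom": 3},
        "H21": {"kind": "atom_point", "atom": 4},
        "H22": {"kind": "atom_point", "atom": 5},
    }
    coms = {
        "W1": {"kind": "center_of_mass", "parents": ["O1", "H11", "H12"],
               "masses": masses},
        "W2": {"kind": "center_of_mass", "parents": ["O2", "H21", "H22"],
               "masses": masses},
    }
    if ndim == 2:
        return build_graph({
            "nodes": {
                **atoms, **coms,
                "b1": {"kind": "vector", "parents": ["O1", "W1"]},
                "b2": {"kind": "vector", "parents": ["O2", "W2"]},
                "r": {"kind": "distance", "parents": ["W1", "W2"]},
                "phi": {"kind": "angle", "parents": ["b1", "b2"]},
            },
            "rcs": ["r", "phi"],
        })
    if ndim == 4:
        return build_graph({
            "nodes": {
                **atoms, **coms,
                "rvec": {"kind": "vector", "parents": ["W1", "W2"]},
                "b1": {"kind": "vector", "parents": ["O1", "W1"]},
                "b2": {"kind": "vector", "parents": ["O2", "W2"]},
                "m": {"kind": "cross_vector", "parents": ["b1", "rvec"]},
                "n": {"kind": "cross_vector", "parents": ["b2", "rvec"]},
                "r": {"kind": "distance", "parents": ["W1", "W2"]},
                "theta1": {"kind": "angle", "parents": ["b1", "rvec"]},
                "theta2": {"kind": "angle", "parents": ["b2", "rvec"]},
                "phi": {"kind": "dihedral", "parents": ["m", "n"],
                        "convention": "signed"},
            },
            "rcs": ["r", "theta1", "theta2", "phi"],
        })
    raise ValueError("ndim must be 1, 2 or 4")
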