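"""Minimal frequency-domain linear elastodynamics on 8-node hexahedra.

Solves (K(1 + iη) − ω²M) u = F for the complex nodal displacement phasor u
of a damped structure under a harmonic point-mass load — the discretized
harmonic-response problem behind the toy temporal-bone model.  Features:

* trilinear hex8 elements, 2×2×2 Gauss quadrature, isotropic materials;
* rate-independent hysteretic damping via a complex modulus E(1 + iη),
  η per material;
* consistent element mass plus lumped surface mass density (soft-tissue
  loading) and a lumped concentrated mass split over an attachment node set
  (the implant);
* the harmonic force distributed equally over the attachment nodes along a
  unit direction;
* homogeneous Dirichlet conditions (all DOFs) on a fixed node set,
  eliminating rigid-body modes;
* one sparse complex LU factorization per frequency, reused across force
  directions.

Internal units are SI (m, kg, s, Pa, N); mesh builders accept mm and convert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger("bcdirect")


class FEError(ValueError):
    pass


# ---------------------------------------------------------------- materials

@dataclass(frozen=True)
class Material:
    """Isotropic linear material: E (Pa), Poisson ratio, density (kg/m³),
    hysteretic loss factor η (dimensionless, default 0.05)."""

    E: float
    nu: float
    rho: float
    eta: float = 0.05

    def __post_init__(self) -> None:
        if self.E <= 0 or self.rho <= 0:
            raise FEError("material needs positive E and rho")
        if not (-1.0 < self.nu < 0.5):
            raise FEError(f"Poisson ratio {self.nu} outside (-1, 0.5)")
        if self.eta < 0:
            raise FEError("loss factor must be non-negative")

    @property
    def D(self) -> np.ndarray:
        """6×6 isotropic elasticity matrix (Voigt order xx,yy,zz,xy,yz,zx)."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


# ------------------------------------------------------------------- model

@dataclass
class FEModel:
    """Hex8 finite-element model.

    nodes: (n, 3) coordinates, meters.  elements: (E, 8) connectivity in the
    standard hex ordering (bottom face CCW, then top face).  material_ids
    maps each element into ``materials``.  surface_masses carries
    (quad faces, density kg/m²) pairs lumped onto face nodes.  The
    attachment (mass_kg, node ids) models a concentrated implant mass tied
    to a circle of surface nodes; the harmonic force acts there.
    """

    nodes: np.ndarray
    elements: np.ndarray
    material_ids: np.ndarray
    materials: Mapping[int, Material]
    fixed_nodes: np.ndarray
    attachment_mass_kg: float
    attachment_nodes: np.ndarray
    surface_masses: list = field(default_factory=list)
    node_sets: dict = field(default_factory=dict)
    face_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self.material_ids = np.asarray(self.material_ids, dtype=int)
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=int))
        self.attachment_nodes = np.unique(np.asarray(self.attachment_nodes, dtype=int))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise FEError(f"nodes must be (n, 3), got {self.nodes.shape}")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise FEError(f"elements must be (E, 8), got {self.elements.shape}")
        if self.material_ids.shape != (len(self.elements),):
            raise FEError("one material id per element required")
        missing = set(np.unique(self.material_ids)) - set(self.materials)
        if missing:
            raise FEError(f"material ids {sorted(missing)} undefined")
        used = np.unique(self.elements)
        if used.size != len(self.nodes) or used[0] != 0 or used[-1] != len(self.nodes) - 1:
            raise FEError("orphan nodes: every node must belong to an element")
        if self.fixed_nodes.size == 0:
            raise FEError("fixed node set is empty (rigid modes unconstrained)")
        if self.attachment_nodes.size == 0:
            raise FEError("attachment node set is empty")
        if self.attachment_mass_kg < 0:
            raise FEError("attachment mass must be non-negative")

    @property
    def n_dof(self) -> int:
        return 3 * len(self.nodes)

    def content_hash(self) -> str:
        """Deterministic hash of the model content (geometry, sets, materials)."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.nodes, self.elements, self.material_ids,
                    self.fixed_nodes, self.attachment_nodes):
            h.update(np.ascontiguousarray(arr).tobytes())
        for mid in sorted(self.materials):
            m = self.materials[mid]
            h.update(repr((mid, m.E, m.nu, m.rho, m.eta)).encode())
        for faces, dens in self.surface_masses:
            h.update(np.ascontiguousarray(faces).tobytes())
            h.update(repr(float(dens)).encode())
        h.update(repr(float(self.attachment_mass_kg)).encode())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(np.sort(self.node_sets[name])).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class HarmonicLoad:
    """Harmonic point load: amplitude (N, > 0), unit direction (global),
    frequency (Hz, ≥ 0)."""

    amplitude: float
    direction: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise FEError("load direction must be a unit 3-vector")
        object.__setattr__(self, "direction", d)
        if self.amplitude <= 0:
            raise FEError("force amplitude must be positive")
        if self.frequency < 0:
            raise FEError("frequency must be non-negative")


@dataclass(frozen=True)
class HarmonicField:
    """Complex nodal displacement phasors (n, 3), meters, for one
    (direction, frequency) pair."""

    u: np.ndarray
    frequency: float
    direction: np.ndarray

    @property
    def u_mm(self) -> np.ndarray:
        return self.u * 1e3


# ------------------------------------------------------------- hex8 basics

# local corner coordinates, standard ordering
_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
_G = 1.0 / np.sqrt(3.0)
_GAUSS = _XI * _G  # 2×2×2 points share the corner pattern


def _shape(pt: np.ndarray) -> np.ndarray:
    """Trilinear shape values at one local point, (8,)."""
    return 0.125 * np.prod(1.0 + _XI * pt, axis=1)


def _dshape(pt: np.ndarray) -> np.ndarray:
    """Local gradients dN/dξ at one local point, (8, 3)."""
    x, y, z = pt
    d = np.empty((8, 3))
    d[:, 0] = 0.125 * _XI[:, 0] * (1 + _XI[:, 1] * y) * (1 + _XI[:, 2] * z)
    d[:, 1] = 0.125 * _XI[:, 1] * (1 + _XI[:, 0] * x) * (1 + _XI[:, 2] * z)
    d[:, 2] = 0.125 * _XI[:, 2] * (1 + _XI[:, 0] * x) * (1 + _XI[:, 1] * y)
    return d


# ---------------------------------------------------------------- assembly

@dataclass
class Operators:
    """Assembled complex stiffness K* = K(1+iη) and real mass M (CSR),
    restricted bookkeeping for the fixed set."""

    K: sp.csr_matrix          # complex
    M: sp.csr_matrix          # real
    free: np.ndarray          # free dof indices
    n_dof: int


def _element_matrices(coords: np.ndarray, mat: Material):
    """Stiffness (24×24) and consistent mass for one element; checks det J > 0.

    Returns (Ke, Me, volume)."""
    D = mat.D
    Ke = np.zeros((24, 24))
    Me = np.zeros((24, 24))
    vol = 0.0
    for gp in _GAUSS:
        dN = _dshape(gp)                       # (8, 3)
        J = dN.T @ coords                      # (3, 3)
        detJ = np.linalg.det(J)
        if detJ <= 0:
            raise FEError("inverted element (non-positive Jacobian)")
        gradN = dN @ np.linalg.inv(J).T        # (8, 3) cartesian gradients
        B = np.zeros((6, 24))
        B[0, 0::3] = gradN[:, 0]
        B[1, 1::3] = gradN[:, 1]
        B[2, 2::3] = gradN[:, 2]
        B[3, 0::3] = gradN[:, 1]
        B[3, 1::3] = gradN[:, 0]
        B[4, 1::3] = gradN[:, 2]
        B[4, 2::3] = gradN[:, 1]
        B[5, 0::3] = gradN[:, 2]
        B[5, 2::3] = gradN[:, 0]
        Ke += B.T @ D @ B * detJ
        N = _shape(gp)
        NN = np.outer(N, N) * (mat.rho * detJ)
        for k in range(3):
            Me[k::3, k::3] += NN
        vol += detJ
    return Ke, Me, vol


def assemble(model: FEModel) -> Operators:
    """Assemble the complex stiffness and mass operators.

    Element stiffness matrices are scaled by (1 + iη) of their material
    (hysteretic damping).  The mass operator collects consistent element
    mass, surface-density mass lumped in equal thirds onto face-triangle
    nodes, and the attachment mass split equally over its node set.  Both
    operators are symmetric.  Identical elements (same geometry up to
    translation and material) share one element matrix, which makes
    structured toy meshes cheap to assemble.
    """
    n = model.n_dof
    rows, cols = [], []
    kdata, mdata = [], []
    cache: dict = {}
    for e, conn in enumerate(model.elements):
        coords = model.nodes[conn]
        mat = model.materials[int(model.material_ids[e])]
        key = (
            int(model.material_ids[e]),
            tuple(np.round((coords - coords[0]).ravel(), 12)),
        )
        if key not in cache:
            try:
                cache[key] = _element_matrices(coords, mat)
            except FEError as err:
                raise FEError(f"element {e}: {err}") from None
        Ke, Me, _ = cache[key]
        dofs = (3 * conn[:, None] + np.arange(3)[None, :]).ravel()
        r = np.repeat(dofs, 24)
        c = np.tile(dofs, 24)
        rows.append(r)
        cols.append(c)
        kdata.append((Ke * (1.0 + 1j * mat.eta)).ravel())
        mdata.append(Me.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = sp.coo_matrix(
        (np.concatenate(kdata), (rows, cols)), shape=(n, n)
    ).tocsr()
    M = sp.coo_matrix(
        (np.concatenate(mdata), (rows, cols)), shape=(n, n)
    ).tocsr()

    # lumped extra masses on the diagonal
    lump = np.zeros(n)
    for faces, density in model.surface_masses:
        faces = np.asarray(faces, dtype=int)
        for f in faces:
            for tri in ((f[0], f[1], f[2]), (f[0], f[2], f[3])):
                a = 0.5 * np.linalg.norm(
                    np.cross(model.nodes[tri[1]] - model.nodes[tri[0]],
                             model.nodes[tri[2]] - model.nodes[tri[0]])
                )
                for nid in tri:
                    for k in range(3):
                        lump[3 * nid + k] += density * a / 3.0
    if model.attachment_mass_kg > 0:
        share = model.attachment_mass_kg / len(model.attachment_nodes)
        for nid in model.attachment_nodes:
            lump[3 * nid : 3 * nid + 3] += share
    if lump.any():
        M = (M + sp.diags(lump)).tocsr()

    fixed_dofs = (3 * model.fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    return Operators(K=K, M=M, free=free, n_dof=n)


def total_mass(ops: Operators) -> float:
    """Total translational mass along one axis (row sums of M over x-DOFs)."""
    return float(ops.M[0::3, :].sum())


def load_vector(model: FEModel, load: HarmonicLoad) -> np.ndarray:
    """Force split equally over the attachment nodes along the direction."""
    F = np.zeros(model.n_dof, dtype=complex)
    share = load.amplitude / len(model.attachment_nodes)
    for nid in model.attachment_nodes:
        F[3 * nid : 3 * nid + 3] = share * load.direction
    return F


class FrequencySolver:
    """LU factorization of (K* − ω²M) on the free DOFs at one frequency,
    reusable across right-hand sides (force directions)."""

    def __init__(self, model: FEModel, ops: Operators, frequency: float):
        self.model = model
        self.ops = ops
        self.frequency = float(frequency)
        w = 2.0 * np.pi * self.frequency
        A = (ops.K - (w * w) * ops.M).tocsc()[ops.free][:, ops.free]
        try:
            self._lu = spla.splu(A.astype(complex))
        except RuntimeError as err:
            raise FEError(f"singular system at {frequency} Hz: {err}") from None

    def solve(self, F: np.ndarray) -> HarmonicField:
        u = np.zeros(self.ops.n_dof, dtype=complex)
        u[self.ops.free] = self._lu.solve(F[self.ops.free])
        if not np.all(np.isfinite(u.view(float))):
            raise FEError(f"non-finite response at {self.frequency} Hz")
        return HarmonicField(
            u=u.reshape(-1, 3), frequency=self.frequency, direction=np.zeros(3)
        )


def solve_harmonic(
    model: FEModel, load: HarmonicLoad, ops: Operators | None = None
) -> HarmonicField:
    """Single harmonic solve; at f = 0 and η = 0 this is the static solution."""
    if ops is None:
        ops = assemble(model)
    solver = FrequencySolver(model, ops, load.frequency)
    fld = solver.solve(load_vector(model, load))
    return HarmonicField(u=fld.u, frequency=load.frequency, direction=load.direction)


def sweep(
    model: FEModel,
    directions: Sequence[np.ndarray],
    frequencies: Sequence[float],
    amplitude: float = 0.1,
    ops: Operators | None = None,
) -> Iterator[tuple[int, float, HarmonicField]]:
    """Yield (direction index, frequency, field) for a full sweep.

    Frequencies are the outer loop so each factorization is reused for all
    force directions; output order is frequency-major.  Deterministic given
    the model and inputs.
    """
    if ops is None:
        ops = assemble(model)
    dirs = [np.asarray(d, dtype=float) for d in directions]
    for f in frequencies:
        solver = FrequencySolver(model, ops, f)
        for i, d in enumerate(dirs):
            F = load_vector(model, HarmonicLoad(amplitude=amplitude, direction=d, frequency=f))
            fld = solver.solve(F)
            yield i, float(f), HarmonicField(u=fld.u, frequency=float(f), direction=d)


# ------------------------------------------------------------ mesh helpers

def box_mesh(
    n: tuple[int, int, int], size_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
):
    """Structured hex mesh of a box; returns (nodes_m (N,3), elements (E,8),
    index lookup (i,j,k) → node id).  Input dimensions in mm, output meters."""
    nx, ny, nz = n
    lx, ly, lz = (s * 1e-3 for s in size_mm)
    ox, oy, oz = (s * 1e-3 for s in origin_mm)
    xs = np.linspace(ox, ox + lx, nx + 1)
    ys = np.linspace(oy, oy + ly, ny + 1)
    zs = np.linspace(oz, oz + lz, nz + 1)
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    elems = np.empty((nx * ny * nz, 8), dtype=int)
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems[e] = (
                    nid[i, j, k], nid[i + 1, j, k], nid[i + 1, j + 1, k], nid[i, j + 1, k],
                    nid[i, j, k + 1], nid[i + 1, j, k + 1], nid[i + 1, j + 1, k + 1],
                    nid[i, j + 1, k + 1],
                )
                e += 1
    return nodes, elems, nid
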