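"""Tetrahedral head meshes and synthetic concentric-sphere head models.

A head model is a labelled tetrahedral mesh (nodes in metres, per-element
tissue label) plus a set of pointwise scalp electrodes.  Synthetic four-layer
sphere models (brain / CSF / skull / scalp) are generated from quasi-uniform
Fibonacci-lattice nodes on concentric shells, tetrahedralized with a Delaunay
triangulation (the domain is a ball, hence convex, so the Delaunay complex
fills it exactly), and labelled by centroid radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "BRAIN",
    "CSF",
    "SKULL",
    "SCALP",
    "TISSUE_NAMES",
    "HeadMesh",
    "ElectrodeSet",
    "ConductivityMap",
    "MeshingError",
    "generate_sphere_head",
    "fibonacci_sphere",
    "read_mesh_text",
    "write_mesh_text",
    "read_gmsh",
    "read_electrodes_csv",
    "write_electrodes_csv",
]

# Tissue labels, innermost to outermost shell.
BRAIN, CSF, SKULL, SCALP = 1, 2, 3, 4
TISSUE_NAMES = {BRAIN: "brain", CSF: "csf", SKULL: "skull", SCALP: "scalp"}


class MeshingError(RuntimeError):
    """Raised when mesh generation produces a degenerate tetrahedralization."""


@dataclass
class HeadMesh:
    """Labelled tetrahedral mesh.

    Attributes
    ----------
    nodes : (P, 3) float array
        Node coordinates in metres.
    tets : (N_H, 4) int array
        Tetrahedra as 0-based node indices, positively oriented.
    labels : (N_H,) int array
        Per-element tissue label (``BRAIN``..``SCALP`` for sphere models).
    """

    nodes: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    _volumes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (P, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (N_H, 4)")
        if self.labels.shape != (self.tets.shape[0],):
            raise ValueError("labels must have one entry per tetrahedron")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:, :] - x[:, :1, :]
        return np.linalg.det(d) / 6.0

    def element_volumes(self) -> np.ndarray:
        """Per-element volumes in m^3 (cached)."""
        if self._volumes is None:
            self._volumes = self.signed_volumes()
        return self._volumes

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def orient_positively(self) -> None:
        """Swap two vertices of negatively oriented tets; abort on degenerate ones."""
        vol = self.signed_volumes()
        neg = vol < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [1, 0, 2, 3]]
            vol = np.abs(vol)
        bad = np.flatnonzero(vol <= 0)
        if bad.size:
            raise MeshingError(f"degenerate tetrahedra (zero volume): elements {bad[:10].tolist()}")
        self._volumes = vol

    def elements_with_label(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class ElectrodeSet:
    """Pointwise electrodes attached to outer-surface mesh nodes.

    The last electrode is the reference (current-return) electrode, following
    the convention that the expanded injection pattern's final entry closes
    Kirchhoff's law.
    """

    positions: np.ndarray  # (L, 3) metres
    nodes: np.ndarray      # (L,) node indices
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.int64)
        if len(set(self.nodes.tolist())) != len(self.nodes):
            raise ValueError("electrode attachment nodes must be distinct")
        if self.names is None:
            self.names = [f"E{i + 1}" for i in range(len(self.nodes))]

    @property
    def n_electrodes(self) -> int:
        return len(self.nodes)

    @property
    def reference(self) -> int:
        """Index of the reference electrode (always the last one)."""
        return self.n_electrodes - 1


@dataclass
class ConductivityMap:
    """Per-tissue scalar conductivities in S/m.

    Literature defaults: scalp 0.3, skull 0.006, CSF 1.79, brain 0.33 S/m.
    A per-element tensor slot exists for API completeness; the bundled solver
    is isotropic and rejects tensors.
    """

    values: dict[int, float] = field(
        default_factory=lambda: {SCALP: 0.3, SKULL: 0.006, CSF: 1.79, BRAIN: 0.33}
    )
    tensors: np.ndarray | None = None

    def __post_init__(self) -> None:
        for label, sigma in self.values.items():
            if not sigma > 0:
                raise ValueError(f"conductivity for tissue {label} must be > 0, got {sigma}")

    def per_element(self, mesh: HeadMesh) -> np.ndarray:
        """Scalar conductivity per element, following the tissue labels."""
        try:
            table_size = int(max(self.values)) + 1
            table = np.full(table_size, np.nan)
            for label, sigma in self.values.items():
                table[label] = sigma
            sig = table[mesh.labels]
        except (IndexError, ValueError) as exc:
            raise KeyError(f"mesh labels outside conductivity map: {exc}") from exc
        if np.any(np.isnan(sig)):
            missing = sorted(set(mesh.labels.tolist()) - set(self.values))
            raise KeyError(f"no conductivity for tissue labels {missing}")
        return sig


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-angle lattice."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _shell_points(r: float, h: float, rng: np.random.Generator, jitter: float) -> np.ndarray:
    n = max(12, int(np.ceil(4 * np.pi * r * r / (h * h) * 1.15)))
    pts = fibonacci_sphere(n) @ _random_rotation(rng).T
    if jitter > 0:
        # tangential jitter only: keeps every node exactly on its shell
        t = rng.standard_normal(pts.shape)
        t -= (t * pts).sum(axis=1, keepdims=True) * pts
        pts = pts + jitter * t
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return r * pts


def generate_sphere_head(
    radii=(0.080, 0.081, 0.086, 0.092),
    target_edge_length: float = 0.012,
    n_electrodes: int = 64,
    seed: int = 0,
):
    """Generate a four-layer concentric-sphere head model.

    Parameters
    ----------
    radii : increasing 4-sequence of floats
        Outer radii (m) of the brain, CSF, skull and scalp shells.  The
        defaults (80/81/86/92 mm) mimic adult head dimensions with a thin CSF
        layer and a 5 mm skull.
    target_edge_length : float
        Approximate node spacing in metres; controls mesh resolution.
    n_electrodes : int
        Electrodes placed quasi-uniformly on the scalp; the last one is the
        reference.
    seed : int
        Seeds every randomized step (shell rotations, tangential jitter); the
        same seed reproduces the mesh and electrode nodes exactly.

    Returns
    -------
    (HeadMesh, ElectrodeSet)
    """
    radii = [float(r) for r in radii]
    if len(radii) != 4 or any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
        raise ValueError(f"radii must be 4 strictly increasing positive values, got {radii}")
    h = float(target_edge_length)
    if not 0 < h < radii[0]:
        raise ValueError("target_edge_length must be positive and below the brain radius")

    rng = np.random.default_rng(seed)
    boundary_radii = radii

    # Radial stations: boundaries exactly, intermediates where gaps exceed ~1.4 h.
    stations: list[tuple[float, bool]] = []  # (radius, is_tissue_boundary)
    prev = 0.0
    for rb in boundary_radii:
        gap = rb - prev
        n_mid = int(np.floor(gap / (1.4 * h)))
        for k in range(1, n_mid + 1):
            stations.append((prev + gap * k / (n_mid + 1), False))
        stations.append((rb, True))
        prev = rb

    points = [np.zeros((1, 3))]
    outer_start = None
    for r, is_boundary in stations:
        jitter = 0.15 * h / r if r > 0.3 * h else 0.0
        pts = _shell_points(r, h, rng, jitter)
        if is_boundary and r == boundary_radii[-1]:
            outer_start = sum(p.shape[0] for p in points)
        points.append(pts)
    nodes = np.vstack(points)
    outer_nodes = np.arange(outer_start, nodes.shape[0])

    tri = Delaunay(nodes)
    mesh = HeadMesh(nodes=nodes, tets=tri.simplices.copy(), labels=np.zeros(len(tri.simplices)))
    mesh.orient_positively()

    rc = np.linalg.norm(mesh.centroids(), axis=1)
    labels = np.full(mesh.n_elements, SCALP, dtype=np.int64)
    labels[rc < boundary_radii[2]] = SKULL
    labels[rc < boundary_radii[1]] = CSF
    labels[rc < boundary_radii[0]] = BRAIN
    mesh.labels = labels

    vol_total = mesh.element_volumes().sum()
    vol_exact = 4 / 3 * np.pi * boundary_radii[-1] ** 3
    if abs(vol_total - vol_exact) > 0.02 * vol_exact:
        raise MeshingError(
            f"meshed volume {vol_total:.3e} m^3 deviates >2% from analytic "
            f"{vol_exact:.3e} m^3 (radii={radii}, h={h}, seed={seed})"
        )

    electrodes = _place_electrodes(mesh, outer_nodes, n_electrodes, rng)
    return mesh, electrodes


def _place_electrodes(
    mesh: HeadMesh, outer_nodes: np.ndarray, n_electrodes: int, rng: np.random.Generator
) -> ElectrodeSet:
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes (source and reference)")
    if n_electrodes > outer_nodes.size:
        raise MeshingError(
            f"cannot place {n_electrodes} electrodes on {outer_nodes.size} scalp nodes; "
            "reduce target_edge_length"
        )
    targets = fibonacci_sphere(n_electrodes) @ _random_rotation(rng).T
    r_out = np.linalg.norm(mesh.nodes[outer_nodes[0]])
    tree = cKDTree(mesh.nodes[outer_nodes])
    chosen: list[int] = []
    taken: set[int] = set()
    k = min(outer_nodes.size, max(8, n_electrodes // 4))
    for t in targets:
        _, idx = tree.query(r_out * t, k=k)
        idx = np.atleast_1d(idx)
        pick = next((j for j in idx if j not in taken), None)
        if pick is None:  # fall back to full scan
            dists = np.linalg.norm(mesh.nodes[outer_nodes] - r_out * t, axis=1)
            pick = next(j for j in np.argsort(dists) if j not in taken)
        taken.add(int(pick))
        chosen.append(int(outer_nodes[pick]))
    chosen_arr = np.array(chosen, dtype=np.int64)
    return ElectrodeSet(positions=mesh.nodes[chosen_arr].copy(), nodes=chosen_arr)


# ---------------------------------------------------------------------------
# I/O: plain-text mesh format, Gmsh 2.2 ASCII import, electrode CSV
# ---------------------------------------------------------------------------

def write_mesh_text(mesh: HeadMesh, path) -> None:
    """Write the documented plain-text format.

    Layout: header line ``tesopt-mesh 1``; ``P N_H`` counts; P node lines
    ``x y z`` (m, full precision); N_H element lines ``n1 n2 n3 n4 label``
    with 1-based node indices.
    """
    with open(path, "w") as f:
        f.write("tesopt-mesh 1\n")
        f.write(f"{mesh.n_nodes} {mesh.n_elements}\n")
        for p in mesh.nodes:
            f.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for t, lab in zip(mesh.tets + 1, mesh.labels):
            f.write(f"{t[0]} {t[1]} {t[2]} {t[3]} {lab}\n")


def read_mesh_text(path) -> HeadMesh:
    with open(path) as f:
        header = f.readline().split()
        if header[:2] != ["tesopt-mesh", "1"]:
            raise ValueError(f"{path}: not a tesopt-mesh v1 file")
        n_nodes, n_elem = map(int, f.readline().split())
        nodes = np.loadtxt(f, max_rows=n_nodes, dtype=float).reshape(n_nodes, 3)
        table = np.loadtxt(f, max_rows=n_elem, dtype=np.int64).reshape(n_elem, 5)
    return HeadMesh(nodes=nodes, tets=table[:, :4] - 1, labels=table[:, 4])


def read_gmsh(path) -> HeadMesh:
    """Import a Gmsh MSH 2.2 ASCII mesh (tetrahedra only, physical tag = tissue label).

    Non-tetrahedral elements (points, lines, triangles) are skipped.
    """
    nodes_map: dict[int, np.ndarray] = {}
    tets: list[list[int]] = []
    labels: list[int] = []
    with open(path) as f:
        lines = iter(f.read().splitlines())
    for line in lines:
        if line.strip() == "$MeshFormat":
            fmt = next(lines).split()
            if not fmt[0].startswith("2."):
                raise ValueError(f"unsupported MSH version {fmt[0]} (need 2.x ASCII)")
            if fmt[1] != "0":
                raise ValueError("binary MSH files are not supported")
        elif line.strip() == "$Nodes":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                nodes_map[int(parts[0])] = np.array([float(v) for v in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(lines))
            for _ in range(n):
                parts = [int(v) for v in next(lines).split()]
                etype, ntags = parts[1], parts[2]
                if etype != 4:  # 4 = linear tetrahedron
                    continue
                tag = parts[3] if ntags >= 1 else 0
                tets.append(parts[3 + ntags:7 + ntags])
                labels.append(tag)
    if not nodes_map or not tets:
        raise ValueError(f"{path}: no nodes/tetrahedra found")
    ids = sorted(nodes_map)
    remap = {nid: i for i, nid in enumerate(ids)}
    nodes = np.array([nodes_map[nid] for nid in ids])
    tet_arr = np.array([[remap[v] for v in t] for t in tets], dtype=np.int64)
    mesh = HeadMesh(nodes=nodes, tets=tet_arr, labels=np.array(labels, dtype=np.int64))
    mesh.orient_positively()
    return mesh


def write_electrodes_csv(electrodes: ElectrodeSet, path) -> None:
    """CSV ``label,x_m,y_m,z_m``; the last row is the reference electrode."""
    with open(path, "w") as f:
        f.write("label,x_m,y_m,z_m\n")
        for name, p in zip(electrodes.names, electrodes.positions):
            f.write(f"{name},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}\n")


def read_electrodes_csv(path, mesh: HeadMesh, surface_nodes: np.ndarray | None = None) -> ElectrodeSet:
    """Read electrode positions and attach each to the nearest surface node."""
    names: list[str] = []
    pos: list[list[float]] = []
    with open(path) as f:
        header = f.readline()
        if not header.lower().startswith("label"):
            raise ValueError(f"{path}: expected header 'label,x_m,y_m,z_m'")
        for line in f:
            if not line.strip():
                continue
            parts = line.strip().split(",")
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
    pos_arr = np.array(pos)
    candidates = surface_nodes if surface_nodes is not None else _outer_surface_nodes(mesh)
    tree = cKDTree(mesh.nodes[candidates])
    taken: set[int] = set()
    chosen = []
    for p in pos_arr:
        _, idx = tree.query(p, k=min(len(candidates), 8))
        pick = next((j for j in np.atleast_1d(idx) if j not in taken), None)
        if pick is None:
            raise ValueError("electrode positions collapse onto too few surface nodes")
        taken.add(int(pick))
        chosen.append(int(candidates[pick]))
    return ElectrodeSet(positions=pos_arr, nodes=np.array(chosen), names=names)


def _outer_surface_nodes(mesh: HeadMesh) -> np.ndarray:
    """Nodes on the outer boundary (faces owned by exactly one tet)."""
    faces = mesh.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    return np.unique(boundary)
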