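"""Surface-mesh data model, I/O, geodesics and synthetic heart/torso geometry.

The heart surface is a triangulated mesh whose vertices carry an integer
label: 0 for the epicardium (EPI), 1 for the endocardium (ENDO).  Meshes can
be read/written as ASCII PLY, OFF, or legacy VTK polydata; the label travels
as an integer per-vertex scalar field named ``surface_label`` (PLY vertex
property / VTK POINT_DATA scalars; OFF has no attribute channel, so the
labels are appended as a ``# surface_label`` comment block that this reader
understands and other readers ignore).

All coordinates are millimetres and vertex indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

__all__ = [
    "EPI",
    "ENDO",
    "SurfaceMesh",
    "ElectrodeSet",
    "EndoEpiPairing",
    "read_mesh",
    "write_mesh",
    "read_electrodes",
    "write_electrodes",
    "geodesic_distances",
    "pair_endo_epi",
    "GeometryConfig",
    "make_synthetic_geometry",
    "subdivide",
]

EPI = 0
ENDO = 1


class MeshFormatError(ValueError):
    """Unknown or malformed mesh file."""


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant."""


@dataclass
class SurfaceMesh:
    """Triangulated heart surface with per-vertex EPI/ENDO labels."""

    vertices: np.ndarray  # (N, 3) float, mm
    triangles: np.ndarray  # (M, 3) int
    surface_label: np.ndarray  # (N,) int, EPI=0 / ENDO=1

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.surface_label = np.asarray(self.surface_label, dtype=np.int64).ravel()
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = self.n_vertices
        if self.surface_label.shape[0] != n:
            raise MeshValidationError(
                f"{self.surface_label.shape[0]} labels for {n} vertices"
            )
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                bad = self.triangles[
                    ((self.triangles < 0) | (self.triangles >= n)).any(axis=1)
                ]
                raise MeshValidationError(
                    f"triangle indices out of range [0, {n}): {bad.tolist()}"
                )
            degen = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if degen.any():
                raise MeshValidationError(
                    "degenerate triangles (repeated vertex): "
                    f"{self.triangles[degen].tolist()}"
                )
        if not np.isin(self.surface_label, (EPI, ENDO)).all():
            raise MeshValidationError("surface_label must be 0 (EPI) or 1 (ENDO)")
        if not (self.surface_label == EPI).any():
            raise MeshValidationError("mesh must contain at least one EPI vertex")
        used = np.zeros(n, dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            raise MeshValidationError(
                f"isolated vertices (in no triangle): {np.flatnonzero(~used).tolist()}"
            )

    # -- derived ----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def epi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.surface_label == EPI)

    @property
    def endo_indices(self) -> np.ndarray:
        return np.flatnonzero(self.surface_label == ENDO)

    @property
    def has_endo(self) -> bool:
        return bool((self.surface_label == ENDO).any())

    def edges(self) -> np.ndarray:
        """Unique undirected edges (K, 2), each row sorted."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [0, 2]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> csr_matrix:
        """Sparse symmetric adjacency weighted by Euclidean edge length (mm)."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                      np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return g.tocsr()

    def neighbor_lists(self) -> list[np.ndarray]:
        g = self.edge_graph()
        return [g.indices[g.indptr[i]:g.indptr[i + 1]] for i in range(self.n_vertices)]


@dataclass
class ElectrodeSet:
    """Body-surface electrode positions (mm)."""

    positions: np.ndarray  # (N_T, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


@dataclass
class EndoEpiPairing:
    """For each EPI vertex, its Euclidean-nearest ENDO vertex."""

    epi_indices: np.ndarray  # (E,) global vertex indices
    endo_partner: np.ndarray  # (E,) global vertex indices
    distance: np.ndarray  # (E,) mm


# ---------------------------------------------------------------------------
# geodesics / pairing
# ---------------------------------------------------------------------------

def geodesic_distances(mesh: SurfaceMesh, source: int) -> np.ndarray:
    """Shortest-path distance (mm) on the edge graph from one vertex.

    Dijkstra with Euclidean edge weights; unreachable vertices get +inf.
    """
    if not 0 <= source < mesh.n_vertices:
        raise IndexError(f"source {source} out of range [0, {mesh.n_vertices})")
    return dijkstra(mesh.edge_graph(), directed=False, indices=source)


def pair_endo_epi(mesh: SurfaceMesh) -> EndoEpiPairing:
    """Pair every EPI vertex with the closest ENDO vertex (ties: lowest index)."""
    if not mesh.has_endo:
        raise ValueError(
            "mesh has no ENDO vertices; endo-epi delays are undefined on "
            "epicardium-only meshes"
        )
    epi = mesh.epi_indices
    endo = mesh.endo_indices
    d = cdist(mesh.vertices[epi], mesh.vertices[endo])
    j = d.argmin(axis=1)  # first minimum -> smallest endo index
    return EndoEpiPairing(epi, endo[j], d[np.arange(len(epi)), j])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_mesh(path, mesh: SurfaceMesh) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(path, mesh)
    elif ext == ".off":
        _write_off(path, mesh)
    elif ext == ".vtk":
        _write_vtk(path, mesh)
    else:
        raise MeshFormatError(f"unknown mesh extension {ext!r} (use .ply/.off/.vtk)")


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".off":
        return _read_off(path)
    if ext == ".vtk":
        return _read_vtk(path)
    raise MeshFormatError(f"unknown mesh extension {ext!r} (use .ply/.off/.vtk)")


def _write_ply(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {mesh.n_vertices}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write("property int surface_label\n")
        f.write(f"element face {len(mesh.triangles)}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for p, lab in zip(mesh.vertices, mesh.surface_label):
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {lab}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path) as f:
        if f.readline().strip() != "ply":
            raise MeshFormatError(f"{path} is not a PLY file")
        fmt = f.readline().split()
        if fmt[:2] != ["format", "ascii"]:
            raise MeshFormatError("only ASCII PLY is supported")
        n_vert = n_face = 0
        vprops: list[str] = []
        element = None
        for line in f:
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                vprops.append(tok[2])
            elif tok[0] == "end_header":
                break
        try:
            ix, iy, iz = vprops.index("x"), vprops.index("y"), vprops.index("z")
        except ValueError as exc:
            raise MeshFormatError("PLY vertex element lacks x/y/z") from exc
        ilab = vprops.index("surface_label") if "surface_label" in vprops else None
        verts = np.empty((n_vert, 3))
        labels = np.zeros(n_vert, dtype=np.int64)
        for i in range(n_vert):
            tok = f.readline().split()
            verts[i] = float(tok[ix]), float(tok[iy]), float(tok[iz])
            if ilab is not None:
                labels[i] = int(float(tok[ilab]))
        tris = np.empty((n_face, 3), dtype=np.int64)
        for i in range(n_face):
            tok = f.readline().split()
            if int(tok[0]) != 3:
                raise MeshFormatError(f"face {i} is not a triangle")
            tris[i] = int(tok[1]), int(tok[2]), int(tok[3])
    return SurfaceMesh(verts, tris, labels)


def _write_off(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for p in mesh.vertices:
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write("# surface_label " + " ".join(map(str, mesh.surface_label)) + "\n")


def _read_off(path: Path) -> SurfaceMesh:
    labels = None
    with open(path) as f:
        lines = []
        for raw in f:
            s = raw.strip()
            if s.startswith("# surface_label"):
                labels = np.array(s.split()[2:], dtype=np.int64)
            elif s and not s.startswith("#"):
                lines.append(s)
    if not lines or lines[0] != "OFF":
        raise MeshFormatError(f"{path} is not an OFF file")
    n_vert, n_face, _ = (int(x) for x in lines[1].split())
    verts = np.array([l.split()[:3] for l in lines[2:2 + n_vert]], dtype=float)
    tris = np.empty((n_face, 3), dtype=np.int64)
    for i, l in enumerate(lines[2 + n_vert:2 + n_vert + n_face]):
        tok = l.split()
        if int(tok[0]) != 3:
            raise MeshFormatError(f"face {i} is not a triangle")
        tris[i] = int(tok[1]), int(tok[2]), int(tok[3])
    if labels is None:
        labels = np.zeros(n_vert, dtype=np.int64)
    return SurfaceMesh(verts, tris, labels)


def _write_vtk(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("heart surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        m = len(mesh.triangles)
        f.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"POINT_DATA {mesh.n_vertices}\n")
        f.write("SCALARS surface_label int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(map(str, mesh.surface_label)) + "\n")


def _read_vtk(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path) as f:
        header = f.readline()
        if not header.startswith("# vtk"):
            raise MeshFormatError(f"{path} is not a legacy VTK file")
        f.readline()  # title
        if f.readline().strip().upper() != "ASCII":
            raise MeshFormatError("only ASCII legacy VTK is supported")
        if f.readline().split()[-1].upper() != "POLYDATA":
            raise MeshFormatError("only POLYDATA legacy VTK is supported")
        tokens = f.read().split()
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        if tokens[pos].upper() != word:
            raise MeshFormatError(f"expected {word}, found {tokens[pos]}")
        pos += 1

    expect("POINTS")
    n_vert = int(tokens[pos]); pos += 2  # count, dtype
    verts = np.array(tokens[pos:pos + 3 * n_vert], dtype=float).reshape(n_vert, 3)
    pos += 3 * n_vert
    expect("POLYGONS")
    n_face = int(tokens[pos]); pos += 2  # count, total ints
    tris = np.empty((n_face, 3), dtype=np.int64)
    for i in range(n_face):
        if int(tokens[pos]) != 3:
            raise MeshFormatError(f"face {i} is not a triangle")
        tris[i] = int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])
        pos += 4
    labels = np.zeros(n_vert, dtype=np.int64)
    while pos < len(tokens):
        if tokens[pos].upper() == "SCALARS" and tokens[pos + 1] == "surface_label":
            pos += 4  # SCALARS name type ncomp
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            labels = np.array(tokens[pos:pos + n_vert], dtype=np.int64)
            break
        pos += 1
    return SurfaceMesh(verts, tris, labels)


def write_electrodes(path, electrodes: ElectrodeSet) -> None:
    """Plain-text 3-column x y z table in mm."""
    np.savetxt(path, electrodes.positions, fmt="%.10g")


def read_electrodes(path) -> ElectrodeSet:
    """Read a whitespace- or comma-separated 3-column coordinate table."""
    text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.split("#")[0].strip().replace(",", " ")
        if line:
            rows.append([float(x) for x in line.split()[:3]])
    if not rows:
        raise ValueError(f"no electrode coordinates found in {path}")
    return ElectrodeSet(np.array(rows))


# ---------------------------------------------------------------------------
# synthetic geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometryConfig:
    """Synthetic ventricle (half-ellipsoid shell, open at the base) + torso.

    The epicardial shell has the given semi-axes; a ``wall_thickness`` adds a
    nested ENDO shell inset by that amount, joined to the EPI shell along the
    basal rim so both surfaces form one connected graph.  Electrodes sit on
    the lateral surface of a cylinder in near-uniform rings.
    """

    semi_axes: tuple[float, float, float] = (30.0, 30.0, 60.0)  # mm
    wall_thickness: float | None = None  # mm; None -> epicardium only
    target_vertices: int = 100  # per shell
    torso_radius: float = 100.0  # mm
    torso_height: float = 200.0  # mm
    n_electrodes: int = 64
    seed: int = 0
    electrode_jitter: float = 0.0  # mm, tangential jitter on the cylinder


def _ring_layout(target: int) -> list[int]:
    """Per-ring segment counts for ~uniform vertex density on a half-sphere.

    Rings sit at polar angles theta in [pi/2, pi); segment counts scale with
    the ring circumference (sin theta) and are then adjusted so that the
    total vertex count (rings + apex) equals ``target`` exactly.
    """
    # hexagonal-packing spacing for `target` points on area 2*pi
    s = np.sqrt(2.0 * np.pi / max(target, 4) * 2.0 / np.sqrt(3.0))
    n_rings = max(2, int(round(0.5 * np.pi / s)))
    thetas = 0.5 * np.pi + 0.5 * np.pi * np.arange(n_rings) / n_rings
    counts = [max(3, int(round(2.0 * np.pi * np.sin(th) / s))) for th in thetas]
    diff = (target - 1) - sum(counts)
    k = 0
    while diff != 0:  # spread the residual over rings, largest first
        i = np.argsort(counts)[::-1][k % n_rings]
        if diff > 0:
            counts[i] += 1
            diff -= 1
        elif counts[i] > 3:
            counts[i] -= 1
            diff += 1
        k += 1
        if k > 10 * n_rings * (abs(diff) + 1):  # pragma: no cover - safety
            break
    return counts


def _zip_rings(idx_a, ang_a, idx_b, ang_b):
    """Triangulate the band between two vertex rings by angular merge."""
    tris = []
    na, nb = len(idx_a), len(idx_b)
    ia = ib = 0
    while ia < na or ib < nb:
        next_a = ang_a[ia + 1] if ia + 1 < na else ang_a[0] + 2.0 * np.pi
        next_b = ang_b[ib + 1] if ib + 1 < nb else ang_b[0] + 2.0 * np.pi
        if ia < na and (next_a <= next_b or ib >= nb):
            tris.append((idx_a[ia], idx_a[(ia + 1) % na], idx_b[ib % nb]))
            ia += 1
        else:
            tris.append((idx_b[ib], idx_a[ia % na], idx_b[(ib + 1) % nb]))
            ib += 1
    return tris


def _half_ellipsoid(a: float, b: float, c: float, target: int,
                    label: int, index_offset: int = 0):
    """Open half-ellipsoid: base ring at z=0, apex at z=-c, ~uniform density.

    Returns (vertices, triangles, labels, base_ring_indices,
    base_ring_angles) with triangle indices shifted by ``index_offset``.
    """
    counts = _ring_layout(target)
    n_rings = len(counts)
    verts = []
    ring_idx = []
    ring_ang = []
    for i, cnt in enumerate(counts):  # i=0 is the basal ring (theta = pi/2)
        th = 0.5 * np.pi + 0.5 * np.pi * i / n_rings
        phase = np.pi * (i % 2) / cnt  # stagger alternate rings
        angles = 2.0 * np.pi * np.arange(cnt) / cnt + phase
        ring_idx.append(np.arange(len(verts), len(verts) + cnt) + index_offset)
        ring_ang.append(angles)
        for ph in angles:
            verts.append((a * np.sin(th) * np.cos(ph),
                          b * np.sin(th) * np.sin(ph),
                          c * np.cos(th)))
    apex = len(verts) + index_offset
    verts.append((0.0, 0.0, -c))
    tris = []
    for i in range(n_rings - 1):
        tris += _zip_rings(ring_idx[i], ring_ang[i], ring_idx[i + 1],
                           ring_ang[i + 1])
    for j in range(counts[-1]):  # apex fan
        last = ring_idx[-1]
        tris.append((last[j], last[(j + 1) % counts[-1]], apex))
    verts = np.asarray(verts)
    tris = np.asarray(tris, dtype=np.int64)
    labels = np.full(len(verts), label, dtype=np.int64)
    return verts, tris, labels, ring_idx[0], ring_ang[0]


def make_synthetic_geometry(config: GeometryConfig) -> tuple[SurfaceMesh, ElectrodeSet]:
    """Build the synthetic ventricle mesh and electrode set (deterministic per seed)."""
    a, b, c = config.semi_axes
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    w = config.wall_thickness
    if w is not None and w >= min(a, b, c):
        raise ValueError(
            f"wall thickness {w} mm must be smaller than the smallest semi-axis "
            f"{min(a, b, c)} mm"
        )
    if config.n_electrodes < 4:
        raise ValueError("need at least 4 electrodes")

    verts, tris, labels, base_epi, ang_epi = _half_ellipsoid(
        a, b, c, config.target_vertices, EPI
    )
    if w is not None:
        iv, it, il, base_endo, ang_endo = _half_ellipsoid(
            a - w, b - w, c - w, config.target_vertices, ENDO,
            index_offset=len(verts),
        )
        # join the two basal rims (transmural bridge)
        bridge = _zip_rings(base_epi, ang_epi, base_endo, ang_endo)
        verts = np.vstack([verts, iv])
        tris = np.vstack([tris, it, np.asarray(bridge, dtype=np.int64)])
        labels = np.concatenate([labels, il])
    mesh = SurfaceMesh(verts, tris, labels)

    electrodes = _cylinder_electrodes(config, z_center=-c / 2.0)
    d = cdist(mesh.vertices, electrodes.positions)
    if d.min() <= 0:
        raise ValueError("an electrode coincides with a mesh vertex")
    return mesh, electrodes


def _cylinder_electrodes(config: GeometryConfig, z_center: float) -> ElectrodeSet:
    n = config.n_electrodes
    n_rings = int(np.clip(round(np.sqrt(n / 3.0)), 2, n // 2))
    counts = np.full(n_rings, n // n_rings)
    counts[: n % n_rings] += 1
    zs = z_center + np.linspace(-0.5, 0.5, n_rings) * config.torso_height
    rng = np.random.default_rng(config.seed)
    pos = []
    for r, (cnt, z) in enumerate(zip(counts, zs)):
        # stagger alternate rings by half a step for near-uniform coverage
        phase = np.pi * r / cnt
        for j in range(cnt):
            ph = 2.0 * np.pi * j / cnt + phase
            if config.electrode_jitter > 0:
                ph += rng.normal(0.0, config.electrode_jitter / config.torso_radius)
                z_j = z + rng.normal(0.0, config.electrode_jitter)
            else:
                z_j = z
            pos.append((config.torso_radius * np.cos(ph),
                        config.torso_radius * np.sin(ph), z_j))
    return ElectrodeSet(np.array(pos))


def subdivide(mesh: SurfaceMesh) -> SurfaceMesh:
    """Midpoint 1-to-4 subdivision; the original vertices keep their indices.

    Edge midpoints are labeled ENDO only when both edge endpoints are ENDO.
    """
    edges = mesh.edges()
    mid_index = {tuple(e): mesh.n_vertices + k for k, e in enumerate(edges)}
    mid_verts = 0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])
    mid_labels = np.where(
        (mesh.surface_label[edges[:, 0]] == ENDO)
        & (mesh.surface_label[edges[:, 1]] == ENDO),
        ENDO,
        EPI,
    )
    tris = []
    for t in mesh.triangles:
        i, j, k = int(t[0]), int(t[1]), int(t[2])
        mij = mid_index[tuple(sorted((i, j)))]
        mjk = mid_index[tuple(sorted((j, k)))]
        mik = mid_index[tuple(sorted((i, k)))]
        tris += [(i, mij, mik), (j, mjk, mij), (k, mik, mjk), (mij, mjk, mik)]
    return SurfaceMesh(
        np.vstack([mesh.vertices, mid_verts]),
        np.asarray(tris, dtype=np.int64),
        np.concatenate([mesh.surface_label, mid_labels]),
    )
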