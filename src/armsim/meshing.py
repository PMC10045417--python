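"""Voxel label volume → tagged conforming tetrahedral mesh.

Each non-background voxel is split into 6 tetrahedra by the Kuhn
(diagonal-consistent) decomposition, so shared faces match across voxels and
the mesh is conforming by construction.  Node numbering is lexicographic in
(z, y, x) for reproducible matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .phantom import BACKGROUND, LabelVolume
from .reconstruction import GridSpec

__all__ = ["TetMesh", "MeshingError", "voxel_to_tet", "mesh_quality", "KUHN_TETS"]


class MeshingError(ValueError):
    pass


def _build_kuhn_template() -> np.ndarray:
    """6 tets per cube, corners as (dx, dy, dz) bit offsets, positive volume.

    Tet k follows the axis-permutation path from corner (0,0,0) to (1,1,1);
    all six share the main diagonal, making the split translation-consistent
    (conforming across neighbouring voxels).
    """
    from itertools import permutations

    corners = []
    for perm in sorted(permutations((0, 1, 2))):
        c0 = np.zeros(3, dtype=int)
        c1 = c0.copy()
        c1[perm[0]] = 1
        c2 = c1.copy()
        c2[perm[1]] = 1
        c3 = np.ones(3, dtype=int)
        tet = np.array([c0, c1, c2, c3])
        e = (tet[1:] - tet[0]).astype(float)
        if np.linalg.det(e) < 0:
            tet = tet[[0, 2, 1, 3]]
        corners.append(tet)
    return np.array(corners)  # (6, 4, 3)


KUHN_TETS = _build_kuhn_template()

# local faces of a positively oriented tet (a,b,c,d), outward orientation
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


@dataclass
class TetMesh:
    """Tagged tetrahedral mesh in physical mm.

    ``nodes`` (n, 3) with columns (x, y, z); ``tets`` (m, 4) node indices with
    positive signed volume; ``tissue_tags`` (m,).  Meshes produced by
    :func:`voxel_to_tet` keep their source grid for O(1) point location
    (``grid``, ``voxel_ids``: linear voxel index per 6-tet group).
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue_tags: np.ndarray
    grid: Optional[GridSpec] = None
    voxel_ids: Optional[np.ndarray] = None
    _boundary: Optional[tuple] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.tissue_tags = np.asarray(self.tissue_tags, dtype=np.int64).ravel()
        if len(self.tissue_tags) != len(self.tets):
            raise MeshingError("tissue_tags length must match tets")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes in mm^3 (all positive for a valid mesh)."""
        v = self.nodes[self.tets]
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def edge_matrices(self) -> np.ndarray:
        """Per-tet edge matrices E with rows (v1-v0, v2-v0, v3-v0), mm."""
        v = self.nodes[self.tets]
        return v[:, 1:] - v[:, :1]

    # -- boundary -----------------------------------------------------------
    def _compute_boundary(self) -> tuple:
        faces = self.tets[:, _TET_FACES]  # (m, 4, 3)
        faces = faces.reshape(-1, 3)
        owners = np.repeat(np.arange(self.n_tets), 4)
        key = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        boundary_rows = np.nonzero(counts[inverse] == 1)[0]
        bfaces = faces[boundary_rows]
        bowners = owners[boundary_rows]
        a = self.nodes[bfaces[:, 0]]
        b = self.nodes[bfaces[:, 1]]
        c = self.nodes[bfaces[:, 2]]
        nvec = np.cross(b - a, c - a)
        areas = np.linalg.norm(nvec, axis=1) / 2.0  # mm^2
        normals = nvec / np.linalg.norm(nvec, axis=1, keepdims=True)
        centroids = (a + b + c) / 3.0
        return bfaces, bowners, normals, areas, centroids

    @property
    def boundary(self) -> tuple:
        """(faces, owner_tets, outward_normals, areas_mm2, centroids_mm)."""
        if self._boundary is None:
            self._boundary = self._compute_boundary()
        return self._boundary

    @property
    def boundary_faces(self) -> np.ndarray:
        return self.boundary[0]

    # -- point location -----------------------------------------------------
    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Find the containing tet for each query point (mm).

        Returns ``(tet_index, barycentric)``; tet_index −1 where the point is
        outside the meshed region.  Requires the source grid metadata.
        """
        if self.grid is None or self.voxel_ids is None:
            raise MeshingError("mesh lacks grid metadata for point location")
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        nz, ny, nx = self.grid.shape
        dz, dy, dx = self.grid.spacing
        oz, oy, ox = self.grid.origin
        iw = np.floor((pts - np.array([ox, oy, oz])) / np.array([dx, dy, dz]))
        iw = iw.astype(np.int64)
        ok = (
            (iw[:, 0] >= 0) & (iw[:, 0] < nx)
            & (iw[:, 1] >= 0) & (iw[:, 1] < ny)
            & (iw[:, 2] >= 0) & (iw[:, 2] < nz)
        )
        lin = (iw[:, 2] * ny + iw[:, 1]) * nx + iw[:, 0]
        group_of_voxel = self.voxel_ids  # sorted unique linear ids, len K
        pos = np.searchsorted(group_of_voxel, lin)
        pos_clipped = np.clip(pos, 0, len(group_of_voxel) - 1)
        ok &= group_of_voxel[pos_clipped] == lin
        tet_idx = np.full(len(pts), -1, dtype=np.int64)
        bary_out = np.zeros((len(pts), 4))
        sel = np.nonzero(ok)[0]
        if len(sel) == 0:
            return tet_idx, bary_out
        cand = pos_clipped[sel][:, None] * 6 + np.arange(6)[None, :]  # (q, 6)
        v = self.nodes[self.tets[cand]]  # (q, 6, 4, 3)
        e = v[:, :, 1:] - v[:, :, :1]  # (q, 6, 3, 3)
        rhs = pts[sel][:, None, :] - v[:, :, 0]  # (q, 6, 3)
        lam = np.linalg.solve(
            np.swapaxes(e, -1, -2), rhs[..., None]
        )[..., 0]  # (q, 6, 3)
        lam0 = 1.0 - lam.sum(axis=-1)
        bary = np.concatenate([lam0[..., None], lam], axis=-1)  # (q, 6, 4)
        inside = bary.min(axis=-1) >= -1e-9
        best = inside.argmax(axis=1)
        found = inside.any(axis=1)
        tet_idx[sel[found]] = cand[np.arange(len(sel)), best][found]
        bary_out[sel[found]] = bary[np.arange(len(sel)), best][found]
        return tet_idx, bary_out

    # -- i/o ----------------------------------------------------------------
    def save_vtk(self, path: str | Path, point_data: dict | None = None,
                 cell_data: dict | None = None) -> None:
        """Legacy ASCII VTK unstructured grid; tissue tag always included."""
        cell_data = dict(cell_data or {})
        cell_data.setdefault("tissue", self.tissue_tags)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\narmsim tet mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {self.n_nodes} double\n")
            np.savetxt(fh, self.nodes, fmt="%.9g")
            fh.write(f"CELLS {self.n_tets} {self.n_tets * 5}\n")
            cells = np.column_stack(
                [np.full(self.n_tets, 4, dtype=np.int64), self.tets]
            )
            np.savetxt(fh, cells, fmt="%d")
            fh.write(f"CELL_TYPES {self.n_tets}\n")
            np.savetxt(fh, np.full(self.n_tets, 10, dtype=np.int64), fmt="%d")
            fh.write(f"CELL_DATA {self.n_tets}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
            if point_data:
                fh.write(f"POINT_DATA {self.n_nodes}\n")
                for name, arr in point_data.items():
                    arr = np.asarray(arr)
                    if arr.ndim == 1:
                        fh.write(
                            f"SCALARS {name} double 1\nLOOKUP_TABLE default\n"
                        )
                        np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
                    else:
                        fh.write(f"VECTORS {name} double\n")
                        np.savetxt(fh, arr, fmt="%.9g")


def voxel_to_tet(vol: LabelVolume) -> TetMesh:
    """Kuhn-decompose every non-background voxel into 6 tetrahedra."""
    mask = vol.labels != BACKGROUND
    if not mask.any():
        raise MeshingError("label volume has no non-background voxels")
    nz, ny, nx = vol.labels.shape
    iz, iy, ix = np.nonzero(mask)  # lexicographic (z, y, x)
    k = len(iz)
    labels = vol.labels[iz, iy, ix]

    def node_id(gx: np.ndarray, gy: np.ndarray, gz: np.ndarray) -> np.ndarray:
        return (gz * (ny + 1) + gy) * (nx + 1) + gx

    # (k, 6, 4) global grid-node ids, voxel-major so each voxel's 6 tets are
    # contiguous
    tets_global = np.empty((k, 6, 4), dtype=np.int64)
    for t in range(6):
        for c in range(4):
            off = KUHN_TETS[t, c]
            tets_global[:, t, c] = node_id(ix + off[0], iy + off[1], iz + off[2])
    tets_global = tets_global.reshape(-1, 4)

    used, tets = np.unique(tets_global, return_inverse=True)
    tets = tets.reshape(-1, 4)
    gz, rem = np.divmod(used, (ny + 1) * (nx + 1))
    gy, gx = np.divmod(rem, nx + 1)
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    nodes = np.column_stack([ox + gx * dx, oy + gy * dy, oz + gz * dz])

    tags = np.repeat(labels, 6)
    voxel_ids = (iz * ny + iy) * nx + ix  # sorted ascending by construction
    return TetMesh(
        nodes=nodes,
        tets=tets,
        tissue_tags=tags,
        grid=GridSpec.from_label_volume(vol),
        voxel_ids=voxel_ids,
    )


def _dihedral_angles(mesh: TetMesh) -> np.ndarray:
    """All 6 dihedral angles per tet, radians, shape (m, 6)."""
    v = mesh.nodes[mesh.tets]  # (m, 4, 3)
    # outward face normals, face f opposite structure per _TET_FACES
    normals = np.empty((len(v), 4, 3))
    for f, (i, j, l) in enumerate(_TET_FACES):
        n = np.cross(v[:, j] - v[:, i], v[:, l] - v[:, i])
        normals[:, f] = n / np.linalg.norm(n, axis=1, keepdims=True)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    ang = np.empty((len(v), 6))
    for a, (f1, f2) in enumerate(pairs):
        cosv = np.clip(np.einsum("ij,ij->i", normals[:, f1], normals[:, f2]), -1, 1)
        ang[:, a] = np.pi - np.arccos(cosv)
    return ang


def mesh_quality(mesh: TetMesh) -> dict:
    """Counts, dihedral-angle statistics and per-tissue tallies."""
    if mesh.n_tets == 0:
        raise MeshingError("cannot report quality of an empty mesh")
    vols = mesh.tet_volumes()
    ang = _dihedral_angles(mesh)
    tags, counts = np.unique(mesh.tissue_tags, return_counts=True)
    per_tissue = {int(t): int(c) for t, c in zip(tags, counts)}
    return {
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "n_boundary_faces": len(mesh.boundary_faces),
        "total_volume_mm3": float(vols.sum()),
        "min_tet_volume_mm3": float(vols.min()),
        "min_dihedral_deg": float(np.degrees(ang.min())),
        "mean_dihedral_deg": float(np.degrees(ang.mean())),
        "tets_per_tissue": per_tissue,
    }
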