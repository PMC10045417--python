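"""Derived quantities: contact traces, line profiles, effective depth,
stimulation-mode comparison metrics and section exports."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .meshing import TetMesh
from .solver import (
    ElectrodeSpec,
    FieldSolution,
    SolverError,
    TissueProperties,
    current_density,
)

__all__ = [
    "TimeSeriesTrace",
    "LineProfile",
    "probe_trace",
    "contact_node",
    "line_profile",
    "effective_depth",
    "percent_excess",
    "export_section",
    "SectionGrid",
]


@dataclass
class TimeSeriesTrace:
    """Potential over time at one probe location."""

    times: np.ndarray  # s
    values: np.ndarray  # V
    probe_mm: tuple[float, float, float]
    node: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def steady_amplitude(self, frequency: float) -> float:
        """LSQ sinusoid amplitude over the trailing full cycle."""
        period = 1.0 / frequency
        sel = self.times >= self.times[-1] - period
        t = self.times[sel]
        v = self.values[sel]
        design = np.column_stack(
            [np.sin(2 * np.pi * frequency * t), np.cos(2 * np.pi * frequency * t)]
        )
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return float(np.hypot(*coef))

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="time_s,potential_v",
            comments="",
        )


@dataclass
class LineProfile:
    """|J| samples along the inter-electrode center line."""

    positions_mm: np.ndarray  # arc distance from skin entry
    j_mag: np.ndarray  # A/m²
    tissue: np.ndarray  # label per sample (0 where outside)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.j_mag = np.asarray(self.j_mag, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype=np.int64)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be monotone increasing")
        if np.any(self.j_mag < -1e-300):
            raise ValueError("|J| must be non-negative")

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.positions_mm, self.j_mag, self.tissue]),
            delimiter=",",
            header="pos_mm,j_a_per_m2,tissue",
            comments="",
        )


def contact_node(mesh: TetMesh, electrode: ElectrodeSpec) -> int:
    """Mesh node nearest the electrode-center skin contact."""
    center = np.asarray(electrode.center)
    lo = mesh.nodes.min(axis=0) - 2 * electrode.normal_slack
    hi = mesh.nodes.max(axis=0) + 2 * electrode.normal_slack
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError(
            f"probe {tuple(center)} lies outside the mesh bounding box"
        )
    return int(np.linalg.norm(mesh.nodes - center, axis=1).argmin())


def probe_trace(sol: FieldSolution, electrode: ElectrodeSpec) -> TimeSeriesTrace:
    """φ(t) at the node nearest the electrode-center skin contact."""
    if sol.mode != "transient":
        raise SolverError("probe_trace requires a transient solution")
    node = contact_node(sol.mesh, electrode)
    return TimeSeriesTrace(
        times=sol.times,
        values=sol.phi[:, node],
        probe_mm=tuple(sol.mesh.nodes[node]),
        node=node,
    )


def _segment_contacts(
    mesh: TetMesh, e1: ElectrodeSpec, e2: ElectrodeSpec
) -> tuple[np.ndarray, np.ndarray]:
    p1 = mesh.nodes[contact_node(mesh, e1)]
    p2 = mesh.nodes[contact_node(mesh, e2)]
    return p1, p2


def line_profile(
    sol: FieldSolution,
    e1: ElectrodeSpec,
    e2: ElectrodeSpec,
    n: int = 200,
    props: Optional[TissueProperties] = None,
    f_eval: float = 1000.0,
    j_elements: Optional[np.ndarray] = None,
) -> LineProfile:
    """Sample |J| at ``n`` uniform points between the electrode skin contacts.

    Element-constant |J| (complex magnitude for phasor fields); arc position
    measured from the first electrode's skin entry.  Samples are nudged a tiny
    step inward so the endpoints land inside the mesh.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    mesh = sol.mesh
    if j_elements is None:
        if props is None:
            raise ValueError("provide props (or precomputed j_elements)")
        j_elements = current_density(sol, props, f_eval)
    j_mag = np.abs(j_elements)
    j_mag = np.linalg.norm(j_mag, axis=1)
    p1, p2 = _segment_contacts(mesh, e1, e2)
    ts = np.linspace(0.0, 1.0, n)
    # nudge endpoints inward by a fraction of a voxel
    shrink = 1e-3
    ts_eff = shrink + ts * (1 - 2 * shrink)
    pts = p1[None, :] + ts_eff[:, None] * (p2 - p1)[None, :]
    tet_idx, _ = mesh.locate(pts)
    if np.all(tet_idx < 0):
        raise SolverError("inter-electrode segment does not intersect the mesh")
    jvals = np.where(tet_idx >= 0, j_mag[np.clip(tet_idx, 0, None)], 0.0)
    tissues = np.where(tet_idx >= 0, mesh.tissue_tags[np.clip(tet_idx, 0, None)], 0)
    positions = ts * float(np.linalg.norm(p2 - p1))
    return LineProfile(positions_mm=positions, j_mag=jvals, tissue=tissues)


def effective_depth(profile: LineProfile, threshold: float = 10.0) -> float:
    """Largest arc depth (mm) in the entry-side half with |J| ≥ threshold.

    Linear interpolation locates the crossing between samples; returns 0.0 if
    the entry sample is already below threshold, and half the segment length
    if the whole first half stays at or above it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(profile.positions_mm) == 0:
        raise ValueError("empty profile")
    half = profile.positions_mm[-1] / 2.0
    sel = profile.positions_mm <= half + 1e-12
    pos = profile.positions_mm[sel]
    j = profile.j_mag[sel]
    if j[0] < threshold:
        return 0.0
    below = np.nonzero(j < threshold)[0]
    if len(below) == 0:
        return float(half)
    k = int(below[0])  # first sample below threshold; k-1 is >= threshold
    j0, j1 = j[k - 1], j[k]
    x0, x1 = pos[k - 1], pos[k]
    frac = (j0 - threshold) / (j0 - j1)
    return float(x0 + frac * (x1 - x0))


def percent_excess(a: float, b: float) -> float:
    """(a/b − 1)·100, rounded to one decimal."""
    if b <= 0:
        raise ValueError("reference quantity must be > 0")
    return round((a / b - 1.0) * 100.0, 1)


@dataclass
class SectionGrid:
    """Regular 2-D sample of a field on an axis-aligned plane."""

    axis: int  # plane normal: 0=x, 1=y, 2=z
    offset_mm: float
    coords_u: np.ndarray  # mm, first in-plane axis
    coords_v: np.ndarray  # mm, second in-plane axis
    phi: np.ndarray  # (nv, nu), NaN outside mesh
    j_mag: np.ndarray  # (nv, nu)
    j_vec: np.ndarray  # (nv, nu, 3)
    tissue: np.ndarray  # (nv, nu) labels, 0 outside
    mask: np.ndarray  # True where data valid


def export_section(
    sol: FieldSolution,
    axis: int,
    offset_mm: float,
    resolution_mm: float = 1.0,
    props: Optional[TissueProperties] = None,
    f_eval: float = 1000.0,
    j_elements: Optional[np.ndarray] = None,
) -> SectionGrid:
    """Sample φ (nodal interpolation) and J (element lookup) on a plane.

    ``axis`` is the plane normal; the in-plane axes are the remaining two in
    ascending order.  Cells outside the mesh are flagged in ``mask`` and hold
    NaN/0 values.
    """
    mesh = sol.mesh
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    if not lo[axis] <= offset_mm <= hi[axis]:
        raise ValueError(
            f"plane {'xyz'[axis]}={offset_mm} mm does not intersect the mesh "
            f"(range [{lo[axis]:.2f}, {hi[axis]:.2f}])"
        )
    if j_elements is None:
        if props is None:
            raise ValueError("provide props (or precomputed j_elements)")
        j_elements = current_density(sol, props, f_eval)
    u_ax, v_ax = [a for a in range(3) if a != axis]
    cu = np.arange(lo[u_ax], hi[u_ax] + resolution_mm / 2, resolution_mm)
    cv = np.arange(lo[v_ax], hi[v_ax] + resolution_mm / 2, resolution_mm)
    U, V = np.meshgrid(cu, cv, indexing="xy")
    pts = np.empty((U.size, 3))
    pts[:, axis] = offset_mm
    pts[:, u_ax] = U.ravel()
    pts[:, v_ax] = V.ravel()
    tet_idx, bary = mesh.locate(pts)
    ok = tet_idx >= 0
    phi_nodal = sol.phi if sol.phi.ndim == 1 else sol.phi[-1]
    phi = np.full(U.size, np.nan, dtype=phi_nodal.dtype)
    safe = np.clip(tet_idx, 0, None)
    phi_vals = np.einsum(
        "qi,qi->q", bary, phi_nodal[mesh.tets[safe]]
    )
    phi[ok] = phi_vals[ok]
    jv = np.zeros((U.size, 3), dtype=j_elements.dtype)
    jv[ok] = j_elements[safe[ok]]
    jm = np.linalg.norm(np.abs(jv), axis=1)
    tissue = np.zeros(U.size, dtype=np.int64)
    tissue[ok] = mesh.tissue_tags[safe[ok]]
    shape = U.shape
    return SectionGrid(
        axis=axis,
        offset_mm=offset_mm,
        coords_u=cu,
        coords_v=cv,
        phi=np.abs(phi).reshape(shape) if np.iscomplexobj(phi) else phi.reshape(shape),
        j_mag=jm.reshape(shape),
        j_vec=jv.reshape(shape + (3,)),
        tissue=tissue.reshape(shape),
        mask=ok.reshape(shape),
    )
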