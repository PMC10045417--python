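"""Quasi-static complex-conductivity finite-element solver.

Solves ∇·(−σ̃∇φ) ≈ 0 with σ̃ = σ + iωε₀εᵣ on a tagged tetrahedral mesh, with
impressed-current electrode patches (uniform normal flux, renormalized to ±I)
and an insulating exterior elsewhere (natural boundary condition).  Phasor and
transient (backward-difference BDF2) modes share the same P1 assembly.

Geometry is in mm; assembly converts to SI metres, so potentials are volts and
current densities A/m².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import yaml
from scipy import sparse
from scipy.sparse.linalg import splu

from .meshing import TetMesh
from .phantom import TISSUE_LABELS, TISSUE_NAMES

__all__ = [
    "EPS0",
    "TissueProperties",
    "default_tissue_properties",
    "tissue_properties_at",
    "complex_conductivity",
    "ElectrodeSpec",
    "StimulusWaveform",
    "StimulusProtocol",
    "FieldSolution",
    "SolverError",
    "assemble",
    "electrode_load",
    "boundary_flux_load",
    "ElectrodeLoad",
    "solve_phasor",
    "solve_transient",
    "current_density",
    "recovered_current",
]

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

MAX_CURRENT_A = 0.020  # safety limit on injected current


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# tissue electrical properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProperties:
    """Per-tissue (frequency, σ, εᵣ) tables.

    ``table`` maps tissue label → (freq_hz, sigma_s_per_m, eps_r) arrays with
    strictly increasing frequencies.
    """

    table: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for lab, (f, s, e) in self.table.items():
            f, s, e = (np.asarray(v, dtype=float) for v in (f, s, e))
            if not (np.all(np.diff(f) > 0) and np.all(s > 0) and np.all(e > 0)):
                raise ValueError(
                    f"tissue {lab}: frequencies must increase, sigma/eps_r > 0"
                )
            object.__setattr__(self, "table", {**self.table, lab: (f, s, e)})

    @property
    def labels(self) -> list[int]:
        return sorted(self.table)


# Printed four-row dispersion table per tissue: frequency (Hz), σ (S/m), εᵣ.
# Marrow has no separate row and reuses the skeleton values.
_FREQS = np.array([1e3, 1e4, 1e5, 1e6])
_TABLE_BY_NAME: dict[str, tuple[list[float], list[float]]] = {
    "skin": ([2.00e-4, 2.04e-4, 4.51e-4, 1.32e-2],
             [1.14e3, 1.13e3, 1.12e3, 9.91e2]),
    "fat": ([2.24e-2, 2.38e-2, 2.44e-2, 2.51e-2],
            [2.41e4, 1.09e3, 9.29e1, 2.72e1]),
    "muscle": ([3.20e-1, 3.40e-1, 3.60e-1, 5.00e-1],
               [4.30e5, 2.60e4, 8.10e3, 1.80e3]),
    "cortical_bone": ([2.02e-3, 2.04e-3, 2.08e-3, 2.44e-3],
                      [2.70e3, 5.22e2, 2.27e2, 1.45e2]),
    "marrow": ([2.02e-3, 2.04e-3, 2.08e-3, 2.44e-3],
               [2.70e3, 5.22e2, 2.27e2, 1.45e2]),
}


def default_tissue_properties() -> TissueProperties:
    """The built-in dispersion table (1 kHz – 1 MHz, four points per tissue)."""
    table = {
        TISSUE_LABELS[name]: (_FREQS.copy(), np.array(sig), np.array(epsr))
        for name, (sig, epsr) in _TABLE_BY_NAME.items()
    }
    return TissueProperties(table=table)


def tissue_properties_at(
    props: TissueProperties, tissue: int | str, f: float
) -> tuple[float, float]:
    """(σ, εᵣ) at frequency ``f``; log-log linear interpolation between rows.

    Exact table values at tabulated frequencies; no extrapolation outside the
    tabulated range.
    """
    if isinstance(tissue, str):
        tissue = TISSUE_LABELS[tissue]
    if tissue not in props.table:
        raise KeyError(
            f"no properties for tissue {tissue} "
            f"({TISSUE_NAMES.get(tissue, 'unknown')})"
        )
    freqs, sig, epsr = props.table[tissue]
    if not freqs[0] <= f <= freqs[-1]:
        raise ValueError(
            f"frequency {f} Hz outside tabulated range "
            f"[{freqs[0]}, {freqs[-1]}] Hz (no extrapolation)"
        )
    # exact at tabulated points (avoid round-trip through logs)
    hit = np.nonzero(freqs == f)[0]
    if len(hit):
        i = int(hit[0])
        return float(sig[i]), float(epsr[i])
    lf = np.log(f)
    s = np.exp(np.interp(lf, np.log(freqs), np.log(sig)))
    e = np.exp(np.interp(lf, np.log(freqs), np.log(epsr)))
    return float(s), float(e)


def complex_conductivity(
    props: TissueProperties, tissue: int | str, f: float
) -> complex:
    """σ̃ = σ + iωε₀εᵣ evaluated at material frequency ``f`` (ω = 2πf)."""
    s, e = tissue_properties_at(props, tissue, f)
    return s + 1j * 2 * np.pi * f * EPS0 * e


# ---------------------------------------------------------------------------
# protocol types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeSpec:
    """Square patch electrode on the body surface.

    ``axis`` (0=x, 1=y, 2=z) with ``sign`` gives the outward direction the
    patch faces; boundary faces are selected whose outward normal has a
    positive component (> 0.5) along it and whose centroid falls inside the
    patch footprint (``edge_lengths`` tangentially, ``normal_slack`` along the
    axis, all mm).
    """

    center: tuple[float, float, float]
    polarity: int
    axis: int = 0
    sign: int = 1
    edge_lengths: tuple[float, float] = (20.0, 20.0)
    normal_slack: float = 3.0

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if any(e <= 0 for e in self.edge_lengths):
            raise ValueError("edge lengths must be > 0")


@dataclass(frozen=True)
class StimulusWaveform:
    """DC (constant I) or AC (A·sin(2πft)) injected-current waveform."""

    mode: Literal["DC", "AC"]
    amplitude: float  # ampere
    frequency: float = 0.0  # Hz, AC only
    material_frequency: float = 1000.0  # Hz used to evaluate σ, εᵣ

    def __post_init__(self) -> None:
        if self.mode not in ("DC", "AC"):
            raise ValueError("mode must be 'DC' or 'AC'")
        if abs(self.amplitude) > MAX_CURRENT_A:
            raise ValueError(
                f"current amplitude {self.amplitude} A exceeds the "
                f"{MAX_CURRENT_A * 1e3:.0f} mA limit"
            )
        if self.mode == "AC" and self.frequency <= 0:
            raise ValueError("AC waveform requires frequency > 0")

    def current(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.mode == "DC":
            return self.amplitude * np.ones_like(np.asarray(t, dtype=float))
        return self.amplitude * np.sin(2 * np.pi * self.frequency * np.asarray(t))


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrode pair plus waveform."""

    anode: ElectrodeSpec
    cathode: ElectrodeSpec
    waveform: StimulusWaveform

    def __post_init__(self) -> None:
        if self.anode.polarity != 1 or self.cathode.polarity != -1:
            raise ValueError("protocol needs one +1 (anode) and one -1 (cathode)")
        # patches must not overlap (axis-aligned footprint boxes)
        lo_a = np.asarray(self.anode.center) - _half_extent(self.anode)
        hi_a = np.asarray(self.anode.center) + _half_extent(self.anode)
        lo_c = np.asarray(self.cathode.center) - _half_extent(self.cathode)
        hi_c = np.asarray(self.cathode.center) + _half_extent(self.cathode)
        if np.all(lo_a < hi_c) and np.all(lo_c < hi_a):
            raise ValueError("electrode patches overlap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulusProtocol":
        raw = yaml.safe_load(Path(path).read_text())
        def _elec(d: dict, pol: int) -> ElectrodeSpec:
            return ElectrodeSpec(
                center=tuple(d["center"]),
                polarity=pol,
                axis=int(d.get("axis", 0)),
                sign=int(d.get("sign", 1)),
                edge_lengths=tuple(d.get("edge_lengths", (20.0, 20.0))),
                normal_slack=float(d.get("normal_slack", 3.0)),
            )
        wf = raw["waveform"]
        waveform = StimulusWaveform(
            mode=wf["mode"],
            amplitude=float(wf["amplitude"]),
            frequency=float(wf.get("frequency", 0.0)),
            material_frequency=float(wf.get("material_frequency", 1000.0)),
        )
        return cls(
            anode=_elec(raw["anode"], 1),
            cathode=_elec(raw["cathode"], -1),
            waveform=waveform,
        )


def _half_extent(e: ElectrodeSpec) -> np.ndarray:
    h = np.empty(3)
    tang = [a for a in range(3) if a != e.axis]
    h[e.axis] = e.normal_slack
    h[tang[0]] = e.edge_lengths[0] / 2.0
    h[tang[1]] = e.edge_lengths[1] / 2.0
    return h


@dataclass
class FieldSolution:
    """Nodal potential (phasor or time series) on a mesh.

    ``phi``: complex (n,) for phasor mode, real (n_steps, n) for transient.
    ``times`` in seconds for transient mode.  Zero-mean gauge throughout.
    """

    mesh: TetMesh
    phi: np.ndarray
    mode: Literal["phasor", "transient"]
    frequency: float = 0.0
    times: Optional[np.ndarray] = None
    waveform: Optional[StimulusWaveform] = None
    J: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _p1_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-tet barycentric gradients (m, 4, 3) in 1/m and volumes in m^3."""
    e = mesh.edge_matrices() * 1e-3  # mm → m; rows are edge vectors
    vols = np.linalg.det(e) / 6.0
    if np.any(vols <= 0):
        raise SolverError("mesh contains non-positive tet volumes")
    einv = np.linalg.inv(e)  # columns of einv are gradients of λ1..λ3? see below
    # x = v0 + E^T ξ with E rows = edges ⇒ ∇ξ_i = row i of (E^T)^{-1} = col i of E^{-1}
    grads = np.swapaxes(einv, 1, 2)  # (m, 3, 3): row i = ∇λ_{i+1}
    g0 = -grads.sum(axis=1, keepdims=True)
    return np.concatenate([g0, grads], axis=1), vols


def assemble(
    mesh: TetMesh, props: TissueProperties, f_eval: float
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """(Kσ, Kε): P1 stiffness operators for conduction and displacement.

    Kσ uses per-tet σ(f_eval); Kε uses ε₀εᵣ(f_eval).  Both are symmetric
    positive semidefinite with the constants as nullspace.
    """
    tags = np.unique(mesh.tissue_tags)
    sig_lut = np.zeros(int(tags.max()) + 1)
    eps_lut = np.zeros_like(sig_lut)
    for t in tags:
        try:
            s, e = tissue_properties_at(props, int(t), f_eval)
        except KeyError:
            raise SolverError(
                f"missing tissue properties for tag {int(t)} "
                f"({TISSUE_NAMES.get(int(t), 'unknown')})"
            )
        sig_lut[t] = s
        eps_lut[t] = EPS0 * e
    grads, vols = _p1_gradients(mesh)
    ke = np.einsum("mid,mjd,m->mij", grads, grads, vols)  # (m, 4, 4)
    rows = np.broadcast_to(mesh.tets[:, :, None], ke.shape).ravel()
    cols = np.broadcast_to(mesh.tets[:, None, :], ke.shape).ravel()
    n = mesh.n_nodes
    sig_e = sig_lut[mesh.tissue_tags]
    eps_e = eps_lut[mesh.tissue_tags]
    k_sig = sparse.coo_matrix(
        ((ke * sig_e[:, None, None]).ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()
    k_eps = sparse.coo_matrix(
        ((ke * eps_e[:, None, None]).ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()
    return k_sig, k_eps


def lumped_node_volumes(mesh: TetMesh) -> np.ndarray:
    """Nodal quadrature weights (m^3): each tet spreads its volume evenly."""
    vols = mesh.tet_volumes() * 1e-9  # mm^3 → m^3
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.tets.ravel(), np.repeat(vols / 4.0, 4))
    return w


# ---------------------------------------------------------------------------
# electrode load
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeLoad:
    """Load vector for a protocol at unit description current I."""

    b: np.ndarray  # (n,) nodal load, ampere
    current: float
    anode_faces: np.ndarray  # boundary-face row indices
    cathode_faces: np.ndarray
    anode_area_m2: float
    cathode_area_m2: float

    @property
    def realized_j(self) -> float:
        """Realized impressed current density I / s_realized at the anode."""
        return self.current / self.anode_area_m2


def boundary_flux_load(
    mesh: TetMesh,
    selector: Callable[[np.ndarray, np.ndarray], np.ndarray],
    current: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Uniform-flux load over boundary faces chosen by ``selector``.

    ``selector(centroids_mm, normals)`` returns a boolean face mask.  The face
    integral is renormalized so the total injected current is exactly
    ``current`` (ampere).  Returns (b, face_rows, area_m2).
    """
    faces, _, normals, areas_mm2, centroids = mesh.boundary
    sel = np.nonzero(selector(centroids, normals))[0]
    if len(sel) == 0:
        raise SolverError("electrode patch covers no boundary face")
    areas_m2 = areas_mm2[sel] * 1e-6
    total_area = float(areas_m2.sum())
    b = np.zeros(mesh.n_nodes)
    contrib = current * areas_m2 / total_area / 3.0
    for c in range(3):
        np.add.at(b, faces[sel, c], contrib)
    return b, sel, total_area


def _patch_selector(e: ElectrodeSpec):
    h = _half_extent(e)
    center = np.asarray(e.center)
    axis_vec = np.zeros(3)
    axis_vec[e.axis] = e.sign

    def sel(centroids: np.ndarray, normals: np.ndarray) -> np.ndarray:
        inside = np.all(np.abs(centroids - center) <= h[None, :], axis=1)
        facing = normals @ axis_vec > 0.5
        return inside & facing

    return sel


def electrode_load(
    mesh: TetMesh,
    electrodes: Sequence[ElectrodeSpec] | StimulusProtocol,
    current: float,
) -> ElectrodeLoad:
    """Impressed-current load: +I over the anode patch, −I over the cathode.

    Uniform normal flux per patch, renormalized so the anode face integral is
    exactly +I and the cathode exactly −I (realized j = I / s_realized).
    """
    if isinstance(electrodes, StimulusProtocol):
        anode, cathode = electrodes.anode, electrodes.cathode
    else:
        pols = {e.polarity for e in electrodes}
        if len(electrodes) != 2 or pols != {1, -1}:
            raise ValueError("need exactly one anode (+1) and one cathode (-1)")
        anode = next(e for e in electrodes if e.polarity == 1)
        cathode = next(e for e in electrodes if e.polarity == -1)
    try:
        b_a, fa, area_a = boundary_flux_load(mesh, _patch_selector(anode), current)
    except SolverError:
        raise SolverError(_no_face_message(mesh, anode, "anode"))
    try:
        b_c, fc, area_c = boundary_flux_load(
            mesh, _patch_selector(cathode), -current
        )
    except SolverError:
        raise SolverError(_no_face_message(mesh, cathode, "cathode"))
    return ElectrodeLoad(
        b=b_a + b_c,
        current=current,
        anode_faces=fa,
        cathode_faces=fc,
        anode_area_m2=area_a,
        cathode_area_m2=area_c,
    )


def _no_face_message(mesh: TetMesh, e: ElectrodeSpec, name: str) -> str:
    _, _, _, _, centroids = mesh.boundary
    d = np.linalg.norm(centroids - np.asarray(e.center), axis=1)
    i = int(d.argmin())
    return (
        f"{name} patch at {e.center} covers no boundary face; nearest face "
        f"centroid is {tuple(np.round(centroids[i], 2))} ({d[i]:.2f} mm away)"
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _check_compatible(b: np.ndarray) -> None:
    scale = np.abs(b).sum()
    if scale > 0 and abs(b.sum()) > 1e-12 * scale:
        raise SolverError(
            f"incompatible load: sum(b) = {b.sum():.3e} (‖b‖₁ = {scale:.3e})"
        )


def _gauge_weights(mesh: Optional[TetMesh], n: int,
                   weights: Optional[np.ndarray]) -> np.ndarray:
    if weights is not None:
        return np.asarray(weights, dtype=float)
    if mesh is not None:
        return lumped_node_volumes(mesh)
    return np.ones(n)


def _factorize_grounded(a: sparse.spmatrix, ground: int = 0):
    """Sparse LU of ``a`` with one node grounded (row/col zeroed, diag 1).

    Grounding keeps the matrix sparse (unlike a bordered zero-mean Lagrange
    system) and the returned solution is re-gauged afterwards; SuperLU runs in
    symmetric mode without pivoting, valid for these (complex-)symmetric
    positive-definite operators.
    """
    al = a.tolil(copy=True)
    al[ground, :] = 0.0
    al[:, ground] = 0.0
    al[ground, ground] = 1.0
    return splu(
        al.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )


def solve_phasor(
    k_sig: sparse.spmatrix,
    k_eps: sparse.spmatrix,
    b: np.ndarray,
    f: float,
    mesh: Optional[TetMesh] = None,
    weights: Optional[np.ndarray] = None,
    gauge: Literal["zero-mean", "ground", "lagrange"] = "zero-mean",
    ground_node: int = 0,
    rtol: float = 1e-8,
) -> FieldSolution:
    """Solve (Kσ + iωKε)φ = b under the chosen gauge.

    Direct sparse factorization; raises if the residual exceeds ``rtol``·‖b‖.
    ``zero-mean`` grounds one node and re-centres to zero volume-weighted
    mean; ``ground`` leaves φ(ground_node) = 0; ``lagrange`` enforces the
    zero-mean constraint directly through a bordered saddle-point system (an
    independent algebraic route, intended for gauge cross-checks on small
    meshes).
    """
    _check_compatible(b)
    omega = 2 * np.pi * f
    a = (k_sig + 1j * omega * k_eps) if f != 0 else k_sig
    n = a.shape[0]
    w = _gauge_weights(mesh, n, weights)
    if gauge not in ("zero-mean", "ground", "lagrange"):
        raise ValueError(f"unknown gauge {gauge!r}")
    if gauge == "lagrange":
        wc = sparse.csc_matrix(w.reshape(-1, 1).astype(a.dtype))
        big = sparse.bmat([[a, wc], [wc.T, None]], format="csc")
        rhs = np.concatenate([b.astype(big.dtype), [0.0]])
        phi = splu(big).solve(rhs)[:n]
    else:
        lu = _factorize_grounded(a, ground_node)
        rhs = b.astype(complex if f != 0 else float).copy()
        rhs[ground_node] = 0.0
        phi = lu.solve(rhs)
    res = np.linalg.norm(a @ phi - b)
    if res > rtol * max(np.linalg.norm(b), 1e-300):
        raise SolverError(
            f"phasor solve residual {res:.3e} exceeds {rtol:.0e}·‖b‖"
        )
    if gauge == "zero-mean":
        phi = phi - np.average(phi, weights=w)
    return FieldSolution(mesh=mesh, phi=phi, mode="phasor", frequency=f)


def estimate_time_constant(
    k_sig: sparse.spmatrix, k_eps: sparse.spmatrix, b: np.ndarray,
    mesh: Optional[TetMesh] = None, weights: Optional[np.ndarray] = None,
) -> float:
    """Rayleigh-quotient RC time constant from the resistive solution."""
    phi = solve_phasor(k_sig, k_eps, b, 0.0, mesh=mesh, weights=weights).phi
    num = float(phi @ (k_eps @ phi))
    den = float(phi @ (k_sig @ phi))
    if den <= 0:
        raise SolverError("cannot estimate RC time constant from a zero load")
    return num / den


def solve_transient(
    k_sig: sparse.spmatrix,
    k_eps: sparse.spmatrix,
    waveform: StimulusWaveform,
    b_unit: np.ndarray,
    dt: Optional[float] = None,
    t_end: Optional[float] = None,
    mesh: Optional[TetMesh] = None,
    weights: Optional[np.ndarray] = None,
    scheme: Literal["bdf2", "be"] = "bdf2",
    tau: Optional[float] = None,
) -> FieldSolution:
    """March (Kσ + Kε d/dt)φ = I(t)·b_unit from φ(0) = 0.

    ``b_unit`` is the electrode load for a 1 A injection; the waveform scales
    it each step.  Backward-difference stepping: BDF2 with an at-rest ghost
    history (φ(−Δt) = 0, valid since the body is undisturbed before injection),
    so one factorization serves the whole march; ``scheme="be"`` forces plain
    backward Euler.  Defaults: AC → 64 steps per cycle for 4 cycles;
    DC → Δt = τ/8, T = 16τ with τ the Rayleigh-quotient RC estimate (pass
    ``tau`` to skip that extra solve).
    """
    _check_compatible(b_unit)
    if waveform.mode == "AC":
        f = waveform.frequency
        if dt is None:
            dt = 1.0 / (64.0 * f)
        if dt > 1.0 / (16.0 * f):
            raise SolverError(
                f"Δt = {dt:.3e} s under-resolves the {f} Hz cycle "
                f"(need Δt ≤ 1/(16f) = {1/(16*f):.3e} s)"
            )
        if t_end is None:
            t_end = 4.0 / f
    else:
        if dt is None or t_end is None:
            if tau is None:
                tau = estimate_time_constant(
                    k_sig, k_eps, b_unit, mesh=mesh, weights=weights
                )
            if dt is None:
                dt = tau / 8.0
            if t_end is None:
                t_end = 16.0 * tau
    if dt <= 0 or t_end < dt:
        raise ValueError("need dt > 0 and t_end >= dt")

    n = k_sig.shape[0]
    w = _gauge_weights(mesh, n, weights)
    n_steps = int(np.ceil(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    phi = np.zeros((n_steps + 1, n))
    cur = np.asarray(waveform.current(times))

    if scheme == "be":
        lu = _factorize_grounded(k_sig + k_eps / dt)
        for k in range(1, n_steps + 1):
            rhs = cur[k] * b_unit + k_eps @ phi[k - 1] / dt
            rhs[0] = 0.0
            phi[k] = lu.solve(rhs)
    elif scheme == "bdf2":
        lu = _factorize_grounded(k_sig + 1.5 * k_eps / dt)
        for k in range(1, n_steps + 1):
            prev2 = phi[k - 2] if k >= 2 else np.zeros(n)  # ghost: at rest
            rhs = cur[k] * b_unit + k_eps @ (2.0 * phi[k - 1] - 0.5 * prev2) / dt
            rhs[0] = 0.0
            phi[k] = lu.solve(rhs)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    phi -= np.average(phi, axis=1, weights=w)[:, None]
    return FieldSolution(
        mesh=mesh, phi=phi, mode="transient",
        frequency=waveform.frequency if waveform.mode == "AC" else 0.0,
        times=times, waveform=waveform,
    )


# ---------------------------------------------------------------------------
# derived fields
# ---------------------------------------------------------------------------

def element_gradient(mesh: TetMesh, phi_nodal: np.ndarray) -> np.ndarray:
    """Per-element (constant) gradient of a nodal field, in field-unit/m."""
    grads, _ = _p1_gradients(mesh)
    return np.einsum("mid,mi->md", grads, phi_nodal[mesh.tets])


def current_density(
    sol: FieldSolution,
    props: TissueProperties,
    f_eval: float,
    step: int = -1,
) -> np.ndarray:
    """Per-element current density J (A/m²), constant per P1 element.

    Phasor: J = −(σ + iωε₀εᵣ)∇φ (complex, (m, 3)).  Transient: J at time step
    ``step``, −σ∇φ − ε₀εᵣ ∂∇φ/∂t with a backward difference (needs ≥ 2 steps).
    """
    mesh = sol.mesh
    if mesh is None:
        raise SolverError("solution has no mesh reference")
    tags = np.unique(mesh.tissue_tags)
    sig_lut = np.zeros(int(tags.max()) + 1)
    eps_lut = np.zeros_like(sig_lut)
    for t in tags:
        s, e = tissue_properties_at(props, int(t), f_eval)
        sig_lut[t] = s
        eps_lut[t] = EPS0 * e
    sig_e = sig_lut[mesh.tissue_tags][:, None]
    eps_e = eps_lut[mesh.tissue_tags][:, None]
    if sol.mode == "phasor":
        g = element_gradient(mesh, sol.phi)
        omega = 2 * np.pi * sol.frequency
        return -(sig_e + 1j * omega * eps_e) * g
    if sol.phi.ndim != 2 or sol.phi.shape[0] < 2:
        raise SolverError(
            "transient current density needs at least 2 time steps"
        )
    idx = range(sol.phi.shape[0])[step]
    if idx == 0:
        raise SolverError("cannot form a backward difference at step 0")
    g1 = element_gradient(mesh, sol.phi[idx])
    g0 = element_gradient(mesh, sol.phi[idx - 1])
    dt = float(sol.times[idx] - sol.times[idx - 1])
    return -sig_e * g1 - eps_e * (g1 - g0) / dt


def recovered_current(
    mesh: TetMesh, j_elements: np.ndarray, face_rows: np.ndarray
) -> complex:
    """Discrete flux integral of element J over selected boundary faces (A).

    Positive sign convention: current flowing *into* the domain.
    """
    faces, owners, normals, areas_mm2, _ = mesh.boundary
    sel_owners = owners[face_rows]
    flux = np.einsum(
        "fd,fd->f", j_elements[sel_owners], normals[face_rows]
    )  # J·n̂ outward
    return -np.sum(flux * areas_mm2[face_rows] * 1e-6)
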