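"""Closed-form volume-conductor references for solver verification.

Three independent oracles:

* :func:`slab_solution` — 1-D layered slab under uniform impressed flux
  (interface potentials by Ohm's law per layer).
* :func:`annulus_solution` — 2-D two-layer disk with opposing surface-arc
  current injection, solved by a Fourier cosine series with per-mode radial
  transfer matrices.
* :func:`box_patch_solution` — homogeneous rectangular box with square patch
  electrodes on opposite z faces, solved by a double Fourier-cosine series;
  exactly voxelizable geometry, used for mesh-convergence studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .solver import EPS0

__all__ = [
    "SlabLayer",
    "SlabSpec",
    "slab_solution",
    "annulus_solution",
    "box_patch_solution",
]


@dataclass(frozen=True)
class SlabLayer:
    thickness_mm: float
    sigma: float  # S/m
    eps_r: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0 or self.sigma <= 0 or self.eps_r < 0:
            raise ValueError("need thickness > 0, sigma > 0, eps_r >= 0")

    def sigma_tilde(self, f: float) -> complex:
        return self.sigma + 1j * 2 * np.pi * f * EPS0 * self.eps_r


@dataclass(frozen=True)
class SlabSpec:
    """Stack of layers under uniform impressed flux J0 (A/m²) at frequency f."""

    layers: tuple[SlabLayer, ...]
    j0: float
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")


def slab_solution(spec: SlabSpec) -> np.ndarray:
    """Potentials at the layer interfaces (len(layers)+1 values), zero-mean.

    Current flows from the last interface (entry, high potential) toward the
    first; the drop across layer k is J0·d_k/σ̃_k.  The gauge is the
    thickness-weighted (volume) mean of the piecewise-linear potential.
    """
    drops = np.array(
        [spec.j0 * (l.thickness_mm * 1e-3) / l.sigma_tilde(spec.frequency)
         for l in spec.layers]
    )
    pots = np.concatenate([[0.0], np.cumsum(drops)])
    # volume-weighted mean of a piecewise-linear profile
    d = np.array([l.thickness_mm for l in spec.layers])
    mids = (pots[:-1] + pots[1:]) / 2.0
    mean = (mids * d).sum() / d.sum()
    return pots - mean


@dataclass(frozen=True)
class AnnulusLayer:
    sigma: complex  # σ̃ of the layer (complex allowed)


def annulus_solution(
    inner_sigma: complex,
    outer_sigma: complex,
    a_mm: float,
    b_mm: float,
    arc_halfwidth_rad: float,
    current_per_height: float,
    n_terms: int = 64,
    tail_tol: float = 0.01,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Series solution of the two-layer disk conduction problem.

    Inner disk r < a with ``inner_sigma``; annulus a < r < b with
    ``outer_sigma``.  Current ``current_per_height`` (A per metre of extruded
    height) enters through the arc |θ| < α at r = b and leaves through the
    opposite arc |θ − π| < α.  Returns an evaluator ``phi(r_mm, theta)`` in
    volts (zero mean by the series' odd-harmonic structure).

    Raises if the relative series tail bound exceeds ``tail_tol``.
    """
    if not 0 < a_mm < b_mm:
        raise ValueError("need 0 < a < b")
    if not 0 < arc_halfwidth_rad < np.pi / 2:
        raise ValueError("arc half-width must be in (0, π/2)")
    if n_terms < 8:
        raise ValueError("n_terms must be >= 8")
    a = a_mm * 1e-3
    b = b_mm * 1e-3
    alpha = arc_halfwidth_rad
    j0 = current_per_height / (2 * alpha * b)  # A/m² on the arc
    s1, s2 = complex(inner_sigma), complex(outer_sigma)
    kappa = (s2 - s1) / (s2 + s1)
    t = a / b

    ns = np.arange(1, n_terms + 1, 2)  # odd harmonics only
    g = 4 * j0 * np.sin(ns * alpha) / (np.pi * ns)  # flux cosine coefficients
    # normalized radial basis: inner A'(r/a)^n, outer B'(r/b)^n + C'(r/b)^-n
    B = g * b / (s2 * ns * (1.0 - kappa * t ** (2 * ns)))
    C = B * kappa * t ** (2.0 * ns)
    A = B * t**ns * (1.0 + kappa)

    # tail bound on the outer-boundary value of the truncated remainder
    scale = abs(np.sum(B + C))
    tail = (4 * j0 * b) / (np.pi * abs(s2) * (1 - abs(kappa))) / (2 * n_terms)
    if scale > 0 and tail / scale > tail_tol:
        raise ValueError(
            f"series tail bound {tail / scale:.2%} exceeds {tail_tol:.0%}; "
            "increase n_terms"
        )

    real_inputs = abs(s1.imag) == 0 and abs(s2.imag) == 0

    def phi(r_mm: np.ndarray, theta: np.ndarray) -> np.ndarray:
        r = np.atleast_1d(np.asarray(r_mm, dtype=float)) * 1e-3
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        shape = np.broadcast_shapes(r.shape, theta.shape)
        r_b = np.broadcast_to(r, shape).ravel()
        th_b = np.broadcast_to(theta, shape).ravel()
        out = np.zeros(len(r_b), dtype=complex)
        inner = r_b < a
        cosmat = np.cos(th_b[:, None] * ns[None, :])
        if inner.any():
            ri = r_b[inner] / a
            out[inner] = (
                A[None, :] * ri[:, None] ** ns[None, :] * cosmat[inner]
            ).sum(axis=1)
        if (~inner).any():
            ro = r_b[~inner] / b
            # C (r/b)^-n = B κ (a²/(b r))^n, with a²/(br) < a/b < 1 for r > a
            decay = (a * a) / (b * b * ro)
            out[~inner] = (
                B[None, :]
                * (ro[:, None] ** ns[None, :]
                   + kappa * decay[:, None] ** ns[None, :])
                * cosmat[~inner]
            ).sum(axis=1)
        out = out.reshape(shape)
        return out.real if real_inputs else out

    return phi


def box_patch_solution(
    lx_mm: float,
    ly_mm: float,
    lz_mm: float,
    patch_x_mm: tuple[float, float],
    patch_y_mm: tuple[float, float],
    sigma: complex,
    current: float,
    n_modes: int = 96,
) -> Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Series solution for a homogeneous box with opposed patch electrodes.

    Insulating walls except a rectangular patch on z = Lz (current +I in) and
    the same footprint on z = 0 (current −I out).  Double cosine expansion in
    (x, y); returns an evaluator ``phi(x_mm, y_mm, z_mm)`` with zero volume
    mean.
    """
    lx, ly, lz = lx_mm * 1e-3, ly_mm * 1e-3, lz_mm * 1e-3
    x0, x1 = (v * 1e-3 for v in patch_x_mm)
    y0, y1 = (v * 1e-3 for v in patch_y_mm)
    if not (0 <= x0 < x1 <= lx and 0 <= y0 < y1 <= ly):
        raise ValueError("patch footprint must lie inside the box")
    area = (x1 - x0) * (y1 - y0)
    j0 = current / area  # A/m² on each patch
    s = complex(sigma)

    m = np.arange(n_modes + 1)

    def cos_coeff(n: np.ndarray, lo: float, hi: float, L: float) -> np.ndarray:
        """Coefficients of 1_[lo,hi] in the cosine basis cos(nπx/L)."""
        c = np.empty(len(n))
        c[0] = (hi - lo) / L
        nn = n[1:]
        k = nn * np.pi / L
        c[1:] = 2.0 * (np.sin(k * hi) - np.sin(k * lo)) / (k * L)
        return c

    cx = cos_coeff(m, x0, x1, lx)
    cy = cos_coeff(m, y0, y1, ly)
    kx = m * np.pi / lx
    ky = m * np.pi / ly
    K = np.sqrt(kx[:, None] ** 2 + ky[None, :] ** 2)  # (m, n)
    Cmn = j0 * cx[:, None] * cy[None, :]
    # Both patches impose σ Z'(0) = σ Z'(Lz) = C_mn, so each non-(0,0) mode is
    # Z(z) = Q sinh(k(z − Lz/2)) / cosh(k Lz/2) with Q = C/(σk); the (0,0)
    # mode is the uniform through-flow, linear in z.
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = Cmn / (s * K)
    Q[0, 0] = 0.0

    def phi(x_mm: np.ndarray, y_mm: np.ndarray, z_mm: np.ndarray) -> np.ndarray:
        x = np.asarray(x_mm, dtype=float) * 1e-3
        y = np.asarray(y_mm, dtype=float) * 1e-3
        z = np.asarray(z_mm, dtype=float) * 1e-3
        shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
        x, y, z = (np.broadcast_to(v, shape).ravel() for v in (x, y, z))
        cxq = np.cos(np.outer(x, kx))  # (q, m+1)
        cyq = np.cos(np.outer(y, ky))
        out = np.zeros(len(x), dtype=complex)
        uz, inv = np.unique(z, return_inverse=True)
        for lvl, zz in enumerate(uz):
            idx = np.nonzero(inv == lvl)[0]
            zmat = Q * np.sinh(K * (zz - lz / 2.0)) / np.cosh(K * lz / 2.0)
            out[idx] = np.einsum(
                "qm,mn,qn->q", cxq[idx], zmat, cyq[idx], optimize=True
            )
        out = out + (j0 * cx[0] * cy[0] / s) * (z - lz / 2.0)
        if abs(s.imag) < 1e-300:
            return out.real.reshape(shape)
        return out.reshape(shape)

    return phi
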