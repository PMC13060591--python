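"""Quasi-static potential solve and field post-processing.

The pulse is long (ms) compared with any dielectric relaxation time, so each
pulse is modelled as a steady conduction problem: solve div(sigma grad phi)=0
on the conductivity grid with Dirichlet electrode rows (anode under the
tissue at +V, cathode in the reservoir at 0 V) and insulating side walls.
The discretization is a flux-conservative finite-difference scheme with
harmonic-mean face conductivities, which resolves sharp conductor/insulator
contrasts without flux leakage; the resulting symmetric M-matrix system is
solved directly (or by preconditioned conjugate gradients on request).

The field magnitude is the central-difference gradient of the potential, and
an optional Gaussian smoothing stands in for the sub-grid spreading of the
field around each nanochannel mouth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .chip import ConductivityGrid
from .errors import ConfigurationError, SolverError

__all__ = [
    "PulseProtocol",
    "BoundaryConditions",
    "PotentialGrid",
    "FieldGrid",
    "solve_potential",
    "field_magnitude",
    "smooth_field",
]


@dataclass(frozen=True)
class PulseProtocol:
    """Electroporation pulse train: defaults 200 V, 10 ms, 10 pulses."""

    voltage: float = 200.0
    pulse_ms: float = 10.0
    n_pulses: int = 10
    gap_ms: float = 100.0

    def __post_init__(self):
        if self.voltage < 0:
            raise ConfigurationError("voltage must be >= 0")
        if self.pulse_ms <= 0:
            raise ConfigurationError("pulse duration must be > 0")
        if self.n_pulses < 1:
            raise ConfigurationError("n_pulses must be >= 1")
        if self.gap_ms < 0:
            raise ConfigurationError("inter-pulse gap must be >= 0")


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet electrode rows; side walls are zero-normal-flux.

    ``anode_rows`` are held at ``voltage`` (the positive electrode placed
    under the nerve), ``cathode_rows`` at 0 V (reservoir electrode).
    """

    anode_rows: tuple[int, ...]
    cathode_rows: tuple[int, ...]
    voltage: float

    def __post_init__(self):
        if not self.anode_rows or not self.cathode_rows:
            raise ConfigurationError("anode and cathode row sets must be non-empty")
        if set(self.anode_rows) & set(self.cathode_rows):
            raise ConfigurationError("anode and cathode rows must be disjoint")
        if self.voltage < 0:
            raise ConfigurationError("voltage must be >= 0")

    @classmethod
    def plate_electrodes(cls, n_rows: int, voltage: float) -> "BoundaryConditions":
        """Bottom row = anode (+V), top row = cathode (0 V)."""
        return cls(anode_rows=(n_rows - 1,), cathode_rows=(0,), voltage=voltage)


@dataclass
class PotentialGrid:
    """Solved electric potential (V) on the grid; spacing in µm."""

    values: np.ndarray
    spacing: float


@dataclass
class FieldGrid:
    """Electric-field magnitude (V/m) on the grid; spacing in µm."""

    values: np.ndarray
    spacing: float


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def solve_potential(
    sigma: ConductivityGrid,
    bc: BoundaryConditions,
    tol: float = 1e-8,
    max_iter: int = 50_000,
    method: str = "direct",
    sigma_floor: float = 1e-15,
) -> PotentialGrid:
    """Solve div(sigma grad phi) = 0 with the stated boundary conditions.

    Parameters
    ----------
    sigma
        Conductivity grid (S/m); values are floored at ``sigma_floor`` so
        insulators stay strictly positive.
    bc
        Electrode rows and applied voltage.
    tol
        Relative residual target for the assembled linear system.
    max_iter
        Iteration cap for ``method='cg'``.
    method
        ``'direct'`` (sparse LU, default) or ``'cg'`` (Jacobi-preconditioned
        conjugate gradients).

    Raises
    ------
    SolverError
        If the residual target is not met; the error carries the residual.
    """
    s = np.maximum(np.asarray(sigma.sigma, dtype=float), sigma_floor)
    nr, nc = s.shape
    n = nr * nc

    fixed = np.zeros((nr, nc), dtype=bool)
    phi_fixed = np.zeros((nr, nc), dtype=float)
    for r in bc.cathode_rows:
        fixed[r, :] = True
    for r in bc.anode_rows:
        fixed[r, :] = True
        phi_fixed[r, :] = bc.voltage

    if bc.voltage == 0.0:
        return PotentialGrid(values=np.zeros((nr, nc)), spacing=sigma.spacing)

    # Face conductances; square cells, so the geometric factor cancels.
    gv = _harmonic(s[:-1, :], s[1:, :])  # between (r, c) and (r+1, c)
    gh = _harmonic(s[:, :-1], s[:, 1:])  # between (r, c) and (r, c+1)

    idx = np.arange(n).reshape(nr, nc)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)

    def couple(ia: np.ndarray, ib: np.ndarray, g: np.ndarray):
        ia, ib, g = ia.ravel(), ib.ravel(), g.ravel()
        fa, fb = fixed.ravel()[ia], fixed.ravel()[ib]
        pf = phi_fixed.ravel()
        np.add.at(diag, ia[~fa], g[~fa])
        np.add.at(diag, ib[~fb], g[~fb])
        both_free = ~fa & ~fb
        rows.append(ia[both_free]); cols.append(ib[both_free]); vals.append(-g[both_free])
        rows.append(ib[both_free]); cols.append(ia[both_free]); vals.append(-g[both_free])
        a_free_b_fixed = ~fa & fb
        np.add.at(b, ia[a_free_b_fixed], g[a_free_b_fixed] * pf[ib[a_free_b_fixed]])
        b_free_a_fixed = fa & ~fb
        np.add.at(b, ib[b_free_a_fixed], g[b_free_a_fixed] * pf[ia[b_free_a_fixed]])

    couple(idx[:-1, :], idx[1:, :], gv)
    couple(idx[:, :-1], idx[:, 1:], gh)

    free = ~fixed.ravel()
    free_idx = np.flatnonzero(free)
    remap = -np.ones(n, dtype=int)
    remap[free_idx] = np.arange(free_idx.size)

    rows = remap[np.concatenate(rows)]
    cols = remap[np.concatenate(cols)]
    vals = np.concatenate(vals)
    m = free_idx.size
    A = sp.coo_matrix(
        (np.concatenate([vals, diag[free_idx]]),
         (np.concatenate([rows, np.arange(m)]),
          np.concatenate([cols, np.arange(m)]))),
        shape=(m, m),
    ).tocsr()
    rhs = b[free_idx]

    if method == "direct":
        x = spla.spsolve(A, rhs)
    elif method == "cg":
        pre = spla.LinearOperator((m, m), matvec=lambda v: v / A.diagonal())
        x, info = spla.cg(A, rhs, rtol=tol, maxiter=max_iter, M=pre)
        if info > 0:
            res = float(np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
            raise SolverError(
                f"CG did not converge within {max_iter} iterations", residual=res
            )
    else:
        raise ConfigurationError(f"unknown solver method {method!r}")

    denom = max(float(np.linalg.norm(rhs)), 1e-300)
    residual = float(np.linalg.norm(A @ x - rhs)) / denom
    if not np.isfinite(residual) or residual > max(tol, 1e-6):
        raise SolverError(f"residual {residual:g} exceeds tolerance", residual=residual)

    phi = phi_fixed.copy()
    phi.ravel()[free_idx] = x
    # clamp rounding-level excursions beyond the electrode potentials
    phi = np.clip(phi, 0.0, bc.voltage)
    return PotentialGrid(values=phi, spacing=sigma.spacing)


def field_magnitude(
    phi: PotentialGrid, sigma: ConductivityGrid | None = None
) -> FieldGrid:
    """|E| (V/m) from the potential: central differences in the interior,
    one-sided at the edges.

    When ``sigma`` is given, the conduction field |J|/sigma is returned
    instead, computed from the same harmonic-mean face fluxes the solver
    conserves.  The two coincide exactly in homogeneous media; across
    sharp conductor/insulator interfaces the conduction field is the
    physically meaningful driving field in the tissue (a plain gradient
    straddling the material jump reports a spurious interface field).
    """
    if phi.values.shape[0] < 2 or phi.values.shape[1] < 2:
        raise ConfigurationError("field gradient needs at least a 2x2 grid")
    h_m = phi.spacing * 1e-6
    if sigma is None:
        gy, gx = np.gradient(phi.values, h_m)
        return FieldGrid(values=np.hypot(gy, gx), spacing=phi.spacing)

    s = np.asarray(sigma.sigma, dtype=float)
    if s.shape != phi.values.shape:
        raise ConfigurationError("conductivity and potential shapes differ")
    v = phi.values

    def axis_field(axis: int) -> np.ndarray:
        sl_a = [slice(None)] * 2
        sl_b = [slice(None)] * 2
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        g = _harmonic(s[tuple(sl_a)], s[tuple(sl_b)])
        j_face = g * (v[tuple(sl_a)] - v[tuple(sl_b)]) / h_m  # face current density
        e = np.zeros_like(v)
        cnt = np.zeros_like(v)
        e[tuple(sl_a)] += j_face
        cnt[tuple(sl_a)] += 1
        e[tuple(sl_b)] += j_face
        cnt[tuple(sl_b)] += 1
        return e / np.maximum(cnt, 1) / np.maximum(s, 1e-300)

    return FieldGrid(
        values=np.hypot(axis_field(0), axis_field(1)), spacing=phi.spacing
    )


def smooth_field(
    field: FieldGrid, sigma_smooth: float = 1.0, mask: np.ndarray | None = None
) -> FieldGrid:
    """Gaussian-smooth the field map (sigma in cells, reflective boundaries).

    ``sigma_smooth = 0`` is the identity; constant fields are fixed points.

    With ``mask`` the smoothing is normalized over the masked region
    (smooth(E*m)/smooth(m), zero outside), so values outside the mask —
    e.g. the enormous dielectric field inside the insulating chip body —
    never bleed into the region of interest.  Constants on the mask remain
    fixed points.
    """
    if sigma_smooth < 0:
        raise ConfigurationError("sigma_smooth must be >= 0")
    if sigma_smooth == 0:
        out = field.values.copy()
        if mask is not None:
            out = out * mask
        return FieldGrid(values=out, spacing=field.spacing)
    if mask is None:
        out = ndi.gaussian_filter(field.values, sigma=sigma_smooth, mode="reflect")
        return FieldGrid(values=out, spacing=field.spacing)
    m = np.asarray(mask, dtype=float)
    num = ndi.gaussian_filter(field.values * m, sigma=sigma_smooth, mode="reflect")
    den = ndi.gaussian_filter(m, sigma=sigma_smooth, mode="reflect")
    out = np.zeros_like(num)
    nz = den > 1e-12
    out[nz] = num[nz] / den[nz]
    out = out * (m > 0)
    return FieldGrid(values=out, spacing=field.spacing)
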