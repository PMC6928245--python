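"""Cytosolic Ca²⁺ diffusion and SR uptake/transfer fluxes.

Transport operates on the (disc, layer) grid of free [Ca²⁺].  Radial
diffusion within each disc uses a conservative finite-volume stencil on the
concentric annuli, integrated implicitly (backward Euler, one tridiagonal
solve per disc per step) so the fine radial mesh imposes no stability limit
on the time step.  Longitudinal diffusion between discs is explicit — the
inter-disc spacing is coarse, so its stability bound is far above any dt the
engine uses — with the longitudinal coefficient reduced to 70% of the radial
one (anisotropy of the observed cell-wide waves).  Both directions are
flux-form, hence mass-conserving to solver precision, with no-flux walls at
the sarcolemma and at both cell ends; membrane and SR fluxes enter as
separate source terms.

Cytosolic buffering is folded into the effective diffusion coefficients and
flux magnitudes (the dynamic field is free Ca²⁺); see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .geometry import CellGeometry, CytosolGrid, SRState

__all__ = [
    "DiffusionParams",
    "SercaParams",
    "diffusion_step",
    "serca_uptake",
    "nsr_jsr_transfer",
    "longitudinal_dt_max",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Effective cytosolic diffusion coefficients, µm²/ms."""

    d_radial: float = 0.8
    d_longitudinal: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.d_longitudinal is None:
            object.__setattr__(self, "d_longitudinal", 0.7 * self.d_radial)
        if self.d_radial <= 0 or self.d_longitudinal <= 0:
            raise ValueError("diffusion coefficients must be positive")


@dataclass(frozen=True)
class SercaParams:
    """Hill-type SERCA uptake from each disc's core region into its NSR.

    ``vmax`` is a molar rate per disc (µM·µm³/ms); ``km`` the half-activation
    cytosolic [Ca²⁺] (µM); ``hill`` the Hill coefficient; ``modifier`` the
    multiplicative conductance factor (1.2 under isoproterenol).
    """

    vmax: float = 40.0
    km: float = 1.35
    hill: float = 6.0
    modifier: float = 1.0

    def scaled(self, factor: float) -> "SercaParams":
        return replace(self, modifier=self.modifier * factor)


@njit(cache=True, error_model="numpy")
def _radial_matrix(edges: np.ndarray, hz: float, d_r: float):
    """Per-layer volumes and inter-layer conductances g_k = D·A_k/dr.

    g[k] couples layer k and k+1 through the cylindrical face at r=edges[k+1];
    units µm³/ms so that g·Δc is a molar flux in µM·µm³/ms.
    """
    n = edges.shape[0] - 1
    dr = edges[1] - edges[0]
    vol = np.empty(n)
    g = np.empty(n - 1)
    for k in range(n):
        vol[k] = np.pi * (edges[k + 1] ** 2 - edges[k] ** 2) * hz
    for k in range(n - 1):
        area = 2.0 * np.pi * edges[k + 1] * hz
        g[k] = d_r * area / dr
    return vol, g


@njit(cache=True, error_model="numpy")
def _radial_implicit_disc_ws(
    c: np.ndarray, vol: np.ndarray, g: np.ndarray, dt: float, work: np.ndarray
):
    """Backward-Euler radial diffusion for one disc (Thomas solve), in place.

    ``work`` is a (2, n) scratch array (diagonal and RHS) so the hot loop
    performs no allocation.
    """
    n = c.shape[0]
    b = work[0]
    d = work[1]
    for k in range(n):
        b[k] = vol[k] / dt
        d[k] = vol[k] / dt * c[k]
    for k in range(n - 1):
        b[k] += g[k]
        b[k + 1] += g[k]
    # Thomas algorithm; sub/super diagonals are both -g[k]
    for k in range(1, n):
        w = -g[k - 1] / b[k - 1]
        b[k] -= w * -g[k - 1]
        d[k] -= w * d[k - 1]
    c[n - 1] = d[n - 1] / b[n - 1]
    for k in range(n - 2, -1, -1):
        c[k] = (d[k] + g[k] * c[k + 1]) / b[k]


@njit(cache=True, error_model="numpy")
def _radial_implicit_disc(c: np.ndarray, vol: np.ndarray, g: np.ndarray, dt: float):
    work = np.empty((2, c.shape[0]))
    _radial_implicit_disc_ws(c, vol, g, dt, work)


@njit(cache=True, error_model="numpy")
def _diffusion_step_kernel(
    ca: np.ndarray,
    edges: np.ndarray,
    hz: float,
    d_r: float,
    d_l: float,
    dt: float,
) -> None:
    n_discs, n_layers = ca.shape
    vol, g = _radial_matrix(edges, hz, d_r)
    # explicit longitudinal half-update (flux form, per layer)
    if n_discs > 1:
        flux = np.empty((n_discs - 1, n_layers))
        for j in range(n_discs - 1):
            for k in range(n_layers):
                area_k = vol[k] / hz  # annulus cross-section
                flux[j, k] = d_l * area_k * (ca[j + 1, k] - ca[j, k]) / hz
        for j in range(n_discs - 1):
            for k in range(n_layers):
                ca[j, k] += dt * flux[j, k] / vol[k]
                ca[j + 1, k] -= dt * flux[j, k] / vol[k]
    # implicit radial update disc by disc
    for j in range(n_discs):
        _radial_implicit_disc(ca[j], vol, g, dt)


def longitudinal_dt_max(geometry: CellGeometry, params: DiffusionParams) -> float:
    """Stability bound of the explicit longitudinal stencil, ms."""
    hz = geometry.disc_height
    return hz * hz / (2.0 * params.d_longitudinal)


def diffusion_step(
    grid: CytosolGrid, params: DiffusionParams, dt: float
) -> CytosolGrid:
    """Advance the grid by one diffusion step of ``dt`` ms (no sources).

    Longitudinal transport is explicit and checked against its stability
    bound; radial transport is implicit and unconditionally stable.  Total
    free-Ca mass is conserved to solver precision.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_max = longitudinal_dt_max(grid.geometry, params)
    if dt > dt_max:
        raise ValueError(
            f"dt={dt} ms exceeds the explicit longitudinal stability bound; "
            f"maximum admissible dt is {dt_max:.6g} ms"
        )
    ca = grid.ca.copy()
    _diffusion_step_kernel(
        ca,
        grid.geometry.radial_edges,
        grid.geometry.disc_height,
        params.d_radial,
        params.d_longitudinal,
        dt,
    )
    return CytosolGrid(geometry=grid.geometry, ca=ca)


@njit(cache=True, error_model="numpy")
def _serca_rate(ca_core: float, vmax: float, km: float, hill: float, modifier: float) -> float:
    if ca_core <= 0.0:
        return 0.0
    x = ca_core ** hill
    return modifier * vmax * x / (x + km ** hill)


def serca_uptake(
    grid: CytosolGrid, sr: SRState, params: SercaParams
) -> np.ndarray:
    """Per-disc SERCA molar uptake rate (µM·µm³/ms), cytosol core → NSR.

    Senses the volume-weighted [Ca²⁺] of each disc's core coupling region
    (the innermost ``n_core_coupling_layers`` layers).
    """
    g = grid.geometry
    ncl = g.n_core_coupling_layers
    v = g.layer_volumes[:, :ncl]
    ca_core = (grid.ca[:, :ncl] * v).sum(axis=1) / v.sum(axis=1)
    out = np.empty(g.n_discs)
    for j in range(g.n_discs):
        out[j] = _serca_rate(
            float(ca_core[j]), params.vmax, params.km, params.hill, params.modifier
        )
    return out


def nsr_jsr_transfer(sr: SRState, dt: float, tau_tr: float = 40.0) -> SRState:
    """First-order NSR→JSR refill over ``dt`` ms with time constant ``tau_tr``.

    The exchanged moles are conserved between the two compartments; the
    relaxation is integrated exactly (exponential), so any ``dt`` is stable.
    """
    if dt <= 0 or tau_tr <= 0:
        raise ValueError("dt and tau_tr must be positive")
    g = sr.geometry
    vj, vn = g.jsr_volume, g.nsr_volume
    # both concentrations relax toward the mass-weighted equilibrium
    ceq = (sr.ca_jsr * vj + sr.ca_nsr * vn) / (vj + vn)
    # JSR relaxes toward NSR with rate 1/tau_tr; the pair decays with the
    # combined rate (1/tau_tr)·(1 + vj/vn) toward ceq
    rate = (1.0 / tau_tr) * (1.0 + vj / vn)
    decay = np.exp(-rate * dt)
    jsr = ceq + (sr.ca_jsr - ceq) * decay
    nsr = ceq + (sr.ca_nsr - ceq) * decay
    return SRState(geometry=g, ca_jsr=jsr, ca_nsr=nsr)
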