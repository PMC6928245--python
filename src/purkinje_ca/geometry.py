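"""Spatial discretization and state containers for the cylindrical Purkinje cell.

The cell is a cylinder (default 129 µm long, 8 µm wide) cut into ``n_discs``
axial discs; each disc's cross-section is cut into ``n_layers`` concentric
annular layers of equal radial thickness.  Index conventions, fixed throughout
the package:

* disc index 0 is at one end of the cell, disc ``n_discs - 1`` at the other;
* layer index 0 is the core (the sub-SR region, adjacent to the sarcoplasmic
  reticulum), layer ``n_layers - 1`` is the outermost shell under the
  sarcolemma (the sub-SL region).

The SR itself is not radially resolved: each disc carries a junctional (JSR,
release) and a network (NSR, uptake) compartment as per-disc scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellGeometry",
    "CytosolGrid",
    "SRState",
    "MembraneState",
    "build_geometry",
]


@dataclass(frozen=True)
class CellGeometry:
    """Dimensions and derived volumes of the discretized cylindrical cell.

    Volumes are in µm³, lengths in µm.  ``layer_volumes[j, k]`` is the volume
    of layer ``k`` of disc ``j``; because the discretization is uniform all
    rows are identical, but the full array is kept for clarity of indexing.
    """

    length: float = 129.0
    diameter: float = 8.0
    n_discs: int = 10
    n_layers: int = 81
    sr_volume_fraction_nsr: float = 0.035
    sr_volume_fraction_jsr: float = 0.0002
    n_subsl_layers: int = 1
    n_subsr_layers: int = 1
    # region over which the RyR/SERCA fluxes exchange with the cytosol
    # (None: min(9, n_layers))
    n_core_coupling_layers: int = None  # type: ignore[assignment]

    radial_edges: np.ndarray = field(init=False, repr=False)
    layer_volumes: np.ndarray = field(init=False, repr=False)
    disc_height: float = field(init=False)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("cell length and diameter must be positive")
        if self.n_discs < 2 or self.n_layers < 2:
            raise ValueError("need at least 2 discs and 2 layers")
        if not (1 <= self.n_subsl_layers < self.n_layers):
            raise ValueError("n_subsl_layers out of range")
        if not (1 <= self.n_subsr_layers < self.n_layers):
            raise ValueError("n_subsr_layers out of range")
        if self.n_core_coupling_layers is None:
            object.__setattr__(self, "n_core_coupling_layers", min(9, self.n_layers))
        if not (1 <= self.n_core_coupling_layers <= self.n_layers):
            raise ValueError("n_core_coupling_layers out of range")
        radius = self.diameter / 2.0
        edges = np.linspace(0.0, radius, self.n_layers + 1)
        hz = self.length / self.n_discs
        ring_areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        vols = np.tile(ring_areas * hz, (self.n_discs, 1))
        object.__setattr__(self, "radial_edges", edges)
        object.__setattr__(self, "layer_volumes", vols)
        object.__setattr__(self, "disc_height", hz)

    @property
    def total_volume(self) -> float:
        """Cytosolic cylinder volume π·(d/2)²·L in µm³."""
        return float(np.pi * (self.diameter / 2.0) ** 2 * self.length)

    @property
    def disc_volume(self) -> float:
        return self.total_volume / self.n_discs

    @property
    def membrane_area(self) -> float:
        """Lateral sarcolemmal area π·d·L in µm² (end caps neglected)."""
        return float(np.pi * self.diameter * self.length)

    @property
    def capacitance_pF(self) -> float:
        """Whole-cell capacitance at 1 µF/cm² = 0.01 pF/µm²."""
        return 0.01 * self.membrane_area

    @property
    def nsr_volume(self) -> float:
        """NSR volume per disc, µm³."""
        return self.sr_volume_fraction_nsr * self.disc_volume

    @property
    def jsr_volume(self) -> float:
        """JSR volume per disc, µm³."""
        return self.sr_volume_fraction_jsr * self.disc_volume

    def subsl_volume_per_disc(self) -> float:
        return float(self.layer_volumes[0, -self.n_subsl_layers:].sum())

    def subsr_volume_per_disc(self) -> float:
        return float(self.layer_volumes[0, : self.n_subsr_layers].sum())


def build_geometry(
    length: float = 129.0,
    diameter: float = 8.0,
    n_discs: int = 10,
    n_layers: int = 81,
    **kwargs,
) -> CellGeometry:
    """Construct a :class:`CellGeometry`, validating dimensions.

    Shell volumes come from concentric annuli of equal radial thickness, so
    their per-disc sum equals the disc cylinder volume exactly (to rounding).
    """
    return CellGeometry(
        length=length, diameter=diameter, n_discs=n_discs, n_layers=n_layers, **kwargs
    )


@dataclass
class CytosolGrid:
    """Free cytosolic [Ca²⁺] in µM on the (disc, layer) grid."""

    geometry: CellGeometry
    ca: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ca is None:
            self.ca = np.full(
                (self.geometry.n_discs, self.geometry.n_layers), 0.1, dtype=float
            )
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (self.geometry.n_discs, self.geometry.n_layers):
            raise ValueError("ca array shape does not match geometry")
        if not np.all(np.isfinite(self.ca)) or np.any(self.ca < 0):
            raise ValueError("ca must be finite and non-negative")

    def subsl_mean(self) -> float:
        """Volume-weighted mean [Ca²⁺] of the sub-sarcolemmal layer(s), µM."""
        n = self.geometry.n_subsl_layers
        v = self.geometry.layer_volumes[:, -n:]
        return float((self.ca[:, -n:] * v).sum() / v.sum())

    def subsr_mean(self) -> float:
        """Volume-weighted mean [Ca²⁺] of the sub-SR core layer(s), µM."""
        n = self.geometry.n_subsr_layers
        v = self.geometry.layer_volumes[:, :n]
        return float((self.ca[:, :n] * v).sum() / v.sum())

    def volume_average(self) -> float:
        """Volume-weighted whole-cytosol mean [Ca²⁺], µM."""
        v = self.geometry.layer_volumes
        return float((self.ca * v).sum() / v.sum())

    def total_mass(self) -> float:
        """Total cytosolic free Ca²⁺, µM·µm³."""
        return float((self.ca * self.geometry.layer_volumes).sum())


@dataclass
class SRState:
    """Per-disc junctional and network SR free [Ca²⁺] in µM."""

    geometry: CellGeometry
    ca_jsr: np.ndarray = None  # type: ignore[assignment]
    ca_nsr: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.geometry.n_discs
        if self.ca_jsr is None:
            self.ca_jsr = np.full(n, 600.0)
        if self.ca_nsr is None:
            self.ca_nsr = np.full(n, 600.0)
        self.ca_jsr = np.asarray(self.ca_jsr, dtype=float)
        self.ca_nsr = np.asarray(self.ca_nsr, dtype=float)
        for arr in (self.ca_jsr, self.ca_nsr):
            if arr.shape != (n,):
                raise ValueError("SR arrays must have length n_discs")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("SR concentrations must be finite and non-negative")

    def total_mass(self) -> float:
        """Total SR free Ca²⁺ (JSR + NSR), µM·µm³."""
        g = self.geometry
        return float(self.ca_jsr.sum() * g.jsr_volume + self.ca_nsr.sum() * g.nsr_volume)


@dataclass
class MembraneState:
    """Membrane potential, gating variables and bulk ion concentrations.

    Gating variables are dimensionless in [0, 1]; ``v`` is in mV; ``nai`` and
    ``ki`` in mM.  The gate ordering is defined by
    :data:`purkinje_ca.currents.GATE_NAMES`.
    """

    v: float = -80.0
    gates: np.ndarray = None  # type: ignore[assignment]
    nai: float = 8.0
    ki: float = 140.0

    def __post_init__(self) -> None:
        from .currents import GATE_NAMES

        if self.gates is None:
            self.gates = np.zeros(len(GATE_NAMES))
        self.gates = np.clip(np.asarray(self.gates, dtype=float), 0.0, 1.0)
        if not np.isfinite(self.v):
            raise ValueError("membrane potential must be finite")
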