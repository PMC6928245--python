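"""Stochastic store-overload-induced Ca²⁺ release (SOICR) — the CPVT phenotype.

Mutant RyR2 channels leak spontaneously when the SR is overloaded.  Per
evaluation (once per macro time step) each disc draws ``Y_leak ~ U[0,1]``
and a leak fires on disc ``i`` iff ``Y_leak,i · [Ca]_JSR,i`` exceeds a fixed
threshold.  The default threshold of 594 µM calibrates the per-evaluation
trigger probability to exactly 1% at a JSR load of 600 µM — and, because
``Y ≤ 1``, to zero below 594 µM, making the leak a genuine store-overload
phenomenon.

A triggered disc is assigned an open probability ``Z`` drawn from a
lognormal law (µ = −1.3, σ = 0.5, clipped at 1, median ≈ 0.27) chosen to
mimic open probabilities seen during stimulus-induced action potentials.
While the leak is active the disc's Monte-Carlo gating is suspended and its
RyR open probability follows the sustained decay ``Z · exp(−(t−t₀)/τ)`` with
τ = 125 ms, deactivating once it falls below a floor (default 1% of ``Z``).
At most one disc leaks at a time; if several discs pass threshold in the
same step the largest product ``Y·[Ca]_JSR`` wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LeakParams",
    "LeakState",
    "leak_trigger",
    "assign_leak_popen",
    "leak_popen_at",
]

MU_DEFAULT = -1.3
SIGMA_DEFAULT = 0.5
TAU_DEFAULT = 125.0
THRESHOLD_DEFAULT = 594.0


@dataclass(frozen=True)
class LeakParams:
    enabled: bool = False
    threshold: float = THRESHOLD_DEFAULT  # µM-scaled product threshold
    mu: float = MU_DEFAULT
    sigma: float = SIGMA_DEFAULT
    tau: float = TAU_DEFAULT  # ms
    floor_fraction: float = 0.01  # deactivate when P falls below this × Z

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.floor_fraction < 1):
            raise ValueError("floor_fraction must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class LeakState:
    """State of the (at most one) active spontaneous-release event."""

    active_disc: Optional[int] = None
    z_assigned: float = 0.0
    t_onset: float = 0.0
    tau: float = TAU_DEFAULT

    @property
    def active(self) -> bool:
        return self.active_disc is not None


def leak_trigger(
    ca_jsr_per_disc: np.ndarray,
    y_draws: np.ndarray,
    threshold: float = THRESHOLD_DEFAULT,
) -> Optional[int]:
    """Return the disc index firing a leak this evaluation, or ``None``.

    Disc ``i`` is eligible iff ``y_draws[i] · ca_jsr_per_disc[i] > threshold``;
    among eligible discs the largest product wins (single-disc rule).
    """
    ca = np.asarray(ca_jsr_per_disc, dtype=float)
    y = np.asarray(y_draws, dtype=float)
    if ca.shape != y.shape:
        raise ValueError("ca_jsr_per_disc and y_draws must have equal shapes")
    prod = y * ca
    if not np.any(prod > threshold):
        return None
    return int(np.argmax(prod))


def assign_leak_popen(z_draw: float) -> float:
    """Clip a lognormal draw to the maximum open probability of 1."""
    if z_draw < 0:
        raise ValueError("lognormal draw cannot be negative")
    return min(float(z_draw), 1.0)


def leak_popen_at(t: float, leak: LeakState, floor_fraction: float = 0.01) -> float:
    """Open probability of the leaking disc at time ``t`` (ms).

    Exponential sustain ``Z·exp(−(t−t₀)/τ)``; returns 0 once the value drops
    below ``floor_fraction · Z`` (the event has deactivated).
    """
    if not leak.active:
        return 0.0
    if t < leak.t_onset:
        raise ValueError("t precedes leak onset")
    p = leak.z_assigned * np.exp(-(t - leak.t_onset) / leak.tau)
    if p < floor_fraction * leak.z_assigned:
        return 0.0
    return float(p)
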