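"""Two-state stochastic RyR gating with a per-step Monte-Carlo update.

Each SR disc carries a population of ``N`` identical ryanodine-receptor
channels that flip between closed and open states.  The opening rate is
Ca²⁺-dependent through a fourth-order Hill term in the sub-SR cytosolic
[Ca²⁺] with a half-saturation ``K_m`` that itself falls sigmoidally with
junctional-SR [Ca²⁺] (store sensitization).  The whole-population dynamics

    dP_open/dt = P_close · k_open · (1 + (K_m/Ca_subSR)⁴)⁻¹ − k_close · P_open

are realized stochastically: per time step, at most one channel per disc
opens or closes, chosen by comparing a single uniform draw against the
aggregate transition probabilities

    P_T,open  = k_open · (1 + (K_m/Ca_subSR)⁴)⁻¹ · N_close · dt
    P_T,close = k_close · N_open · dt.

If ``P_T,open + P_T,close`` would exceed 1 the step is subcycled (dt halved
recursively) so the one-transition-per-step semantics is preserved.  An
"open" event with every channel already open (or "close" at zero open) is a
no-op.

The rate constants ``k_open``/``k_close`` and the per-disc channel count are
model parameters (see :mod:`purkinje_ca.config` for defaults and the methods
note for their calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "RyRPopulation",
    "km_ryr",
    "transition_probs",
    "mc_update",
    "ryr_flux",
    "open_prob_ode_rhs",
    "stationary_open_fraction",
]


@dataclass
class RyRPopulation:
    """State of one disc's RyR channel population."""

    n_total: int
    n_open: int = 0
    k_open: float = 1.8  # 1/ms, aggregate opening rate scale
    k_close: float = 1.0  # 1/ms

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 <= self.n_open <= self.n_total):
            raise ValueError("n_open must be in [0, n_total]")
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValueError("rates must be positive")

    @property
    def p_open(self) -> float:
        return self.n_open / self.n_total


@njit(cache=True, error_model="numpy")
def _seed_numba_rng(seed: int) -> None:
    """Seed numba's internal RNG stream (used by the jitted MC update)."""
    np.random.seed(seed)


@njit(cache=True, error_model="numpy")
def _km_ryr(ca_jsr: float) -> float:
    return 3.51 / (1.0 + np.exp((ca_jsr - 530.0) / 200.0)) + 0.25


def km_ryr(ca_jsr: float) -> float:
    """Half-saturation [Ca²⁺] of RyR activation, µM, as a function of JSR load.

    Strictly decreasing from 3.76 µM (empty store) to the 0.25 µM asymptote
    (overloaded store): a fuller store sensitizes the channel to cytosolic Ca.
    """
    if ca_jsr < 0:
        raise ValueError("ca_jsr must be non-negative")
    return float(_km_ryr(ca_jsr))


@njit(cache=True, error_model="numpy")
def _hill_open(ca_subsr: float, km: float) -> float:
    if ca_subsr <= 0.0:
        return 0.0
    r = km / ca_subsr
    return 1.0 / (1.0 + r * r * r * r)


def transition_probs(
    pop: RyRPopulation, ca_subsr: float, ca_jsr: float, dt: float
) -> tuple[float, float]:
    """Aggregate open/close transition probabilities for one time step.

    Returns ``(P_T,open, P_T,close)``.  These scale with ``N·dt``; callers
    integrating in time must subcycle when their sum exceeds 1 (the engine
    does this automatically, see :func:`mc_step`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if ca_subsr < 0 or ca_jsr < 0:
        raise ValueError("concentrations must be non-negative")
    km = _km_ryr(ca_jsr)
    n_close = pop.n_total - pop.n_open
    pt_open = pop.k_open * _hill_open(ca_subsr, km) * n_close * dt
    pt_close = pop.k_close * pop.n_open * dt
    return pt_open, pt_close


def mc_update(pop: RyRPopulation, pt_open: float, pt_close: float, u: float) -> RyRPopulation:
    """Single Monte-Carlo transition given a uniform draw ``u`` ∈ [0, 1].

    ``u < P_T,open`` opens one channel; ``P_T,open ≤ u < P_T,open+P_T,close``
    closes one; otherwise no change.  Boundary events are no-ops.
    """
    if pt_open < 0 or pt_close < 0 or pt_open + pt_close > 1.0 + 1e-12:
        raise ValueError("transition probabilities must be >= 0 and sum to <= 1")
    if not (0.0 <= u <= 1.0):
        raise ValueError("u must lie in [0, 1]")
    n_open = pop.n_open
    if u < pt_open:
        n_open = min(n_open + 1, pop.n_total)
    elif u < pt_open + pt_close:
        n_open = max(n_open - 1, 0)
    return RyRPopulation(
        n_total=pop.n_total, n_open=n_open, k_open=pop.k_open, k_close=pop.k_close
    )


@njit(cache=True, error_model="numpy")
def _mc_step(
    n_open: int,
    n_total: int,
    k_open: float,
    k_close: float,
    ca_subsr: float,
    ca_jsr: float,
    dt: float,
) -> int:
    """Advance one disc's channel count by ``dt``, subcycling as needed.

    Consumes numba's per-thread RNG stream (seed it with ``np.random.seed``
    inside jitted code before use).
    """
    km = _km_ryr(ca_jsr)
    hill = _hill_open(ca_subsr, km)
    # choose the number of subcycles so pt_open + pt_close <= 1 holds even
    # in the worst case (all channels on the faster side)
    worst = max(k_open * hill, k_close) * n_total * dt
    n_sub = 1
    while worst / n_sub > 1.0:
        n_sub *= 2
    h = dt / n_sub
    for _ in range(n_sub):
        pt_open = k_open * hill * (n_total - n_open) * h
        pt_close = k_close * n_open * h
        u = np.random.random()
        if u < pt_open:
            if n_open < n_total:
                n_open += 1
        elif u < pt_open + pt_close:
            if n_open > 0:
                n_open -= 1
    return n_open


def mc_step(
    pop: RyRPopulation, ca_subsr: float, ca_jsr: float, dt: float, rng: np.random.Generator
) -> RyRPopulation:
    """Python-level per-step update with automatic subcycling.

    Uses a numpy ``Generator`` (one draw per subcycle) rather than numba's
    internal stream; the simulation engine uses the jitted twin ``_mc_step``.
    """
    km = _km_ryr(ca_jsr)
    hill = _hill_open(ca_subsr, km)
    worst = max(pop.k_open * hill, pop.k_close) * pop.n_total * dt
    n_sub = 1
    while worst / n_sub > 1.0:
        n_sub *= 2
    h = dt / n_sub
    out = pop
    for _ in range(n_sub):
        pt_open, pt_close = transition_probs(out, ca_subsr, ca_jsr, h)
        out = mc_update(out, pt_open, pt_close, float(rng.random()))
    return out


def ryr_flux(
    pop_or_popen, ca_jsr: float, ca_subsr: float, g_rel: float
) -> float:
    """SR→cytosol release flux in µM·µm³/ms (moles per ms, concentration·volume).

    Linear in the open fraction and the JSR–cytosol driving force:
    ``g_rel · P_open · (ca_jsr − ca_subsr)`` with ``g_rel`` in µm³/ms.
    """
    p_open = pop_or_popen.p_open if isinstance(pop_or_popen, RyRPopulation) else float(pop_or_popen)
    return g_rel * p_open * (ca_jsr - ca_subsr)


def open_prob_ode_rhs(
    p_open: float, ca_subsr: float, ca_jsr: float, k_open: float, k_close: float
) -> float:
    """Deterministic mean-field RHS dP_open/dt for the two-state scheme."""
    km = _km_ryr(ca_jsr)
    return (1.0 - p_open) * k_open * _hill_open(ca_subsr, km) - k_close * p_open


def stationary_open_fraction(
    ca_subsr: float, ca_jsr: float, k_open: float, k_close: float
) -> float:
    """Closed-form stationary open fraction k'ₒ/(k'ₒ + k_c) at clamped Ca²⁺."""
    km = _km_ryr(ca_jsr)
    ko_eff = k_open * _hill_open(ca_subsr, km)
    if ko_eff == 0.0:
        return 0.0
    return ko_eff / (ko_eff + k_close)
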