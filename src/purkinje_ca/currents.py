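"""Membrane ionic current set for the mouse Purkinje cell.

Hodgkin–Huxley formulations of the currents carried by the non-T-tubulated
Purkinje sarcolemma: fast and late Na⁺ (I_Na, I_NaL), transient outward K⁺
(I_to), L- and T-type Ca²⁺ (I_CaL, I_CaT), inward rectifier and slow delayed
rectifier K⁺ (I_K1, I_Ks), Na⁺/K⁺ pump (I_NaK), Na⁺–Ca²⁺ exchanger (NCX) and
small background leaks (I_Cab, I_Nab).  Conventions: V in mV, t in ms,
currents in pA/pF (≡ µA/µF at 1 µF/cm²), outward positive.

Because the cell has no T-tubules, every Ca²⁺-sensing and Ca²⁺-carrying
current reads/feeds the sub-sarcolemmal (outermost) layer of the cytosolic
grid: I_CaL Ca-dependent inactivation and NCX sense sub-SL [Ca²⁺], and the
summed Ca²⁺-carrying current is deposited there as a mass source (charge ↔
mass consistent by construction).

Maximal conductances are configuration parameters with defaults calibrated
so the control model paced at 1 Hz reproduces the reference AP and Ca
transient morphology (see the methods note).  A multiplicative modifier
stack implements β-adrenergic (isoproterenol) scaling and fractional
channel blockade; modifiers compose, and isoproterenol application is
guarded against double application.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GATE_NAMES",
    "CURRENT_NAMES",
    "IonicParams",
    "apply_isoproterenol",
    "apply_blockade",
    "membrane_rhs",
    "gate_inf_tau",
    "compute_currents",
]

GATE_NAMES = ("m", "h", "j", "hl", "r", "s", "d", "f", "b", "g", "xs")
N_GATES = len(GATE_NAMES)

CURRENT_NAMES = (
    "i_na",
    "i_nal",
    "i_to",
    "i_cal",
    "i_cat",
    "i_k1",
    "i_ks",
    "i_nak",
    "i_ncx",
    "i_cab",
    "i_nab",
)
N_CURRENTS = len(CURRENT_NAMES)

# physical constants
F_FARADAY = 96485.0  # C/mol
RTF = 26.712  # mV at 310 K

# fixed extracellular milieu (mM)
NA_O = 140.0
K_O = 5.4
CA_O = 1.8

# ordering of the effective-conductance vector handed to the jitted kernel
COND_NAMES = (
    "g_na",
    "g_nal",
    "g_to",
    "g_cal",
    "g_cat",
    "g_k1",
    "g_ks",
    "p_nak",
    "k_ncx",
    "g_cab",
    "g_nab",
    "e_cal",
    "e_cat",
    "km_fca",
    "km_ncx_act",
    "k1_vhalf",
    "k1_slope",
)

# channels the modifier stack may address ("serca" is consumed by the engine)
MODIFIABLE = (
    "g_na",
    "g_nal",
    "g_to",
    "g_cal",
    "g_cat",
    "g_k1",
    "g_ks",
    "p_nak",
    "k_ncx",
    "g_cab",
    "g_nab",
    "serca",
)

# aliases accepted by apply_blockade
BLOCKADE_ALIASES = {
    "CaL": "g_cal",
    "CaT": "g_cat",
    "NaK": "p_nak",
    "NCX": "k_ncx",
}

ISO_SCALINGS = {
    "g_cat": 2.15,  # +115%
    "g_cal": 2.0,  # +100%
    "p_nak": 1.35,  # +35%
    "g_ks": 1.8,  # +80%
    "serca": 1.2,  # +20%
    "g_k1": 0.8,  # −20%
}

_DEFAULT_BASE = {
    "g_na": 8.5,  # mS/µF
    "g_nal": 0.0085,
    "g_to": 0.05,
    "g_cal": 0.63,
    "g_cat": 0.178,
    "g_k1": 0.3,
    "g_ks": 0.13,
    "p_nak": 1.4,  # pA/pF
    "k_ncx": 200.0,  # pA/pF scaling of the exchanger
    "g_cab": 1e-5,
    "g_nab": 0.0018,
    "e_cal": 60.0,  # mV, effective reversal of the ohmic L-type formulation
    "e_cat": 45.0,
    "km_fca": 0.8,  # µM, Ca-dependent inactivation of I_CaL
    "km_ncx_act": 0.3,  # µM, allosteric Ca activation of NCX
    "k1_vhalf": -68.0,  # mV, rectification midpoint of I_K1
    "k1_slope": 0.2,  # 1/mV, rectification steepness of I_K1
}


@dataclass
class IonicParams:
    """Maximal conductances plus a multiplicative modifier stack.

    ``base`` holds native values; ``modifiers`` holds one accumulated factor
    per channel (default 1).  The effective value is ``base × factor``; a
    factor of 0 removes the current entirely.
    """

    base: dict = field(default_factory=lambda: dict(_DEFAULT_BASE))
    modifiers: dict = field(default_factory=lambda: {k: 1.0 for k in MODIFIABLE})
    isoproterenol_applied: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.base) - set(_DEFAULT_BASE)
        if unknown:
            raise ValueError(f"unknown conductance parameters: {sorted(unknown)}")
        for k, v in self.base.items():
            if k.startswith(("g_", "p_", "k_")) and v < 0:
                raise ValueError(f"conductance {k} must be non-negative")
        for k, v in self.modifiers.items():
            if k not in MODIFIABLE:
                raise ValueError(f"unknown modifier target: {k}")
            if v < 0:
                raise ValueError(f"modifier factor for {k} must be non-negative")
        # fill any missing base entries with defaults
        for k, v in _DEFAULT_BASE.items():
            self.base.setdefault(k, v)
        for k in MODIFIABLE:
            self.modifiers.setdefault(k, 1.0)

    def copy(self) -> "IonicParams":
        return IonicParams(
            base=dict(self.base),
            modifiers=dict(self.modifiers),
            isoproterenol_applied=self.isoproterenol_applied,
        )

    def effective(self, name: str) -> float:
        return self.base[name] * self.modifiers.get(name, 1.0)

    @property
    def serca_modifier(self) -> float:
        return self.modifiers["serca"]

    def cond_vector(self) -> np.ndarray:
        """Effective-parameter vector in :data:`COND_NAMES` order."""
        out = np.empty(len(COND_NAMES))
        for i, name in enumerate(COND_NAMES):
            out[i] = self.effective(name) if name in self.modifiers else self.base[name]
        return out


def apply_isoproterenol(params: IonicParams) -> IonicParams:
    """Return params with the β-adrenergic scalings applied.

    I_CaT ×2.15, I_CaL ×2.0, I_NaK ×1.35, I_Ks ×1.8, SERCA ×1.2, I_K1 ×0.8.
    Applying twice is rejected.
    """
    if params.isoproterenol_applied:
        raise ValueError("isoproterenol modifiers already applied")
    out = params.copy()
    for k, f in ISO_SCALINGS.items():
        out.modifiers[k] *= f
    out.isoproterenol_applied = True
    return out


def apply_blockade(params: IonicParams, channel: str, fraction: float) -> IonicParams:
    """Scale the named channel by ``(1 − fraction)``; composes with other modifiers."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("blockade fraction must lie in [0, 1]")
    key = BLOCKADE_ALIASES.get(channel, channel)
    if key not in MODIFIABLE:
        raise ValueError(f"unknown channel for blockade: {channel}")
    out = params.copy()
    out.modifiers[key] *= 1.0 - fraction
    return out


# ---------------------------------------------------------------------------
# gate kinetics
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def _gate_inf_tau(v: float, inf: np.ndarray, tau: np.ndarray) -> None:
    # I_Na activation m
    dv = v + 47.13
    if abs(dv) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-v / 11.0)
    inf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)
    # I_Na inactivation h, j
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp((80.0 + v) / -6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    inf[1] = ah / (ah + bh)
    tau[1] = 1.0 / (ah + bh)
    inf[2] = aj / (aj + bj)
    tau[2] = 1.0 / (aj + bj)
    # late Na inactivation hL (slow)
    inf[3] = 1.0 / (1.0 + math.exp((v + 91.0) / 6.1))
    tau[3] = 600.0
    # I_to activation r / inactivation s
    inf[4] = 1.0 / (1.0 + math.exp(-(v + 14.0) / 7.0))
    tau[4] = 0.8 + 2.2 * math.exp(-((v + 25.0) / 30.0) ** 2)
    inf[5] = 1.0 / (1.0 + math.exp((v + 45.2) / 5.7))
    tau[5] = 8.0 + 30.0 / (1.0 + math.exp((v + 35.0) / 8.0))
    # I_CaL activation d / voltage inactivation f
    inf[6] = 1.0 / (1.0 + math.exp(-(v + 10.0) / 6.24))
    tau[6] = 0.6 + 1.4 * math.exp(-((v + 15.0) / 18.0) ** 2)
    inf[7] = 1.0 / (1.0 + math.exp((v + 35.0) / 4.5))
    tau[7] = 3.0 + 6.0 * math.exp(-((v + 25.0) / 20.0) ** 2)
    # I_CaT activation b / inactivation g (low-voltage activated)
    inf[8] = 1.0 / (1.0 + math.exp(-(v + 53.0) / 5.0))
    tau[8] = 8.0 + 2.0 * math.exp(-((v + 50.0) / 18.0) ** 2)
    inf[9] = 1.0 / (1.0 + math.exp((v + 70.0) / 4.5))
    tau[9] = 4.0 + 90.0 / (1.0 + math.exp((v + 45.0) / 5.0))
    # I_Ks activation xs (rapidly activating, deactivates below -50 mV)
    inf[10] = 1.0 / (1.0 + math.exp(-(v + 35.0) / 6.0))
    tau[10] = 3.0 + 9.0 * math.exp(-((v + 10.0) / 25.0) ** 2)


def gate_inf_tau(v: float) -> tuple[np.ndarray, np.ndarray]:
    """Steady states and time constants of all gates at potential ``v``."""
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    _gate_inf_tau(v, inf, tau)
    return inf, tau


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------


@njit(cache=True, error_model="numpy")
def _compute_currents(
    v: float,
    gates: np.ndarray,
    nai: float,
    ki: float,
    ca_sl_uM: float,
    cond: np.ndarray,
    out: np.ndarray,
) -> None:
    g_na = cond[0]
    g_nal = cond[1]
    g_to = cond[2]
    g_cal = cond[3]
    g_cat = cond[4]
    g_k1 = cond[5]
    g_ks = cond[6]
    p_nak = cond[7]
    k_ncx = cond[8]
    g_cab = cond[9]
    g_nab = cond[10]
    e_cal = cond[11]
    e_cat = cond[12]
    km_fca = cond[13]
    km_ncx_act = cond[14]
    k1_vhalf = cond[15]
    k1_slope = cond[16]

    e_na = RTF * math.log(NA_O / nai)
    e_k = RTF * math.log(K_O / ki)
    ca_mM = max(ca_sl_uM, 1e-6) * 1e-3
    e_ca = 0.5 * RTF * math.log(CA_O / ca_mM)

    m = gates[0]
    h = gates[1]
    j = gates[2]
    hl = gates[3]
    r = gates[4]
    s = gates[5]
    d = gates[6]
    f = gates[7]
    b = gates[8]
    g = gates[9]
    xs = gates[10]

    out[0] = g_na * m * m * m * h * j * (v - e_na)
    out[1] = g_nal * m * m * m * hl * (v - e_na)
    out[2] = g_to * r * s * (v - e_k)
    fca = 1.0 / (1.0 + (ca_sl_uM / km_fca) ** 2)
    out[3] = g_cal * d * f * fca * (v - e_cal)
    out[4] = g_cat * b * g * (v - e_cat)
    out[5] = g_k1 * (v - e_k) / (1.0 + math.exp(k1_slope * (v - k1_vhalf)))
    out[6] = g_ks * xs * (v - e_k)
    sigma = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0365 * sigma * math.exp(-v / RTF)
    )
    out[7] = (
        p_nak
        * fnak
        * (K_O / (K_O + 1.5))
        * (nai ** 1.5 / (nai ** 1.5 + 10.0 ** 1.5))
    )
    ev1 = math.exp(0.35 * v / RTF)
    ev2 = math.exp(-0.65 * v / RTF)
    num = ev1 * nai ** 3 * CA_O - ev2 * NA_O ** 3 * ca_mM
    den = (87.5 ** 3 + NA_O ** 3) * (1.38 + CA_O) * (1.0 + 0.1 * ev2)
    # allosteric activation by sub-SL Ca: silences the exchanger at
    # diastolic Ca while leaving transient/wave-driven exchange intact
    act = ca_sl_uM * ca_sl_uM / (ca_sl_uM * ca_sl_uM + km_ncx_act * km_ncx_act)
    out[8] = k_ncx * act * num / den
    out[9] = g_cab * (v - e_ca)
    out[10] = g_nab * (v - e_na)


def compute_currents(
    v: float, gates: np.ndarray, nai: float, ki: float, ca_sl_uM: float, cond: np.ndarray
) -> np.ndarray:
    """All membrane currents (pA/pF, :data:`CURRENT_NAMES` order)."""
    out = np.empty(N_CURRENTS)
    _compute_currents(float(v), np.asarray(gates, float), nai, ki, ca_sl_uM, cond, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite membrane current at V={v}: {out}")
    return out


def membrane_rhs(state, grid, params: IonicParams, i_stim: float = 0.0):
    """dV/dt (mV/ms), gate derivatives, and the per-current breakdown.

    ``state`` is a :class:`~purkinje_ca.geometry.MembraneState`; Ca²⁺-sensing
    currents read the sub-SL layer mean of ``grid``.  Returns
    ``(dvdt, dgates, currents)``.
    """
    ca_sl = grid.subsl_mean()
    cond = params.cond_vector()
    cur = compute_currents(state.v, state.gates, state.nai, state.ki, ca_sl, cond)
    dvdt = -(cur.sum() + i_stim)
    inf, tau = gate_inf_tau(state.v)
    dgates = (inf - state.gates) / tau
    return dvdt, dgates, cur


def ca_current_to_flux(i_pApF: float, capacitance_pF: float, z: int = 2) -> float:
    """Convert a Ca-carrying membrane current to a molar flux into the cell.

    Returns µM·µm³/ms; positive = Ca entering the cytosol.  Inward current
    (negative ``i``) carrying Ca²⁺ in gives a positive flux.
    """
    return -i_pApF * capacitance_pF * 1e6 / (z * F_FARADAY)
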