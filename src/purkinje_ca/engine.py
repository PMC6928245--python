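"""Coupled stochastic integration engine.

Advances the full cell state — membrane potential and gates, bulk Na⁺/K⁺,
the (disc, layer) cytosolic Ca²⁺ grid, per-disc JSR/NSR, Monte-Carlo RyR
channel counts and the spontaneous-leak state — with operator splitting at
a fixed two-level time step: ``dt_fast`` (default 0.005 ms) around stimuli
and during upstrokes, ``dt_base`` (default 0.02 ms) otherwise.  All times
live on the integer ``dt_fast`` grid so the step sequence, the RNG stream
and the recording cadence are exactly reproducible for a given
(config, seed).

Within one step: membrane currents and gates (Rush–Larsen) → sarcolemmal
Ca²⁺ source into the sub-SL layer → per-disc RyR release / leak override /
SERCA uptake / passive SR leak / NSR→JSR refill → leak trigger evaluation →
cytosolic diffusion (explicit longitudinal, implicit radial).

A single numba RNG stream drives all stochastic draws; per-disc draws are
consumed in fixed disc order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .currents import (
    F_FARADAY,
    GATE_NAMES,
    IonicParams,
    _compute_currents,
    _gate_inf_tau,
)
from .geometry import CellGeometry
from .leak import LeakParams
from .ryr import _hill_open, _km_ryr
from .transport import DiffusionParams, SercaParams

__all__ = ["RyRParams", "NumericParams", "Model", "CellState", "SimulationTrace", "simulate"]

N_GATES = len(GATE_NAMES)


@dataclass(frozen=True)
class RyRParams:
    """Stochastic RyR population parameters (per disc)."""

    n_total: int = 10
    k_open: float = 1.8  # 1/ms
    k_close: float = 1.0  # 1/ms
    g_rel: float = 1.0  # µm³/ms, release conductance per disc

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if min(self.k_open, self.k_close) <= 0 or self.g_rel < 0:
            raise ValueError("rates must be positive")


@dataclass(frozen=True)
class NumericParams:
    dt_base: float = 0.02  # ms
    dt_fast: float = 0.005  # ms
    rec_dt: float = 0.1  # ms, trace sampling interval
    dvdt_fast_threshold: float = 3.0  # mV/ms; faster stepping above this
    stim_fast_window: float = 3.0  # ms of forced fast stepping after stimulus onset

    def __post_init__(self) -> None:
        ratio = self.dt_base / self.dt_fast
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("dt_base must be an integer multiple of dt_fast")
        stride = self.rec_dt / self.dt_base
        if abs(stride - round(stride)) > 1e-9 or stride < 1:
            raise ValueError("rec_dt must be an integer multiple of dt_base")


@dataclass
class Model:
    """Full parameterization of one simulation."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    ionic: IonicParams = field(default_factory=IonicParams)
    serca: SercaParams = field(default_factory=SercaParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    ryr: RyRParams = field(default_factory=RyRParams)
    leak: LeakParams = field(default_factory=LeakParams)
    numeric: NumericParams = field(default_factory=NumericParams)
    tau_tr: float = 500.0  # ms, NSR→JSR refill time constant
    g_sr_leak: float = 1e-4  # µm³/ms per disc, passive NSR→cytosol leak
    # conductance of a spontaneous (SOICR) release event: the stuck-open RyR
    # cluster drains the network SR directly while the leak is active
    g_scr: float = 8.0  # µm³/ms per disc
    # axial coupling of adjacent discs' NSR compartments (the SR forms a
    # continuous network along the cell), µm³/ms
    g_nsr_axial: float = 1.0

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items() if not isinstance(v, np.ndarray)}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CellState:
    """Complete dynamic state, suitable for chaining simulation stages."""

    v: float
    gates: np.ndarray
    nai: float
    ki: float
    ca: np.ndarray  # (n_discs, n_layers) µM
    ca_jsr: np.ndarray
    ca_nsr: np.ndarray
    n_open: np.ndarray  # int64 per disc
    leak_disc: int = -1
    leak_z: float = 0.0
    leak_t0: float = 0.0

    def copy(self) -> "CellState":
        return CellState(
            v=self.v,
            gates=self.gates.copy(),
            nai=self.nai,
            ki=self.ki,
            ca=self.ca.copy(),
            ca_jsr=self.ca_jsr.copy(),
            ca_nsr=self.ca_nsr.copy(),
            n_open=self.n_open.copy(),
            leak_disc=self.leak_disc,
            leak_z=self.leak_z,
            leak_t0=self.leak_t0,
        )


def default_initial_state(model: Model) -> CellState:
    """Initial condition near the 1 Hz paced steady state of the control model.

    Starting from these values a few prepacing beats suffice to wash out
    initial transients; a truly quiescent cell can be obtained by passing a
    custom :class:`CellState`.
    """
    from .currents import gate_inf_tau

    g = model.geometry
    v0 = -86.4
    inf, _ = gate_inf_tau(v0)
    return CellState(
        v=v0,
        gates=inf.copy(),
        nai=7.85,
        ki=140.15,
        ca=np.full((g.n_discs, g.n_layers), 0.44),
        ca_jsr=np.full(g.n_discs, 240.0),
        ca_nsr=np.full(g.n_discs, 600.0),
        n_open=np.zeros(g.n_discs, dtype=np.int64),
    )


@dataclass
class SimulationTrace:
    """Uniformly sampled time series plus event metadata from one run."""

    t: np.ndarray  # ms, relative to run start
    v: np.ndarray  # mV
    i_cal: np.ndarray  # pA/pF
    i_cat: np.ndarray
    i_ncx: np.ndarray
    ca_avg: np.ndarray  # volume-averaged cytosolic free Ca, µM
    ca_subsl: np.ndarray
    ca_subsr: np.ndarray
    ca_jsr: np.ndarray  # (n, n_discs)
    ca_nsr_mean: np.ndarray
    ryr_flux: np.ndarray  # (n, n_discs), µM·µm³/ms
    p_open_mean: np.ndarray
    leak_events: np.ndarray  # (k, 3): disc, t_onset, z
    stim_times: np.ndarray
    seed: int
    config_hash: str
    dt_rec: float

    def save(self, path: str) -> None:
        from .io import save_trace

        save_trace(self, path)


@njit(cache=True, error_model="numpy")
def _seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True, error_model="numpy")
def _run_kernel(
    y,  # float64[4]: v, nai, ki, dvdt_last
    gates,
    ca,
    jsr,
    nsr,
    nopen,
    leakst,  # float64[3]: disc(-1 inactive), z, t_onset (absolute ms)
    t0,
    n_fast_total,
    dt_fast,
    ratio,
    rec_stride,
    stim_starts,
    stim_amp,
    stim_dur,
    stim_fast_units,
    cond,
    ep,
    vol,
    grad,
    rec,  # (n_rec, 8 + 3*n_discs)
    leak_log,  # (max, 3)
    nleak,  # int64[1]
):
    n_discs, n_layers = ca.shape
    c_pF = ep[0]
    serca_vmax = ep[1]
    serca_km = ep[2]
    serca_hill = ep[3]
    tau_tr = ep[4]
    g_rel = ep[5]
    d_l = ep[6]
    hz = ep[7]
    k_open = ep[8]
    k_close = ep[9]
    n_ryr = int(ep[10])
    leak_on = ep[11] > 0.5
    leak_thr = ep[12]
    leak_mu = ep[13]
    leak_sigma = ep[14]
    leak_tau = ep[15]
    leak_floor = ep[16]
    v_jsr = ep[17]
    v_nsr = ep[18]
    ncl = int(ep[19])
    g_srleak = ep[20]
    conv_ion = ep[21]  # mM per (pA/pF · ms)
    dvdt_thr = ep[22]
    g_scr = ep[23]
    g_nsr_ax = ep[24]

    vcore = 0.0
    for k in range(ncl):
        vcore += vol[k]
    vtot = 0.0
    for k in range(n_layers):
        vtot += vol[k]
    v_subsl = vol[n_layers - 1] * n_discs
    ca_flux_conv = c_pF * 1e6 / F_FARADAY  # per-F units; /2 for divalent

    cur = np.empty(11)
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    jrel = np.empty(n_discs)
    rhs = np.empty(n_layers)
    lcol = np.empty(n_layers)

    # prefactored radial diffusion matrices for the two admissible dt values:
    # tri[0]=vol/dt, tri[1]=forward-elimination multipliers, tri[2]=1/diag
    tri_b = np.empty((3, n_layers))
    tri_f = np.empty((3, n_layers))
    for which in range(2):
        dtw = dt_fast * ratio if which == 0 else dt_fast
        tri = tri_b if which == 0 else tri_f
        for k in range(n_layers):
            tri[0, k] = vol[k] / dtw
        diag = np.empty(n_layers)
        for k in range(n_layers):
            diag[k] = vol[k] / dtw
        for k in range(n_layers - 1):
            diag[k] += grad[k]
            diag[k + 1] += grad[k]
        tri[1, 0] = 0.0
        for k in range(1, n_layers):
            w = -grad[k - 1] / diag[k - 1]
            diag[k] -= w * -grad[k - 1]
            tri[1, k] = w
        for k in range(n_layers):
            tri[2, k] = 1.0 / diag[k]

    n_stim = stim_starts.shape[0]
    stim_ptr = 0
    i = 0
    rec_idx = 0
    dt_base = dt_fast * ratio
    ok = 1

    while True:
        t = t0 + i * dt_fast
        if i % rec_stride == 0:
            # instantaneous RyR flux and open probability per disc
            for j in range(n_discs):
                if int(leakst[0]) == j:
                    p = leakst[1] * math.exp(-(t - leakst[2]) / leak_tau)
                    jrel[j] = g_rel * p * (jsr[j] - ca[j, 0]) + max(
                        g_scr * p * (nsr[j] - ca[j, 0]), 0.0
                    )
                else:
                    p = nopen[j] / n_ryr
                    jrel[j] = g_rel * p * (jsr[j] - ca[j, 0])
            casl = 0.0
            casr = 0.0
            caavg = 0.0
            for j in range(n_discs):
                casl += ca[j, n_layers - 1]
                casr += ca[j, 0]
                for k in range(n_layers):
                    caavg += ca[j, k] * vol[k]
            casl /= n_discs
            casr /= n_discs
            caavg /= vtot * n_discs
            _compute_currents(y[0], gates, y[1], y[2], casl, cond, cur)
            rec[rec_idx, 0] = y[0]
            rec[rec_idx, 1] = cur[3]
            rec[rec_idx, 2] = cur[4]
            rec[rec_idx, 3] = cur[8]
            rec[rec_idx, 4] = caavg
            rec[rec_idx, 5] = casl
            rec[rec_idx, 6] = casr
            nsrm = 0.0
            pom = 0.0
            for j in range(n_discs):
                nsrm += nsr[j]
                if int(leakst[0]) == j:
                    pom += leakst[1] * math.exp(-(t - leakst[2]) / leak_tau)
                else:
                    pom += nopen[j] / n_ryr
                rec[rec_idx, 8 + j] = jsr[j]
                rec[rec_idx, 8 + n_discs + j] = jrel[j]
            rec[rec_idx, 7] = nsrm / n_discs
            pom /= n_discs
            rec[rec_idx, 8 + 2 * n_discs] = pom
            rec_idx += 1
        if i >= n_fast_total:
            break

        # advance the stimulus pointer
        while stim_ptr < n_stim and t >= stim_starts[stim_ptr] + stim_dur:
            stim_ptr += 1
        in_stim = stim_ptr < n_stim and stim_starts[stim_ptr] <= t < stim_starts[stim_ptr] + stim_dur
        near_stim = (
            stim_ptr < n_stim
            and stim_starts[stim_ptr] - dt_base <= t < stim_starts[stim_ptr] + stim_fast_units * dt_fast
        )

        fast = in_stim or near_stim or abs(y[3]) > dvdt_thr
        if (not fast) and i % ratio == 0 and i + ratio <= n_fast_total:
            dt = dt_base
            di = ratio
        else:
            dt = dt_fast
            di = 1

        # --- membrane ---
        casl = 0.0
        for j in range(n_discs):
            casl += ca[j, n_layers - 1]
        casl /= n_discs
        _compute_currents(y[0], gates, y[1], y[2], casl, cond, cur)
        istim = stim_amp if in_stim else 0.0
        isum = istim
        for q in range(11):
            isum += cur[q]
        dvdt = -isum
        _gate_inf_tau(y[0], inf, tau)
        for q in range(N_GATES):
            gates[q] = inf[q] + (gates[q] - inf[q]) * math.exp(-dt / tau[q])
        y[0] += dt * dvdt
        y[3] = dvdt
        y[1] += dt * conv_ion * -(cur[0] + cur[1] + cur[10] + 3.0 * cur[7] + 3.0 * cur[8])
        y[2] += dt * conv_ion * -(cur[2] + cur[5] + cur[6] - 2.0 * cur[7] + istim)

        # --- sarcolemmal Ca source into sub-SL layer ---
        flux_in = ca_flux_conv * (-(cur[3] + cur[4] + cur[9]) * 0.5 + cur[8])
        dca_sl = dt * flux_in / v_subsl
        for j in range(n_discs):
            ca[j, n_layers - 1] += dca_sl
            if ca[j, n_layers - 1] < 0.0:
                ca[j, n_layers - 1] = 0.0

        # --- per-disc SR fluxes and RyR gating ---
        # leak deactivation check
        ld = int(leakst[0])
        if ld >= 0:
            p_now = leakst[1] * math.exp(-(t - leakst[2]) / leak_tau)
            if p_now < leak_floor * leakst[1]:
                np_round = int(p_now * n_ryr + 0.5)
                nopen[ld] = np_round
                leakst[0] = -1.0
                ld = -1

        for j in range(n_discs):
            casr_j = ca[j, 0]
            scr = 0.0
            if j == ld:
                p = leakst[1] * math.exp(-(t - leakst[2]) / leak_tau)
                scr = g_scr * p * (nsr[j] - casr_j)
                if scr < 0.0:
                    scr = 0.0
            else:
                p = nopen[j] / n_ryr
            rel = g_rel * p * (jsr[j] - casr_j)
            # SERCA from the core coupling region
            cmass = 0.0
            for k in range(ncl):
                cmass += ca[j, k] * vol[k]
            ca_core = cmass / vcore
            if ca_core > 0.0:
                x = ca_core ** serca_hill
                up = serca_vmax * x / (x + serca_km ** serca_hill)
            else:
                up = 0.0
            take = dt * up
            if take > cmass:
                take = cmass
            if cmass > 0.0:
                fac = 1.0 - take / cmass
                for k in range(ncl):
                    ca[j, k] *= fac
            # passive NSR leak into the core
            psl = dt * g_srleak * (nsr[j] - ca_core)
            # RyR release deposit (uniform over the core region)
            dep = dt * rel + psl + dt * scr
            dca = dep / vcore
            for k in range(ncl):
                ca[j, k] += dca
                if ca[j, k] < 0.0:
                    ca[j, k] = 0.0
            jsr[j] -= dt * rel / v_jsr
            if jsr[j] < 0.0:
                jsr[j] = 0.0
            nsr[j] += (take - psl - dt * scr) / v_nsr
            # NSR → JSR refill
            mtr = (nsr[j] - jsr[j]) * (v_jsr / tau_tr) * dt
            jsr[j] += mtr / v_jsr
            nsr[j] -= mtr / v_nsr
            # Monte-Carlo gating (suspended on the leaking disc)
            if j != ld:
                km = _km_ryr(jsr[j])
                hill = _hill_open(max(casr_j, 0.0), km)
                worst = max(k_open * hill, k_close) * n_ryr * dt
                n_sub = 1
                while worst / n_sub > 1.0:
                    n_sub *= 2
                h = dt / n_sub
                no = nopen[j]
                for _ in range(n_sub):
                    pt_o = k_open * hill * (n_ryr - no) * h
                    pt_c = k_close * no * h
                    u = np.random.random()
                    if u < pt_o:
                        if no < n_ryr:
                            no += 1
                    elif u < pt_o + pt_c:
                        if no > 0:
                            no -= 1
                nopen[j] = no

        # --- axial NSR exchange between adjacent discs ---
        if n_discs > 1 and g_nsr_ax > 0.0:
            prev = nsr[0]
            for j in range(n_discs - 1):
                fl = dt * g_nsr_ax * (nsr[j + 1] - prev)
                prev = nsr[j + 1]
                nsr[j] += fl / v_nsr
                nsr[j + 1] -= fl / v_nsr

        # --- leak trigger (one evaluation per step, all discs) ---
        if leak_on and int(leakst[0]) < 0:
            best = -1
            bestprod = leak_thr
            for j in range(n_discs):
                # Y ≤ 1, so discs below threshold can never fire; skip their draw
                if jsr[j] <= leak_thr:
                    continue
                yd = np.random.random()
                prod = yd * jsr[j]
                if prod > bestprod:
                    bestprod = prod
                    best = j
            if best >= 0:
                z = np.random.lognormal(leak_mu, leak_sigma)
                if z > 1.0:
                    z = 1.0
                leakst[0] = best
                leakst[1] = z
                leakst[2] = t + dt
                if nleak[0] < leak_log.shape[0]:
                    leak_log[nleak[0], 0] = best
                    leak_log[nleak[0], 1] = t + dt
                    leak_log[nleak[0], 2] = z
                nleak[0] += 1

        # --- diffusion ---
        if n_discs > 1:
            r_l = dt * d_l / (hz * hz)  # per-volume exchange factor, same all layers
            for k in range(n_layers):
                lcol[k] = ca[0, k]
            for j in range(n_discs - 1):
                for k in range(n_layers):
                    dq = r_l * (ca[j + 1, k] - lcol[k])
                    lcol[k] = ca[j + 1, k]
                    ca[j, k] += dq
                    ca[j + 1, k] -= dq
        tri = tri_b if di == ratio else tri_f
        for j in range(n_discs):
            rhs[0] = tri[0, 0] * ca[j, 0]
            for k in range(1, n_layers):
                rhs[k] = tri[0, k] * ca[j, k] - tri[1, k] * rhs[k - 1]
            ca[j, n_layers - 1] = rhs[n_layers - 1] * tri[2, n_layers - 1]
            for k in range(n_layers - 2, -1, -1):
                ca[j, k] = (rhs[k] + grad[k] * ca[j, k + 1]) * tri[2, k]

        i += di
        if i % 4000 == 0:
            finite = math.isfinite(y[0]) and -250.0 < y[0] < 250.0
            if finite:
                for j in range(n_discs):
                    if not (math.isfinite(ca[j, 0]) and math.isfinite(jsr[j])):
                        finite = False
                        break
            if not finite:
                ok = 0
                break
    return ok


def _engine_params(model: Model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = model.geometry
    edges = g.radial_edges
    dr = edges[1] - edges[0]
    hz = g.disc_height
    vol = g.layer_volumes[0].astype(float)
    grad = model.diffusion.d_radial * (2.0 * np.pi * edges[1:-1] * hz) / dr
    v_cyto_L = g.total_volume * 1e-15
    conv_ion = g.capacitance_pF * 1e-15 / F_FARADAY / v_cyto_L * 1e3
    lk = model.leak
    ep = np.array(
        [
            g.capacitance_pF,
            model.serca.vmax * model.serca.modifier * model.ionic.serca_modifier,
            model.serca.km,
            model.serca.hill,
            model.tau_tr,
            model.ryr.g_rel,
            model.diffusion.d_longitudinal,
            hz,
            model.ryr.k_open,
            model.ryr.k_close,
            float(model.ryr.n_total),
            1.0 if lk.enabled else 0.0,
            lk.threshold,
            lk.mu,
            lk.sigma,
            lk.tau,
            lk.floor_fraction,
            g.jsr_volume,
            g.nsr_volume,
            float(g.n_core_coupling_layers),
            model.g_sr_leak,
            conv_ion,
            model.numeric.dvdt_fast_threshold,
            model.g_scr,
            model.g_nsr_axial,
        ]
    )
    return ep, vol, grad


def simulate(
    model: Model,
    t_total: float,
    stim_times: np.ndarray,
    seed: int,
    initial_state: Optional[CellState] = None,
    stim_amplitude: float = -80.0,
    stim_duration: float = 0.5,
    t_offset: float = 0.0,
) -> tuple[SimulationTrace, CellState]:
    """Run one simulation stage of ``t_total`` ms.

    ``stim_times`` are onset times in ms (run-local); they are snapped to the
    ``dt_base`` grid.  Returns the recorded trace and the final state, which
    can seed a subsequent stage.  Deterministic for fixed (model, seed,
    initial_state).
    """
    num = model.numeric
    dt_fast = num.dt_fast
    ratio = int(round(num.dt_base / num.dt_fast))
    rec_stride = int(round(num.rec_dt / num.dt_fast))
    n_fast_total = int(round(t_total / dt_fast))
    n_rec = n_fast_total // rec_stride + 1

    state = (initial_state or default_initial_state(model)).copy()
    if state.leak_disc >= 0 and state.leak_t0 > t_offset:
        # an active leak carried across stages must keep a monotonic clock;
        # if the caller restarted time, re-anchor the onset at the stage start
        state.leak_t0 = t_offset
    g = model.geometry
    cond = model.ionic.cond_vector()
    ep, vol, grad = _engine_params(model)

    stim = np.asarray(stim_times, dtype=float)
    stim = np.round(stim / num.dt_base) * num.dt_base + t_offset

    rec = np.empty((n_rec, 9 + 2 * g.n_discs))
    leak_log = np.zeros((100000, 3))
    nleak = np.zeros(1, dtype=np.int64)
    y = np.array([state.v, state.nai, state.ki, 0.0])
    leakst = np.array([float(state.leak_disc), state.leak_z, state.leak_t0])

    _seed_rng(int(seed) % (2**31 - 1))
    ok = _run_kernel(
        y,
        state.gates,
        state.ca,
        state.ca_jsr,
        state.ca_nsr,
        state.n_open,
        leakst,
        t_offset,
        n_fast_total,
        dt_fast,
        ratio,
        rec_stride,
        stim,
        stim_amplitude,
        stim_duration,
        float(num.stim_fast_window / dt_fast),
        cond,
        ep,
        vol,
        grad,
        rec,
        leak_log,
        nleak,
    )
    if not ok:
        raise FloatingPointError(
            f"numerical blow-up: V left [-250, 250] mV (last V={y[0]:.3g} mV, "
            f"Nai={y[1]:.3g}, Ki={y[2]:.3g})"
        )

    state.v = y[0]
    state.nai = y[1]
    state.ki = y[2]
    state.leak_disc = int(leakst[0])
    state.leak_z = leakst[1]
    state.leak_t0 = leakst[2]

    nd = g.n_discs
    k = min(int(nleak[0]), leak_log.shape[0])
    trace = SimulationTrace(
        t=np.arange(n_rec) * num.rec_dt + t_offset,
        v=rec[:, 0].copy(),
        i_cal=rec[:, 1].copy(),
        i_cat=rec[:, 2].copy(),
        i_ncx=rec[:, 3].copy(),
        ca_avg=rec[:, 4].copy(),
        ca_subsl=rec[:, 5].copy(),
        ca_subsr=rec[:, 6].copy(),
        ca_nsr_mean=rec[:, 7].copy(),
        ca_jsr=rec[:, 8 : 8 + nd].copy(),
        ryr_flux=rec[:, 8 + nd : 8 + 2 * nd].copy(),
        p_open_mean=rec[:, 8 + 2 * nd].copy(),
        leak_events=leak_log[:k].copy(),
        stim_times=stim,
        seed=int(seed),
        config_hash=model.config_hash(),
        dt_rec=num.rec_dt,
    )
    return trace, state
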