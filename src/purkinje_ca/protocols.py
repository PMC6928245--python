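"""Stimulation protocols and experiment drivers.

Protocols chain simulation stages with a continuous clock: optional
steady-state prepacing, a pacing or burst-pacing phase, and a quiescent
observation window.  Each driver is deterministic for a given (model
configuration, seed); replicate batches derive per-replicate seeds from a
base seed.

Time convention for analysis follows the burst experiments: time 0 of the
observation window is the onset of the last paced beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .analysis import (
    EventRecord,
    detect_events,
    detect_sparks_iterative,
    detect_sparks_simple,
    spark_frequency,
)
from .currents import apply_blockade, apply_isoproterenol
from .engine import CellState, Model, SimulationTrace, simulate

__all__ = [
    "StimulusProtocol",
    "CPVTResult",
    "run_simulation",
    "run_cpvt_experiment",
    "blockade_sweep",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Pacing parameters.

    ``prepace_time`` is the scaled-down steady-state pacing phase (the full
    experimental protocol paces for minutes; see the methods note).
    """

    amplitude: float = -80.0  # µA/µF
    duration: float = 0.5  # ms
    frequency: float = 1.0  # Hz
    prepace_time: float = 15.0  # s
    burst_time: float = 5.0  # s
    observe_time: float = 15.0  # s
    first_stimulus: float = 50.0  # ms into the run

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.duration >= self.period:
            raise ValueError("stimulus duration must be shorter than the period")

    @property
    def period(self) -> float:
        """Pacing period in ms."""
        return 1000.0 / self.frequency

    def stim_times(self, t_total: float, start: float = None) -> np.ndarray:
        if start is None:
            start = self.first_stimulus
        return np.arange(start, t_total, self.period)


def run_simulation(
    protocol: StimulusProtocol,
    model: Model,
    seed: int,
    t_total: float,
    initial_state: Optional[CellState] = None,
) -> tuple[SimulationTrace, CellState]:
    """Single paced run of ``t_total`` ms at the protocol's frequency."""
    stim = protocol.stim_times(t_total)
    return simulate(
        model,
        t_total,
        stim,
        seed=seed,
        initial_state=initial_state,
        stim_amplitude=protocol.amplitude,
        stim_duration=protocol.duration,
    )


@dataclass
class CPVTResult:
    """Outcome of one burst-pacing experiment."""

    burst_trace: SimulationTrace
    observe_trace: SimulationTrace
    events: EventRecord
    sparks: list
    spark_freq: float  # per 100 µm per s
    t_last_paced: float  # absolute ms; time 0 of the observation window


def run_cpvt_experiment(
    model: Model,
    seed: int,
    freq: float = 5.0,
    iso: bool = False,
    burst_time: float = 5.0,
    observe_time: float = 15.0,
    prepace_time: float = 2.0,
    stim_amplitude: float = -80.0,
    stim_duration: float = 0.5,
) -> CPVTResult:
    """Burst-pace a CPVT-phenotype cell and analyze the post-pacing window.

    ``prepace_time`` seconds of 1 Hz pacing, ``burst_time`` seconds of burst
    pacing at ``freq`` Hz, then ``observe_time`` seconds without stimuli.
    DADs/triggered APs are detected on the observation voltage; sparks on
    the per-disc RyR flux with the simple detector (control) or the
    iterative two-SD detector (isoproterenol).
    """
    if not model.leak.enabled:
        raise ValueError("CPVT experiment requires the spontaneous-leak model enabled")
    m = model
    if iso and not m.ionic.isoproterenol_applied:
        m = replace(model, ionic=apply_isoproterenol(model.ionic))

    t = 0.0
    state = None
    if prepace_time > 0:
        pre_ms = prepace_time * 1000.0
        stim = np.arange(50.0, pre_ms, 1000.0)
        _, state = simulate(
            m, pre_ms, stim, seed=seed, initial_state=state,
            stim_amplitude=stim_amplitude, stim_duration=stim_duration, t_offset=t,
        )
        t += pre_ms
    burst_ms = burst_time * 1000.0
    period = 1000.0 / freq
    burst_stim = np.arange(t, t + burst_ms, period)
    tr_burst, state = simulate(
        m, burst_ms, burst_stim - t + 0.0, seed=seed + 10_000, initial_state=state,
        stim_amplitude=stim_amplitude, stim_duration=stim_duration, t_offset=t,
    )
    t_last = float(burst_stim[-1])
    t += burst_ms
    obs_ms = observe_time * 1000.0
    tr_obs, state = simulate(
        m, obs_ms, np.array([]), seed=seed + 20_000, initial_state=state,
        stim_amplitude=stim_amplitude, stim_duration=stim_duration, t_offset=t,
    )
    events = detect_events(
        tr_obs.v, tr_obs.t, (tr_obs.t[0], tr_obs.t[-1]), stim_times=np.array([])
    )
    detector = detect_sparks_iterative if iso else detect_sparks_simple
    sparks = detector(tr_obs.ryr_flux, tr_obs.t)
    freq_sparks = spark_frequency(sparks, m.geometry.length, observe_time)
    return CPVTResult(
        burst_trace=tr_burst,
        observe_trace=tr_obs,
        events=events,
        sparks=sparks,
        spark_freq=freq_sparks,
        t_last_paced=t_last,
    )


def blockade_sweep(
    model: Model,
    channel: str,
    seeds: list[int],
    fractions: Optional[np.ndarray] = None,
    freq: float = 5.0,
    prepace_time: float = 2.0,
    observe_time: float = 15.0,
) -> list[dict]:
    """Burst experiments across blockade fractions of one channel.

    All runs include isoproterenol (the blockade study is performed on the
    β-adrenergically stimulated CPVT model).  Returns one record per
    fraction with per-seed triggered-AP/DAD counts and spark frequencies.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.01, 0.1), 2)
    iso_params = (
        model.ionic
        if model.ionic.isoproterenol_applied
        else apply_isoproterenol(model.ionic)
    )
    out = []
    for frac in fractions:
        params = apply_blockade(iso_params, channel, float(frac))
        m = replace(model, ionic=params)
        trig, dads, freqs = [], [], []
        for s in seeds:
            res = run_cpvt_experiment(
                m, seed=int(s), freq=freq, iso=False,  # modifiers already applied
                prepace_time=prepace_time, observe_time=observe_time,
            )
            trig.append(res.events.n_triggered)
            dads.append(res.events.n_dads)
            freqs.append(res.spark_freq)
        out.append(
            {
                "channel": channel,
                "fraction": float(frac),
                "triggered": trig,
                "dads": dads,
                "spark_freq": freqs,
                "triggered_mean": float(np.mean(trig)),
                "dad_mean": float(np.mean(dads)),
                "spark_freq_mean": float(np.mean(freqs)),
            }
        )
    return out
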